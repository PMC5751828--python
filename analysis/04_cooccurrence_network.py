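#!/usr/bin/env python
"""Ensemble cross-site co-occurrence / co-exclusion network.

Scores every NS-genus x NPA-genus pair with four metrics, keeps edges
significant for at least two of them with a unanimous sign, and writes the
edge list (results/network_edges.tsv) plus GraphML.
"""

import argparse
from pathlib import Path

import networkx as nx

from nichepair import io as npio
from nichepair.conet import build_consensus_network
from nichepair.datamodel import to_relative_abundance, top_genera_union
from nichepair.pipeline import stage_seed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = npio.read_paired_cohort(
        args.cohort / "ns_abundance.tsv", args.cohort / "npa_abundance.tsv",
        args.cohort / "metadata.csv")
    rel = cohort.with_tables(to_relative_abundance(cohort.ns_table),
                             to_relative_abundance(cohort.npa_table))
    top, _ = top_genera_union(rel.ns_table, rel.npa_table, 10)

    net = build_consensus_network(rel, genera=top, n_null=1000,
                                  seed=stage_seed(args.seed, "network"))
    net.edge_frame().to_csv(args.out / "network_edges.tsv", sep="\t", index=False)
    nx.write_graphml(net.to_networkx(), args.out / "network.graphml")

    same = [e["source"][1] for e in net.edges
            if e["source"][1] == e["target"][1] and e["sign"] == "co-occurrence"]
    print(f"{len(net.edges)} consensus edges from {net.n_evaluated} pairs "
          f"({len(net.sign_conflicts)} sign conflicts dropped)")
    print(f"same-genus co-occurrence across sites: {', '.join(sorted(same))}")


if __name__ == "__main__":
    main()
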