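#!/usr/bin/env python
"""Richness, Shannon diversity and genus-abundance summaries by sample type.

Reads the simulated cohort from results/cohort/ and writes per-site alpha
diversity plus the mean/SD relative abundance of the top genera
(results/diversity_summary.csv) — the cohort-description table of the
analysis.
"""

import argparse
from pathlib import Path

import pandas as pd

from nichepair import io as npio
from nichepair.datamodel import to_relative_abundance, top_genera_union
from nichepair.diversity import alpha_diversity


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = npio.read_paired_cohort(
        args.cohort / "ns_abundance.tsv", args.cohort / "npa_abundance.tsv",
        args.cohort / "metadata.csv")
    ns = to_relative_abundance(cohort.ns_table)
    npa = to_relative_abundance(cohort.npa_table)
    top, _ = top_genera_union(ns, npa, 10)

    rows = []
    for name, tbl in (("NS", ns), ("NPA", npa)):
        alpha = alpha_diversity(tbl)
        alpha.to_csv(args.out / f"alpha_{name.lower()}.csv")
        for genus in top:
            rows.append({
                "site": name, "genus": genus,
                "mean_abundance": tbl.data[genus].mean(),
                "sd_abundance": tbl.data[genus].std(),
            })
        print(f"{name}: median richness {alpha['richness'].median():.0f}, "
              f"median Shannon {alpha['shannon'].median():.2f} nats")
    pd.DataFrame(rows).to_csv(args.out / "diversity_summary.csv", index=False)
    print(f"top genera (union of per-site top 10): {', '.join(top)}")


if __name__ == "__main__":
    main()
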