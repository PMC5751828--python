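"""End-to-end orchestration: simulate/ingest -> diversity -> concordance ->
network -> profiling -> severity, with deterministic per-stage seeding.

Every random stage derives its own substream from the master seed and the
stage name, so re-running one stage can never perturb another.  The run
configuration is serialized verbatim into the output directory together
with a hash, which lets a re-run with an identical configuration reuse the
simulated inputs instead of regenerating them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as npio
from .concordance import cross_site_matrix, pairing_permutation_test
from .conet import build_consensus_network
from .datamodel import (
    PairedCohort,
    PhyloTree,
    ValidationError,
    to_relative_abundance,
    top_genera_union,
)
from .diversity import alpha_diversity
from .profiling import cluster_composite, cluster_site_profiles
from .severity import SeverityModelSpec, crude_or, fit_glmm_logistic, fit_logistic, profile_outcome_tables
from .synthetic import CohortSpec, generate_cohort, generate_random_tree

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed, independent of stage order."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Either ``simulate=True`` (inputs generated from ``cohort_spec``) or
    explicit input paths.  Stage toggles switch the analysis stages; all
    tunables are explicit so the configuration file fully determines the
    run.
    """

    out_dir: str = "nichepair_run"
    seed: int = 0
    simulate: bool = True
    n_subjects: int = 815
    ns_path: str | None = None
    npa_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    stages: tuple[str, ...] = (
        "diversity", "concordance", "network", "profiling", "severity"
    )
    n_top: int = 10
    min_prevalence: float = 0.10
    alpha: float = 0.05
    min_support: int = 2
    n_perm: int = 10_000
    n_null: int = 1000
    composite_k: int = 10
    ns_profile_k: int = 6
    dominance_threshold: float = 0.40
    los_threshold: int = 5
    reference_profile: str = "Moraxella-dominant"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output path excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the summary dictionary.

    Artifacts land under ``config.out_dir`` in one subdirectory per stage;
    the summary is also written as ``summary.json``.
    """
    if not config.stages:
        raise ValidationError("no stages enabled")
    known = {"diversity", "concordance", "network", "profiling", "severity"}
    unknown = set(config.stages) - known
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    inputs_dir = out / "inputs"
    hash_file = out / "config_hash.txt"
    summary: dict = {"config_hash": config.config_hash(), "stages": {}}

    # ---- ingest / simulate -------------------------------------------------
    cached = (
        hash_file.exists()
        and hash_file.read_text().strip() == config.config_hash()
        and (inputs_dir / "ns_abundance.tsv").exists()
    )
    if config.simulate:
        if cached:
            cohort = npio.read_paired_cohort(
                inputs_dir / "ns_abundance.tsv",
                inputs_dir / "npa_abundance.tsv",
                inputs_dir / "metadata.csv",
            )
            tree = npio.read_tree(inputs_dir / "tree.nwk")
            summary["inputs"] = {"source": "cache"}
        else:
            spec = CohortSpec(
                n_subjects=config.n_subjects,
                seed=stage_seed(config.seed, "simulate"),
            )
            cohort, truth = generate_cohort(spec)
            tree = generate_random_tree(list(cohort.ns_table.taxon_ids),
                                        stage_seed(config.seed, "tree"))
            inputs_dir.mkdir(exist_ok=True)
            npio.write_paired_cohort(cohort, inputs_dir)
            npio.write_tree(tree, inputs_dir / "tree.nwk")
            truth.to_csv(inputs_dir / "ground_truth.csv")
            summary["inputs"] = {"source": "simulated", "n_subjects": cohort.n_subjects}
    else:
        missing = [p for p in (config.ns_path, config.npa_path, config.metadata_path)
                   if p is None]
        if missing:
            raise ValidationError("ingest mode needs ns/npa/metadata paths")
        cohort = npio.read_paired_cohort(
            config.ns_path, config.npa_path, config.metadata_path
        )
        tree = npio.read_tree(config.tree_path) if config.tree_path else None
        summary["inputs"] = {"source": "files", "n_subjects": cohort.n_subjects}
    hash_file.write_text(config.config_hash() + "\n")

    rel = cohort.with_tables(
        to_relative_abundance(cohort.ns_table),
        to_relative_abundance(cohort.npa_table),
    )
    top_genera, truncated = top_genera_union(rel.ns_table, rel.npa_table, config.n_top)
    summary["top_genera"] = top_genera
    summary["top_genera_truncated"] = truncated

    # ---- diversity ---------------------------------------------------------
    if "diversity" in config.stages:
        ddir = out / "diversity"
        ddir.mkdir(exist_ok=True)
        stats = {}
        for tbl, name in ((rel.ns_table, "ns"), (rel.npa_table, "npa")):
            alpha = alpha_diversity(tbl)
            alpha.to_csv(ddir / f"alpha_{name}.csv")
            stats[name] = {
                "median_richness": float(alpha["richness"].median()),
                "median_shannon": float(alpha["shannon"].median()),
            }
        summary["stages"]["diversity"] = stats

    # ---- concordance -------------------------------------------------------
    if "concordance" in config.stages:
        cdir = out / "concordance"
        cdir.mkdir(exist_ok=True)
        rho = cross_site_matrix(rel, top_genera)
        rho.write_tsv(cdir / "cross_site_rho.tsv")
        perm = pairing_permutation_test(
            rel, top_genera, n_perm=config.n_perm,
            seed=stage_seed(config.seed, "concordance"),
        )
        _write_json(perm.to_dict(), cdir / "permutation_test.json")
        diag = {g: float(rho.rho.loc[g, g]) for g in top_genera
                if np.isfinite(rho.rho.loc[g, g])}
        summary["stages"]["concordance"] = {
            **perm.to_dict(),
            "max_diagonal_genus": max(diag, key=diag.get) if diag else None,
        }

    # ---- network -----------------------------------------------------------
    if "network" in config.stages:
        ndir = out / "network"
        ndir.mkdir(exist_ok=True)
        net = build_consensus_network(
            rel, genera=top_genera, alpha=config.alpha,
            min_support=config.min_support, n_null=config.n_null,
            seed=stage_seed(config.seed, "network"),
            min_prevalence=config.min_prevalence,
        )
        net.edge_frame().to_csv(ndir / "edges.tsv", sep="\t", index=False)
        import networkx as nx

        nx.write_graphml(net.to_networkx(), ndir / "network.graphml")
        summary["stages"]["network"] = {
            "n_edges": len(net.edges),
            "n_evaluated": net.n_evaluated,
            "n_sign_conflicts": len(net.sign_conflicts),
            "same_genus_cooccurrence": sorted(
                e["source"][1] for e in net.edges
                if e["source"][1] == e["target"][1] and e["sign"] == "co-occurrence"
            ),
        }

    # ---- profiling ---------------------------------------------------------
    clusters = None
    if "profiling" in config.stages or "severity" in config.stages:
        pdir = out / "profiling"
        pdir.mkdir(exist_ok=True)
        comp_res, comp_means = cluster_composite(rel, top_genera, k=config.composite_k)
        comp_res.assignment_frame().to_csv(pdir / "composite_assignments.csv")
        comp_means.to_csv(pdir / "composite_cluster_means.tsv", sep="\t")
        if tree is None:
            raise ValidationError("profiling requires a tree for weighted UniFrac")
        clusters = cluster_site_profiles(
            rel.ns_table, tree, k=config.ns_profile_k,
            dominance_threshold=config.dominance_threshold,
        )
        clusters.assignment_frame().to_csv(pdir / "ns_profile_assignments.csv")
        sizes = clusters.cluster_sizes()
        _write_json(
            {
                "composite_k": comp_res.k,
                "composite_silhouette": comp_res.avg_silhouette,
                "ns_k": clusters.k,
                "ns_silhouette": clusters.avg_silhouette,
                "ns_profile_names": {str(c): n for c, n in clusters.profile_names.items()},
                "ns_cluster_sizes": {str(c): s for c, s in sizes.items()},
            },
            pdir / "model_selection.json",
        )
        summary["stages"]["profiling"] = {
            "ns_profiles": {
                clusters.profile_names[c]: int(s) for c, s in sizes.items()
            },
            "ns_silhouette": clusters.avg_silhouette,
        }

    # ---- severity ----------------------------------------------------------
    if "severity" in config.stages:
        sdir = out / "severity"
        sdir.mkdir(exist_ok=True)
        rows = []
        profile_of = pd.Series(
            [clusters.profile_names[c] for c in clusters.labels],
            index=list(clusters.sample_ids),
        )
        present = set(profile_of)
        reference = config.reference_profile
        if reference not in present:
            # small cohorts may miss the configured reference; fall back to the
            # largest profile and record the substitution
            reference = profile_of.value_counts().index[0]
        summary["stages"]["severity_reference"] = reference
        for outcome in ("icu_use", "los_ge_days"):
            mspec = SeverityModelSpec(
                outcome=outcome,
                reference_profile=reference,
                random_intercept="site_id",
                los_threshold=config.los_threshold,
            )
            tables, n_missing = profile_outcome_tables(clusters, cohort, mspec)
            crude = {
                name: crude_or(t, correction="none" if min(t.a, t.b, t.c, t.d) > 0
                               else "haldane")
                for name, t in tables.items() if " vs all" not in name
            }
            adjusted, site_sd = fit_glmm_logistic(mspec, cohort, clusters)
            adj_by_term = {r.term: r for r in adjusted}
            for name, cr in sorted(crude.items()):
                adj = adj_by_term.get(f"profile[{name}]")
                rows.append({
                    "outcome": outcome,
                    "profile": name,
                    "crude_or": cr.odds_ratio,
                    "crude_ci_low": cr.ci_low,
                    "crude_ci_high": cr.ci_high,
                    "crude_p": cr.p_value,
                    "adjusted_or": adj.odds_ratio if adj else np.nan,
                    "adjusted_ci_low": adj.ci_low if adj else np.nan,
                    "adjusted_ci_high": adj.ci_high if adj else np.nan,
                    "adjusted_p": adj.p_value if adj else np.nan,
                    "site_sd": site_sd,
                    "n_missing_outcome": n_missing,
                })
        table4 = pd.DataFrame(rows)
        table4.to_csv(sdir / "severity_models.csv", index=False)
        summary["stages"]["severity"] = {
            r["outcome"] + "/" + r["profile"]: {
                "crude_or": r["crude_or"], "adjusted_or": r["adjusted_or"],
            }
            for r in rows
        }

    _write_json(summary, out / "summary.json")
    return summary
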