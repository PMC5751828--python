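"""Bipartite ensemble co-occurrence / co-exclusion network between sites.

Each candidate edge links an NS genus with an NPA genus and is scored by
four metrics across subjects: Spearman correlation, Pearson correlation,
Bray-Curtis dissimilarity and symmetrized Kullback-Leibler divergence.
Significance comes from a permutation null: the NPA genus profile is
shuffled across subjects and every metric is recomputed.  Because the two
ends of a cross-site pair live on *different* compositions (the NS and NPA
simplices), a plain shuffle is exchangeable with the observed pairing and
the resulting p-values are calibrated.  A renormalized variant
(``renormalize=True``) additionally re-closes each shuffled composition —
the correction that matters when both genera share one composition, i.e.
for within-site pairs.  An edge enters the consensus network when at least
``min_support`` metrics are significant at ``alpha`` with a unanimous
co-occurrence/co-exclusion call; its weight is the observed Spearman
correlation.

p-values use the add-one rule, two-sided around the null mean:
``p = (1 + #{|null - mean| >= |obs - mean|}) / (1 + n_null)``.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import AbundanceTable, PairedCohort, ValidationError

__all__ = [
    "METRICS",
    "EdgeCandidate",
    "ConsensusNetwork",
    "prevalence_filter",
    "metric_scores",
    "edge_significance",
    "build_consensus_network",
]

METRICS = ("spearman", "pearson", "braycurtis", "kld")

#: pseudocount added before the Kullback-Leibler renormalization
KLD_PSEUDOCOUNT = 1e-6


def prevalence_filter(table: AbundanceTable, min_frac: float = 0.10) -> list[str]:
    """Genera with nonzero abundance in at least ceil(min_frac * n) samples."""
    if not (0 < min_frac <= 1):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    need = math.ceil(min_frac * table.n_samples)
    nonzero = (table.matrix > 0).sum(axis=0)
    return [g for g, c in zip(table.taxon_ids, nonzero) if c >= need]


def _sym_kld(x: np.ndarray, y: np.ndarray, eps: float = KLD_PSEUDOCOUNT) -> float:
    """Symmetrized KL divergence of the pseudocounted, renormalized profiles."""
    xt = (x + eps) / (x + eps).sum()
    yt = (y + eps) / (y + eps).sum()
    return float(0.5 * ((xt - yt) * np.log(xt / yt)).sum())


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x.std()
    ys = y.std()
    if xs == 0 or ys == 0:
        return math.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (xs * ys))


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    return _pearson(rankdata(x), rankdata(y))


def _braycurtis(x: np.ndarray, y: np.ndarray) -> float:
    denom = (x + y).sum()
    if denom == 0:
        return math.nan
    return float(np.abs(x - y).sum() / denom)


def metric_scores(x, y) -> dict[str, float]:
    """Observed scores for all four metrics; undefined scores are NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length vectors")
    return {
        "spearman": _spearman(x, y),
        "pearson": _pearson(x, y),
        "braycurtis": _braycurtis(x, y),
        "kld": _sym_kld(x, y),
    }


def _null_scores(
    x: np.ndarray,
    y: np.ndarray,
    n_null: int,
    rng: np.random.Generator,
    renormalize: bool = False,
) -> dict[str, np.ndarray]:
    """Vectorized per-metric null scores under permutation of ``y``.

    With ``renormalize`` the shuffled value replaces the subject's own and
    the composition is re-closed, ``y~(s) = y(pi(s)) / (1 - y(s) + y(pi(s)))``
    (appropriate when x and y share one composition); without it the
    shuffled profile is used as-is (the exchangeable null for cross-site
    pairs).
    """
    n = len(y)
    perms = np.empty((n_null, n), dtype=np.intp)
    base = np.arange(n)
    for b in range(n_null):
        perms[b] = rng.permutation(base)
    y_perm = y[perms]
    if renormalize:
        denom = 1.0 - y[None, :] + y_perm
        denom[denom <= 0] = np.finfo(float).tiny
        y_null = y_perm / denom
    else:
        y_null = y_perm

    out: dict[str, np.ndarray] = {}
    # pearson
    xc = x - x.mean()
    xs = xc.std()
    yc = y_null - y_null.mean(axis=1, keepdims=True)
    ysd = y_null.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pearson"] = (yc @ xc) / n / np.where(ysd == 0, np.nan, ysd) / (xs or np.nan)
    # spearman: pearson on ranks
    xr = rankdata(x)
    xrc = xr - xr.mean()
    xrs = xrc.std()
    yr = rankdata(y_null, axis=1)
    yrc = yr - yr.mean(axis=1, keepdims=True)
    yrsd = yr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["spearman"] = (yrc @ xrc) / n / np.where(yrsd == 0, np.nan, yrsd) / (xrs or np.nan)
    # bray-curtis
    sums = (x[None, :] + y_null).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["braycurtis"] = np.abs(x[None, :] - y_null).sum(axis=1) / sums
    # symmetric KLD on pseudocounted profiles
    eps = KLD_PSEUDOCOUNT
    xt = (x + eps) / (x + eps).sum()
    yt = y_null + eps
    yt /= yt.sum(axis=1, keepdims=True)
    out["kld"] = 0.5 * ((xt[None, :] - yt) * np.log(xt[None, :] / yt)).sum(axis=1)
    return out


def _two_sided_p(observed: float, null: np.ndarray) -> float:
    null = null[np.isfinite(null)]
    if not np.isfinite(observed) or len(null) == 0:
        return math.nan
    # center on the pooled mean (observed included) so the observed draw is
    # exchangeable with the null draws and the p-value is level-valid
    mu = (null.sum() + observed) / (len(null) + 1)
    extreme = int((np.abs(null - mu) >= np.abs(observed - mu)).sum())
    return (1 + extreme) / (1 + len(null))


def edge_significance(
    x,
    y,
    n_null: int = 1000,
    seed: int = 0,
    renormalize: bool = False,
) -> tuple[dict[str, float], dict[str, str | None]]:
    """Per-metric two-sided permutation p-values and co-occurrence calls.

    Returns ``(p_values, signs)``; a metric whose score is undefined gets a
    NaN p-value and sign ``None``.  Correlations call co-occurrence when the
    observed value is positive; dissimilarities call co-occurrence when the
    observed value is below the null median (the profiles are closer than
    random pairings) and co-exclusion when above.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    observed = metric_scores(x, y)
    null = _null_scores(x, y, n_null, rng, renormalize=renormalize)
    p_values: dict[str, float] = {}
    signs: dict[str, str | None] = {}
    for m in METRICS:
        obs = observed[m]
        p_values[m] = _two_sided_p(obs, null[m])
        if not np.isfinite(obs):
            signs[m] = None
        elif m in ("spearman", "pearson"):
            signs[m] = "co-occurrence" if obs > 0 else "co-exclusion"
        else:
            med = float(np.nanmedian(null[m]))
            signs[m] = "co-occurrence" if obs < med else "co-exclusion"
    return p_values, signs


@dataclass(frozen=True)
class EdgeCandidate:
    """A scored NS-genus / NPA-genus pair."""

    source: tuple[str, str]  # ("NS", genus)
    target: tuple[str, str]  # ("NPA", genus)
    scores: dict[str, float]
    p_values: dict[str, float]
    sign_votes: dict[str, str | None]

    def significant_metrics(self, alpha: float) -> list[str]:
        return [
            m for m in METRICS
            if np.isfinite(self.p_values.get(m, math.nan)) and self.p_values[m] < alpha
        ]


@dataclass(frozen=True)
class ConsensusNetwork:
    """Retained edges plus audit trail of evaluated and conflicted pairs."""

    nodes: tuple[tuple[str, str], ...]
    edges: tuple[dict, ...]
    n_evaluated: int
    sign_conflicts: tuple[tuple[str, str], ...] = ()
    alpha: float = 0.05
    min_support: int = 2

    def edge_frame(self) -> pd.DataFrame:
        cols = ["source_site", "source_genus", "target_site", "target_genus",
                "sign", "weight", "n_supporting"] + [f"p_{m}" for m in METRICS]
        rows = []
        for e in self.edges:
            rows.append([
                e["source"][0], e["source"][1], e["target"][0], e["target"][1],
                e["sign"], e["weight"], e["n_supporting"],
                *[e["p_values"][m] for m in METRICS],
            ])
        return pd.DataFrame(rows, columns=cols)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for site, genus in self.nodes:
            g.add_node(f"{site}:{genus}", site=site, genus=genus)
        for e in self.edges:
            g.add_edge(
                f"{e['source'][0]}:{e['source'][1]}",
                f"{e['target'][0]}:{e['target'][1]}",
                sign=e["sign"],
                weight=float(e["weight"]),
                n_supporting=int(e["n_supporting"]),
            )
        return g

    def has_edge(self, ns_genus: str, npa_genus: str, sign: str | None = None) -> bool:
        for e in self.edges:
            if e["source"][1] == ns_genus and e["target"][1] == npa_genus:
                return sign is None or e["sign"] == sign
        return False


def _name_seed(seed: int, ns_genus: str, npa_genus: str) -> np.random.Generator:
    """Seed derived from the genus names so results do not depend on column order."""
    digest = hashlib.sha256(f"{ns_genus}\t{npa_genus}".encode()).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:8], "big")])


def build_consensus_network(
    cohort: PairedCohort,
    genera: list[str] | None = None,
    alpha: float = 0.05,
    min_support: int = 2,
    n_null: int = 1000,
    seed: int = 0,
    min_prevalence: float = 0.10,
    renormalize: bool = False,
) -> ConsensusNetwork:
    """Evaluate every cross-site genus pair and keep the consensus edges.

    Both site tables are filtered at ``min_prevalence`` first (optionally
    after restriction to ``genera``).  An edge needs ``min_support`` metrics
    with p < ``alpha`` and a unanimous sign among those significant metrics;
    pairs whose significant metrics disagree on the sign are dropped and
    recorded in ``sign_conflicts``.  Results are invariant to subject order
    (rows are canonicalized by subject id) and to genus column order
    (per-pair seeds derive from genus names).
    """
    ns = cohort.ns_table if genera is None else cohort.ns_table.restrict(genera)
    npa = cohort.npa_table if genera is None else cohort.npa_table.restrict(genera)
    ns_genera = prevalence_filter(ns, min_prevalence)
    npa_genera = prevalence_filter(npa, min_prevalence)
    nodes = [("NS", g) for g in ns_genera] + [("NPA", g) for g in npa_genera]
    if not ns_genera or not npa_genera:
        return ConsensusNetwork(tuple(nodes), (), 0, alpha=alpha, min_support=min_support)

    order = np.argsort(np.asarray(cohort.subjects))
    ns_mat = ns.data[ns_genera].to_numpy(dtype=float)[order]
    npa_mat = npa.data[npa_genera].to_numpy(dtype=float)[order]

    edges: list[dict] = []
    conflicts: list[tuple[str, str]] = []
    n_eval = 0
    for i, gi in enumerate(ns_genera):
        x = ns_mat[:, i]
        for j, gj in enumerate(npa_genera):
            y = npa_mat[:, j]
            n_eval += 1
            rng = _name_seed(seed, gi, gj)
            observed = metric_scores(x, y)
            null = _null_scores(x, y, n_null, rng, renormalize=renormalize)
            p_values = {m: _two_sided_p(observed[m], null[m]) for m in METRICS}
            signs: dict[str, str | None] = {}
            for m in METRICS:
                if not np.isfinite(observed[m]):
                    signs[m] = None
                elif m in ("spearman", "pearson"):
                    signs[m] = "co-occurrence" if observed[m] > 0 else "co-exclusion"
                else:
                    med = float(np.nanmedian(null[m]))
                    signs[m] = "co-occurrence" if observed[m] < med else "co-exclusion"
            cand = EdgeCandidate(("NS", gi), ("NPA", gj), observed, p_values, signs)
            sig = cand.significant_metrics(alpha)
            if len(sig) < min_support:
                continue
            votes = {signs[m] for m in sig}
            if len(votes) != 1:
                conflicts.append((gi, gj))
                continue
            edges.append({
                "source": ("NS", gi),
                "target": ("NPA", gj),
                "sign": votes.pop(),
                "weight": observed["spearman"],
                "n_supporting": len(sig),
                "p_values": p_values,
                "scores": observed,
            })
    return ConsensusNetwork(
        nodes=tuple(nodes),
        edges=tuple(edges),
        n_evaluated=n_eval,
        sign_conflicts=tuple(conflicts),
        alpha=alpha,
        min_support=min_support,
    )
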