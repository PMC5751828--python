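"""Intra-individual concordance between the two airway sites.

Two views of the same question: (i) a genus-by-genus cross-site Spearman
matrix — entry (i, j) correlates the NS abundance of genus i with the NPA
abundance of genus j across subjects; (ii) a permutation test on the mean
within-pair Spearman correlation, where each subject's NS and NPA top-genera
vectors are correlated and the null re-pairs NPA samples with subjects
uniformly at random.

The permutation test is exact in spirit: p = (1 + #{null >= observed}) /
(1 + n_perm), one-sided, so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .datamodel import AbundanceTable, PairedCohort, ValidationError

__all__ = [
    "CrossSiteCorrelation",
    "PermutationTestResult",
    "spearman",
    "cross_site_matrix",
    "pairing_permutation_test",
]


class ConstantVectorError(ValueError):
    """Spearman correlation is undefined when a vector is constant."""


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties).

    Raises :class:`ConstantVectorError` for a constant input so the caller
    can decide how to handle the undefined case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length vectors")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantVectorError("constant vector: correlation undefined")
    return float(spearmanr(x, y).statistic)


@dataclass(frozen=True)
class CrossSiteCorrelation:
    """Cross-site Spearman matrix over the top genera.

    ``rho.loc[g_ns, g_npa]`` is the correlation across subjects between NS
    abundance of ``g_ns`` and NPA abundance of ``g_npa``; the matrix is not
    symmetric because the two axes are different sample types.  Undefined
    entries (a constant genus on either side) are NaN and enumerated in
    ``undefined``.
    """

    genera: tuple[str, ...]
    rho: pd.DataFrame
    undefined: tuple[tuple[str, str], ...]

    def write_tsv(self, path) -> None:
        out = self.rho.copy()
        out.index.name = "ns_genus"
        out.to_csv(path, sep="\t")


def cross_site_matrix(cohort: PairedCohort, genera: list[str]) -> CrossSiteCorrelation:
    """Spearman correlations between NS and NPA abundances of the top genera."""
    if cohort.n_subjects < 3:
        raise ValidationError("need at least 3 paired subjects")
    ns = cohort.ns_table.restrict(genera).matrix
    npa = cohort.npa_table.restrict(genera).matrix
    g = len(genera)
    rho = np.full((g, g), np.nan)
    undefined: list[tuple[str, str]] = []
    ns_const = [np.all(ns[:, i] == ns[0, i]) for i in range(g)]
    npa_const = [np.all(npa[:, j] == npa[0, j]) for j in range(g)]
    # rank once per genus; Spearman = Pearson on ranks
    ns_r = rankdata(ns, axis=0)
    npa_r = rankdata(npa, axis=0)
    ns_z = (ns_r - ns_r.mean(axis=0)) / np.where(ns_r.std(axis=0) == 0, 1, ns_r.std(axis=0))
    npa_z = (npa_r - npa_r.mean(axis=0)) / np.where(npa_r.std(axis=0) == 0, 1, npa_r.std(axis=0))
    full = ns_z.T @ npa_z / ns.shape[0]
    for i in range(g):
        for j in range(g):
            if ns_const[i] or npa_const[j]:
                undefined.append((genera[i], genera[j]))
            else:
                rho[i, j] = full[i, j]
    frame = pd.DataFrame(rho, index=list(genera), columns=list(genera))
    return CrossSiteCorrelation(tuple(genera), frame, tuple(undefined))


@dataclass(frozen=True)
class PermutationTestResult:
    """Result of the paired-sample concordance permutation test."""

    observed_stat: float
    null_mean: float
    null_sd: float
    n_perm: int
    p_value: float
    seed: int
    n_dropped_pairs: int

    def to_dict(self) -> dict:
        return {
            "observed_mean_spearman": self.observed_stat,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "seed": self.seed,
            "n_dropped_pairs": self.n_dropped_pairs,
        }


def _standardized_ranks(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise standardized average ranks; flags rows that are constant."""
    r = rankdata(mat, axis=1)
    sd = r.std(axis=1)
    constant = sd == 0
    z = (r - r.mean(axis=1, keepdims=True)) / np.where(constant, 1.0, sd)[:, None]
    z[constant] = 0.0
    return z, constant


def pairing_permutation_test(
    cohort: PairedCohort,
    genera: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test on the mean within-pair Spearman correlation.

    The observed statistic averages, over subjects, the Spearman correlation
    between the subject's NS and NPA abundance vectors restricted to
    ``genera``.  Each permutation re-assigns the NPA samples to subjects by a
    uniform shuffle (fixed points allowed) and recomputes the statistic.
    Pairs where either vector is constant are dropped (counted in
    ``n_dropped_pairs``); the same rule applies within every permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if cohort.n_subjects < 10:
        raise ValidationError("need at least 10 paired subjects")
    ns = cohort.ns_table.restrict(genera).matrix
    npa = cohort.npa_table.restrict(genera).matrix
    g = len(genera)
    if g < 3:
        raise ValidationError("need at least 3 genera for within-pair correlation")

    ns_z, ns_const = _standardized_ranks(ns)
    npa_z, npa_const = _standardized_ranks(npa)
    # corr(i, j) between NS vector of subject i and NPA vector of subject j
    corr = ns_z @ npa_z.T / g
    valid = np.outer(~ns_const, ~npa_const)
    diag = np.diag_indices(len(corr))
    obs_mask = valid[diag]
    observed = float(corr[diag][obs_mask].mean())
    n_dropped = int((~obs_mask).sum())

    rng = np.random.default_rng(seed)
    n = len(corr)
    null = np.empty(n_perm)
    idx = np.arange(n)
    for b in range(n_perm):
        perm = rng.permutation(n)
        vals = corr[idx, perm]
        mask = valid[idx, perm]
        null[b] = vals[mask].mean()
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return PermutationTestResult(
        observed_stat=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        n_perm=n_perm,
        p_value=p,
        seed=seed,
        n_dropped_pairs=n_dropped,
    )
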