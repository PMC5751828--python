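"""Alpha- and beta-diversity: richness, Shannon index, Bray-Curtis, weighted UniFrac.

Shannon entropy is reported in nats.  Weighted UniFrac delegates to
scikit-bio and defaults to the normalized variant (values in [0, 1],
comparable across sequencing depths); ``normalized=False`` gives the raw
branch-length-weighted sum, which on a star tree with unit branch lengths
reduces to the Manhattan distance between proportion vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix as _SkbioDM
from skbio.diversity import beta_diversity

from .datamodel import (
    AbundanceTable,
    DegenerateSampleError,
    MappingError,
    PhyloTree,
    ValidationError,
)

#: integer rescaling factor applied before handing proportions to scikit-bio
_SCALE = 10 ** 9

__all__ = [
    "DiversityProfile",
    "DistanceMatrix",
    "richness",
    "shannon_index",
    "alpha_diversity",
    "bray_curtis",
    "weighted_unifrac",
    "distance_matrix",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample ids and a metric name."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("distance matrix must be square and match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(v < -1e-12):
            raise ValidationError("negative dissimilarity")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


def richness(p: np.ndarray) -> int:
    """Number of taxa with nonzero abundance."""
    return int(np.count_nonzero(np.asarray(p, dtype=float)))


def shannon_index(p) -> float:
    """Shannon entropy -sum(p ln p) in nats, with 0 ln 0 = 0.

    ``p`` must lie on the probability simplex (sum 1 within 1e-9).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValidationError("negative proportion")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"proportions sum to {p.sum():.12g}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample richness and Shannon index (nats) for a proportions table."""
    if table.mode != "proportions":
        raise ValidationError("alpha diversity expects a proportions table")
    rows = {
        sid: (richness(row), shannon_index(row))
        for sid, row in zip(table.sample_ids, table.matrix)
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["richness", "shannon"])


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("negative abundance")
    denom = (x + y).sum()
    if denom == 0:
        raise DegenerateSampleError("Bray-Curtis undefined for two all-zero vectors")
    return float(_scipy_braycurtis(x, y))


def weighted_unifrac(
    x,
    y,
    taxa: list[str],
    tree: PhyloTree,
    normalized: bool = True,
) -> float:
    """Weighted UniFrac between two proportion vectors over ``taxa``.

    Raw form: sum over branches of length * |A_b - B_b| where A_b, B_b are
    the subtree proportion totals of each community; the normalized form
    divides by sum of length * (A_b + B_b).
    """
    tree.require_taxa(taxa)
    from skbio.diversity.beta import weighted_unifrac as _wu

    # skbio truncates inputs to integer counts; proportions are rescaled to
    # large integers first (UniFrac is invariant to the common scale).
    xi = np.round(np.asarray(x, float) * _SCALE)
    yi = np.round(np.asarray(y, float) * _SCALE)
    return float(_wu(xi, yi, taxa, tree.tree, normalized=normalized))


def distance_matrix(
    table: AbundanceTable,
    metric: str = "braycurtis",
    tree: PhyloTree | None = None,
    normalized: bool = True,
) -> DistanceMatrix:
    """All pairwise dissimilarities between the samples of one table.

    ``metric`` is ``"braycurtis"`` or ``"wunifrac"`` (the latter requires a
    tree whose leaves cover the table's taxa).
    """
    if table.mode != "proportions":
        raise ValidationError("distance matrices are computed on proportions tables")
    ids = table.sample_ids
    mat = table.matrix
    if metric == "braycurtis":
        zero_rows = [s for s, row in zip(ids, mat) if row.sum() == 0]
        if len(zero_rows) >= 2:
            raise DegenerateSampleError(
                f"Bray-Curtis undefined between all-zero samples {zero_rows[:2]}"
            )
        out = squareform(pdist(mat, metric="braycurtis"))
        return DistanceMatrix(tuple(ids), out, "braycurtis")
    if metric == "wunifrac":
        if tree is None:
            raise ValidationError("weighted UniFrac requires a tree")
        tree.require_taxa(table.taxon_ids)
        sk: _SkbioDM = beta_diversity(
            "weighted_unifrac",
            np.round(mat * _SCALE),
            ids=ids,
            taxa=table.taxon_ids,
            tree=tree.tree,
            normalized=normalized,
        )
        name = "wunifrac" if normalized else "wunifrac_raw"
        return DistanceMatrix(tuple(ids), np.asarray(sk.data, dtype=float), name)
    raise ValidationError(f"unknown metric {metric!r}")
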