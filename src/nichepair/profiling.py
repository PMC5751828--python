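"""Dominance-profile discovery: PAM clustering with model selection.

Subjects are clustered on a precomputed dissimilarity matrix by
partitioning around medoids (PAM): a greedy BUILD phase picks medoids that
minimize the total distance-to-medoid objective, then SWAP passes exchange a
medoid with a non-medoid while any exchange lowers the objective.  The
implementation is fully deterministic — every tie is broken by the lowest
sample index — so a given matrix always yields the same clustering.

Model selection offers the average silhouette width (primary) and a gap
statistic computed on a classical-MDS embedding of the dissimilarities,
with uniform reference sets drawn in the embedding's bounding box.

Two clustering recipes mirror the study design: composite NS+NPA top-genera
vectors under Bray-Curtis (fixed k = 10 in replication mode), and NS-only
weighted-UniFrac clustering (k = 6) whose clusters are then named after
their dominant genus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datamodel import AbundanceTable, PairedCohort, PhyloTree, ValidationError
from .diversity import DistanceMatrix, distance_matrix

__all__ = [
    "ClusteringResult",
    "pam",
    "avg_silhouette",
    "gap_statistic",
    "composite_vectors",
    "cluster_composite",
    "cluster_site_profiles",
    "name_profiles",
]

#: floor inside log(W) so zero-dispersion clusterings stay finite
LOG_W_EPS = 1e-12


@dataclass
class ClusteringResult:
    """PAM assignment plus model-selection diagnostics."""

    k: int
    labels: np.ndarray
    medoids: tuple[str, ...]
    objective: float
    sample_ids: tuple[str, ...]
    avg_silhouette: float | None = None
    gap_curve: pd.DataFrame | None = None
    profile_names: dict[int, str] = field(default_factory=dict)

    def assignment_frame(self) -> pd.DataFrame:
        names = [self.profile_names.get(c, str(c)) for c in self.labels]
        return pd.DataFrame(
            {"cluster": self.labels, "profile": names},
            index=pd.Index(self.sample_ids, name="subject_id"),
        )

    def cluster_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def _validate_square(d: DistanceMatrix) -> np.ndarray:
    v = np.asarray(d.values, dtype=float)
    if np.any(v < 0) or not np.allclose(v, v.T, atol=1e-12):
        raise ValidationError("PAM needs a symmetric nonnegative dissimilarity matrix")
    return v


def pam(d: DistanceMatrix, k: int) -> ClusteringResult:
    """Partitioning around medoids with BUILD initialization and SWAP passes.

    Deterministic: all ties break toward the lowest sample index.  Cluster
    labels are numbered by ascending medoid index.
    """
    dm = _validate_square(d)
    n = dm.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")

    # BUILD: start from the sample minimizing its row sum, then greedily add
    # the medoid giving the largest objective decrease.
    medoids = [int(np.argmin(dm.sum(axis=1)))]
    nearest = dm[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.minimum(dm, nearest[None, :]).sum(axis=1)  # objective if added
        gains[medoids] = np.inf
        cand = int(np.argmin(gains))
        medoids.append(cand)
        nearest = np.minimum(nearest, dm[cand])

    def nearest_two(meds: list[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sub = dm[meds]  # k x n
        order = np.argsort(sub, axis=0, kind="stable")
        d1 = sub[order[0], np.arange(n)]
        if len(meds) > 1:
            d2 = sub[order[1], np.arange(n)]
        else:
            d2 = np.full(n, np.inf)
        assign = np.asarray(meds)[order[0]]
        return d1, d2, assign

    # SWAP: accept the best improving (medoid, candidate) exchange until none.
    while True:
        meds_sorted = sorted(medoids)
        d1, d2, assign = nearest_two(meds_sorted)
        best = (0.0, None)
        for m in meds_sorted:
            mine = assign == m
            # cost change of swapping medoid m for candidate h, for all h
            a = np.minimum(dm[:, ~mine] - d1[None, ~mine], 0.0).sum(axis=1)
            b = (np.minimum(dm[:, mine], d2[None, mine]) - d1[None, mine]).sum(axis=1)
            total = a + b
            total[meds_sorted] = np.inf
            h = int(np.argmin(total))
            if total[h] < best[0] - 1e-12:
                best = (float(total[h]), (m, h))
        if best[1] is None:
            break
        m, h = best[1]
        medoids.remove(m)
        medoids.append(h)

    meds_sorted = sorted(medoids)
    d1, _, assign = nearest_two(meds_sorted)
    label_of = {m: i for i, m in enumerate(meds_sorted)}
    labels = np.array([label_of[a] for a in assign])
    return ClusteringResult(
        k=k,
        labels=labels,
        medoids=tuple(d.ids[m] for m in meds_sorted),
        objective=float(d1.sum()),
        sample_ids=tuple(d.ids),
    )


def avg_silhouette(d: DistanceMatrix, labels: np.ndarray) -> float:
    """Average silhouette width (b - a) / max(a, b); singletons contribute 0."""
    dm = _validate_square(d)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    n = dm.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            continue  # singleton: s = 0
        a = dm[i, own].sum() / (own.sum() - 1)
        b = min(dm[i, labels == c].mean() for c in clusters if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def _pcoa_embedding(d: DistanceMatrix) -> np.ndarray:
    """Classical multidimensional scaling; keeps positive-eigenvalue axes."""
    from skbio.stats.ordination import pcoa

    res = pcoa(d.values, warn_neg_eigval=False)
    coords = res.samples.to_numpy()
    eigs = res.eigvals.to_numpy()
    keep = eigs > max(eigs.max(), 0) * 1e-10
    if not keep.any():
        return np.zeros((d.n, 1))
    return coords[:, keep]


def gap_statistic(
    d: DistanceMatrix,
    k_range: list[int] | range,
    n_ref: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Gap statistic over ``k_range`` with uniform bounding-box references.

    Samples are embedded by classical MDS; ``n_ref`` reference datasets are
    drawn uniformly in the embedding's bounding box and clustered with PAM on
    Euclidean distances.  ``gap(k) = mean_b log W_ref_b(k) - log W_obs(k)``
    with W the PAM objective; ``se`` includes the simulation correction
    ``sqrt(1 + 1/n_ref)``.  The returned frame has columns ``k, gap, se,
    selected`` where ``selected`` marks the smallest k with
    ``gap(k) >= gap(k+1) - se(k+1)`` (last k if none qualifies).
    """
    ks = list(k_range)
    if ks != sorted(ks) or len(set(ks)) != len(ks) or not ks:
        raise ValueError("k_range must be strictly increasing and nonempty")
    emb = _pcoa_embedding(d)
    rng = np.random.default_rng(seed)
    lo, hi = emb.min(axis=0), emb.max(axis=0)

    def pam_logw(mat: DistanceMatrix, k: int) -> float:
        return float(np.log(pam(mat, k).objective + LOG_W_EPS))

    log_w_obs = np.array([pam_logw(d, k) for k in ks])
    log_w_ref = np.empty((n_ref, len(ks)))
    ids = tuple(str(i) for i in range(d.n))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=emb.shape)
        ref_d = DistanceMatrix(ids, squareform(pdist(ref)), "euclidean")
        for j, k in enumerate(ks):
            log_w_ref[b, j] = pam_logw(ref_d, k)

    gap = log_w_ref.mean(axis=0) - log_w_obs
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_ref)
    selected = np.zeros(len(ks), dtype=bool)
    chosen = len(ks) - 1
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - se[j + 1]:
            chosen = j
            break
    selected[chosen] = True
    return pd.DataFrame({"k": ks, "gap": gap, "se": se, "selected": selected})


def composite_vectors(cohort: PairedCohort, genera: list[str]) -> pd.DataFrame:
    """Adjoin NS and NPA top-genera proportions into one vector per subject.

    Columns are ``NS:<genus>`` then ``NPA:<genus>`` in identical genus order;
    each half sums to <= 1 (mass outside the top genera is dropped).
    """
    ns = cohort.ns_table.restrict(genera).data
    npa = cohort.npa_table.restrict(genera).data
    ns.columns = [f"NS:{g}" for g in genera]
    npa.columns = [f"NPA:{g}" for g in genera]
    return pd.concat([ns, npa], axis=1)


def _select_k_by_silhouette(d: DistanceMatrix, k_min: int = 2, k_max: int = 15) -> int:
    best_k, best_s = k_min, -np.inf
    for k in range(k_min, min(k_max, d.n - 1) + 1):
        res = pam(d, k)
        if len(np.unique(res.labels)) < 2:
            continue
        s = avg_silhouette(d, res.labels)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k


def cluster_composite(
    cohort: PairedCohort,
    genera: list[str],
    k: int | str = 10,
) -> tuple[ClusteringResult, pd.DataFrame]:
    """PAM on Bray-Curtis dissimilarities of composite NS+NPA vectors.

    ``k`` may be an integer (replication default 10) or ``"auto"`` for
    silhouette selection over 2..15.  Returns the clustering and the
    per-cluster mean abundance of every composite column (heat-map data).
    """
    comp = composite_vectors(cohort, genera)
    mat = comp.to_numpy(dtype=float)
    zero = mat.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValidationError("multiple subjects have no top-genera mass")
    dm = DistanceMatrix(
        tuple(comp.index), squareform(pdist(mat, metric="braycurtis")), "braycurtis"
    )
    kk = _select_k_by_silhouette(dm) if k == "auto" else int(k)
    result = pam(dm, kk)
    if kk >= 2:
        result.avg_silhouette = avg_silhouette(dm, result.labels)
    means = comp.groupby(result.labels).mean()
    means.index.name = "cluster"
    return result, means


def cluster_site_profiles(
    table: AbundanceTable,
    tree: PhyloTree,
    k: int | str = 6,
    dominance_threshold: float = 0.40,
) -> ClusteringResult:
    """Weighted-UniFrac PAM clustering of one site's samples, with naming.

    Replication default is k = 6 (the NS dominance profiles); ``"auto"``
    selects k by average silhouette width over 2..15.
    """
    dm = distance_matrix(table, metric="wunifrac", tree=tree)
    kk = _select_k_by_silhouette(dm) if k == "auto" else int(k)
    result = pam(dm, kk)
    if kk >= 2 and len(np.unique(result.labels)) >= 2:
        result.avg_silhouette = avg_silhouette(dm, result.labels)
    result.profile_names = name_profiles(result, table, threshold=dominance_threshold)
    return result


def name_profiles(
    result: ClusteringResult,
    table: AbundanceTable,
    threshold: float = 0.40,
) -> dict[int, str]:
    """Name each cluster ``<Genus>-dominant`` or ``mixed``.

    A cluster is genus-dominant when the within-cluster mean relative
    abundance of its top genus reaches ``threshold``; ties break by higher
    within-cluster prevalence, then lexicographically.
    """
    data = table.data.loc[list(result.sample_ids)]
    names: dict[int, str] = {}
    for c in np.unique(result.labels):
        members = data[result.labels == c]
        means = members.mean(axis=0)
        prevalence = (members > 0).mean(axis=0)
        ranking = pd.DataFrame({"mean": means, "prev": prevalence})
        ranking = ranking.sort_index().sort_values(
            ["mean", "prev"], ascending=[False, False], kind="stable"
        )
        top_genus = ranking.index[0]
        if ranking["mean"].iloc[0] >= threshold:
            names[int(c)] = f"{top_genus}-dominant"
        else:
            names[int(c)] = "mixed"
    return names
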