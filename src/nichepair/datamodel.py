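"""Core data containers and table operations for paired-site microbiome cohorts.

The central object is :class:`AbundanceTable`, a samples x taxa matrix tagged
with the anatomical site it was collected from (anterior nares ``NS`` or
nasopharyngeal aspirate ``NPA``) and whether it holds read counts or
per-sample proportions.  A :class:`PairedCohort` aligns one NS and one NPA
sample per subject with the subject-level clinical metadata.

All joins between the two sites are done on subject id, never on row
position, so a shuffled input file cannot silently misalign pairs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "AbundanceTable",
    "TaxonomyMap",
    "PairedCohort",
    "PhyloTree",
    "ValidationError",
    "FormatError",
    "DegenerateSampleError",
    "MappingError",
    "collapse_to_genus",
    "to_relative_abundance",
    "top_genera_union",
    "rarefy",
    "UNCLASSIFIED",
    "COVARIATE_COLUMNS",
]

#: Reserved genus bucket for OTUs without a genus assignment.
UNCLASSIFIED = "Unclassified"

#: The 11 patient-level adjustment covariates, in canonical order.  Categorical
#: variables are stored as strings; the reference level is listed first in
#: :data:`COVARIATE_LEVELS`.
COVARIATE_COLUMNS = (
    "age_months",
    "male_sex",
    "race_ethnicity",
    "gestational_age_weeks",
    "prev_breathing_problems",
    "daycare",
    "other_children_home",
    "hx_antibiotics",
    "hx_corticosteroids",
    "antibiotics_prehosp_visit",
    "virus_pcr",
)

#: Levels (reference first) for the categorical covariates.
COVARIATE_LEVELS = {
    "race_ethnicity": ("white", "black", "hispanic", "other"),
    "virus_pcr": ("rsv_only", "rhinovirus_only", "other"),
}


class ValidationError(ValueError):
    """An input violates a structural invariant (negative entry, duplicate id...)."""


class FormatError(ValueError):
    """A file does not parse as the documented on-disk format."""


class DegenerateSampleError(ValidationError):
    """A sample is unusable for the requested operation (e.g. all-zero row)."""


class MappingError(KeyError):
    """A taxon is missing from a taxonomy map or a phylogenetic tree."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups}")


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x taxa abundance matrix for one anatomical site.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and taxon (OTU or genus) ids as
        columns.  Entries are nonnegative read counts or proportions.
    site:
        Site label, conventionally ``"NS"`` or ``"NPA"``.
    mode:
        ``"counts"`` or ``"proportions"``.  In proportions mode every row must
        sum to 1 within 1e-9.
    """

    data: pd.DataFrame
    site: str
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise ValidationError(f"mode must be 'counts' or 'proportions', got {self.mode!r}")
        _check_unique(list(self.data.index), "sample ids")
        _check_unique(list(self.data.columns), "taxon ids")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            bad = self.data.index[(values < 0).any(axis=1)][0]
            raise ValidationError(f"negative abundance in sample {bad!r}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite abundance entry")
        if self.mode == "proportions" and values.size:
            sums = values.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                bad = self.data.index[np.argmax(np.abs(sums - 1.0))]
                raise ValidationError(
                    f"proportions row {bad!r} sums to {sums[np.argmax(np.abs(sums - 1.0))]:.12g}, not 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def restrict(self, taxa: Sequence[str]) -> "AbundanceTable":
        """Subset to the given taxa, in the given order.

        Restricting a proportions table breaks the row-sum-to-1 invariant
        (mass outside the subset is discarded, not renormalized), so the
        result is a :class:`SubCompositionTable` whose rows may sum to < 1.
        """
        missing = [t for t in taxa if t not in self.data.columns]
        if missing:
            raise MappingError(f"taxa not in table: {missing}")
        return SubCompositionTable(self.data.loc[:, list(taxa)].copy(), self.site, self.mode)

    def reorder_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise MappingError(f"samples not in table: {missing}")
        return dataclasses.replace(self, data=self.data.loc[list(sample_ids)])


class SubCompositionTable(AbundanceTable):
    """An abundance table restricted to a taxon subset.

    Rows are proportions of the *full* composition, so they may sum to less
    than 1; the simplex invariant is deliberately not enforced.
    """

    def __post_init__(self) -> None:  # rows may sum to <= 1
        _check_unique(list(self.data.index), "sample ids")
        _check_unique(list(self.data.columns), "taxon ids")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise ValidationError("negative abundance entry")


@dataclass(frozen=True)
class TaxonomyMap:
    """OTU id -> genus name mapping with an optional catch-all bucket.

    ``allow_unclassified`` routes OTUs absent from the map to
    :data:`UNCLASSIFIED` so read mass is conserved through the collapse.
    """

    otu_to_genus: Mapping[str, str]
    allow_unclassified: bool = True
    unclassified_label: str = UNCLASSIFIED

    def genus_of(self, otu_id: str) -> str:
        genus = self.otu_to_genus.get(otu_id)
        if genus is None or genus == "":
            if self.allow_unclassified:
                return self.unclassified_label
            raise MappingError(f"OTU {otu_id!r} has no genus assignment")
        return genus


@dataclass(frozen=True)
class PhyloTree:
    """Rooted phylogenetic tree over taxon ids, backed by :class:`skbio.TreeNode`."""

    tree: skbio.TreeNode

    def __post_init__(self) -> None:
        names = [t.name for t in self.tree.tips()]
        if any(n is None for n in names):
            raise ValidationError("tree has unnamed tips")
        _check_unique(names, "tree tip labels")
        for node in self.tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise ValidationError("negative branch length")

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def require_taxa(self, taxa: Iterable[str]) -> None:
        leaves = set(self.leaf_names)
        missing = [t for t in taxa if t not in leaves]
        if missing:
            raise MappingError(f"taxa missing from tree: {missing}")


@dataclass(frozen=True)
class PairedCohort:
    """One NS and one NPA sample per subject plus subject metadata.

    ``metadata`` is indexed by subject id and carries ``site_id`` (collection
    hospital), the 11 covariates of :data:`COVARIATE_COLUMNS`, ``icu_use``
    (nullable boolean) and ``los_days`` (nullable nonnegative integer).
    """

    subjects: tuple[str, ...]
    ns_table: AbundanceTable
    npa_table: AbundanceTable
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        subs = list(self.subjects)
        _check_unique(subs, "subject ids")
        for tbl, name in ((self.ns_table, "NS"), (self.npa_table, "NPA")):
            if list(tbl.sample_ids) != subs:
                raise ValidationError(
                    f"{name} table samples must match subject order exactly"
                )
        if len(self.metadata) and list(self.metadata.index) != subs:
            raise ValidationError("metadata index must match subject order")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def with_tables(self, ns: AbundanceTable, npa: AbundanceTable) -> "PairedCohort":
        return dataclasses.replace(self, ns_table=ns, npa_table=npa)


# ---------------------------------------------------------------------------
# Table operations
# ---------------------------------------------------------------------------

def collapse_to_genus(table: AbundanceTable, taxmap: TaxonomyMap) -> AbundanceTable:
    """Sum OTU columns into genus columns; row sums are preserved exactly.

    Genus columns appear in order of first appearance among the OTU columns.
    """
    genera = [taxmap.genus_of(otu) for otu in table.taxon_ids]
    collapsed = table.data.T.groupby(pd.Index(genera, name="genus"), sort=False).sum().T
    return dataclasses.replace(table, data=collapsed)


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Divide every row by its sum, turning counts into proportions."""
    if table.mode != "counts":
        raise ValidationError("table is already in proportions mode")
    sums = table.data.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise DegenerateSampleError(
            f"cannot normalize all-zero sample(s): {list(zero.index)}"
        )
    return dataclasses.replace(table, data=table.data.div(sums, axis=0), mode="proportions")


def overall_abundance(table: AbundanceTable) -> pd.Series:
    """Per-genus overall abundance: sum of relative abundances over all samples."""
    if table.mode != "proportions":
        raise ValidationError("overall abundance is defined on proportions tables")
    return table.data.sum(axis=0)


def top_genera_union(
    ns: AbundanceTable,
    npa: AbundanceTable,
    n_top: int = 10,
) -> tuple[list[str], bool]:
    """Union of each site's ``n_top`` most abundant genera.

    Per-site ranking is by overall abundance (sum of relative abundances over
    samples); the union is ordered by combined NS+NPA overall abundance,
    descending, with ties broken lexicographically.  Returns
    ``(genera, truncated)`` where ``truncated`` flags that a site had fewer
    than ``n_top`` genera.
    """

    def site_top(table: AbundanceTable) -> tuple[list[str], bool]:
        totals = overall_abundance(table)
        # stable deterministic order: abundance desc, then name asc
        ranked = totals.sort_index().sort_values(ascending=False, kind="stable")
        return list(ranked.index[:n_top]), len(ranked) < n_top

    ns_top, ns_short = site_top(ns)
    npa_top, npa_short = site_top(npa)
    union = set(ns_top) | set(npa_top)

    combined = overall_abundance(ns).reindex(sorted(union), fill_value=0.0).add(
        overall_abundance(npa).reindex(sorted(union), fill_value=0.0), fill_value=0.0
    )
    ordered = list(combined.sort_index().sort_values(ascending=False, kind="stable").index)
    return ordered, (ns_short or npa_short)


def rarefy(
    table: AbundanceTable,
    depth: int,
    seed: int,
    min_floor: int | None = None,
) -> tuple[AbundanceTable, list[str]]:
    """Subsample each sample's reads to a common depth, without replacement.

    Samples whose total count is below ``depth`` (or below ``min_floor`` if
    given) are dropped and their ids returned alongside the rarefied table.
    Reproducible for a fixed ``seed``.
    """
    if table.mode != "counts":
        raise ValidationError("rarefaction requires a counts table")
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    floor = depth if min_floor is None else max(depth, min_floor)
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValidationError("rarefaction requires integer counts")
    counts = np.round(counts).astype(np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= floor
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    kept = counts[keep]
    out = np.empty_like(kept)
    for i, row in enumerate(kept):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    data = pd.DataFrame(
        out,
        index=[s for s, k in zip(table.sample_ids, keep) if k],
        columns=table.taxon_ids,
    )
    return dataclasses.replace(table, data=data), dropped


def default_rarefaction_depth(table: AbundanceTable, floor: int = 1000) -> int:
    """Minimum retained row sum after dropping samples below ``floor`` reads."""
    totals = table.data.sum(axis=1)
    retained = totals[totals >= floor]
    if retained.empty:
        raise DegenerateSampleError(f"no sample reaches the {floor}-read floor")
    return int(retained.min())
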