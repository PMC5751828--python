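"""Readers and writers for the on-disk formats.

Abundance matrices are UTF-8 tab-separated files: header row of taxon ids,
first column of sample ids.  Metadata is CSV indexed by subject id.  Taxonomy
maps are two-column TSV (otu_id, genus).  Trees are newick.  Writers mirror
readers so a read/write/read round trip is exact.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import skbio

from .datamodel import (
    COVARIATE_COLUMNS,
    AbundanceTable,
    FormatError,
    PairedCohort,
    PhyloTree,
    TaxonomyMap,
    ValidationError,
)

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_taxonomy_map",
    "write_taxonomy_map",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_paired_cohort",
    "write_paired_cohort",
]


def read_abundance_table(path: str | Path, site: str, mode: str = "counts") -> AbundanceTable:
    """Read a samples x taxa TSV matrix (header = taxon ids, column 1 = sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype_backend="numpy_nullable")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse abundance TSV {path}: {exc}") from exc
    if df.isna().to_numpy().any():
        raise FormatError(f"missing or ragged entries in {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric abundance entry in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "sample_id"
    return AbundanceTable(data=df, site=site, mode=mode)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    # counts serialize as integers so round trips are byte-stable
    if table.mode == "counts" and (df.to_numpy() == df.to_numpy().round()).all():
        df = df.astype(int)
    df.to_csv(path, sep="\t")


def read_taxonomy_map(path: str | Path, allow_unclassified: bool = True) -> TaxonomyMap:
    """Read a two-column TSV of (otu_id, genus); empty genus marks unassigned."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise FormatError(f"taxonomy map {path} must have exactly 2 columns")
    otus = df.iloc[:, 0]
    if otus.duplicated().any():
        raise FormatError(f"duplicate OTU ids in taxonomy map {path}")
    return TaxonomyMap(
        otu_to_genus=dict(zip(otus, df.iloc[:, 1])),
        allow_unclassified=allow_unclassified,
    )


def write_taxonomy_map(taxmap: TaxonomyMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {"otu_id": list(taxmap.otu_to_genus), "genus": list(taxmap.otu_to_genus.values())}
    )
    df.to_csv(path, sep="\t", index=False)


_BOOL_COLUMNS = (
    "male_sex",
    "prev_breathing_problems",
    "daycare",
    "other_children_home",
    "hx_antibiotics",
    "hx_corticosteroids",
    "antibiotics_prehosp_visit",
    "icu_use",
)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the subject metadata CSV (index = subject id).

    Expected columns: ``site_id``, the 11 covariates, ``icu_use``,
    ``los_days``.  Boolean columns accept 0/1; outcomes may be blank
    (missing).
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    required = {"site_id", *COVARIATE_COLUMNS}
    missing = sorted(required - set(df.columns))
    if missing:
        raise FormatError(f"metadata {path} missing columns: {missing}")
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    if "los_days" in df.columns:
        if (df["los_days"].dropna() < 0).any():
            raise ValidationError("negative los_days in metadata")
        df["los_days"] = df["los_days"].astype("Int64")
    df["site_id"] = df["site_id"].astype(str)
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype("Int64")  # 0/1 with blanks for missing
    out.index.name = "subject_id"
    out.to_csv(path)


def read_tree(path: str | Path) -> PhyloTree:
    return PhyloTree(skbio.TreeNode.read(str(path), format="newick"))


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    tree.tree.write(str(path), format="newick")


def read_paired_cohort(
    ns_path: str | Path,
    npa_path: str | Path,
    metadata_path: str | Path,
    mode: str = "counts",
) -> PairedCohort:
    """Assemble a cohort from site tables plus metadata, joining on subject id.

    Only subjects present in both site tables and the metadata are kept, in
    metadata order.
    """
    ns = read_abundance_table(ns_path, site="NS", mode=mode)
    npa = read_abundance_table(npa_path, site="NPA", mode=mode)
    meta = read_metadata(metadata_path)
    subjects = [s for s in meta.index if s in set(ns.sample_ids) and s in set(npa.sample_ids)]
    if not subjects:
        raise ValidationError("no subject appears in both site tables and metadata")
    return PairedCohort(
        subjects=tuple(subjects),
        ns_table=ns.reorder_samples(subjects),
        npa_table=npa.reorder_samples(subjects),
        metadata=meta.loc[subjects],
    )


def write_paired_cohort(cohort: PairedCohort, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ns": out / "ns_abundance.tsv",
        "npa": out / "npa_abundance.tsv",
        "metadata": out / "metadata.csv",
    }
    write_abundance_table(cohort.ns_table, paths["ns"])
    write_abundance_table(cohort.npa_table, paths["npa"])
    write_metadata(cohort.metadata, paths["metadata"])
    return paths
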