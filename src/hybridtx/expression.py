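"""Expression-matrix data model and I/O.

An expression matrix is a dense, non-negative pandas DataFrame of FPKM
values with gene identifiers as the index and sample identifiers as
columns. Sample metadata is a DataFrame with one row per sample describing
the cell line it came from, its role (parent or hybrid), ploidy, phenotype
and replicate index.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "PLOIDIES",
    "PHENOTYPES",
    "META_COLUMNS",
    "compute_fpkm",
    "read_expression",
    "write_expression",
    "write_sample_sheet",
    "validate_expression",
    "validate_meta",
    "line_means",
    "line_mean_matrix",
    "reference_parent_lines",
]

ROLES = frozenset({"parent_ES", "parent_FIB", "hybrid"})
PLOIDIES = frozenset({"2N", "4N", "near4N"})
PHENOTYPES = frozenset({"ES_like", "FIB_like", "NA"})
META_COLUMNS = ("sample_id", "line_id", "role", "ploidy", "phenotype", "replicate")


def compute_fpkm(
    fragment_count: float, transcript_length_bp: float, total_mapped_fragments: float
) -> float:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``FPKM = 1e9 * fragments / (length_bp * total_mapped_fragments)``.
    """
    if transcript_length_bp <= 0:
        raise ValueError("transcript_length_bp must be > 0")
    if total_mapped_fragments <= 0:
        raise ValueError("total_mapped_fragments must be > 0")
    if fragment_count < 0:
        raise ValueError("fragment_count must be >= 0")
    return 1e9 * fragment_count / (transcript_length_bp * total_mapped_fragments)


def validate_expression(matrix: pd.DataFrame) -> None:
    """Check matrix invariants: finite, non-negative, unique ids, no holes."""
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate gene_id: {dup!r}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValueError(f"duplicate sample_id: {dup!r}")
    for sample in matrix.columns:
        col = matrix[sample]
        if not pd.api.types.is_numeric_dtype(col):
            bad = col[pd.to_numeric(col, errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric FPKM for gene {gene!r} in sample {sample!r}"
            )
        arr = col.to_numpy(dtype=float)
        if np.isnan(arr).any():
            gene = col.index[np.isnan(arr)][0]
            raise ValueError(f"missing FPKM for gene {gene!r} in sample {sample!r}")
        if not np.isfinite(arr).all():
            gene = col.index[~np.isfinite(arr)][0]
            raise ValueError(f"non-finite FPKM for gene {gene!r} in sample {sample!r}")
        if (arr < 0).any():
            gene = col.index[arr < 0][0]
            raise ValueError(f"negative FPKM for gene {gene!r} in sample {sample!r}")


def validate_meta(meta: pd.DataFrame, matrix: pd.DataFrame | None = None) -> None:
    """Check the sample sheet and (optionally) its agreement with a matrix."""
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in sheet: {dup!r}")
    bad_role = set(meta["role"]) - ROLES
    if bad_role:
        raise ValueError(f"unknown role(s): {sorted(bad_role)}")
    bad_ploidy = set(meta["ploidy"]) - PLOIDIES
    if bad_ploidy:
        raise ValueError(f"unknown ploidy value(s): {sorted(bad_ploidy)}")
    bad_phen = set(meta["phenotype"]) - PHENOTYPES
    if bad_phen:
        raise ValueError(f"unknown phenotype value(s): {sorted(bad_phen)}")
    hybrids = meta[meta["role"] == "hybrid"]
    if (hybrids["phenotype"] == "NA").any():
        line = hybrids.loc[hybrids["phenotype"] == "NA", "line_id"].iloc[0]
        raise ValueError(f"hybrid line {line!r} must carry a phenotype")
    if (meta["replicate"].astype(int) < 1).any():
        raise ValueError("replicate indices must be positive")
    if matrix is not None:
        sheet = set(meta["sample_id"])
        cols = set(matrix.columns)
        if cols - sheet:
            raise ValueError(
                f"matrix samples absent from sheet: {sorted(cols - sheet)}"
            )
        if sheet - cols:
            raise ValueError(
                f"sheet samples absent from matrix: {sorted(sheet - cols)}"
            )


def read_expression(
    path: str | Path, sample_sheet_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an expression TSV (first column ``gene_id``) and its sample sheet.

    Returns the validated ``(matrix, meta)`` pair; every matrix column must
    be listed in the sheet and vice versa.
    """
    matrix = pd.read_csv(path, sep="\t", index_col="gene_id")
    # phenotype uses the literal string "NA"; stop pandas eating it
    meta = pd.read_csv(
        sample_sheet_path,
        sep="\t",
        dtype={"sample_id": str, "line_id": str},
        keep_default_na=False,
        na_values=[],
    )
    meta["replicate"] = meta["replicate"].astype(int)
    validate_expression(matrix)
    validate_meta(meta, matrix)
    return matrix, meta


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def write_sample_sheet(meta: pd.DataFrame, path: str | Path) -> None:
    meta.loc[:, list(META_COLUMNS)].to_csv(path, sep="\t", index=False)


def _line_samples(meta: pd.DataFrame, line_id: str) -> list[str]:
    samples = meta.loc[meta["line_id"] == line_id, "sample_id"].tolist()
    if not samples:
        raise KeyError(f"unknown line_id: {line_id!r}")
    return samples


def line_means(
    matrix: pd.DataFrame, meta: pd.DataFrame, line_id: str, log_scale: bool = False
) -> pd.Series:
    """Per-gene mean FPKM across a line's replicate columns.

    Arithmetic mean by default (the convention FPKM tables are reported in);
    ``log_scale=True`` averages log2(FPKM+1) and transforms back, which
    downweights single outlier replicates.
    """
    samples = _line_samples(meta, line_id)
    sub = matrix[samples]
    if log_scale:
        return np.exp2(np.log2(sub + 1.0).mean(axis=1)) - 1.0
    return sub.mean(axis=1)


def line_mean_matrix(
    matrix: pd.DataFrame, meta: pd.DataFrame, log_scale: bool = False
) -> pd.DataFrame:
    """Genes x lines matrix of replicate-mean FPKM, one column per line."""
    lines = meta["line_id"].drop_duplicates().tolist()
    return pd.DataFrame(
        {line: line_means(matrix, meta, line, log_scale=log_scale) for line in lines}
    )


def reference_parent_lines(meta: pd.DataFrame, reference_ploidy: str) -> tuple[str, str]:
    """The (ES-parent, fibroblast-parent) line ids at the reference ploidy."""
    out = []
    for role in ("parent_ES", "parent_FIB"):
        lines = meta.loc[
            (meta["role"] == role) & (meta["ploidy"] == reference_ploidy), "line_id"
        ].drop_duplicates()
        if len(lines) != 1:
            raise ValueError(
                f"expected exactly one {role} line at ploidy {reference_ploidy}, "
                f"found {lines.tolist()}"
            )
        out.append(lines.iloc[0])
    return out[0], out[1]
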