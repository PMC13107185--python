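"""Core containers and I/O for protein x sample expression data.

An :class:`ExpressionMatrix` holds log2 reference-ratio values (proteins in
rows, samples in columns, NaN = not quantified).  Sample metadata and the
patient clinical table are validated pandas DataFrames with fixed column
names; see :data:`METADATA_COLUMNS` and :data:`CLINICAL_COLUMNS`.

TSV dialect: tab separated, first column holds protein IDs, header row holds
sample IDs; missing values are written as empty cells and read from empty
cells or a bare ``"."``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("Healthy", "NAT", "Tumor")

METADATA_COLUMNS = ["sample_id", "patient_id", "tissue", "batch"]
CLINICAL_COLUMNS = [
    "patient_id", "os_time", "os_event", "dfs_time", "dfs_event",
    "ptnm", "t_stage", "n_stage", "sex", "age",
]

PTNM_LEVELS = {"I": 1, "II": 2, "III": 3, "IV": 4}


class MatrixFormatError(ValueError):
    """Raised when an expression TSV violates the documented dialect."""


@dataclass(eq=False)
class ExpressionMatrix:
    """Protein x sample matrix of log2 reference-ratios.

    ``data`` rows are indexed by protein ID, columns by sample ID; NaN marks
    a protein not quantified in a sample.  IDs must be unique on both axes.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise MatrixFormatError(f"duplicate protein IDs: {dups[:5]}")
        if cols.duplicated().any():
            dups = sorted(cols[cols.duplicated()].unique())
            raise MatrixFormatError(f"duplicate sample IDs: {dups[:5]}")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            raise MatrixFormatError("non-numeric columns in expression matrix")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.data.to_numpy(dtype=float)).any():
                raise MatrixFormatError("infinite values in expression matrix")
        self.data = self.data.astype(float)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy())

    def subset_proteins(self, protein_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(protein_ids)].copy())


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a protein x sample TSV (empty cell or "." = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."],
                     keep_default_na=False, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise MatrixFormatError(f"duplicate protein IDs in {path}: {dups[:5]}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        mask = raw.isna() | (raw.str.strip() == "")
        vals = pd.to_numeric(raw.where(~mask), errors="coerce")
        bad = (~mask) & vals.isna()
        if bad.any():
            row = df.index[bad][0]
            raise MatrixFormatError(
                f"non-numeric cell at protein {row!r}, sample {col!r}: "
                f"{raw[bad].iloc[0]!r}")
        out[col] = vals
    return ExpressionMatrix(out)


def write_expression_matrix(m: ExpressionMatrix, path, float_format: str = "%.6g") -> None:
    """Write matrix to TSV; missing values become empty cells."""
    m.data.to_csv(path, sep="\t", na_rep="", float_format=float_format,
                  index_label="protein_id")


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_sample_metadata(meta)


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta = meta[METADATA_COLUMNS].copy()
    bad = set(meta["tissue"]) - set(TISSUES)
    if bad:
        raise ValueError(f"unknown tissue labels: {sorted(bad)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    tn = meta[meta["tissue"].isin(["NAT", "Tumor"])]
    if (tn["patient_id"].str.strip() == "").any():
        raise ValueError("NAT/Tumor samples require a patient_id")
    per = tn.groupby(["patient_id", "tissue"]).size()
    if (per > 1).any():
        raise ValueError("a patient has more than one NAT or Tumor sample")
    return meta


def read_clinical_table(path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_clinical_table(clin)


def validate_clinical_table(clin: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    clin = clin[CLINICAL_COLUMNS].copy()
    if clin["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in clinical table")
    for c in ("os_time", "dfs_time", "age"):
        clin[c] = pd.to_numeric(clin[c])
    for c in ("os_event", "dfs_event"):
        clin[c] = pd.to_numeric(clin[c]).astype(int)
        if not clin[c].isin([0, 1]).all():
            raise ValueError(f"{c} must be 0/1")
    if (clin["os_time"] <= 0).any() or (clin["dfs_time"] <= 0).any():
        raise ValueError("survival times must be positive")
    bad = set(clin["ptnm"]) - set(PTNM_LEVELS)
    if bad:
        raise ValueError(f"unknown pTNM levels: {sorted(bad)}")
    return clin


def ptnm_ordinal(ptnm: pd.Series) -> pd.Series:
    """Encode pTNM stage I..IV as ordinal integers 1..4."""
    return ptnm.map(PTNM_LEVELS).astype(int)


def normalize_to_reference(raw: pd.DataFrame, reference_column: str,
                           center: str = "sample") -> ExpressionMatrix:
    """log2(sample / pooled reference) ratios, then mean-centering.

    Parameters
    ----------
    raw : DataFrame
        Non-negative reporter intensities, proteins x samples, including the
        pooled-reference channel as one column.
    reference_column : str
        Column holding the pooled internal reference.
    center : {"sample", "protein", "none"}
        Axis of mean-centering after the log2 ratio.  Per-sample (column)
        centering is the default: batch effects manifest as sample-level
        shifts, and it makes the result invariant to rescaling any sample's
        raw intensities by a constant.

    Proteins whose reference intensity is zero/negative cannot be ratioed
    and are set fully missing (with a warning).
    """
    if reference_column not in raw.columns:
        raise KeyError(f"reference column {reference_column!r} not found")
    if center not in ("sample", "protein", "none"):
        raise ValueError(f"unknown centering axis {center!r}")
    ref = raw[reference_column].astype(float)
    vals = raw.drop(columns=[reference_column]).astype(float)
    bad_ref = ~(ref > 0)
    if bad_ref.any():
        warnings.warn(
            f"{int(bad_ref.sum())} proteins with non-positive reference "
            "intensity set to missing")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(vals.where(vals > 0).div(ref.where(~bad_ref), axis=0))
    if center == "sample":
        ratios = ratios - ratios.mean(axis=0, skipna=True)
    elif center == "protein":
        ratios = ratios.sub(ratios.mean(axis=1, skipna=True), axis=0)
    return ExpressionMatrix(ratios)


def filter_by_quantification(m: ExpressionMatrix, min_fraction: float) -> ExpressionMatrix:
    """Keep proteins quantified in >= ceil(min_fraction * n_samples) samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    n = m.shape[1]
    need = math.ceil(min_fraction * n)
    counts = m.data.notna().sum(axis=1)
    keep = counts[counts >= need].index
    if len(keep) == 0:
        warnings.warn("quantification filter removed every protein")
    return ExpressionMatrix(m.data.loc[keep].copy())


def ihc_composite_score(intensity_grade: int, percent_grade: int) -> int:
    """Composite immunostaining score: intensity (0-3) x positive-cell
    percentage grade (0-4), total range 0-12."""
    if intensity_grade not in (0, 1, 2, 3):
        raise ValueError(f"intensity grade {intensity_grade} outside 0-3")
    if percent_grade not in (0, 1, 2, 3, 4):
        raise ValueError(f"percent grade {percent_grade} outside 0-4")
    return intensity_grade * percent_grade
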