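"""Data model and delimited-file I/O shared by every pipeline stage.

Beta-value matrices (CpGs x samples), sample sheets, and CpG annotation are
plain TSV files; upstream array preprocessing is out of scope and beta
matrices are the interface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "CpGAnnotation",
    "FormatError",
    "ValidationError",
    "compute_beta",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
    "align",
    "region_to_lobe",
]


class FormatError(ValueError):
    """Raised when an input file violates its structural contract."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


#: region vocabulary -> broad lobe grouping; regions not listed map to "other"
REGION_LOBE_MAP = {
    "parietal": "parietal",
    "parietal lobe": "parietal",
    "parietal cortex": "parietal",
    "sensory cortex": "parietal",
    "frontal": "frontal",
    "frontal lobe": "frontal",
    "right frontal lobe": "frontal",
    "left frontal lobe": "frontal",
    "frontal gyrus": "frontal",
    "motor cortex": "frontal",
    "occipital": "occipital",
    "occipital lobe": "occipital",
    "occipital cortex": "occipital",
    "visual cortex": "occipital",
}

SAMPLE_SHEET_REQUIRED = ["sample_id", "individual_id", "region", "diagnosis", "age", "sex"]
SAMPLE_SHEET_OPTIONAL = [
    "lobe",
    "bank",
    "cag_length",
    "vonsattel_grade",
    "onset_age",
    "prop_neurons",
    "postmortem_interval",
]


def region_to_lobe(region: str) -> str:
    """Map a brain-region label to one of frontal/parietal/occipital/other."""
    return REGION_LOBE_MAP.get(str(region).strip().lower(), "other")


def compute_beta(M, U):
    """Methylation fraction from methylated (M) and unmethylated (U) intensities.

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + 100).  Negative intensities
    are clamped to zero; the +100 offset keeps the result strictly below 1.

    Accepts scalars or arrays; raises :class:`ValidationError` on non-finite
    input.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(U))):
        raise ValidationError("intensities must be finite")
    m = np.maximum(M, 0.0)
    u = np.maximum(U, 0.0)
    beta = m / (m + u + 100.0)
    if beta.ndim == 0:
        return float(beta)
    return beta


@dataclass
class BetaMatrix:
    """CpG-by-sample beta values for one region/lobe."""

    values: np.ndarray
    cpg_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    def validate(self):
        if self.values.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise FormatError("duplicate CpG ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            raise ValidationError(f"non-finite beta values at {self._cells(bad)}")
        if np.any((self.values < 0) | (self.values > 1)):
            bad = np.argwhere((self.values < 0) | (self.values > 1))
            raise ValidationError(f"beta values outside [0,1] at {self._cells(bad)}")

    def _cells(self, idx, limit=10):
        cells = [f"({self.cpg_ids[i]}, {self.sample_ids[j]})" for i, j in idx[:limit]]
        more = "" if len(idx) <= limit else f" and {len(idx) - limit} more"
        return ", ".join(cells) + more

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_cpgs(self, cpg_ids) -> "BetaMatrix":
        pos = {c: i for i, c in enumerate(self.cpg_ids)}
        rows = [pos[c] for c in cpg_ids]
        return BetaMatrix(self.values[rows], list(cpg_ids), list(self.sample_ids))

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [pos[s] for s in sample_ids]
        return BetaMatrix(self.values[:, cols], list(self.cpg_ids), list(sample_ids))


@dataclass
class SampleSheet:
    """Typed per-sample covariate table (one row per sample_id)."""

    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        df = self.table.copy()
        missing = [c for c in SAMPLE_SHEET_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample_id: {dups}")
        for col in SAMPLE_SHEET_OPTIONAL:
            if col not in df.columns:
                df[col] = np.nan
        df["age"] = pd.to_numeric(df["age"], errors="raise")
        for col in ("cag_length", "vonsattel_grade", "onset_age", "prop_neurons", "postmortem_interval"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if df["lobe"].isna().all():
            df["lobe"] = df["region"].map(region_to_lobe)
        df = df.set_index("sample_id", drop=False)
        self.table = df
        self._check_invariants()

    def _check_invariants(self):
        df = self.table
        if (df["age"] <= 0).any():
            raise ValidationError("age must be > 0 for all samples")
        prop = df["prop_neurons"].dropna()
        if ((prop < 0) | (prop > 1)).any():
            raise ValidationError("prop_neurons must lie in [0,1]")
        hd = df[df["diagnosis"] == "HD"]
        low_cag = hd["cag_length"].dropna() < 36
        if low_cag.any():
            ids = hd.loc[low_cag[low_cag].index, "sample_id"].tolist()
            msg = f"HD samples with cag_length < 36: {ids}"
            self.warnings.append(msg)
            warnings.warn(msg)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, sample_ids) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)].reset_index(drop=True))

    def column(self, name: str, sample_ids=None) -> np.ndarray:
        df = self.table if sample_ids is None else self.table.loc[list(sample_ids)]
        return df[name].to_numpy()


@dataclass
class CpGAnnotation:
    """CpG -> gene / genomic position mapping."""

    table: pd.DataFrame

    CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X", "Y", "MT", "unknown"]

    def __post_init__(self):
        df = self.table.copy()
        required = ["cpg_id", "gene_symbol", "chromosome", "position"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        if df["cpg_id"].duplicated().any():
            raise FormatError("duplicate cpg_id in annotation")
        df["gene_symbol"] = df["gene_symbol"].fillna("").astype(str)
        df["chromosome"] = df["chromosome"].astype(str)
        bad = ~df["chromosome"].isin(self.CHROMOSOMES)
        if bad.any():
            raise ValidationError(
                f"unknown chromosomes: {sorted(df.loc[bad, 'chromosome'].unique())}"
            )
        df["position"] = pd.to_numeric(df["position"], errors="raise").astype(int)
        self.table = df.set_index("cpg_id", drop=False)

    def gene_of(self, cpg_id: str) -> str:
        return self.table.at[cpg_id, "gene_symbol"]


# ---------------------------------------------------------------------------
# readers / writers


def read_beta_matrix(path, delimiter: str = "\t") -> BetaMatrix:
    """Read a CpG-by-sample beta matrix (first column CpG ids, header samples)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.isna().any().any():
        na = df.isna()
        cells = [
            f"({df.index[i]}, {df.columns[j]})" for i, j in zip(*np.where(na.to_numpy()))
        ][:10]
        raise ValidationError(f"missing beta values not allowed; NA at {cells}")
    return BetaMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str)))


def write_beta_matrix(beta: BetaMatrix, path, delimiter: str = "\t", float_format: str = "%.8g"):
    beta.to_frame().to_csv(path, sep=delimiter, index_label="cpg_id", float_format=float_format)


def read_sample_sheet(path, delimiter: str = "\t") -> SampleSheet:
    df = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str, "individual_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path, delimiter: str = "\t"):
    sheet.table.to_csv(path, sep=delimiter, index=False)


def read_annotation(path, delimiter: str = "\t") -> CpGAnnotation:
    df = pd.read_csv(path, sep=delimiter, dtype={"cpg_id": str, "chromosome": str})
    return CpGAnnotation(df)


def write_annotation(annot: CpGAnnotation, path, delimiter: str = "\t"):
    annot.table.to_csv(path, sep=delimiter, index=False)


def align(beta: BetaMatrix, sheet: SampleSheet):
    """Restrict matrix columns and sheet rows to their common sample ids.

    Returns ``(beta, sheet, dropped_from_beta, dropped_from_sheet)`` with
    columns ordered by their appearance in the beta matrix.
    """
    in_sheet = set(sheet.sample_ids)
    common = [s for s in beta.sample_ids if s in in_sheet]
    if not common:
        raise ValidationError("no samples in common between beta matrix and sample sheet")
    dropped_beta = [s for s in beta.sample_ids if s not in in_sheet]
    common_set = set(common)
    dropped_sheet = [s for s in sheet.sample_ids if s not in common_set]
    beta2 = beta.subset_samples(common) if dropped_beta else beta
    sheet2 = SampleSheet(sheet.table.loc[common].reset_index(drop=True))
    return beta2, sheet2, dropped_beta, dropped_sheet
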