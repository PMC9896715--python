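"""Typed in-memory data model and readers/writers for the pipeline's file formats.

The pipeline works with four external artefacts: a gene-by-sample raw count
matrix (TSV/CSV, genes as rows), a sample table linking samples to patients
and sample type (tumour vs adjacent normal), a clinical table keyed by
patient, and GMT gene-set collections.  Gene identifiers are opaque strings;
no genome annotation is consulted anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


TUMOUR = "tumour"
NORMAL = "normal"

_SAMPLE_TYPE_ALIASES = {
    "tumour": TUMOUR,
    "tumor": TUMOUR,
    "t": TUMOUR,
    "normal": NORMAL,
    "adjacent_normal": NORMAL,
    "adj_normal": NORMAL,
    "n": NORMAL,
}

_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none"}


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Raw integer RNA-seq counts, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {arr.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0):
                g, s = np.argwhere(frac != 0)[0]
                raise FormatError(
                    f"non-integral count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}: {arr[g, s]!r}"
                )
        arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}: {arr[g, s]}"
            )
        self.counts = arr

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def subset_genes(self, gene_ids) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), list(self.sample_ids), self.counts[rows])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, cols])


@dataclass
class SampleTable:
    """sample -> patient mapping with sample type (tumour/normal) and optional region."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame.copy()
        required = {"sample_id", "patient_id", "sample_type"}
        missing = required - set(f.columns)
        if missing:
            raise FormatError(f"sample table missing columns: {sorted(missing)}")
        f["sample_id"] = f["sample_id"].astype(str)
        f["patient_id"] = f["patient_id"].astype(str)
        _check_unique(f["sample_id"], "sample")
        types = []
        for s, t in zip(f["sample_id"], f["sample_type"]):
            key = str(t).strip().lower()
            if key not in _SAMPLE_TYPE_ALIASES:
                raise FormatError(f"unknown sample_type {t!r} for sample {s!r}")
            types.append(_SAMPLE_TYPE_ALIASES[key])
        f["sample_type"] = types
        if "region" not in f.columns:
            f["region"] = ""
        self.frame = f.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def patient_ids(self) -> list[str]:
        """Unique patients in first-appearance order."""
        return list(dict.fromkeys(self.frame["patient_id"]))

    def samples_of(self, patient_id: str, sample_type: str | None = None) -> list[str]:
        f = self.frame
        mask = f["patient_id"] == patient_id
        if sample_type is not None:
            mask &= f["sample_type"] == sample_type
        return list(f.loc[mask, "sample_id"])

    def patient_of(self, sample_id: str) -> str:
        f = self.frame
        return str(f.loc[f["sample_id"] == sample_id, "patient_id"].iloc[0])

    def subset(self, sample_ids) -> "SampleTable":
        keep = self.frame["sample_id"].isin(set(sample_ids))
        return SampleTable(self.frame.loc[keep].reset_index(drop=True))


@dataclass
class ClinicalTable:
    """Per-patient clinical data: recurrence-free survival plus covariates.

    ``rfs_days`` must be non-negative and ``recurrence_event`` binary; other
    columns are free-form covariates (categoricals as strings, continuous as
    floats with NaN for missing).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame.copy()
        required = {"patient_id", "rfs_days", "recurrence_event"}
        missing = required - set(f.columns)
        if missing:
            raise FormatError(f"clinical table missing columns: {sorted(missing)}")
        f["patient_id"] = f["patient_id"].astype(str)
        _check_unique(f["patient_id"], "patient")
        f["rfs_days"] = pd.to_numeric(f["rfs_days"], errors="raise")
        if (f["rfs_days"] < 0).any():
            bad = f.loc[f["rfs_days"] < 0, "patient_id"].iloc[0]
            raise FormatError(f"negative rfs_days for patient {bad!r}")
        f["recurrence_event"] = pd.to_numeric(f["recurrence_event"], errors="raise").astype(int)
        if not f["recurrence_event"].isin([0, 1]).all():
            raise FormatError("recurrence_event must be 0 or 1")
        self.frame = f.reset_index(drop=True)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.frame["patient_id"])


@dataclass
class GeneSetCollection:
    """Named gene sets: set_name -> (description, members)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> set[str]:
        return set(self.sets[name][1])

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_counts(path, dialect: str = "tsv") -> CountMatrix:
    """Read a gene-by-sample count table (first column gene ids, header samples)."""
    frame = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicate gene identifier: {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise FormatError(f"duplicate sample identifier: {dup!r}")
    for col in frame.columns:
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            gene = frame.index[vals.isna()][0]
            raise FormatError(
                f"non-numeric count at gene {gene!r}, sample {col!r}: "
                f"{frame.loc[gene, col]!r}"
            )
        frame[col] = vals
    return CountMatrix.from_frame(frame)


def write_counts(cm: CountMatrix, path, dialect: str = "tsv") -> None:
    cm.to_frame().to_csv(path, sep=_sep(dialect), index_label="gene_id")


def read_sample_table(path, dialect: str = "tsv") -> SampleTable:
    frame = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    return SampleTable(frame)


def write_sample_table(table: SampleTable, path, dialect: str = "tsv") -> None:
    table.frame.to_csv(path, sep=_sep(dialect), index=False)


def read_clinical(path, dialect: str = "tsv") -> ClinicalTable:
    """Read the clinical table; empty strings and "NA" are treated as missing."""
    frame = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    for col in frame.columns:
        is_na = frame[col].str.strip().str.lower().isin(_NA_TOKENS)
        frame[col] = frame[col].mask(is_na)
    # coerce columns that are numeric apart from missing values
    for col in frame.columns:
        if col == "patient_id":
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.notna().sum() == frame[col].notna().sum():
            frame[col] = coerced
    return ClinicalTable(frame)


def write_clinical(table: ClinicalTable, path, dialect: str = "tsv") -> None:
    table.frame.to_csv(path, sep=_sep(dialect), index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file: name TAB description TAB member...

    Trailing empty fields are dropped and duplicate members deduplicated
    (first occurrence order preserved).
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = (desc, tuple(dict.fromkeys(members)))
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in coll.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")
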