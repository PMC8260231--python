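"""Data model and I/O for methylome beta matrices, sample sheets, probe
annotation and transcription-factor binding tables.

All genomic coordinates are 0-based half-open (BED convention); probe records
are 2-bp CpG intervals.  Beta values are methylation proportions in [0, 1];
missing values are carried as NaN and excluded pairwise in downstream
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

SHEET_COLUMNS = ("sample_id", "age", "sex", "castrated", "tissue", "species",
                 "mass", "batch")
_REQUIRED_SHEET = ("sample_id", "age", "sex", "castrated", "tissue", "species")

UNMAPPED_CHROM = "."


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f", ""}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise DataError(f"cannot parse boolean value {value!r}")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check sample-sheet invariants, returning a normalized copy.

    Invariants: unique sample_id, non-negative ages, sex in {female, male},
    castrated only for males.  Column names are matched case-insensitively;
    extra columns are preserved untouched.
    """
    rename = {c: c.strip().lower() for c in sheet.columns
              if c.strip().lower() in SHEET_COLUMNS}
    sheet = sheet.rename(columns=rename).copy()
    missing = [c for c in _REQUIRED_SHEET if c not in sheet.columns]
    if missing:
        raise DataError(f"sample sheet missing required columns: {missing}")
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"duplicate sample ids: {dups}")
    sheet["age"] = pd.to_numeric(sheet["age"], errors="raise")
    if (sheet["age"] < 0).any():
        bad = sheet.loc[sheet["age"] < 0, "sample_id"].tolist()
        raise DataError(f"negative ages for samples: {bad}")
    sheet["sex"] = sheet["sex"].astype(str).str.strip().str.lower()
    unknown = set(sheet["sex"]) - {"female", "male"}
    if unknown:
        raise DataError(f"sex must be 'female' or 'male', got {sorted(unknown)}")
    sheet["castrated"] = sheet["castrated"].map(_parse_bool).astype(bool)
    bad = sheet["castrated"] & (sheet["sex"] != "male")
    if bad.any():
        raise DataError(
            f"castrated=True on non-male samples: {sheet.loc[bad, 'sample_id'].tolist()}")
    if "mass" in sheet.columns:
        sheet["mass"] = pd.to_numeric(sheet["mass"], errors="coerce")
    return sheet.set_index("sample_id", drop=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(
        pd.read_csv(path, float_precision="round_trip"))


def _float_fmt(v: float) -> str:
    # shortest representation that round-trips the exact double
    return repr(float(v))


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False, float_format=_float_fmt)


def group_label(sheet: pd.DataFrame) -> pd.Series:
    """Cohort group per sample: female / intact male / castrated male."""
    lab = pd.Series("female", index=sheet.index)
    male = sheet["sex"] == "male"
    lab[male & ~sheet["castrated"]] = "intact"
    lab[male & sheet["castrated"]] = "castrate"
    return lab


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------

def validate_beta_matrix(beta: pd.DataFrame) -> pd.DataFrame:
    beta.index = beta.index.astype(str)
    if beta.index.duplicated().any():
        raise DataError(
            f"duplicate probe ids: {beta.index[beta.index.duplicated()].tolist()}")
    values = beta.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out_of_range = (values < 0) | (values > 1)
    if out_of_range.any():
        rows = np.where(out_of_range.any(axis=1))[0]
        probes = beta.index[rows].tolist()
        raise DataError(f"beta values outside [0, 1] for probes: {probes}")
    return beta.astype(float)


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probes x samples TSV: first column probe_id, header of sample ids."""
    try:
        beta = pd.read_csv(path, sep="\t", index_col=0,
                           float_precision="round_trip")
    except ValueError as exc:  # pragma: no cover - pandas message carries position
        raise DataError(f"malformed beta matrix: {exc}") from exc
    for col in beta.columns:
        try:
            beta[col] = pd.to_numeric(beta[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise DataError(f"non-numeric beta value in column {col!r}: {exc}") from exc
    beta.columns = beta.columns.astype(str)
    return validate_beta_matrix(beta)


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id", float_format=_float_fmt)


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("chrom", "start", "end", "probe_id", "score", "strand", "gene")


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    ann = ann.copy()
    ann["probe_id"] = ann["probe_id"].astype(str)
    if ann["probe_id"].duplicated().any():
        raise DataError("duplicate probe ids in annotation")
    ann["mapped"] = ann["chrom"].astype(str) != UNMAPPED_CHROM
    mapped = ann[ann["mapped"]]
    bad = mapped["start"] >= mapped["end"]
    if bad.any():
        raise DataError(
            f"annotation intervals with start >= end: {mapped.loc[bad, 'probe_id'].tolist()}")
    return ann.set_index("probe_id", drop=False)


def read_probe_annotation(path) -> pd.DataFrame:
    """Read BED6-like TSV with a trailing gene column (no header).

    Unmapped probes carry chrom '.' with start=end=0; '.' gene means none.
    """
    ann = pd.read_csv(path, sep="\t", header=None, names=ANNOTATION_COLUMNS,
                      dtype={"chrom": str, "probe_id": str, "gene": str})
    for col in ("start", "end"):
        vals = pd.to_numeric(ann[col], errors="raise")
        if not np.allclose(vals, np.round(vals)):
            raise DataError(f"non-integer coordinates in annotation column {col}")
        ann[col] = vals.astype(int)
    ann.loc[ann["gene"] == ".", "gene"] = ""
    return validate_annotation(ann)


def write_probe_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out["gene"] = out["gene"].replace("", ".")
    out[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# TF binding table
# ---------------------------------------------------------------------------

@dataclass
class TFBindingTable:
    """ChIP-seq-style peak intervals per transcription factor (BED4+)."""

    records: pd.DataFrame  # columns chrom, start, end, tf_name

    def __post_init__(self):
        rec = self.records
        if (rec["start"] >= rec["end"]).any():
            bad = rec[rec["start"] >= rec["end"]]
            raise DataError(f"peak intervals with start >= end:\n{bad}")
        if (rec["tf_name"].astype(str).str.len() == 0).any():
            raise DataError("empty tf_name in binding table")

    @property
    def tf_names(self) -> list[str]:
        return sorted(self.records["tf_name"].unique())

    def __len__(self) -> int:
        return len(self.records)


def load_tf_table(bed_path) -> TFBindingTable:
    """Read a BED4+ file of TF peaks (chrom, start, end, tf_name)."""
    rec = pd.read_csv(bed_path, sep="\t", header=None, usecols=[0, 1, 2, 3],
                      names=["chrom", "start", "end", "tf_name"],
                      dtype={"chrom": str, "tf_name": str})
    for col in ("start", "end"):
        vals = pd.to_numeric(rec[col], errors="raise")
        if not np.allclose(vals, np.round(vals)):
            raise DataError(f"non-integer coordinate in binding table column {col}")
        rec[col] = vals.astype(int)
    return TFBindingTable(rec)


def write_tf_table(table: TFBindingTable, path) -> None:
    table.records[["chrom", "start", "end", "tf_name"]].to_csv(
        path, sep="\t", header=False, index=False)


def probes_overlapping(tf: str, table: TFBindingTable, annotation: pd.DataFrame,
                       probe_ids) -> set[str]:
    """Probe ids whose CpG interval overlaps >=1 peak of ``tf`` by >=1 bp.

    Half-open semantics: a probe [150, 152) does not overlap a peak [50, 150).
    All requested probes must be present and mapped in the annotation.
    """
    probe_ids = set(map(str, probe_ids))
    known = set(annotation.index[annotation["mapped"]])
    unknown = sorted(probe_ids - known)
    if unknown:
        raise DataError(f"probes missing from annotation or unmapped: {unknown}")
    peaks = table.records[table.records["tf_name"] == tf]
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in peaks.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(grp["start"], grp["end"]))
    hits = set()
    sub = annotation.loc[sorted(probe_ids)]
    for probe_id, chrom, start, end in zip(sub["probe_id"], sub["chrom"],
                                           sub["start"], sub["end"]):
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(start, end):
            hits.add(probe_id)
    return hits


# ---------------------------------------------------------------------------
# joined dataset
# ---------------------------------------------------------------------------

@dataclass
class MethylomeDataset:
    """Beta matrix joined to sample metadata (and optionally probe annotation).

    After construction the beta columns and the sample-sheet rows are the
    same ids in the same order.
    """

    beta: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame | None = None

    def __post_init__(self):
        if list(self.beta.columns) != list(self.samples.index):
            raise DataError("beta columns do not match sample sheet order; "
                            "use align_dataset()")

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def ages(self) -> pd.Series:
        return self.samples["age"]

    def sample_mask(self, stratum) -> np.ndarray:
        """Boolean mask over samples from a pandas query string, a boolean
        array, or None (all samples)."""
        if stratum is None:
            return np.ones(self.n_samples, dtype=bool)
        if isinstance(stratum, str):
            idx = self.samples.query(stratum).index
            return self.samples.index.isin(idx)
        mask = np.asarray(stratum, dtype=bool)
        if mask.shape != (self.n_samples,):
            raise DataError(f"stratum mask has shape {mask.shape}, "
                            f"expected ({self.n_samples},)")
        return mask

    def subset(self, stratum) -> "MethylomeDataset":
        mask = self.sample_mask(stratum)
        return MethylomeDataset(self.beta.loc[:, mask],
                                self.samples.loc[mask],
                                self.annotation)


def align_dataset(beta: pd.DataFrame, samples: pd.DataFrame,
                  annotation: pd.DataFrame | None = None) -> MethylomeDataset:
    """Join a beta matrix and sample sheet on their common sample ids.

    Columns are reordered to the sheet's order; samples present in only one
    input are dropped with a logged count.  An empty intersection is an error.
    """
    shared = [s for s in samples.index if s in set(beta.columns)]
    if not shared:
        raise DataError("no sample ids shared between beta matrix and sample sheet")
    n_dropped = (len(samples) - len(shared)) + (beta.shape[1] - len(shared))
    if n_dropped:
        logger.info("align_dataset: dropped %d samples absent from one input",
                    n_dropped)
    return MethylomeDataset(beta.loc[:, shared], samples.loc[shared], annotation)


def load_dataset(beta_path, sheet_path, annotation_path=None) -> MethylomeDataset:
    """Load and align the three standard files into a MethylomeDataset."""
    beta = read_beta_matrix(beta_path)
    sheet = read_sample_sheet(sheet_path)
    ann = read_probe_annotation(annotation_path) if annotation_path else None
    return align_dataset(beta, sheet, ann)


def concat_datasets(a: MethylomeDataset, b: MethylomeDataset) -> MethylomeDataset:
    """Concatenate two datasets sample-wise over their shared probes
    (e.g. to pool two species for a dual-species clock)."""
    if set(a.samples.index) & set(b.samples.index):
        raise DataError("datasets share sample ids; cannot concatenate")
    probes = [p for p in a.beta.index if p in set(b.beta.index)]
    if not probes:
        raise DataError("datasets share no probes")
    beta = pd.concat([a.beta.loc[probes], b.beta.loc[probes]], axis=1)
    samples = pd.concat([a.samples, b.samples], axis=0)
    return MethylomeDataset(beta, samples, a.annotation)
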