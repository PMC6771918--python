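"""Copy-number profiles, chrY read-count vectors, and cohort manifests.

File formats (all plain text, UTF-8, LF endings):

* profile TSV — columns ``chrom  start  end  ratio`` (header optional), one
  row per grid bin; ``ratio`` is the per-bin log2 of observed/expected read
  counts.  Missing values are any of ``NaN``, ``NA``, ``nan`` or an empty
  field; absent rows likewise mark the bin as missing.
* Y-count TSV — columns ``chrom  start  end  normalized_count`` on the 5-kb
  chrY grid; ``normalized_count`` is reads in bin / total aligned reads.
* manifest CSV/TSV — header ``sample_id,path,sex[,ffy][,y_path]``.

Missing bins are carried as NaN in the profile array and exposed through a
boolean mask; they are never silently zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError
from .grids import BinGrid

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"NaN", "NA", "nan", ""}
SEX_ALIASES = {
    "male": "male", "m": "male",
    "female": "female", "f": "female",
    "unknown": "unknown", "u": "unknown", "na": "unknown", "": "unknown",
}


@dataclass
class CopyNumberProfile:
    """One sample's binned log2-ratio profile on a shared grid.

    ``log2_ratio`` has one entry per grid bin; NaN marks bins of
    undeterminable copy number.  ``y_counts`` optionally holds normalized
    read abundances on a separate (finer) chrY grid.
    """

    sample_id: str
    grid: BinGrid
    log2_ratio: np.ndarray
    sex_label: str = "unknown"
    y_counts: np.ndarray | None = None
    y_grid: BinGrid | None = None

    def __post_init__(self) -> None:
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        if self.log2_ratio.shape != (self.grid.n_bins,):
            raise FormatError(
                f"profile {self.sample_id!r}: {self.log2_ratio.shape[0]} values "
                f"for a grid of {self.grid.n_bins} bins"
            )
        if self.sex_label not in {"male", "female", "unknown"}:
            raise FormatError(f"bad sex label {self.sex_label!r}")
        if self.y_counts is not None:
            self.y_counts = np.asarray(self.y_counts, dtype=float)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of bins with no usable ratio."""
        return np.isnan(self.log2_ratio)

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.missing))


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    """Read a whitespace/tab table that may or may not carry a header row."""
    head = pd.read_csv(path, sep="\t", nrows=1, header=None, dtype=str)
    has_header = str(head.iloc[0, 0]).lstrip("#").strip().lower() == columns[0]
    df = pd.read_csv(
        path, sep="\t", header=0 if has_header else None, dtype=str,
        keep_default_na=False,
    )
    if df.shape[1] < len(columns):
        raise FormatError(
            f"{path}: expected {len(columns)} columns {columns}, got {df.shape[1]}"
        )
    df = df.iloc[:, : len(columns)]
    df.columns = columns
    # line number in the file, for error messages (1-based, header-aware)
    df["_line"] = np.arange(len(df)) + (2 if has_header else 1)
    return df


def _parse_values(df: pd.DataFrame, grid: BinGrid, value_col: str, path) -> np.ndarray:
    values = np.full(grid.n_bins, np.nan)
    seen = np.zeros(grid.n_bins, dtype=bool)
    chrom = df["chrom"].to_numpy()
    start = df["start"].astype(int).to_numpy()
    raw = df[value_col].to_numpy()
    lines = df["_line"].to_numpy()
    for c, s, v, ln in zip(chrom, start, raw, lines):
        idx = grid.index_of(c, int(s))
        if idx is None:
            raise FormatError(f"{path}, line {ln}: bin ({c}, {s}) not on the grid")
        if seen[idx]:
            raise FormatError(f"{path}, line {ln}: duplicate bin ({c}, {s})")
        seen[idx] = True
        token = str(v).strip()
        if token not in MISSING_TOKENS:
            values[idx] = float(token)
    return values


def read_profile(path, grid: BinGrid, sample_id: str | None = None) -> CopyNumberProfile:
    """Read a profile TSV onto ``grid``; unlisted grid bins become missing."""
    df = _read_table(path, ["chrom", "start", "end", "ratio"])
    values = _parse_values(df, grid, "ratio", path)
    sid = sample_id if sample_id is not None else str(path)
    return CopyNumberProfile(sid, grid, values)


def write_profile(profile: CopyNumberProfile, path) -> None:
    """Write a profile TSV (one row per grid bin, NaN token for missing)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("chrom\tstart\tend\tratio\n")
        for (c, s, e), v in zip(profile.grid.bins, profile.log2_ratio):
            token = "NaN" if np.isnan(v) else repr(float(v))
            fh.write(f"{c}\t{s}\t{e}\t{token}\n")


def read_y_counts(path, y_grid: BinGrid) -> np.ndarray:
    """Read normalized chrY 5-kb read abundances onto ``y_grid``.

    Bins absent from the file are taken as zero observed reads (a count of 0
    is informative for chrY, unlike an undeterminable log2 ratio).
    """
    df = _read_table(path, ["chrom", "start", "end", "normalized_count"])
    values = _parse_values(df, y_grid, "normalized_count", path)
    return np.nan_to_num(values, nan=0.0)


def write_y_counts(counts: np.ndarray, y_grid: BinGrid, path) -> None:
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (y_grid.n_bins,):
        raise FormatError("y-count vector does not match the Y grid")
    with open(path, "w", newline="\n") as fh:
        fh.write("chrom\tstart\tend\tnormalized_count\n")
        for (c, s, e), v in zip(y_grid.bins, counts):
            fh.write(f"{c}\t{s}\t{e}\t{float(v)!r}\n")


@dataclass
class ManifestRecord:
    sample_id: str
    path: str
    sex: str
    ffy: float | None = None
    y_path: str | None = None


@dataclass
class CohortManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def validate_paths(self) -> list[str]:
        """Return one message per missing profile/Y-count file, with row numbers."""
        import os

        problems = []
        for i, rec in enumerate(self.records, start=1):
            if not os.path.exists(rec.path):
                problems.append(f"row {i}: profile path not found: {rec.path}")
            if rec.y_path and not os.path.exists(rec.y_path):
                problems.append(f"row {i}: y-count path not found: {rec.y_path}")
        return problems


def normalize_sex(token: str) -> str:
    key = str(token).strip().lower()
    if key not in SEX_ALIASES:
        raise FormatError(f"unrecognized sex token {token!r}")
    return SEX_ALIASES[key]


def read_manifest(path) -> CohortManifest:
    """Read a cohort manifest (CSV or TSV, sniffed from the header line)."""
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        warnings.warn(f"{path}: empty manifest")
        return CohortManifest([])
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"sample_id", "path", "sex"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    ids = df["sample_id"].tolist()
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicate sample_id(s): {', '.join(dupes)}")
    records = []
    for _, row in df.iterrows():
        ffy = None
        if "ffy" in df.columns and str(row["ffy"]).strip() != "":
            ffy = float(row["ffy"])
        y_path = None
        if "y_path" in df.columns and str(row["y_path"]).strip() != "":
            y_path = str(row["y_path"])
        records.append(
            ManifestRecord(row["sample_id"], row["path"], normalize_sex(row["sex"]),
                           ffy=ffy, y_path=y_path)
        )
    if not records:
        warnings.warn(f"{path}: manifest has a header but no rows")
    return CohortManifest(records)


def write_manifest(manifest: CohortManifest, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("sample_id,path,sex,ffy,y_path\n")
        for rec in manifest.records:
            ffy = "" if rec.ffy is None else repr(rec.ffy)
            fh.write(f"{rec.sample_id},{rec.path},{rec.sex},{ffy},{rec.y_path or ''}\n")
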