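"""Peak lists and depth-profile matrices: reading, thresholding, the
assign/separate workflow, and depth-trend labelling.

A peak list is a delimited text export (tab, comma or semicolon) with a
header naming an ``mz`` column, an optional ``intensity`` column and any
number of per-scan columns (``scan_0001`` ...) that together form each
peak's depth profile. The iterative filter mirrors the two-pass
workflow used on real instrument exports: assign a first chemistry,
separate what matched, re-search the remainder with the next box.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import AssignmentSet, SearchConstraints, assign_peaklist

__all__ = [
    "Peak",
    "PeakList",
    "read_peaklist",
    "write_peaklist",
    "apply_intensity_threshold",
    "separate",
    "iterative_filter",
    "extract_depth_profiles",
    "depth_trend",
]


@dataclass(frozen=True)
class Peak:
    id: str
    mz: float
    total_intensity: float
    profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mz) or self.mz <= 0:
            raise ValueError(f"peak {self.id!r}: m/z must be positive and finite")
        if self.total_intensity < 0:
            raise ValueError(f"peak {self.id!r}: intensity must be >= 0")


@dataclass
class PeakList:
    """An ordered collection of peaks from one depth-profile acquisition."""

    peaks: list[Peak] = field(default_factory=list)
    polarity: str | None = None
    n_scans: int = 0
    metadata: str = ""

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise ValueError("peak ids must be unique")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def ids(self) -> list[str]:
        return [p.id for p in self.peaks]

    def get(self, peak_id: str) -> Peak:
        for p in self.peaks:
            if p.id == peak_id:
                return p
        raise KeyError(f"unknown peak id {peak_id!r}")

    def subset(self, ids) -> "PeakList":
        wanted = set(ids)
        unknown = wanted - set(self.ids())
        if unknown:
            raise KeyError(f"unknown peak ids: {sorted(unknown)}")
        return PeakList(
            peaks=[p for p in self.peaks if p.id in wanted],
            polarity=self.polarity,
            n_scans=self.n_scans,
            metadata=self.metadata,
        )


def _sniff_delimiter(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    counts = {d: header.count(d) for d in ("\t", ",", ";")}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise ValueError(f"{path}: could not detect a delimiter in the header")
    return best


def _find_column(columns, names) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for name in names:
        if name in lowered:
            return lowered[name]
    return None


def read_peaklist(
    path: str | Path,
    delimiter: str | None = None,
    polarity: str | None = None,
) -> PeakList:
    """Read a delimited peak-list export.

    The delimiter is auto-detected among tab/comma/semicolon unless
    forced. Columns: ``mz`` (required; ``m/z`` accepted), ``intensity``
    (optional when scan columns exist — then it is their sum), ``id``
    (optional; generated as p0001... otherwise) and any columns starting
    with ``scan`` taken in file order as the depth profile. Non-numeric
    cells are rejected with their row number. Duplicate m/z rows are
    legal (vendor exports can contain shoulder peaks) and keep distinct
    ids.
    """
    delim = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    mz_col = _find_column(df.columns, ["mz", "m/z"])
    if mz_col is None:
        raise ValueError(f"{path}: no 'mz' column in header {list(df.columns)}")
    inten_col = _find_column(df.columns, ["intensity", "total_intensity"])
    id_col = _find_column(df.columns, ["id", "peak_id"])
    scan_cols = [c for c in df.columns if c.lower().startswith("scan")]

    def numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric value in column {col!r} at row {row}")
        return vals.to_numpy(dtype=float)

    mz = numeric(mz_col)
    profiles = (
        np.column_stack([numeric(c) for c in scan_cols]) if scan_cols else None
    )
    if inten_col is not None:
        total = numeric(inten_col)
    elif profiles is not None:
        total = profiles.sum(axis=1)
    else:
        raise ValueError(f"{path}: need an intensity column or scan columns")

    ids = (
        df[id_col].astype(str).tolist()
        if id_col is not None
        else [f"p{i + 1:04d}" for i in range(len(df))]
    )
    peaks = [
        Peak(
            id=ids[i],
            mz=float(mz[i]),
            total_intensity=float(total[i]),
            profile=profiles[i].copy() if profiles is not None else None,
        )
        for i in range(len(df))
    ]
    return PeakList(
        peaks=peaks,
        polarity=polarity,
        n_scans=len(scan_cols),
        metadata=f"read from {path}",
    )


def _fmt_float(x: float) -> str:
    # >=6 decimal places (1 ppm at m/z 100 is 1e-4), full precision kept
    s = f"{x:.6f}"
    return s if float(s) == x else repr(float(x))


def write_peaklist(pl: PeakList, path: str | Path, delimiter: str = "\t") -> None:
    """Write a peak list in the same dialect :func:`read_peaklist` reads."""
    buf = io.StringIO()
    scan_cols = [f"scan_{i + 1:04d}" for i in range(pl.n_scans)]
    buf.write(delimiter.join(["id", "mz", "intensity"] + scan_cols) + "\n")
    for p in pl.peaks:
        row = [p.id, _fmt_float(p.mz), _fmt_float(p.total_intensity)]
        if pl.n_scans:
            prof = p.profile if p.profile is not None else np.zeros(pl.n_scans)
            row += [_fmt_float(float(v)) for v in prof]
        buf.write(delimiter.join(row) + "\n")
    Path(path).write_text(buf.getvalue())


def apply_intensity_threshold(pl: PeakList, min_counts: float) -> PeakList:
    """Drop peaks below the minimum total intensity, preserving order.

    Mirrors the manual noise cut applied when exporting instrument peak
    searches; the threshold is sample-specific and chosen by the user.
    """
    if min_counts < 0:
        raise ValueError("min_counts must be >= 0")
    return PeakList(
        peaks=[p for p in pl.peaks if p.total_intensity >= min_counts],
        polarity=pl.polarity,
        n_scans=pl.n_scans,
        metadata=pl.metadata,
    )


def separate(pl: PeakList, aset: AssignmentSet) -> tuple[PeakList, PeakList]:
    """Partition a peak list into (assigned, unassigned) by an assignment.

    The two halves are disjoint, their union is the input, and peak
    content is untouched.
    """
    known = set(pl.ids())
    referenced = set(aset.peak_ids)
    unknown = referenced - known
    if unknown:
        raise KeyError(f"assignment references unknown peak ids: {sorted(unknown)}")
    assigned_ids = set(aset.candidates)
    assigned = PeakList(
        peaks=[p for p in pl.peaks if p.id in assigned_ids],
        polarity=pl.polarity,
        n_scans=pl.n_scans,
        metadata=pl.metadata,
    )
    unassigned = PeakList(
        peaks=[p for p in pl.peaks if p.id not in assigned_ids],
        polarity=pl.polarity,
        n_scans=pl.n_scans,
        metadata=pl.metadata,
    )
    return assigned, unassigned


def iterative_filter(
    pl: PeakList, stages: list[SearchConstraints], **flags
) -> tuple[list[AssignmentSet], PeakList]:
    """Run assign -> separate repeatedly: stage k searches the residue of
    stage k-1, so each peak is annotated by at most one stage. Returns
    the per-stage assignment sets and the final residue."""
    if not stages:
        raise ValueError("at least one search stage required")
    residue = pl
    results: list[AssignmentSet] = []
    for constraints in stages:
        aset = assign_peaklist(residue, constraints, **flags)
        results.append(aset)
        _, residue = separate(residue, aset)
    return results, residue


def extract_depth_profiles(
    pl: PeakList, peak_ids=None, normalize: bool = False
) -> pd.DataFrame:
    """Depth-profile matrix (peaks x scans) for the requested ids.

    Rows come back in request order; with ``normalize=True`` each row is
    scaled to unit maximum (rows of all zeros stay zero).
    """
    ids = list(peak_ids) if peak_ids is not None else pl.ids()
    rows = []
    for pid in ids:
        peak = pl.get(pid)
        if peak.profile is None:
            raise ValueError(f"peak {pid!r} has no depth profile")
        prof = np.asarray(peak.profile, dtype=float)
        if normalize and prof.max() > 0:
            prof = prof / prof.max()
        rows.append(prof)
    columns = [f"scan_{i + 1:04d}" for i in range(pl.n_scans)]
    return pd.DataFrame(rows, index=ids, columns=columns)


def depth_trend(profile) -> str:
    """Classify a depth profile by comparing the mean intensity of the
    first and last third of scans: rising intensity with sputter dose is
    'substrate-like', falling is 'overlayer-like', ties are 'flat'. No
    smoothing is applied."""
    prof = np.asarray(profile, dtype=float)
    if prof.size < 2:
        raise ValueError("profile needs at least 2 scans")
    k = max(1, prof.size // 3)
    first, last = prof[:k].mean(), prof[-k:].mean()
    if last > first:
        return "substrate-like"
    if first > last:
        return "overlayer-like"
    return "flat"
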