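"""Peak-list containers and I/O.

A :class:`PeakList` holds the cross-peaks of one spectrum: each
:class:`Peak` carries K chemical shifts (ppm), and the list carries one
positional uncertainty per spectral dimension (also ppm).  Reference and
target spectra are matched dimension-by-dimension, so two lists entering
a matching run must share K (and, when both declare axis nuclei, the same
nucleus on each axis).

Supported on-disk formats are Sparky/POKY ``.list`` exports (whitespace
table: assignment label followed by K shift columns, optionally trailing
height/volume columns) and generic delimited tables with a header row.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakList",
    "PeakListError",
    "read_sparky_list",
    "read_delimited",
    "write_match_report",
    "read_match_report",
    "validate_pair",
    "NO_MATCH",
]

#: Sentinel used wherever a reference peak is assigned to no target peak.
NO_MATCH = "NO_MATCH"


class PeakListError(ValueError):
    """Raised for malformed peak-list files or inconsistent dimensions."""


@dataclass(frozen=True)
class Peak:
    """A single cross-peak: integer id, optional assignment label, K shifts in ppm."""

    peak_id: int
    shifts: tuple[float, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(s) for s in self.shifts):
            raise PeakListError(f"peak {self.peak_id}: non-finite chemical shift")


@dataclass
class PeakList:
    """An ordered collection of cross-peaks from one spectrum.

    Parameters
    ----------
    spectrum_id:
        Free-form identifier (file stem by default).
    sigmas:
        Positional uncertainty per dimension, ppm; strictly positive.
    peaks:
        Peaks in acquisition/file order; ``peak_id`` equals row index.
    axis_nuclei:
        Optional nucleus label per axis, e.g. ``("H", "N")``.
    """

    spectrum_id: str
    sigmas: tuple[float, ...]
    peaks: list[Peak] = field(default_factory=list)
    axis_nuclei: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.sigmas = tuple(float(s) for s in self.sigmas)
        if any(s <= 0 or not math.isfinite(s) for s in self.sigmas):
            raise PeakListError("all sigmas must be finite and > 0")
        if not self.peaks:
            raise PeakListError("peak list contains no peaks")
        k = len(self.sigmas)
        for p in self.peaks:
            if len(p.shifts) != k:
                raise PeakListError(
                    f"peak {p.peak_id} has {len(p.shifts)} shifts, expected {k}"
                )
        ids = [p.peak_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise PeakListError("duplicate peak_id")
        if self.axis_nuclei is not None and len(self.axis_nuclei) != k:
            raise PeakListError("axis_nuclei length must equal dimensionality")

    @property
    def ndim(self) -> int:
        """Number of spectral dimensions K."""
        return len(self.sigmas)

    def __len__(self) -> int:
        return len(self.peaks)

    def shift_array(self) -> np.ndarray:
        """(n_peaks, K) array of chemical shifts."""
        return np.array([p.shifts for p in self.peaks], dtype=float)

    def labels(self) -> list[str]:
        return [p.label if p.label is not None else str(p.peak_id) for p in self.peaks]


def validate_pair(ref: PeakList, tgt: PeakList) -> None:
    """Check that two lists can be matched: equal K and compatible axis nuclei."""
    if ref.ndim != tgt.ndim:
        raise PeakListError(
            f"dimension mismatch: reference K={ref.ndim}, target K={tgt.ndim}"
        )
    if ref.axis_nuclei is not None and tgt.axis_nuclei is not None:
        if tuple(ref.axis_nuclei) != tuple(tgt.axis_nuclei):
            raise PeakListError(
                f"axis nuclei differ: {ref.axis_nuclei} vs {tgt.axis_nuclei}"
            )


def _parse_float(token: str, path: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise PeakListError(
            f"{path}:{lineno}: cannot parse shift value {token!r}"
        ) from exc


def read_sparky_list(
    path: str | Path,
    sigmas: Sequence[float],
    *,
    spectrum_id: str | None = None,
    axis_nuclei: Sequence[str] | None = None,
) -> PeakList:
    """Read a Sparky/POKY ``.list`` peak list.

    The expected layout is one peak per line: an assignment label followed
    by K whitespace-separated shifts.  A header line starting with
    ``Assignment`` and blank lines are skipped; trailing non-numeric or
    extra numeric columns (heights, volumes) beyond the first K numeric
    columns are ignored, but every data row must supply at least K numeric
    columns and all rows must agree on the column count.
    """
    path = Path(path)
    k = len(sigmas)
    peaks: list[Peak] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            toks = line.split()
            if lineno == 1 and toks[0].lower().startswith("assignment"):
                continue
            if ncols is None:
                ncols = len(toks)
            elif len(toks) != ncols:
                raise PeakListError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(toks)} vs {ncols} earlier)"
                )
            if len(toks) < 1 + k:
                raise PeakListError(
                    f"{path}:{lineno}: expected a label plus {k} shift columns, "
                    f"got {len(toks)} columns"
                )
            shifts = tuple(_parse_float(t, str(path), lineno) for t in toks[1 : 1 + k])
            peaks.append(Peak(peak_id=len(peaks), shifts=shifts, label=toks[0]))
    if not peaks:
        raise PeakListError(f"{path}: no peaks found")
    return PeakList(
        spectrum_id=spectrum_id or path.stem,
        sigmas=tuple(sigmas),
        peaks=peaks,
        axis_nuclei=tuple(axis_nuclei) if axis_nuclei is not None else None,
    )


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text()[:4096]
    header = sample.splitlines()[0] if sample.splitlines() else ""
    has_comma = "," in header
    has_tab = "\t" in header
    if has_comma and has_tab:
        raise PeakListError(f"{path}: ambiguous delimiter (header has both ',' and tab)")
    if has_comma:
        return ","
    if has_tab:
        return "\t"
    raise PeakListError(f"{path}: could not detect delimiter (expected CSV or TSV)")


def read_delimited(
    path: str | Path,
    shift_columns: Sequence[str],
    sigmas: Sequence[float],
    *,
    spectrum_id: str | None = None,
    axis_nuclei: Sequence[str] | None = None,
) -> PeakList:
    """Read a CSV/TSV peak table with a header row.

    ``shift_columns`` names the K shift columns in axis order; a ``label``
    column is used for assignments when present.  The delimiter is
    auto-detected between comma and tab.
    """
    path = Path(path)
    if len(shift_columns) != len(sigmas):
        raise PeakListError(
            f"{len(shift_columns)} shift columns but {len(sigmas)} sigmas"
        )
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in shift_columns if c not in df.columns]
    if missing:
        raise PeakListError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise PeakListError(f"{path}: no peaks found")
    labels = df["label"].astype(str).tolist() if "label" in df.columns else None
    peaks = []
    for i, row in enumerate(df.itertuples(index=False)):
        shifts = []
        for c in shift_columns:
            v = df[c].iloc[i]
            try:
                shifts.append(float(v))
            except (TypeError, ValueError) as exc:
                raise PeakListError(f"{path}: non-numeric value {v!r} in column {c}") from exc
        peaks.append(
            Peak(peak_id=i, shifts=tuple(shifts), label=labels[i] if labels else None)
        )
    return PeakList(
        spectrum_id=spectrum_id or path.stem,
        sigmas=tuple(sigmas),
        peaks=peaks,
        axis_nuclei=tuple(axis_nuclei) if axis_nuclei is not None else None,
    )


_REPORT_COLUMNS = [
    "reference_id",
    "reference_label",
    "target_id",
    "target_label",
    "posterior_probability",
    "csp_ppm",
    "csp_posterior_mass",
    "csp_estimate_mean",
    "csp_estimate_sd",
]


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_match_report(report, path: str | Path) -> None:
    """Write a match report (see :mod:`shiftmatch.analysis`) to CSV.

    One row per reference peak; ``target_id`` holds the literal string
    ``NO_MATCH`` for unmatched references, in which case the CSP columns
    are left empty.  Values round-trip at 6 significant digits.
    """
    rows = report.rows if hasattr(report, "rows") else report
    path = Path(path)
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(_REPORT_COLUMNS)
    for r in rows:
        w.writerow([_fmt(getattr(r, c)) for c in _REPORT_COLUMNS])
    path.write_text(buf.getvalue())


def read_match_report(path: str | Path) -> pd.DataFrame:
    """Read a match-report CSV back into a DataFrame (target_id stays string)."""
    return pd.read_csv(path, dtype={"target_id": str, "reference_label": str,
                                    "target_label": str})
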