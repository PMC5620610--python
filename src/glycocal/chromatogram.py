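"""Reading, windowing and peak-picking of SEC chromatograms.

A chromatogram is a uniformly sampled time/intensity series tagged with its
detection wavelength (232 nm for the enoxaparin backbone chromophore, 310 nm
for the pNP-tagged standards).  Files are plain two-column CSV
(``time_min,intensity``); integration is trapezoidal on the uniform grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Chromatogram",
    "Peak",
    "AnalysisWindow",
    "ChromatogramFormatError",
    "read_chromatogram",
    "write_chromatogram",
    "detect_peaks",
    "apply_window",
    "total_area",
]

_UNIFORM_TOL = 1e-6  # max allowed deviation of grid spacing, minutes


class ChromatogramFormatError(ValueError):
    """Raised for unreadable or malformed chromatogram files."""


@dataclass
class Chromatogram:
    times: np.ndarray  # minutes, strictly increasing, uniform spacing
    intensities: np.ndarray  # detector response, arbitrary units
    wavelength: float  # nm
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("chromatogram needs at least 2 points")
        if self.intensities.shape != self.times.shape:
            raise ValueError("times and intensities must have equal length")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if dt.max() - dt.min() > _UNIFORM_TOL:
            raise ValueError("time grid must be uniform (resample first)")

    @property
    def dt(self) -> float:
        """Grid spacing in minutes."""
        return float(self.times[1] - self.times[0])

    def scaled(self, factor: float) -> "Chromatogram":
        return replace(self, intensities=self.intensities * factor)


@dataclass(frozen=True)
class Peak:
    apex_rt: float  # minutes
    start: float  # minutes
    end: float  # minutes
    area: float  # intensity * min (trapezoidal)
    height: float

    def __post_init__(self) -> None:
        if not (self.start < self.apex_rt < self.end):
            raise ValueError("peak bounds must bracket the apex")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass(frozen=True)
class AnalysisWindow:
    """Retention-time window retained for analysis (salt/solvent peaks excluded)."""

    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("window requires t_min < t_max")


def read_chromatogram(path: str | Path, wavelength: float, label: str = "") -> Chromatogram:
    """Read a two-column ``time_min,intensity`` CSV (header optional).

    Non-uniformly sampled input is resampled onto a uniform grid by linear
    interpolation (with a warning); times must be strictly increasing.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ChromatogramFormatError(f"cannot read {path}: {exc}") from exc
    # Drop a header row if the first row is non-numeric.
    first = frame.iloc[0]
    try:
        [float(v) for v in first]
    except (TypeError, ValueError):
        frame = frame.iloc[1:]
    if frame.shape[1] < 2:
        raise ChromatogramFormatError(f"{path}: expected two columns")
    try:
        times = frame.iloc[:, 0].astype(float).to_numpy()
        intensities = frame.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        bad = int(np.argmax([not _is_number(v) for v in frame.iloc[:, 0]]))
        raise ChromatogramFormatError(f"{path}: non-numeric value near row {bad + 1}") from exc
    if times.size < 2:
        raise ChromatogramFormatError(f"{path}: need at least 2 data rows")
    dt = np.diff(times)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 2
        raise ChromatogramFormatError(f"{path}: time not increasing at row {row}")
    if dt.max() - dt.min() > _UNIFORM_TOL:
        warnings.warn(f"{path}: non-uniform sampling; resampling onto a uniform grid")
        grid = np.linspace(times[0], times[-1], times.size)
        intensities = np.interp(grid, times, intensities)
        times = grid
    return Chromatogram(times, intensities, wavelength, label=label or path.stem)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_chromatogram(c: Chromatogram, path: str | Path) -> None:
    """Write a chromatogram as ``time_min,intensity`` CSV with header."""
    frame = pd.DataFrame({"time_min": c.times, "intensity": c.intensities})
    frame.to_csv(path, index=False)


def total_area(c: Chromatogram) -> float:
    """Trapezoidal area under the trace (intensity * min)."""
    return float(np.trapezoid(c.intensities, c.times))


def detect_peaks(
    c: Chromatogram, min_height_frac: float = 0.05, min_separation: float = 0.2
) -> list[Peak]:
    """Detect peaks as local maxima above ``min_height_frac`` of the global max.

    Maxima closer than ``min_separation`` minutes are merged (highest wins);
    peak bounds are placed at the flanking minima (or trace edges) and areas
    integrated trapezoidally between them.  A flat or empty-signal trace
    yields no peaks.
    """
    if not 0 < min_height_frac < 1:
        raise ValueError("min_height_frac must be in (0, 1)")
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    y = c.intensities
    ymax = float(y.max())
    if ymax <= 0 or np.allclose(y, y[0]):
        return []
    distance = max(1, int(round(min_separation / c.dt)))
    idx, _ = find_peaks(y, height=min_height_frac * ymax, distance=distance)
    if idx.size == 0:
        return []
    peaks: list[Peak] = []
    bounds = np.empty(idx.size + 1, dtype=int)
    bounds[0] = 0
    bounds[-1] = y.size - 1
    for k in range(idx.size - 1):
        seg = slice(idx[k], idx[k + 1] + 1)
        bounds[k + 1] = idx[k] + int(np.argmin(y[seg]))
    for k, i in enumerate(idx):
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        if hi <= lo:  # pragma: no cover - guards degenerate adjacency
            continue
        area = float(np.trapezoid(y[lo : hi + 1], c.times[lo : hi + 1]))
        peaks.append(
            Peak(
                apex_rt=float(c.times[i]),
                start=float(c.times[lo]),
                end=float(c.times[hi]),
                area=max(area, 0.0),
                height=float(y[i]),
            )
        )
    return peaks


def apply_window(c: Chromatogram, w: AnalysisWindow) -> Chromatogram:
    """Restrict a chromatogram to times within ``[t_min, t_max]``."""
    mask = (c.times >= w.t_min) & (c.times <= w.t_max)
    if mask.sum() < 2:
        raise ValueError(
            f"window [{w.t_min}, {w.t_max}] overlaps fewer than 2 samples of "
            f"[{c.times[0]:.3f}, {c.times[-1]:.3f}]"
        )
    return Chromatogram(c.times[mask], c.intensities[mask], c.wavelength, label=c.label)
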