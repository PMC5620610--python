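"""Slice analysis: weight-average MW and MW-distribution fractions.

A calibrated chromatogram is divided into slices, one per sampling point: the
calibration model assigns each slice a molecular weight M_i and the detector
signal supplies its abundance N_i.  The weight-average molecular weight is

    Mw = sum_i(N_i * M_i^2) / sum_i(N_i * M_i)

with N_i the number of molecules at M_i.  Under UV detection at 232 nm each
enoxaparin chain carries one unsaturated-uronate chromophore, so the signal is
taken as proportional to molar chain concentration (``detector="molar"``,
N_i = intensity); for mass-proportional detectors such as RI use
``detector="mass"`` (N_i = intensity / M_i).

Distribution fractions (M2000, M2000-8000, M8000) are mass-fraction
percentages: shares of sum(N_i * M_i) below 2000 Da, within [2000, 8000] Da,
and above 8000 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from glycocal.calibration import CalibrationModel, predict_mw
from glycocal.chromatogram import AnalysisWindow, Chromatogram, apply_window

__all__ = [
    "SliceDistribution",
    "MwResult",
    "MonographCheck",
    "MonographCriterion",
    "chromatogram_to_distribution",
    "compute_mw",
    "compute_mn",
    "compute_distribution_fractions",
    "analyze_distribution",
    "check_monograph",
    "round_to_50",
]

# Pharmacopeial acceptance limits for enoxaparin MW analysis.
RS_LABEL_MW = 4370.0  # Da, reference-standard label value
RS_TOLERANCE = 150.0  # Da
SAMPLE_MW_RANGE = (3800.0, 5000.0)  # Da
M2000_RANGE = (12.0, 20.0)  # %
M2000_8000_RANGE = (68.0, 82.0)  # %
M8000_MAX = 18.0  # %


@dataclass
class SliceDistribution:
    """Per-slice (M_i, N_i) pairs with extrapolation bookkeeping."""

    m: np.ndarray  # Da, > 0
    n: np.ndarray  # molar abundance, >= 0, arbitrary units
    detector: str = "molar"
    extrapolated: Optional[np.ndarray] = None  # bool mask, slices outside rt_range

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.m.shape != self.n.shape or self.m.ndim != 1:
            raise ValueError("m and n must be 1-d arrays of equal length")
        if np.any(self.m <= 0):
            raise ValueError("all slice masses must be positive")
        if np.any(self.n < 0):
            raise ValueError("slice abundances must be non-negative")
        if self.n.sum() <= 0:
            raise ValueError("distribution carries no signal")
        if self.extrapolated is None:
            self.extrapolated = np.zeros(self.m.shape, dtype=bool)


def chromatogram_to_distribution(
    c: Chromatogram,
    model: CalibrationModel,
    window: AnalysisWindow | None = None,
    detector: str = "molar",
) -> SliceDistribution:
    """Convert a 232 nm chromatogram into a slice distribution.

    Each sampling point inside the window becomes one slice with
    ``M_i = predict_mw(model, t_i)``.  Negative intensities (baseline noise)
    are clipped to zero abundance.  Slices whose retention time lies outside
    the model's training range are flagged as extrapolated.
    """
    if detector not in ("molar", "mass"):
        raise ValueError("detector must be 'molar' or 'mass'")
    if window is not None:
        c = apply_window(c, window)
    mw, flag = predict_mw(model, c.times)
    mw = np.atleast_1d(mw)
    if np.any(~np.isfinite(mw)) or np.any(mw <= 0):
        raise ValueError("calibration produced non-positive or non-finite MW")
    n = np.clip(c.intensities, 0.0, None)
    if detector == "mass":
        n = n / mw
    if n.sum() <= 0:
        raise ValueError("no signal inside the analysis window")
    return SliceDistribution(m=mw, n=n, detector=detector, extrapolated=np.atleast_1d(flag))


def compute_mw(d: SliceDistribution) -> float:
    """Weight-average molecular weight: sum(N*M^2) / sum(N*M)."""
    nm = d.n * d.m
    denom = float(nm.sum())
    if denom <= 0:
        raise ValueError("sum(N*M) is zero; Mw undefined")
    return float((nm * d.m).sum() / denom)


def compute_mn(d: SliceDistribution) -> float:
    """Number-average molecular weight: sum(N*M) / sum(N)."""
    total_n = float(d.n.sum())
    if total_n <= 0:
        raise ValueError("sum(N) is zero; Mn undefined")
    return float((d.n * d.m).sum() / total_n)


def compute_distribution_fractions(
    d: SliceDistribution, basis: str = "mass"
) -> tuple[float, float, float]:
    """Percentages of the distribution below 2000 Da, in [2000, 8000] Da and
    above 8000 Da.

    ``basis="mass"`` (default) shares out sum(N_i*M_i); ``basis="molar"``
    shares out sum(N_i).  Boundaries: M2000 is strict (< 2000), the middle
    band is the closed interval [2000, 8000], M8000 is strict (> 8000).
    """
    if basis == "mass":
        wgt = d.n * d.m
    elif basis == "molar":
        wgt = d.n
    else:
        raise ValueError("basis must be 'mass' or 'molar'")
    total = float(wgt.sum())
    if total <= 0:
        raise ValueError("distribution carries no weight")
    low = float(wgt[d.m < 2000.0].sum()) / total * 100.0
    high = float(wgt[d.m > 8000.0].sum()) / total * 100.0
    mid = 100.0 - low - high
    return (low, mid, high)


def round_to_50(mw: float) -> float:
    """Round an Mw to the nearest 50 Da (reporting convention)."""
    return 50.0 * round(mw / 50.0)


@dataclass
class MwResult:
    mw: float  # Da, raw
    m2000: float  # % below 2000 Da
    m2000_8000: float  # % in [2000, 8000] Da
    m8000: float  # % above 8000 Da
    extrapolated_pct: float = 0.0  # % of signal assigned by extrapolation

    @property
    def mw_rounded_50(self) -> float:
        return round_to_50(self.mw)

    def to_dict(self) -> dict:
        return {
            "mw_da": self.mw,
            "mw_rounded_50": self.mw_rounded_50,
            "m2000_pct": self.m2000,
            "m2000_8000_pct": self.m2000_8000,
            "m8000_pct": self.m8000,
            "extrapolated_pct": self.extrapolated_pct,
        }


def analyze_distribution(d: SliceDistribution, basis: str = "mass") -> MwResult:
    """Compute Mw, distribution fractions and the extrapolated signal share."""
    low, mid, high = compute_distribution_fractions(d, basis=basis)
    total = float(d.n.sum())
    extrap = float(d.n[d.extrapolated].sum()) / total * 100.0 if total > 0 else 0.0
    return MwResult(
        mw=compute_mw(d), m2000=low, m2000_8000=mid, m8000=high, extrapolated_pct=extrap
    )


@dataclass(frozen=True)
class MonographCriterion:
    name: str
    value: float
    low: Optional[float]
    high: Optional[float]
    passed: bool

    @property
    def allowed(self) -> str:
        lo = "-inf" if self.low is None else f"{self.low:g}"
        hi = "+inf" if self.high is None else f"{self.high:g}"
        return f"[{lo}, {hi}]"


@dataclass
class MonographCheck:
    criteria: list[MonographCriterion] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.criteria)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "criteria": [
                {
                    "name": c.name,
                    "value": c.value,
                    "allowed": c.allowed,
                    "passed": c.passed,
                }
                for c in self.criteria
            ],
        }


def _criterion(name: str, value: float, low: float | None, high: float | None) -> MonographCriterion:
    ok = (low is None or value >= low) and (high is None or value <= high)
    return MonographCriterion(name=name, value=value, low=low, high=high, passed=ok)


def check_monograph(r: MwResult, rs_mw: float | None = None) -> MonographCheck:
    """Evaluate the pharmacopeial acceptance criteria for an enoxaparin sample.

    * reference standard Mw within 4370 +/- 150 Da (only when ``rs_mw`` given);
    * sample Mw in the closed interval [3800, 5000] Da;
    * M2000 in [12.0, 20.0] %;
    * M2000-8000 in [68.0, 82.0] %;
    * M8000 not more than 18.0 %.
    """
    check = MonographCheck()
    if rs_mw is not None:
        check.criteria.append(
            _criterion(
                "reference standard Mw (4370+/-150 Da)",
                rs_mw,
                RS_LABEL_MW - RS_TOLERANCE,
                RS_LABEL_MW + RS_TOLERANCE,
            )
        )
    check.criteria.append(_criterion("sample Mw (Da)", r.mw, *SAMPLE_MW_RANGE))
    check.criteria.append(_criterion("M2000 (%)", r.m2000, *M2000_RANGE))
    check.criteria.append(_criterion("M2000-8000 (%)", r.m2000_8000, *M2000_8000_RANGE))
    check.criteria.append(_criterion("M8000 (%)", r.m8000, None, M8000_MAX))
    return check
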