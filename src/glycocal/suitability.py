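"""Dual-wavelength system-suitability procedure.

Three pNP-tagged internal standards (by default the 8-mer NS, 12-mer NS6S and
16-mer NS6S oligosaccharides) are co-injected with the enoxaparin sample.
Their retention times are verified at 310 nm against expected values within
+/-0.1 min; their residual absorbance at 232 nm — predetermined by running the
standards alone — is then subtracted from the sample trace before slice
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from glycocal.chromatogram import Chromatogram, detect_peaks

__all__ = [
    "SuitabilityEntry",
    "SuitabilityReport",
    "DEFAULT_INTERNAL_STANDARDS",
    "DEFAULT_RT_TOLERANCE",
    "check_internal_standards",
    "subtract_standard_trace",
]

# Compound ids of the default internal standards: 8-mer NS, 12-mer NS6S,
# 16-mer NS6S.
DEFAULT_INTERNAL_STANDARDS: tuple[int, ...] = (7, 19, 21)
DEFAULT_RT_TOLERANCE = 0.1  # minutes


@dataclass(frozen=True)
class SuitabilityEntry:
    name: str
    expected_rt: float  # minutes
    observed_rt: Optional[float]  # nearest detected apex, None if unmatched
    delta: Optional[float]  # observed - expected, minutes
    passed: bool


@dataclass
class SuitabilityReport:
    entries: list[SuitabilityEntry] = field(default_factory=list)
    tolerance: float = DEFAULT_RT_TOLERANCE

    @property
    def passed(self) -> bool:
        return bool(self.entries) and all(e.passed for e in self.entries)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "tolerance_min": self.tolerance,
            "standards": [
                {
                    "name": e.name,
                    "expected_rt_min": e.expected_rt,
                    "observed_rt_min": e.observed_rt,
                    "delta_min": e.delta,
                    "passed": e.passed,
                }
                for e in self.entries
            ],
        }


def check_internal_standards(
    c310: Chromatogram,
    expected: Sequence[tuple[str, float]],
    tolerance: float = DEFAULT_RT_TOLERANCE,
    min_height_frac: float = 0.05,
    min_separation: float = 0.2,
) -> SuitabilityReport:
    """Verify internal-standard retention times on the 310 nm trace.

    Peaks are detected and each expected standard is matched to the nearest
    apex (ties toward earlier RT); the check passes only if every standard is
    matched within ``tolerance`` minutes.  A trace with no detectable peaks
    yields a failing report, not an exception.
    """
    if not expected:
        raise ValueError("expected standards list is empty")
    peaks = detect_peaks(c310, min_height_frac=min_height_frac, min_separation=min_separation)
    apexes = np.array([p.apex_rt for p in peaks])
    report = SuitabilityReport(tolerance=tolerance)
    for name, rt in expected:
        if apexes.size == 0:
            report.entries.append(SuitabilityEntry(name, rt, None, None, False))
            continue
        dist = np.abs(apexes - rt)
        best = int(np.argmin(dist))  # argmin takes the first (earlier RT) on ties
        observed = float(apexes[best])
        delta = observed - rt
        report.entries.append(
            SuitabilityEntry(name, rt, observed, delta, abs(delta) <= tolerance)
        )
    return report


def subtract_standard_trace(
    c232_mixture: Chromatogram,
    c232_standards: Chromatogram,
    scale: float = 1.0,
) -> Chromatogram:
    """Remove the internal standards' 232 nm contribution from a mixture trace.

    The standards-alone trace is resampled onto the mixture grid by linear
    interpolation and subtracted pointwise (``mixture - scale * standards``);
    ``scale=1.0`` assumes the same injected amount in both runs.  Negative
    residuals are clipped to zero with a warning.
    """
    if round(c232_mixture.wavelength) != round(c232_standards.wavelength):
        raise ValueError(
            f"wavelength mismatch: {c232_mixture.wavelength} vs {c232_standards.wavelength} nm"
        )
    lo = max(c232_mixture.times[0], c232_standards.times[0])
    hi = min(c232_mixture.times[-1], c232_standards.times[-1])
    if lo >= hi:
        raise ValueError("chromatogram time ranges do not overlap")
    resampled = np.interp(
        c232_mixture.times, c232_standards.times, c232_standards.intensities, left=0.0, right=0.0
    )
    corrected = c232_mixture.intensities - scale * resampled
    n_neg = int((corrected < 0).sum())
    if n_neg:
        warnings.warn(
            f"subtraction produced {n_neg} negative intensities; clipped to zero"
        )
        corrected = np.clip(corrected, 0.0, None)
    return Chromatogram(
        c232_mixture.times,
        corrected,
        c232_mixture.wavelength,
        label=f"{c232_mixture.label}-corrected",
    )
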