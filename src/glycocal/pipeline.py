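"""One-command orchestration of the dual-wavelength analysis workflow.

Order of operations: verify internal-standard retention times on the 310 nm
trace; if the system is suitable (or strict gating is disabled), subtract the
predetermined standards contribution from the 232 nm trace, convert it to a
slice distribution with the configured calibration model, compute Mw and the
distribution fractions, and evaluate the monograph criteria.  With strict
gating (the default) a failed suitability check withholds the Mw section
entirely — no result is reported from an unsuitable system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from glycocal.calibration import CalibrationModel
from glycocal.chromatogram import AnalysisWindow, Chromatogram
from glycocal.mw_metrics import (
    MonographCheck,
    MwResult,
    analyze_distribution,
    check_monograph,
    chromatogram_to_distribution,
)
from glycocal.suitability import (
    DEFAULT_RT_TOLERANCE,
    SuitabilityReport,
    check_internal_standards,
    subtract_standard_trace,
)

__all__ = ["RunConfig", "RunReport", "run_analysis", "default_window"]


def default_window(points, pre_margin: float = 1.0, post_margin: float = 1.0) -> AnalysisWindow:
    """Analysis window derived from the calibration standards' RT span.

    Everything later than the last standard's RT plus ``post_margin`` minutes
    is treated as salt/solvent and excluded; the early bound is the first
    standard's RT minus ``pre_margin``.
    """
    rts = [p.rt for p in points]
    return AnalysisWindow(min(rts) - pre_margin, max(rts) + post_margin)


@dataclass
class RunConfig:
    """Inputs for one analysis run.

    ``mixture_232`` may be a single chromatogram or a sequence of duplicate
    injections; duplicates are analyzed independently and reported as
    mean +/- sd.
    """

    model: CalibrationModel
    mixture_310: Chromatogram
    mixture_232: Chromatogram | Sequence[Chromatogram]
    standards_232: Optional[Chromatogram]  # predetermined standards-alone trace
    expected_rts: Sequence[tuple[str, float]]
    window: Optional[AnalysisWindow] = None
    detector: str = "molar"
    tolerance: float = DEFAULT_RT_TOLERANCE
    subtraction_scale: float = 1.0
    strict: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class RunReport:
    suitability: SuitabilityReport
    verdict: str  # "ok", "monograph fail", or "not suitable"
    mw_result: Optional[MwResult] = None
    monograph: Optional[MonographCheck] = None
    replicate_mw: Optional[list[float]] = None
    mw_sd: Optional[float] = None
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "suitability": self.suitability.to_dict(),
            "mw_result": self.mw_result.to_dict() if self.mw_result else None,
            "monograph": self.monograph.to_dict() if self.monograph else None,
            "replicate_mw": self.replicate_mw,
            "mw_sd": self.mw_sd,
            "provenance": self.provenance,
            "warnings": self.warnings,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _model_provenance(model: CalibrationModel) -> dict:
    info: dict = {"model_type": type(model).__name__}
    for attr in ("C", "epsilon", "gamma", "cv_sse", "r_squared"):
        if hasattr(model, attr):
            info[attr] = getattr(model, attr)
    if hasattr(model, "rt_range"):
        info["rt_range_min"] = list(model.rt_range)
    return info


def run_analysis(cfg: RunConfig) -> RunReport:
    """Execute the full suitability-gated analysis and return a report."""
    suitability = check_internal_standards(
        cfg.mixture_310, cfg.expected_rts, tolerance=cfg.tolerance
    )
    report = RunReport(
        suitability=suitability,
        verdict="ok",
        provenance=_model_provenance(cfg.model),
    )
    if not suitability.passed:
        if cfg.strict:
            report.verdict = "not suitable"
            return report
        report.warnings.append("suitability failed; proceeding (strict gating disabled)")

    mixtures = (
        [cfg.mixture_232] if isinstance(cfg.mixture_232, Chromatogram) else list(cfg.mixture_232)
    )
    results: list[MwResult] = []
    for mixture in mixtures:
        corrected = mixture
        if cfg.standards_232 is not None:
            import warnings as _warnings

            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                corrected = subtract_standard_trace(
                    mixture, cfg.standards_232, scale=cfg.subtraction_scale
                )
            report.warnings.extend(str(w.message) for w in caught)
        dist = chromatogram_to_distribution(
            corrected, cfg.model, window=cfg.window, detector=cfg.detector
        )
        results.append(analyze_distribution(dist))

    if len(results) == 1:
        report.mw_result = results[0]
    else:
        mws = np.array([r.mw for r in results])
        report.replicate_mw = [float(v) for v in mws]
        report.mw_sd = float(mws.std(ddof=1))
        report.mw_result = MwResult(
            mw=float(mws.mean()),
            m2000=float(np.mean([r.m2000 for r in results])),
            m2000_8000=float(np.mean([r.m2000_8000 for r in results])),
            m8000=float(np.mean([r.m8000 for r in results])),
            extrapolated_pct=float(np.mean([r.extrapolated_pct for r in results])),
        )
    report.monograph = check_monograph(report.mw_result)
    if not report.monograph.passed:
        report.verdict = "monograph fail"
    return report
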