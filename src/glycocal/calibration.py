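"""RT -> MW calibration models for SEC analysis of heparin oligosaccharides.

Two calibration strategies are provided:

* the pharmacopeial cubic regression of log10(MW) on retention time, fitted by
  unweighted least squares; and
* a weighted radial-basis-function support-vector regressor (RBF-SVM) in which
  each standard's contribution to the loss is multiplied by a group weight
  reflecting the relative molar abundance of its repeating disaccharide unit
  in enoxaparin (tri-sulfated series and dp4/dp6 weighted 10, NS6S series 4,
  NS2S series 2, all others 1).

Both models map retention time (minutes) to log10(MW/Da).  Validation
follows standard QSAR practice: leave-one-out cross-validated q² and
Y-randomization (label permutation) to confirm the RT-MW relationship is not
chance correlation.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR

from glycocal.masses import StandardRecord

__all__ = [
    "CalibrationPoint",
    "WeightScheme",
    "CubicModel",
    "SvmModel",
    "ValidationReport",
    "DEFAULT_SVM_GRID",
    "EXCLUDED_COMPOUNDS",
    "assemble_training_set",
    "fit_cubic",
    "fit_svm",
    "predict_mw",
    "loo_q2",
    "y_randomize",
    "save_model",
    "load_model",
]

# Small synthetic oligosaccharides whose SEC behaviour deviates from the
# enoxaparin-like calibrants at the low-MW end: the 8-mer and 10-mer
# N-acetylated compounds and the 8-mer N-sulfated compound.  They are
# replaced in that range by the commercial dp4/dp6 oligosaccharides.
EXCLUDED_COMPOUNDS: tuple[int, ...] = (1, 2, 7)


@dataclass(frozen=True)
class CalibrationPoint:
    mw: float  # Da
    rt: float  # minutes
    group: str  # structural group A..G
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.mw <= 0 or self.rt <= 0:
            raise ValueError("mw and rt must be positive")
        if self.weight < 1:
            raise ValueError("weight must be >= 1")


@dataclass(frozen=True)
class WeightScheme:
    """Per-group loss weights for the SVM calibration."""

    factors: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1, "B": 1, "C": 2, "D": 4, "E": 10, "F": 10, "G": 1}
    )

    def weight(self, group: str) -> float:
        return float(self.factors.get(group, 1.0))


def assemble_training_set(
    panel: Sequence[StandardRecord],
    rts: Mapping[Union[int, str], float],
    scheme: WeightScheme | None = None,
) -> list[CalibrationPoint]:
    """Combine the standards panel with measured retention times.

    The three low-MW outlier compounds (``EXCLUDED_COMPOUNDS``) are dropped;
    every remaining standard must have a retention time.  With the full
    36-record panel this yields 33 calibration points (24 synthetic + dp4/dp6
    + 7 calibrant peaks), each carrying its group weight.
    """
    scheme = scheme or WeightScheme()
    points: list[CalibrationPoint] = []
    for rec in panel:
        if rec.compound_id in EXCLUDED_COMPOUNDS:
            continue
        if rec.compound_id not in rts:
            raise KeyError(f"missing retention time for standard {rec.compound_id!r} ({rec.name})")
        points.append(
            CalibrationPoint(
                mw=rec.reported_mw,
                rt=float(rts[rec.compound_id]),
                group=rec.group,
                weight=scheme.weight(rec.group),
            )
        )
    return points


# --------------------------------------------------------------------------
# cubic model


@dataclass
class CubicModel:
    """log10(MW) = a0 + a1*RT + a2*RT^2 + a3*RT^3 (unweighted least squares)."""

    coefficients: np.ndarray  # (a0, a1, a2, a3)
    r_squared: float
    rt_range: tuple[float, float]

    def predict_log10_mw(self, rt: np.ndarray | float) -> np.ndarray | float:
        rt = np.asarray(rt, dtype=float)
        out = np.polynomial.polynomial.polyval(rt, self.coefficients)
        return out if out.ndim else float(out)


def fit_cubic(points: Sequence[CalibrationPoint]) -> CubicModel:
    """Fit the pharmacopeial cubic of log10(MW) versus RT.

    Requires at least four distinct retention times; R² is computed on the
    fitted points themselves.
    """
    rts = np.array([p.rt for p in points], dtype=float)
    y = np.log10([p.mw for p in points])
    if np.unique(rts).size < 4:
        raise ValueError("cubic fit requires >= 4 points with distinct RTs")
    vander = np.vander(rts, 4, increasing=True)
    coeffs, *_ = np.linalg.lstsq(vander, y, rcond=None)
    resid = y - vander @ coeffs
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CubicModel(
        coefficients=coeffs,
        r_squared=r2,
        rt_range=(float(rts.min()), float(rts.max())),
    )


# --------------------------------------------------------------------------
# weighted RBF-SVM model

# Hyperparameter grid searched by weighted leave-one-out CV; gamma applies to
# standardized RT.
DEFAULT_SVM_GRID: dict[str, tuple[float, ...]] = {
    "C": (1.0, 10.0, 100.0, 1000.0),
    "epsilon": (0.001, 0.01, 0.05),
    "gamma": (0.1, 0.5, 1.0, 2.0),
}

_SVR_TOL = 1e-8  # libsvm stopping tolerance; tight so weighting == replication
# During hyperparameter search only, fits are compared at a looser stopping
# tolerance and a capped iteration count; the winning combination is refitted
# to full convergence.  Selection stays deterministic.
_SVR_CV_TOL = 1e-4
_SVR_CV_MAX_ITER = 20_000


@dataclass
class SvmModel:
    """Trained weighted RBF support-vector regressor state.

    Prediction is evaluated directly from the stored support data:
    ``log10(MW) = sum_j dual_j * exp(-gamma * (x - sv_j)^2) + b`` with
    ``x = (RT - rt_mean) / rt_scale``.
    """

    support_x: np.ndarray  # standardized support RTs
    dual_coef: np.ndarray
    intercept: float
    C: float
    epsilon: float
    gamma: float
    rt_mean: float
    rt_scale: float
    rt_range: tuple[float, float]
    cv_sse: float = float("nan")  # weighted LOO-CV squared error at selection

    def predict_log10_mw(self, rt: np.ndarray | float) -> np.ndarray | float:
        rt = np.asarray(rt, dtype=float)
        x = (np.atleast_1d(rt) - self.rt_mean) / self.rt_scale
        k = np.exp(-self.gamma * (x[:, None] - self.support_x[None, :]) ** 2)
        out = k @ self.dual_coef + self.intercept
        return out if rt.ndim else float(out[0])


CalibrationModel = Union[CubicModel, SvmModel]


def _fit_svr(x, y, w, C, epsilon, gamma, tol: float = _SVR_TOL, max_iter: int = -1) -> SVR:
    svr = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma, tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svr.fit(x.reshape(-1, 1), y, sample_weight=w)
    return svr


def _grid_combos(grid: Mapping[str, Iterable[float]]) -> list[tuple[float, float, float]]:
    combos = list(itertools.product(grid["C"], grid["epsilon"], grid["gamma"]))
    if not combos:
        raise ValueError("hyperparameter grid is empty")
    return combos


def fit_svm(
    points: Sequence[CalibrationPoint],
    grid: Mapping[str, Iterable[float]] | None = None,
    seed: int = 0,
    rt_stats: tuple[float, float] | None = None,
) -> SvmModel:
    """Fit the weighted RBF-SVM calibration of log10(MW) on standardized RT.

    Sample weights multiply the per-point loss (equivalent to replicating a
    point ``w`` times).  Hyperparameters are selected from the grid by
    minimizing the weighted leave-one-out squared prediction error; ties break
    to the first grid combination in (C, epsilon, gamma) order, so the fit is
    deterministic for a fixed grid.  ``seed`` is accepted for interface
    symmetry; the fit itself has no stochastic component.  ``rt_stats``
    overrides the standardization constants (mean, scale), e.g. to share them
    across refits of modified copies of one training set.
    """
    if len(points) < 5:
        raise ValueError("SVM calibration requires >= 5 points")
    grid = dict(grid) if grid is not None else DEFAULT_SVM_GRID
    combos = _grid_combos(grid)
    rts = np.array([p.rt for p in points], dtype=float)
    y = np.log10([p.mw for p in points])
    w = np.array([p.weight for p in points], dtype=float)
    if rt_stats is not None:
        mean, scale = float(rt_stats[0]), float(rt_stats[1])
    else:
        mean, scale = float(rts.mean()), float(rts.std())
    if scale == 0:
        raise ValueError("retention times are all identical")
    x = (rts - mean) / scale

    best: tuple[float, float, float] | None = None
    best_sse = np.inf
    n = x.size
    for C, epsilon, gamma in combos:
        sse = 0.0
        for i in range(n):
            mask = np.arange(n) != i
            svr = _fit_svr(
                x[mask], y[mask], w[mask], C, epsilon, gamma,
                tol=_SVR_CV_TOL, max_iter=_SVR_CV_MAX_ITER,
            )
            pred = float(svr.predict(x[i].reshape(1, 1))[0])
            sse += w[i] * (y[i] - pred) ** 2
            if sse >= best_sse:
                break
        if sse < best_sse:
            best_sse, best = sse, (C, epsilon, gamma)
    assert best is not None
    C, epsilon, gamma = best
    svr = _fit_svr(x, y, w, C, epsilon, gamma)
    return SvmModel(
        support_x=svr.support_vectors_.ravel().copy(),
        dual_coef=svr.dual_coef_.ravel().copy(),
        intercept=float(svr.intercept_[0]),
        C=C,
        epsilon=epsilon,
        gamma=gamma,
        rt_mean=mean,
        rt_scale=scale,
        rt_range=(float(rts.min()), float(rts.max())),
        cv_sse=float(best_sse),
    )


def predict_mw(
    model: CalibrationModel, rt: np.ndarray | float
) -> tuple[np.ndarray | float, np.ndarray | bool]:
    """Predict MW (Da) at retention time(s) and flag extrapolation.

    The flag is true wherever ``rt`` falls outside the model's training RT
    range; extrapolated predictions are returned but should be interpreted
    with care.
    """
    arr = np.asarray(rt, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("retention times must be finite")
    if np.any(arr <= 0):
        raise ValueError("retention times must be positive")
    log_mw = model.predict_log10_mw(arr)
    mw = np.power(10.0, log_mw)
    lo, hi = model.rt_range
    flag = (arr < lo) | (arr > hi)
    if arr.ndim == 0:
        return float(mw), bool(flag)
    return mw, flag


# --------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """LOO-CV q² with optional Y-randomization distribution."""

    q2: float
    n_points: int
    model_type: str
    y_randomized_q2: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if self.q2 > 1 + 1e-12:
            raise ValueError("q2 cannot exceed 1")


def _refit_predict_loo(
    points: Sequence[CalibrationPoint], model: str, fit_kwargs: dict
) -> np.ndarray:
    """Leave-one-out predictions of log10(MW) with weights preserved."""
    n = len(points)
    preds = np.empty(n)
    for i in range(n):
        train = [p for j, p in enumerate(points) if j != i]
        if model == "cubic":
            m: CalibrationModel = fit_cubic(train)
        elif model == "svm":
            m = fit_svm(train, **fit_kwargs)
        else:
            raise ValueError(f"unknown model spec {model!r}")
        preds[i] = np.atleast_1d(m.predict_log10_mw(points[i].rt))[0]
    return preds


def loo_q2(
    points: Sequence[CalibrationPoint],
    model: str = "svm",
    **fit_kwargs,
) -> ValidationReport:
    """Leave-one-out cross-validated q² on log10(MW).

    ``q² = 1 − Σ(yᵢ − ŷ₋ᵢ)² / Σ(yᵢ − ȳ)²`` where ``ŷ₋ᵢ`` is the prediction
    of a model refitted without point ``i`` (group weights preserved;
    residuals unweighted).  For the SVM spec the hyperparameters are selected
    once on the full set and held fixed across folds.
    """
    if len(points) < 5:
        raise ValueError("q2 requires >= 5 points")
    y = np.log10([p.mw for p in points])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("q2 undefined: zero variance in log10(MW)")
    if model == "svm" and "grid" not in fit_kwargs:
        full = fit_svm(points, **fit_kwargs)
        fit_kwargs = {
            **fit_kwargs,
            "grid": {"C": (full.C,), "epsilon": (full.epsilon,), "gamma": (full.gamma,)},
        }
    preds = _refit_predict_loo(points, model, fit_kwargs)
    press = float(np.sum((y - preds) ** 2))
    return ValidationReport(q2=1.0 - press / ss_tot, n_points=len(points), model_type=model)


def y_randomize(
    points: Sequence[CalibrationPoint],
    model: str = "svm",
    rounds: int = 20,
    seed: int = 0,
    **fit_kwargs,
) -> ValidationReport:
    """Y-randomization: permute the MW labels, refit, and collect q² values.

    A real RT-MW relationship should give an original q² far above every
    permuted q².  Weights stay attached to their (RT, group) positions; only
    the MW labels are shuffled.  Deterministic for a fixed seed.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    base = loo_q2(points, model=model, **fit_kwargs)
    rng = np.random.default_rng(seed)
    permuted_q2: list[float] = []
    for _ in range(rounds):
        perm = rng.permutation(len(points))
        shuffled = [
            CalibrationPoint(mw=points[j].mw, rt=p.rt, group=p.group, weight=p.weight)
            for p, j in zip(points, perm)
        ]
        try:
            rep = loo_q2(shuffled, model=model, **fit_kwargs)
            permuted_q2.append(rep.q2)
        except ValueError:  # pragma: no cover - degenerate permutation
            permuted_q2.append(float("nan"))
    return ValidationReport(
        q2=base.q2,
        n_points=len(points),
        model_type=model,
        y_randomized_q2=permuted_q2,
    )


# --------------------------------------------------------------------------
# serialization


def save_model(model: CalibrationModel, path: str | Path) -> None:
    """Serialize a calibration model to JSON."""
    if isinstance(model, CubicModel):
        doc = {
            "type": "cubic",
            "coefficients": list(map(float, model.coefficients)),
            "r_squared": model.r_squared,
            "rt_range": list(model.rt_range),
        }
    elif isinstance(model, SvmModel):
        doc = {
            "type": "svm",
            "support_x": model.support_x.tolist(),
            "dual_coef": model.dual_coef.tolist(),
            "intercept": model.intercept,
            "C": model.C,
            "epsilon": model.epsilon,
            "gamma": model.gamma,
            "rt_mean": model.rt_mean,
            "rt_scale": model.rt_scale,
            "rt_range": list(model.rt_range),
            "cv_sse": model.cv_sse,
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> CalibrationModel:
    doc = json.loads(Path(path).read_text())
    if doc["type"] == "cubic":
        return CubicModel(
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            r_squared=float(doc["r_squared"]),
            rt_range=tuple(doc["rt_range"]),
        )
    if doc["type"] == "svm":
        return SvmModel(
            support_x=np.asarray(doc["support_x"], dtype=float),
            dual_coef=np.asarray(doc["dual_coef"], dtype=float),
            intercept=float(doc["intercept"]),
            C=float(doc["C"]),
            epsilon=float(doc["epsilon"]),
            gamma=float(doc["gamma"]),
            rt_mean=float(doc["rt_mean"]),
            rt_scale=float(doc["rt_scale"]),
            rt_range=tuple(doc["rt_range"]),
            cv_sse=float(doc.get("cv_sse", float("nan"))),
        )
    raise ValueError(f"unknown model type {doc.get('type')!r}")
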