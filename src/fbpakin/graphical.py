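"""Graphical (linearized) estimation of the total distribution volume Vt.

Three linearizations of reversible-tracer kinetics are implemented, each an
ordinary least-squares regression over the frames at/after the equilibration
time t*:

* Logan plot:   int_0^T C / C(T)  =  Vt * int_0^T Cp / C(T)  +  b
* MA1:          C(T) = -(Vt/b) int_0^T Cp  +  (1/b) int_0^T C
* MA2:          C(T) = g1 iint Cp + g2 iint C + g3 int C + g4 int Cp
                with Vt = -g1/g2 and g4 an estimate of K1.

Frames are timestamped at their midpoints; tissue integrals use the trapezoid
rule with an initial triangle from (0, 0); plasma integrals use the exact
hybrid input curve.  For the multilinear models the regression domain is
C(T) itself, for the Logan plot it is the transformed ordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .input_function import PlasmaInput, cumulative_plasma_integral, evaluate_plasma
from .tac_data import TissueTAC, ValidationError, _as_float_array

__all__ = [
    "MODELS",
    "RateConstants",
    "GraphicalFit",
    "TStarResult",
    "SingularDesignError",
    "vt_from_rates",
    "cumulative_integral",
    "fit_logan",
    "fit_ma1",
    "fit_ma2",
    "fit_model",
    "find_t_star",
]

MODELS = ("logan", "ma1", "ma2")

#: regression coefficients per model
N_COEF = {"logan": 2, "ma1": 2, "ma2": 4}


class SingularDesignError(ValidationError):
    """Regression design matrix is rank-deficient (degenerate data)."""


@dataclass(frozen=True)
class RateConstants:
    """Two-tissue-compartment rates: K1 (ml/ml/min), k2, k3, k4 (1/min).

    k3 = k4 = 0 collapses to the one-tissue model.
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0

    def __post_init__(self):
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValidationError("rate constants must be non-negative")
        if self.k2 <= 0:
            raise ValidationError("k2 must be positive")
        if self.k3 > 0 and self.k4 <= 0:
            raise ValidationError("reversible model requires k4 > 0 when k3 > 0")

    @property
    def vt(self) -> float:
        return vt_from_rates(self)


def vt_from_rates(rates: RateConstants) -> float:
    """Closed-form total distribution volume (K1/k2)(1 + k3/k4)."""
    if rates.k2 <= 0:
        raise ValidationError("k2 must be positive")
    vt = rates.K1 / rates.k2
    if rates.k3 > 0:
        vt *= 1.0 + rates.k3 / rates.k4
    return vt


@dataclass(frozen=True)
class GraphicalFit:
    """Result of one graphical regression for one VOI."""

    model: str
    voi_name: str
    vt: float  # ml/ml
    intercept: float | None  # b, Logan/MA1 only
    gammas: np.ndarray | None  # MA2 coefficients g1..g4
    t_star: float  # min
    n_points_used: int
    times_used: np.ndarray  # frame midpoints entering the regression
    observed: np.ndarray  # regression-domain observations
    fitted: np.ndarray
    residuals: np.ndarray
    vt_se: float | None = None  # delta-method standard error of Vt
    warnings: tuple = ()

    @property
    def ssr(self) -> float:
        return float(np.sum(self.residuals ** 2))

    @property
    def is_reliable(self) -> bool:
        """Quality-control verdict on the Vt estimate.

        A fit is rejected when Vt is non-positive or non-finite, or when the
        relative standard error of Vt exceeds 50% — the conventional cutoff
        for discarding non-identifiable kinetic parameter estimates.  A
        flipped gamma sign alone does not reject: under near-collinearity
        the coefficients are individually unstable while their ratio (Vt)
        remains well determined, and the ratio is what the SE tests.
        """
        if not np.isfinite(self.vt) or self.vt <= 0:
            return False
        if self.vt_se is not None and not (self.vt_se <= 0.5 * self.vt):
            return False
        return True

    @property
    def k1_estimate(self) -> float | None:
        """MA2's g4 coefficient estimates K1; undefined for other models."""
        return float(self.gammas[3]) if self.gammas is not None else None


@dataclass(frozen=True)
class TStarResult:
    t_star: float
    converged: bool
    fit: GraphicalFit


def cumulative_integral(times, values) -> np.ndarray:
    """Running trapezoid integral at each time, with a triangle from (0, 0).

    The curve is taken as 0 at t = 0 (before bolus arrival) and linear
    between points, so the integral up to the first time is a triangle.
    """
    t = _as_float_array(times, "times")
    v = _as_float_array(values, "values")
    if t.size != v.size:
        raise ValidationError("times and values differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    if t[0] < 0:
        raise ValidationError("times must be non-negative")
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[0.0], v])
        drop_first = True
    else:
        drop_first = False
    cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * (v[:-1] + v[1:]) / 2.0)])
    return cum[1:] if drop_first else cum


def frame_cumulative_integral(tissue: TissueTAC) -> np.ndarray:
    """Running integral of the TAC up to each frame midpoint, frame-aware.

    A frame value is the time average of C over the frame, so its exact
    contribution to the integral is value x duration.  Gaps between frames
    and the half-frame up to the midpoint are filled assuming C is locally
    linear; any lead-in before the first frame is a triangle from (0, 0).
    This uses strictly more information than a midpoint trapezoid and is
    what makes graphical fits of coarse whole-body frames essentially
    unbiased.
    """
    sched = tissue.schedule
    c = tissue.activity
    starts, durs, mids = sched.frame_starts, sched.frame_durations, sched.midpoints
    lead_in = c[0] * starts[0] ** 2 / (2.0 * mids[0]) if starts[0] > 0 else 0.0
    gaps = starts[1:] - (starts[:-1] + durs[:-1])
    gap_area = gaps * (c[:-1] + c[1:]) / 2.0
    full = c * durs
    cum = np.empty(sched.n_frames)
    before = lead_in  # integral up to the start of frame k
    for k in range(sched.n_frames):
        cum[k] = before + c[k] * durs[k] / 2.0
        before += full[k]
        if k < sched.n_frames - 1:
            before += gap_area[k]
    return cum


def _series(tissue: TissueTAC, plasma: PlasmaInput):
    t = tissue.times
    c = tissue.activity
    cum_c = frame_cumulative_integral(tissue)
    cum_cp = cumulative_plasma_integral(plasma, t)
    return t, c, cum_c, cum_cp


def _mask_after(t: np.ndarray, t_star: float) -> np.ndarray:
    return t >= t_star - 1e-9


def _is_identity(tissue: TissueTAC, plasma: PlasmaInput) -> bool:
    cp = evaluate_plasma(plasma, tissue.times)
    scale = np.maximum(np.abs(cp), 1e-300)
    return bool(np.all(np.abs(tissue.activity - cp) / scale < 1e-12))


def _identity_fit(model: str, tissue: TissueTAC, t_star: float, mask) -> GraphicalFit:
    t = tissue.times[mask]
    obs = tissue.activity[mask]
    zeros = np.zeros_like(obs)
    return GraphicalFit(
        model=model, voi_name=tissue.voi_name, vt=1.0, intercept=0.0, gammas=None,
        t_star=t_star, n_points_used=int(mask.sum()), times_used=t,
        observed=obs, fitted=obs.copy(), residuals=zeros, vt_se=0.0,
        warnings=("identity-input",),
    )


def _lstsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularDesignError(
            f"singular design matrix (rank {rank} < {X.shape[1]})"
        )
    return beta


def _coef_cov(X: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """OLS coefficient covariance, s^2 (X'X)^-1 with s^2 = SSR/(n-p)."""
    n, p = X.shape
    s2 = float(np.sum(residuals ** 2)) / (n - p)
    return s2 * np.linalg.inv(X.T @ X)


def _delta_se(cov: np.ndarray, grad: np.ndarray) -> float:
    var = float(grad @ cov @ grad)
    return float(np.sqrt(max(var, 0.0)))


def fit_logan(tissue: TissueTAC, plasma: PlasmaInput, t_star: float) -> GraphicalFit:
    """Logan plot: slope of int C / C(T) against int Cp / C(T) after t*."""
    t, c, cum_c, cum_cp = _series(tissue, plasma)
    mask = _mask_after(t, t_star)
    if mask.sum() < 3:
        raise ValidationError(
            f"Logan fit needs >= 3 frames with midpoint >= {t_star:g} min")
    zero = mask & (c <= 0)
    if zero.any():
        frame = int(np.nonzero(zero)[0][0])
        raise ValidationError(
            f"VOI {tissue.voi_name!r}: C(T) = 0 in frame {frame + 1} after t*")
    if _is_identity(tissue, plasma):
        return _identity_fit("logan", tissue, t_star, mask)
    x = cum_cp[mask] / c[mask]
    y = cum_c[mask] / c[mask]
    X = np.column_stack([x, np.ones_like(x)])
    slope, intercept = _lstsq(X, y)
    fitted = slope * x + intercept
    cov = _coef_cov(X, y - fitted)
    return GraphicalFit(
        model="logan", voi_name=tissue.voi_name, vt=float(slope),
        intercept=float(intercept), gammas=None, t_star=float(t_star),
        n_points_used=int(mask.sum()), times_used=t[mask],
        observed=y, fitted=fitted, residuals=y - fitted,
        vt_se=float(np.sqrt(cov[0, 0])),
    )


def fit_ma1(tissue: TissueTAC, plasma: PlasmaInput, t_star: float) -> GraphicalFit:
    """MA1: regress C(T) on [int Cp, int C]; Vt = -beta1/beta2."""
    t, c, cum_c, cum_cp = _series(tissue, plasma)
    mask = _mask_after(t, t_star)
    if mask.sum() < 3:
        raise ValidationError(
            f"MA1 fit needs >= 3 frames with midpoint >= {t_star:g} min")
    if _is_identity(tissue, plasma):
        return _identity_fit("ma1", tissue, t_star, mask)
    X = np.column_stack([cum_cp[mask], cum_c[mask]])
    y = c[mask]
    b1, b2 = _lstsq(X, y)
    if b2 == 0:
        raise SingularDesignError("MA1: 1/b coefficient is zero")
    vt = -b1 / b2
    fitted = X @ np.array([b1, b2])
    cov = _coef_cov(X, y - fitted)
    se = _delta_se(cov, np.array([-1.0 / b2, b1 / b2**2]))
    return GraphicalFit(
        model="ma1", voi_name=tissue.voi_name, vt=float(vt),
        intercept=float(1.0 / b2), gammas=None, t_star=float(t_star),
        n_points_used=int(mask.sum()), times_used=t[mask],
        observed=y, fitted=fitted, residuals=y - fitted, vt_se=se,
    )


def fit_ma2(tissue: TissueTAC, plasma: PlasmaInput, t_star: float = 20.0) -> GraphicalFit:
    """MA2: regress C(T) on [iint Cp, iint C, int C, int Cp]; Vt = -g1/g2.

    Double integrals are trapezoid integrals of the running single integrals,
    with the same (0, 0) origin.  A non-negative g2 is physically impossible
    (g2 = -k2/k4) and is flagged, not raised.
    """
    t, c, cum_c, cum_cp = _series(tissue, plasma)
    mask = _mask_after(t, t_star)
    if mask.sum() < 5:
        raise ValidationError(
            f"MA2 fit needs >= 5 frames with midpoint >= {t_star:g} min")
    ccum_c = cumulative_integral(t, cum_c)
    ccum_cp = cumulative_integral(t, cum_cp)
    X = np.column_stack([ccum_cp[mask], ccum_c[mask], cum_c[mask], cum_cp[mask]])
    y = c[mask]
    gammas = _lstsq(X, y)
    warnings = ()
    if gammas[1] >= 0:
        warnings = ("unphysical-fit: gamma2 >= 0",)
        vt = np.inf if gammas[1] == 0 else -gammas[0] / gammas[1]
    else:
        vt = -gammas[0] / gammas[1]
    fitted = X @ gammas
    if gammas[1] != 0:
        cov = _coef_cov(X, y - fitted)
        se = _delta_se(cov, np.array([-1.0 / gammas[1], gammas[0] / gammas[1] ** 2,
                                      0.0, 0.0]))
    else:
        se = np.inf
    return GraphicalFit(
        model="ma2", voi_name=tissue.voi_name, vt=float(vt), intercept=None,
        gammas=gammas, t_star=float(t_star), n_points_used=int(mask.sum()),
        times_used=t[mask], observed=y, fitted=fitted, residuals=y - fitted,
        vt_se=se, warnings=warnings,
    )


_FITTERS = {"logan": fit_logan, "ma1": fit_ma1, "ma2": fit_ma2}


def fit_model(model: str, tissue: TissueTAC, plasma: PlasmaInput, t_star: float) -> GraphicalFit:
    if model not in _FITTERS:
        raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")
    return _FITTERS[model](tissue, plasma, t_star)


def find_t_star(
    tissue: TissueTAC,
    plasma: PlasmaInput,
    model: str = "logan",
    max_rel_error: float = 0.01,
) -> TStarResult:
    """Earliest frame midpoint after which the plot is linear within tolerance.

    t* is the smallest midpoint such that, refitting on the frames at/after
    it, the maximum relative deviation |fitted - observed| / |fitted| does
    not exceed ``max_rel_error`` (default 1%).  If no candidate qualifies,
    the latest midpoint that still leaves enough points is returned with
    ``converged=False``.
    """
    if model not in ("logan", "ma1"):
        raise ValidationError("t* search applies to the Logan plot and MA1 only")
    t = tissue.times
    min_points = N_COEF[model] + 1
    candidates = [tm for tm in t if np.sum(_mask_after(t, tm)) >= min_points]
    if not candidates:
        raise ValidationError(
            f"not enough frames for a {model} fit (need {min_points})")
    last_fit = None
    for tm in candidates:
        fit = fit_model(model, tissue, plasma, tm)
        last_fit = fit
        denom = np.maximum(np.abs(fit.fitted), 1e-300)
        if float(np.max(np.abs(fit.residuals) / denom)) <= max_rel_error:
            return TStarResult(float(tm), True, fit)
    return TStarResult(float(candidates[-1]), False, last_fit)
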