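"""Goodness-of-fit metrics and cross-model comparison.

Metrics are computed in each model's own regression domain: C(T) for the
multilinear models, the transformed ordinate for the Logan plot.  The
comparison ranks models by AIC (ascending), breaking ties by Sy.x and then
by the distance of the reduced chi-square from 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphical import GraphicalFit, N_COEF
from .tac_data import ValidationError, _as_float_array

__all__ = [
    "GofReport",
    "ModelComparison",
    "aic",
    "reduced_chi_square",
    "sy_x",
    "r_squared",
    "gof_report",
    "compare_models",
]


@dataclass(frozen=True)
class GofReport:
    model: str
    n: int  # frames used
    p: int  # regression coefficients
    ssr: float
    aic: float
    chi2_reduced: float
    sy_x: float
    r2: float
    exact_fit: bool = False


def aic(n: int, p: int, ssr: float, corrected: bool = False) -> float:
    """Least-squares Akaike information criterion, n*ln(SSR/n) + 2p.

    ``corrected=True`` adds the small-sample AICc term 2p(p+1)/(n-p-1);
    note this is degenerate for n = p + 1 (e.g. 5 frames, 4 coefficients).
    An exact fit (SSR = 0) returns -inf.
    """
    if not n > p >= 1:
        raise ValidationError("AIC requires n > p >= 1")
    if ssr < 0:
        raise ValidationError("SSR must be non-negative")
    if ssr == 0:
        return -math.inf
    value = n * math.log(ssr / n) + 2 * p
    if corrected:
        if n - p - 1 <= 0:
            raise ValidationError("AICc undefined for n <= p + 1")
        value += 2 * p * (p + 1) / (n - p - 1)
    return value


def reduced_chi_square(residuals, sigmas, p: int) -> float:
    """Sum of squared sigma-normalized residuals per degree of freedom."""
    r = _as_float_array(residuals, "residuals")
    s = np.broadcast_to(np.asarray(sigmas, dtype=float), r.shape)
    if np.any(s <= 0):
        raise ValidationError("sigmas must be positive")
    n = r.size
    if not n > p:
        raise ValidationError("reduced chi-square requires n > p")
    return float(np.sum((r / s) ** 2) / (n - p))


def sy_x(residuals, p: int) -> float:
    """Standard deviation of the residuals, sqrt(SSR / (n - p))."""
    r = _as_float_array(residuals, "residuals")
    if not r.size > p:
        raise ValidationError("Sy.x requires n > p")
    return float(np.sqrt(np.sum(r ** 2) / (r.size - p)))


def r_squared(observed, fitted) -> float:
    """Coefficient of determination about the observed mean."""
    obs = _as_float_array(observed, "observed")
    fit = _as_float_array(fitted, "fitted")
    if obs.size != fit.size or obs.size < 2:
        raise ValidationError("r_squared needs >= 2 paired points")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValidationError("r_squared undefined for constant observations")
    ssr = float(np.sum((obs - fit) ** 2))
    return 1.0 - ssr / sst


def gof_report(fit: GraphicalFit, sigmas=None, corrected_aic: bool = False) -> GofReport:
    """Goodness-of-fit battery for one graphical fit.

    When no measurement sigma is supplied, the residual standard deviation
    Sy.x of the fit itself is used, which makes the reduced chi-square equal
    1 by construction — supply the simulator's true noise level for a
    meaningful chi-square.
    """
    n, p = fit.n_points_used, N_COEF[fit.model]
    ssr = fit.ssr
    syx = sy_x(fit.residuals, p)
    if ssr == 0:
        chi2 = 0.0
    else:
        chi2 = reduced_chi_square(fit.residuals, syx if sigmas is None else sigmas, p)
    return GofReport(
        model=fit.model, n=n, p=p, ssr=ssr,
        aic=aic(n, p, ssr, corrected=corrected_aic),
        chi2_reduced=chi2, sy_x=syx,
        r2=r_squared(fit.observed, fit.fitted),
        exact_fit=(ssr == 0),
    )


@dataclass(frozen=True)
class ModelComparison:
    best_model: str
    table: pd.DataFrame  # one row per model, ranked best first


def compare_models(reports: list[GofReport]) -> ModelComparison:
    """Rank fits of one VOI: AIC ascending, then Sy.x, then |chi2 - 1|."""
    if not reports:
        raise ValidationError("compare_models needs at least one fit")
    ranked = sorted(reports, key=lambda g: (g.aic, g.sy_x, abs(g.chi2_reduced - 1.0)))
    table = pd.DataFrame(
        {
            "model": [g.model for g in ranked],
            "n": [g.n for g in ranked],
            "p": [g.p for g in ranked],
            "SSR": [g.ssr for g in ranked],
            "AIC": [g.aic for g in ranked],
            "chi2_reduced": [g.chi2_reduced for g in ranked],
            "Sy.x": [g.sy_x for g in ranked],
            "R2": [g.r2 for g in ranked],
        }
    )
    return ModelComparison(ranked[0].model, table)
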