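"""Shelf-life degradation models for the composite quality index.

Qi declines with storage time t (months).  Two nested models are fitted
by ordinary least squares and compared:

    linear     Qi(t) = -b t + c
    quadratic  Qi(t) = a t^2 - b t + c

The sign convention stores b as printed in shelf-life tables (positive b
means an early downward trend).  Model choice uses the Gaussian-profile
AIC, n ln(rss/n) + 2k with k = (degree + 1) + 1, and the nested
extra-sum-of-squares F-test F = (rss_lin - rss_quad) / (rss_quad / (n - 3))
with p from F(1, n - 3).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PolynomialFit",
    "ModelComparison",
    "fit_polynomial",
    "predict_qi",
    "akaike_information_criterion",
    "compare_linear_quadratic",
    "time_to_threshold",
]


class SingularDesignError(ValueError):
    pass


class PerfectFitError(ValueError):
    pass


@dataclass(frozen=True)
class PolynomialFit:
    degree: int
    a: float  # t^2 coefficient (0 for linear), units month^-2
    b: float  # stored with the printed sign: model is a t^2 - b t + c
    c: float  # intercept, Qi at t = 0
    r_squared: float
    rss: float
    n: int
    aic: float | None = None

    def coefficients(self) -> tuple[float, float, float]:
        return self.a, self.b, self.c


@dataclass(frozen=True)
class ModelComparison:
    linear: PolynomialFit
    quadratic: PolynomialFit
    delta_aic: float  # quadratic minus linear; negative favors quadratic
    f_statistic: float
    p_value: float

    def to_json(self, path=None) -> str:
        payload = {
            "linear": asdict(self.linear),
            "quadratic": asdict(self.quadratic),
            "delta_aic": self.delta_aic,
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _as_arrays(t, qi) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(t, dtype=float)
    qi = np.asarray(qi, dtype=float)
    if t.shape != qi.shape or t.ndim != 1:
        raise ValueError("t and qi must be equal-length 1-D sequences")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(qi))):
        raise ValueError("t and qi must be finite")
    return t, qi


def fit_polynomial(t, qi, degree: int) -> PolynomialFit:
    """OLS fit of Qi on storage time, degree 1 or 2."""
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree}")
    t, qi = _as_arrays(t, qi)
    n = t.size
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if np.ptp(t) == 0.0:
        raise SingularDesignError("t values are all equal")
    X = np.vander(t, degree + 1, increasing=True)  # [1, t, (t^2)]
    coef, _, rank, _ = np.linalg.lstsq(X, qi, rcond=None)
    if rank < degree + 1:
        raise SingularDesignError("design matrix is rank deficient")
    resid = qi - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((qi - qi.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    a = float(coef[2]) if degree == 2 else 0.0
    fit = PolynomialFit(
        degree=degree,
        a=a,
        b=float(-coef[1]),
        c=float(coef[0]),
        r_squared=r2,
        rss=rss,
        n=n,
    )
    try:
        aic = akaike_information_criterion(fit)
    except PerfectFitError:
        aic = None
    return PolynomialFit(**{**asdict(fit), "aic": aic})


def predict_qi(fit: PolynomialFit, t) -> np.ndarray | float:
    """Evaluate a t^2 - b t + c; no clipping (callers decide)."""
    t_arr = np.asarray(t, dtype=float)
    out = fit.a * t_arr**2 - fit.b * t_arr + fit.c
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def akaike_information_criterion(fit: PolynomialFit) -> float:
    """Gaussian-profile AIC = n ln(rss/n) + 2k, k = coefficients + 1."""
    if fit.rss <= 0.0:
        raise PerfectFitError("AIC undefined at zero residual sum of squares")
    k = (fit.degree + 1) + 1
    return fit.n * math.log(fit.rss / fit.n) + 2 * k


def compare_linear_quadratic(t, qi) -> ModelComparison:
    """Nested F-test plus AIC comparison of the two degradation models."""
    t, qi = _as_arrays(t, qi)
    if t.size < 4:
        raise ValueError("need at least 4 points to compare the models")
    lin = fit_polynomial(t, qi, 1)
    quad = fit_polynomial(t, qi, 2)
    if quad.rss <= 0.0:
        raise PerfectFitError("quadratic fit is exact; F-test degenerate")
    n = t.size
    f = max(0.0, (lin.rss - quad.rss)) / (quad.rss / (n - 3))
    p = float(stats.f.sf(f, 1, n - 3))
    delta_aic = (
        math.inf if lin.aic is None else quad.aic - lin.aic
    )
    return ModelComparison(
        linear=lin, quadratic=quad, delta_aic=delta_aic, f_statistic=float(f), p_value=p
    )


def time_to_threshold(fit: PolynomialFit, threshold: float, horizon: float = 120.0):
    """Earliest t in [0, horizon] at which predicted Qi crosses below
    ``threshold``, or None if it never does. Convenience shelf-life helper."""
    if predict_qi(fit, 0.0) <= threshold:
        return 0.0
    roots = np.roots([fit.a, -fit.b, fit.c - threshold]) if fit.a != 0 else (
        np.array([(fit.c - threshold) / fit.b]) if fit.b != 0 else np.array([])
    )
    real = sorted(float(r.real) for r in np.atleast_1d(roots)
                  if abs(r.imag) < 1e-12 and 0.0 <= r.real <= horizon)
    return real[0] if real else None
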