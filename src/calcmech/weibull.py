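"""Two-parameter Weibull statistics for brittle strength samples.

The strength sigma_Y of a brittle specimen is modelled by the cumulative
failure probability

    f(sigma) = 1 - exp(-(sigma / sigma_0)**m)

with shape m (the Weibull modulus: larger means less scatter) and scale
sigma_0 (the 63.2nd-percentile strength).  Two estimators are provided:

* ``linearized`` (default): ordinary least squares of
  ln(-ln(1 - f_i)) on ln(sigma_i) using median-rank plotting positions
  f_i = (i - 0.5)/n; this matches the straight-line Weibull plot
  presentation and returns an R^2.
* ``mle``: the standard two-parameter maximum-likelihood estimator via
  the profiled score equation in m.

Standard errors come from a seeded nonparametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["WeibullFit", "empirical_failure_fraction", "fit_weibull", "weibull_cdf"]


@dataclass(frozen=True)
class WeibullFit:
    """Fitted shape/scale with bootstrap uncertainties."""

    shape: float
    scale: float
    shape_se: float | None
    scale_se: float | None
    method: str
    r_squared: float | None
    n: int

    def cdf(self, sigma: np.ndarray) -> np.ndarray:
        return weibull_cdf(sigma, self.shape, self.scale)


def weibull_cdf(sigma: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """Failure fraction f = 1 - exp(-(sigma/scale)**shape)."""
    sigma = np.asarray(sigma, dtype=float)
    return 1.0 - np.exp(-((sigma / scale) ** shape))


def _validate(strengths) -> np.ndarray:
    x = np.asarray(strengths, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("strength sample is empty")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("strengths must be positive and finite")
    return x


def empirical_failure_fraction(
    strengths,
    plotting_position: str = "median",
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered strengths with their empirical failure fractions.

    ``median`` uses f_i = (i - 0.5)/n (median-rank style); ``mean`` uses
    f_i = i/(n + 1).  Ties keep their input order (stable sort), receiving
    consecutive ranks.
    """
    x = _validate(strengths)
    order = np.argsort(x, kind="stable")
    ranks = np.arange(1, x.size + 1, dtype=float)
    if plotting_position == "median":
        f = (ranks - 0.5) / x.size
    elif plotting_position == "mean":
        f = ranks / (x.size + 1.0)
    else:
        raise ValueError("plotting_position must be 'median' or 'mean'")
    return x[order], f


class WeibullFitError(RuntimeError):
    """Raised when a strength sample cannot support a Weibull fit."""


def _fit_linearized(x: np.ndarray, plotting_position: str) -> tuple[float, float, float]:
    sigma, f = empirical_failure_fraction(x, plotting_position)
    if np.allclose(sigma, sigma[0]):
        raise WeibullFitError("degenerate sample: all strengths equal")
    lx = np.log(sigma)
    ly = np.log(-np.log1p(-f))
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    shape = float(slope)
    scale = float(np.exp(-intercept / slope))
    return shape, scale, r2


def _fit_mle(x: np.ndarray) -> tuple[float, float]:
    if np.allclose(x, x[0]):
        raise WeibullFitError("degenerate sample: all strengths equal")
    logx = np.log(x)
    mean_logx = logx.mean()

    def score(m: float) -> float:
        xm = x**m
        return float(np.sum(xm * logx) / np.sum(xm) - 1.0 / m - mean_logx)

    # score is increasing in m; bracket the root
    lo, hi = 1e-3, 10.0
    while score(hi) < 0 and hi < 1e6:
        hi *= 2.0
    shape = float(optimize.brentq(score, lo, hi, xtol=1e-12))
    scale = float(np.mean(x**shape) ** (1.0 / shape))
    return shape, scale


def fit_weibull(
    strengths,
    method: str = "linearized",
    plotting_position: str = "median",
    n_bootstrap: int = 2000,
    seed: int | None = None,
) -> WeibullFit:
    """Fit the two-parameter Weibull model to a strength sample.

    Requires n >= 3.  Set ``n_bootstrap=0`` to skip standard errors.
    """
    x = _validate(strengths)
    if x.size < 3:
        raise ValueError("need at least 3 strengths to fit")

    def _fit(sample: np.ndarray) -> tuple[float, float, float | None]:
        if method == "linearized":
            return _fit_linearized(sample, plotting_position)
        if method == "mle":
            shape, scale = _fit_mle(sample)
            return shape, scale, None
        raise ValueError("method must be 'linearized' or 'mle'")

    shape, scale, r2 = _fit(x)

    shape_se = scale_se = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        shapes, scales = [], []
        for _ in range(n_bootstrap):
            resample = rng.choice(x, size=x.size, replace=True)
            try:
                s, sc, _ = _fit(resample)
            except WeibullFitError:
                continue
            shapes.append(s)
            scales.append(sc)
        if len(shapes) >= 2:
            shape_se = float(np.std(shapes, ddof=1))
            scale_se = float(np.std(scales, ddof=1))

    return WeibullFit(shape, scale, shape_se, scale_se, method, r2, x.size)
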