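"""Cumulative degree-distribution models and goodness-of-fit comparison.

Brain structural networks typically show an exponentially truncated
power-law degree distribution, P(d) ~ d^(e-1) * exp(-d/d_c): a scaling
regime with exponent parameter e, cut off by an exponential decay in the
probability of hubs above the cutoff degree d_c.  Fitting is done on the
complementary cumulative distribution (fraction of nodes with degree >= d),
which smooths small-sample noise, and the truncated power law is compared
against pure power-law (d^-e) and exponential (exp(-e*d)) alternatives by
their R-square values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DegreeDistributionFit",
    "cumulative_distribution",
    "fit_model",
    "compare_models",
    "MODELS",
]

MODELS = ("truncated_powerlaw", "powerlaw", "exponential")


@dataclass
class DegreeDistributionFit:
    """Fitted degree-distribution model with parameters and R-square."""

    model: str
    amplitude: float
    exponent: float               # e in the model forms above
    cutoff: float | None          # d_c; truncated model only
    r_square: float
    degrees: np.ndarray
    cumulative: np.ndarray
    fitted: np.ndarray
    scale: str = "linear"

    def predict(self, d: np.ndarray) -> np.ndarray:
        return _model_fn(self.model)(
            np.asarray(d, float), *(
                (self.amplitude, self.exponent, self.cutoff)
                if self.model == "truncated_powerlaw"
                else (self.amplitude, self.exponent)
            )
        )


def cumulative_distribution(degrees) -> tuple[np.ndarray, np.ndarray]:
    """Complementary cumulative degree distribution.

    Returns the sorted distinct degree values d and P(k >= d), the fraction
    of nodes whose degree is at least d.  P is non-increasing and equals 1
    at the minimum observed degree.
    """
    k = np.asarray(degrees, dtype=float)
    if k.size < 3:
        raise ValueError("need at least 3 nodes")
    d = np.unique(k)
    p = np.array([(k >= dv).mean() for dv in d])
    return d, p


def _model_fn(model: str):
    if model == "truncated_powerlaw":
        return lambda d, a, e, dc: a * d ** (e - 1) * np.exp(-d / dc)
    if model == "powerlaw":
        return lambda d, a, e: a * d ** (-e)
    if model == "exponential":
        return lambda d, a, e: a * np.exp(-e * d)
    raise ValueError(f"unknown degree-distribution model: {model!r}")


def fit_model(
    degrees_or_d,
    cumulative: np.ndarray | None = None,
    model: str = "truncated_powerlaw",
    scale: str = "linear",
) -> DegreeDistributionFit:
    """Nonlinear least-squares fit of a distribution model to cumulative data.

    Accepts either a raw degree sequence (cumulative computed internally) or
    precomputed ``(d, P)`` pairs.  Degree-0 points are excluded (the
    power-law forms are singular there).  The optimizer restarts from a grid
    of initial values and keeps the best; ``scale="log"`` fits log-residuals
    instead of the default untransformed cumulative values.  R-square is
    1 - SS_res/SS_tot on the fitted scale.
    """
    if cumulative is None:
        d, p = cumulative_distribution(degrees_or_d)
    else:
        d = np.asarray(degrees_or_d, dtype=float)
        p = np.asarray(cumulative, dtype=float)
    keep = d > 0
    d, p = d[keep], p[keep]
    n_params = 3 if model == "truncated_powerlaw" else 2
    if len(d) < n_params:
        raise ValueError(
            f"{model} needs at least {n_params} distinct positive degrees"
        )
    fn = _model_fn(model)
    if scale == "log":
        if np.any(p <= 0):
            raise ValueError("log-scale fitting requires positive P values")
        target = np.log(p)

        def resid_fn(dv, *params):
            with np.errstate(divide="ignore"):
                return np.log(np.maximum(fn(dv, *params), 1e-300))
    elif scale == "linear":
        target = p
        resid_fn = fn
    else:
        raise ValueError("scale must be 'linear' or 'log'")

    d_scale = max(d.mean(), 1.0)
    if model == "truncated_powerlaw":
        starts = [(1.0, e0, dc0)
                  for e0 in (0.5, 1.0, 1.5, 2.5)
                  for dc0 in (d_scale / 2, d_scale, 4 * d_scale)]
        bounds = ([1e-12, -10.0, 1e-9], [np.inf, 10.0, np.inf])
    else:
        starts = [(1.0, e0) for e0 in (0.1, 0.5, 1.0, 2.0, 4.0)]
        bounds = ([1e-12, -10.0], [np.inf, 10.0])

    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(resid_fn, d, target, p0=p0, bounds=bounds,
                                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ss_res = float(np.sum((target - resid_fn(d, *popt)) ** 2))
        if best is None or ss_res < best[0]:
            best = (ss_res, popt)
    if best is None:
        raise RuntimeError(
            f"degree-distribution fit failed to converge for model {model!r}"
        )
    ss_res, popt = best
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    r_square = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    fitted = fn(d, *popt)
    return DegreeDistributionFit(
        model=model,
        amplitude=float(popt[0]),
        exponent=float(popt[1]),
        cutoff=float(popt[2]) if model == "truncated_powerlaw" else None,
        r_square=float(r_square),
        degrees=d,
        cumulative=p,
        fitted=fitted,
        scale=scale,
    )


def compare_models(
    degrees_or_d, cumulative: np.ndarray | None = None, scale: str = "linear"
) -> dict[str, DegreeDistributionFit]:
    """Fit all three models on the same cumulative data, keyed by model name.

    The dictionary is ordered by decreasing R-square, best model first.
    """
    fits = {}
    for model in MODELS:
        try:
            fits[model] = fit_model(degrees_or_d, cumulative, model, scale)
        except (RuntimeError, ValueError):
            continue
    if not fits:
        raise RuntimeError("no degree-distribution model could be fitted")
    return dict(sorted(fits.items(), key=lambda kv: -kv[1].r_square))
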