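"""Hill and sigmoid dose-response fitting and binned response summaries.

Two four-parameter log-logistic forms are used throughout:

* :func:`hill_model` for inhibitor dose-response (signed Hill coefficient;
  a negative coefficient means the response falls with dose, as for CDK
  activity under increasing 1NM-PP1), and
* :func:`fit_sigmoid` for the rising activity-vs-C-CDK-level curve
  (EC50 with a positive slope).

Both fitters do multi-start nonlinear least squares on log-scale shape
parameters and report ``converged=False`` instead of raising when the data
are flat or the optimiser stalls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InsufficientDataError, NormalizationError

__all__ = [
    "HillFit",
    "SigmoidFit",
    "hill_model",
    "sigmoid_model",
    "fit_hill",
    "fit_sigmoid",
    "normalize_to_reference",
    "binned_response",
]


@dataclass(frozen=True)
class HillFit:
    ic50: float
    hill_coef: float
    top: float
    bottom: float
    rss: float
    converged: bool

    def predict(self, dose) -> np.ndarray:
        return hill_model(dose, self.ic50, self.hill_coef, self.top, self.bottom)


@dataclass(frozen=True)
class SigmoidFit:
    ec50: float
    slope: float
    top: float
    bottom: float
    rss: float
    converged: bool

    def predict(self, level) -> np.ndarray:
        return sigmoid_model(level, self.ec50, self.slope, self.top, self.bottom)


def hill_model(dose, ic50: float, hill_coef: float, top: float, bottom: float):
    """response = bottom + (top - bottom) / (1 + (dose/ic50)^(-hill_coef)).

    At dose = ic50 the response is the midpoint for any coefficient; with a
    negative coefficient the curve starts at ``top`` at dose 0 and falls to
    ``bottom``, and vice versa for a positive one.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    ratio = np.empty_like(dose)
    pos = dose > 0
    ratio[pos] = (dose[pos] / ic50) ** (-hill_coef)
    # dose -> 0 limit: x^(-h) -> 0 for h < 0 (response = top), inf for h > 0
    ratio[~pos] = 0.0 if hill_coef < 0 else np.inf
    with np.errstate(invalid="ignore"):
        frac = 1.0 / (1.0 + ratio)
    return bottom + (top - bottom) * frac


def sigmoid_model(level, ec50: float, slope: float, top: float, bottom: float):
    """Rising sigmoid: bottom + (top - bottom) / (1 + (ec50/level)^slope)."""
    level = np.asarray(level, dtype=float)
    if ec50 <= 0 or slope <= 0:
        raise ValueError("ec50 and slope must be positive")
    safe = np.maximum(level, 1e-300)
    with np.errstate(over="ignore"):  # overflow -> inf -> response = bottom
        return bottom + (top - bottom) / (1.0 + (ec50 / safe) ** slope)


def _noise_estimate(responses: np.ndarray) -> float:
    """Robust noise sd from successive differences (flat-data guard)."""
    d = np.diff(responses)
    if len(d) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _multistart_fit(
    x: np.ndarray,
    y: np.ndarray,
    decreasing: bool,
    fix_top: float | None = None,
    fix_bottom: float | None = None,
) -> tuple[float, float, float, float, float, bool]:
    """Shared core: fit |slope| and log(x50) with optional pinned plateaus.

    Returns (x50, abs_slope, top, bottom, rss, converged).  ``decreasing``
    selects which plateau sits at low x.
    """
    lo, hi = float(np.min(y)), float(np.max(y))
    span = hi - lo

    def unpack(theta):
        x50 = np.exp(theta[0])
        s = np.exp(theta[1])
        i = 2
        if fix_top is None:
            top = theta[i]
            i += 1
        else:
            top = fix_top
        bottom = theta[i] if fix_bottom is None else fix_bottom
        return x50, s, top, bottom

    def model(theta):
        x50, s, top, bottom = unpack(theta)
        with np.errstate(over="ignore"):
            frac = 1.0 / (1.0 + (x50 / np.maximum(x, 1e-300)) ** s)
        if decreasing:
            frac = 1.0 - frac
        return bottom + (top - bottom) * frac

    def residuals(theta):
        return model(theta) - y

    # x50 starts: positive-x geometric mean plus the half-range crossing
    xp = x[x > 0]
    starts_x50 = [float(np.exp(np.mean(np.log(xp))))]
    half = lo + span / 2.0
    order = np.argsort(x)
    ys, xs = y[order], x[order]
    crossing = np.nonzero(np.diff(np.sign(ys - half)))[0]
    for i in crossing[:2]:
        c = 0.5 * (xs[i] + xs[i + 1])
        if c > 0:
            starts_x50.append(float(c))

    best = None
    for x50_0 in starts_x50:
        for s0 in (0.5, 1.0, 2.0, 4.0):
            theta0 = [np.log(x50_0), np.log(s0)]
            if fix_top is None:
                theta0.append(hi if not decreasing else hi)
            if fix_bottom is None:
                theta0.append(lo)
            try:
                res = least_squares(
                    residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14,
                    gtol=1e-14, max_nfev=20000,
                )
            except Exception:
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[0]:
                best = (rss, res)
    if best is None:
        return float("nan"), float("nan"), hi, lo, float("inf"), False
    rss, res = best
    x50, s, top, bottom = unpack(res.x)
    ok = bool(res.success) and bool(np.all(np.isfinite([x50, s, top, bottom])))
    if span < 2.0 * _noise_estimate(y) or span == 0.0:
        ok = False
    return float(x50), float(s), float(top), float(bottom), rss, ok


def fit_hill(doses, responses, fix_top: float | None = None,
             fix_bottom: float | None = None) -> HillFit:
    """Least-squares Hill fit with multi-start initialisation.

    Requires at least 4 distinct doses.  The sign of the returned Hill
    coefficient follows the direction of the data (negative when the
    response falls with dose).  Flat data return ``converged=False``.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(x)) < 4:
        raise InsufficientDataError("need at least 4 distinct doses")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InsufficientDataError("doses and responses must be finite")
    # direction from the rank correlation of response with dose
    order = np.argsort(x)
    decreasing = bool(np.polyfit(np.argsort(order), y[order], 1)[0] < 0)
    x50, s, top, bottom, rss, ok = _multistart_fit(x, y, decreasing, fix_top, fix_bottom)
    coef = -s if decreasing else s
    return HillFit(ic50=x50, hill_coef=coef, top=top, bottom=bottom, rss=rss, converged=ok)


def fit_sigmoid(levels, activities, fix_top: float | None = None,
                fix_bottom: float | None = None) -> SigmoidFit:
    """Least-squares fit of the rising activity-vs-level sigmoid.

    Same contract as :func:`fit_hill`; slope is reported positive.
    Plateaus are free by default and can be pinned.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(activities, dtype=float)
    if len(np.unique(x)) < 4:
        raise InsufficientDataError("need at least 4 distinct levels")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InsufficientDataError("levels and activities must be finite")
    x50, s, top, bottom, rss, ok = _multistart_fit(x, y, False, fix_top, fix_bottom)
    return SigmoidFit(ec50=x50, slope=s, top=top, bottom=bottom, rss=rss, converged=ok)


def normalize_to_reference(values, reference_values) -> np.ndarray:
    """Divide by the median of the reference sample (e.g. DMSO maxima)."""
    ref = np.asarray(reference_values, dtype=float)
    if ref.size == 0:
        raise NormalizationError("empty reference")
    med = float(np.median(ref))
    if med <= 0:
        raise NormalizationError("reference median must be positive")
    return np.asarray(values, dtype=float) / med


def binned_response(
    records: pd.DataFrame,
    bin_var: str,
    bin_width: float,
    min_n: int = 10,
    value_col: str = "activity_nc",
    gated_only: bool = True,
) -> pd.DataFrame:
    """Equal-width binned mean response.

    Bins cover the observed range of ``bin_var``; bins with fewer than
    ``min_n`` records are flagged ``low_n`` but kept.  Only records with
    ``gated`` set are used when ``gated_only`` (and the column exists).
    """
    df = records
    if gated_only and "gated" in df.columns:
        df = df[df["gated"].astype(bool)]
    if len(df) == 0:
        raise InsufficientDataError("no gated records to bin")
    v = df[bin_var].to_numpy(dtype=float)
    start = np.floor(v.min() / bin_width) * bin_width
    edges = np.arange(start, v.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([start, start + bin_width])
    which = np.clip(np.digitize(v, edges) - 1, 0, len(edges) - 2)
    out = []
    vals = df[value_col].to_numpy(dtype=float)
    for b in range(len(edges) - 1):
        sel = which == b
        n = int(sel.sum())
        if n == 0:
            continue
        out.append(
            {
                "bin_left": edges[b],
                "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "bin_right": edges[b + 1],
                "n": n,
                "mean": float(vals[sel].mean()),
                "sd": float(vals[sel].std(ddof=1)) if n > 1 else np.nan,
                "low_n": n < min_n,
            }
        )
    result = pd.DataFrame(out)
    result.attrs["bin_var"] = bin_var
    result.attrs["bin_width"] = bin_width
    return result
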