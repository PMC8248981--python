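"""Switch-like-activation metrics.

Bistable CDK activation shows up in three related readouts computed here:
the within-size-bin mean activity vs C-CDK level curve (which averages the
'on' and 'off' subpopulations where the distribution is bimodal), the
maximum gradient of a smoothing-spline fit to that curve (steeper for
switch-like responses), and the structure of residuals when the per-bin
maximum gradients are regressed linearly on cell length — systematically
curved residuals indicate bistability, quantified as the lag-1
autocorrelation of length-ordered residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.isotonic import IsotonicRegression

from .errors import InsufficientDataError

__all__ = [
    "GradientEstimate",
    "ResidualRegression",
    "mean_activity_curve",
    "max_gradient",
    "gradient_residuals",
]


def mean_activity_curve(
    records: pd.DataFrame,
    level_bin_width: float = 100.0,
    min_n: int = 10,
    level_col: str = "cdk_level_au",
    activity_col: str = "activity_nc",
) -> pd.DataFrame:
    """Mean CDK activity per C-CDK level bin (plain within-bin mean).

    Requires at least 3 occupied bins meeting ``min_n``.  Columns:
    ``level_center``, ``mean_activity``, ``n``.
    """
    lv = records[level_col].to_numpy(dtype=float)
    ac = records[activity_col].to_numpy(dtype=float)
    start = np.floor(lv.min() / level_bin_width) * level_bin_width
    edges = np.arange(start, lv.max() + level_bin_width, level_bin_width)
    which = np.clip(np.digitize(lv, edges) - 1, 0, max(len(edges) - 2, 0))
    rows = []
    for b in range(max(len(edges) - 1, 1)):
        sel = which == b
        n = int(sel.sum())
        if n < min_n:
            continue
        rows.append(
            {
                "level_center": 0.5 * (edges[b] + edges[b + 1]) if len(edges) > 1
                else lv.mean(),
                "mean_activity": float(ac[sel].mean()),
                "n": n,
            }
        )
    if len(rows) < 3:
        raise InsufficientDataError(
            f"only {len(rows)} occupied level bins (need >= 3)"
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GradientEstimate:
    value: float
    from_spline: bool  # False when the spline failed and finite differences were used


def max_gradient(
    curve: pd.DataFrame, lam: float | None = None, monotone: bool = False
) -> GradientEstimate:
    """Maximum first derivative of a smoothing spline through the mean curve.

    The spline's smoothing parameter is chosen by generalised
    cross-validation unless ``lam`` pins it.  ``monotone`` applies an
    increasing isotonic fit before the spline; a raw spline's maximum
    derivative is inflated by noise wiggles on shallow curves, and the
    monotone pre-fit removes that bias when comparing gradients across
    conditions.  If the spline cannot be constructed (too few points,
    degenerate spacing), the estimate falls back to finite differences and
    is flagged.
    """
    x = curve["level_center"].to_numpy(dtype=float)
    y = curve["mean_activity"].to_numpy(dtype=float)
    if len(x) < 4:
        raise InsufficientDataError("need at least 4 curve points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if monotone:
        w = curve["n"].to_numpy(dtype=float)[order] if "n" in curve else None
        y = IsotonicRegression(increasing=True).fit_transform(x, y, sample_weight=w)
    try:
        spl = make_smoothing_spline(x, y, lam=lam)
        grid = np.linspace(x[0], x[-1], max(200, 10 * len(x)))
        deriv = spl.derivative()(grid)
        if not np.all(np.isfinite(deriv)):
            raise ValueError("non-finite derivative")
        return GradientEstimate(float(np.max(deriv)), True)
    except Exception:
        g = np.gradient(y, x)
        return GradientEstimate(float(np.max(g)), False)


@dataclass
class ResidualRegression:
    slope: float
    intercept: float
    lengths: np.ndarray
    residuals: np.ndarray  # actual - predicted, ordered by length
    nonlinearity_score: float


def gradient_residuals(lengths, max_gradients) -> ResidualRegression:
    """OLS line of max gradient vs length, residuals, nonlinearity score.

    Residuals are actual minus predicted.  The nonlinearity score is the
    lag-1 autocorrelation of the residuals ordered by length: independent
    scatter around a genuinely linear trend scores near zero, while a
    curved (e.g. convex) trend leaves runs of same-sign residuals and a
    positive score.
    """
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(max_gradients, dtype=float)
    if len(x) < 4:
        raise InsufficientDataError("need at least 4 size bins")
    order = np.argsort(x)
    x, y = x[order], y[order]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    denom = float(np.sum(resid**2))
    # residuals indistinguishable from float round-off mean a perfect line
    floor = (1e-10 * max(float(np.max(np.abs(y))), 1e-30)) ** 2 * len(y)
    score = float(np.sum(resid[1:] * resid[:-1]) / denom) if denom > floor else 0.0
    return ResidualRegression(
        slope=float(slope),
        intercept=float(intercept),
        lengths=x,
        residuals=resid,
        nonlinearity_score=score,
    )
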