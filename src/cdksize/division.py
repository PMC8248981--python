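"""Division statistics: P(Div) hazards, activation-threshold curves and the
synergy decomposition of genotype threshold curves.

P(Div) is the per-minute probability that a cell triggers mitotic C-CDK
degradation by the next observed frame, estimated per size (or level) bin
as the fraction of cell-timepoints followed by a degradation event divided
by the frame interval.

The threshold curve gives, per cell-size bin, the C-CDK level at which a
chosen fraction (default 50%) of cells exceed a fixed activity cut
(default 5).  Bins where the fraction is never reached carry an explicit
``defined=False`` flag; in the synergy decomposition such bins are
substituted by a documented cap (default 1000 AU) and flagged, never
silently numeric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .errors import BinAlignmentError, InsufficientDataError
from .lineage import DEGRADATION, LineageTrace, detect_degradation

__all__ = [
    "PDivCurve",
    "ThresholdCurve",
    "estimate_pdiv",
    "threshold_level",
    "decompose_synergy",
]


@dataclass
class PDivCurve:
    """Binned division-rate estimates (per minute)."""

    bin_var: str
    table: pd.DataFrame  # columns: bin_center, rate_per_min, n_timepoints, n_events


@dataclass
class ThresholdCurve:
    """Size-binned C-CDK activation thresholds.

    ``table`` columns: ``size_bin_center``, ``threshold_au``, ``defined``,
    ``reason`` (empty string when defined), ``n``.
    """

    table: pd.DataFrame
    activity_cut: float = 5.0
    fraction: float = 0.5

    @property
    def centers(self) -> np.ndarray:
        return self.table["size_bin_center"].to_numpy(dtype=float)

    def values_with_cap(self, cap: float) -> tuple[np.ndarray, np.ndarray]:
        """(values, capped_flags) with undefined bins replaced by ``cap``."""
        defined = self.table["defined"].to_numpy(dtype=bool)
        vals = self.table["threshold_au"].to_numpy(dtype=float).copy()
        vals[~defined] = cap
        return vals, ~defined


def estimate_pdiv(
    traces: list[LineageTrace],
    bin_var: str = "size",
    bin_width: float = 1.0,
    use_truth_events: bool = False,
    degradation_drop_frac: float = 0.5,
) -> PDivCurve:
    """P(Div) per bin of size or C-CDK level.

    Every observed cell-timepoint with a successor frame contributes; the
    event indicator is a degradation event at the next frame.  The rate per
    minute is (events / timepoints) / frame_interval.  Events come from
    :func:`~cdksize.lineage.detect_degradation` unless ``use_truth_events``
    selects the simulator's ground-truth events.
    """
    if bin_var not in ("size", "level"):
        raise ValueError("bin_var must be 'size' or 'level'")
    values, events_flags, dts = [], [], []
    for tr in traces:
        if tr.n_frames < 2:
            continue
        if use_truth_events:
            ev = sorted({e.frame for e in tr.events if e.kind == DEGRADATION})
        else:
            ev = detect_degradation(tr, drop_frac=degradation_drop_frac)
        ev_set = set(ev)
        v = tr.series(bin_var)
        for t in range(tr.n_frames - 1):
            values.append(v[t])
            events_flags.append((t + 1) in ev_set)
            dts.append(tr.frame_interval_min)
    if not values:
        raise InsufficientDataError("no usable cell-timepoints")
    values = np.asarray(values)
    flags = np.asarray(events_flags, dtype=bool)
    dt = float(np.mean(dts))
    start = np.floor(values.min() / bin_width) * bin_width
    edges = np.arange(start, values.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([start, start + bin_width])
    which = np.clip(np.digitize(values, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        n = int(sel.sum())
        if n == 0:
            continue
        n_ev = int(flags[sel].sum())
        rows.append(
            {
                "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "rate_per_min": (n_ev / n) / dt,
                "n_timepoints": n,
                "n_events": n_ev,
            }
        )
    return PDivCurve(bin_var=bin_var, table=pd.DataFrame(rows))


def _crossing_level(
    centers: np.ndarray, f: np.ndarray, fraction: float
) -> float | None:
    """Smallest level where the monotone curve crosses ``fraction``."""
    if f[0] >= fraction:
        return float(centers[0])
    above = np.nonzero(f >= fraction)[0]
    if len(above) == 0:
        return None
    i = above[0]
    c0, c1, f0, f1 = centers[i - 1], centers[i], f[i - 1], f[i]
    if f1 == f0:
        return float(c1)
    return float(c0 + (fraction - f0) * (c1 - c0) / (f1 - f0))


def threshold_level(
    records: pd.DataFrame,
    size_bin_width: float = 1.0,
    size_bins: np.ndarray | None = None,
    activity_cut: float = 5.0,
    fraction: float = 0.5,
    level_window_au: float = 100.0,
    min_per_window: int = 20,
    min_n_bin: int = 100,
    size_var: str = "length_um",
) -> ThresholdCurve:
    """Per-size-bin C-CDK level at which ``fraction`` of cells exceed the
    activity cut.

    Within each size bin, cells are grouped into sliding level windows
    (width ``level_window_au``, 50% overlap); the exceedance fraction per
    window is smoothed with an increasing isotonic fit (exceedance must be
    monotone in level up to noise, giving a unique crossing), and the
    threshold is the smallest level where the smoothed curve crosses
    ``fraction``, by linear interpolation between window centres.  Bins
    where the fraction is never reached, or with fewer than ``min_n_bin``
    cells, are flagged undefined with a reason code.
    """
    df = records
    if "gated" in df.columns and df["gated"].any():
        df = df[df["gated"].astype(bool)]
    if len(df) == 0:
        raise InsufficientDataError("no records")
    sizes = df[size_var].to_numpy(dtype=float)
    levels = df["cdk_level_au"].to_numpy(dtype=float)
    acts = df["activity_nc"].to_numpy(dtype=float)
    if size_bins is None:
        start = np.floor(sizes.min() / size_bin_width) * size_bin_width
        size_bins = np.arange(start, sizes.max() + size_bin_width, size_bin_width)
    size_bins = np.asarray(size_bins, dtype=float)
    which = np.digitize(sizes, size_bins) - 1
    rows = []
    step = level_window_au / 2.0
    for b in range(len(size_bins) - 1):
        center = 0.5 * (size_bins[b] + size_bins[b + 1])
        sel = which == b
        n = int(sel.sum())
        if n < min_n_bin:
            rows.append(
                {"size_bin_center": center, "threshold_au": np.nan,
                 "defined": False, "reason": "low_n", "n": n}
            )
            continue
        lv, ac = levels[sel], acts[sel]
        w_centers, w_f, w_n = [], [], []
        c = lv.min() + step
        while c <= lv.max() + step / 2.0:
            in_w = (lv >= c - step) & (lv < c + step)
            nw = int(in_w.sum())
            if nw >= min_per_window:
                w_centers.append(c)
                w_f.append(float((ac[in_w] > activity_cut).mean()))
                w_n.append(nw)
            c += step
        if len(w_centers) < 2:
            rows.append(
                {"size_bin_center": center, "threshold_au": np.nan,
                 "defined": False, "reason": "too_few_windows", "n": n}
            )
            continue
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        f_hat = iso.fit_transform(w_centers, w_f, sample_weight=w_n)
        thr = _crossing_level(np.asarray(w_centers), np.asarray(f_hat), fraction)
        if thr is None:
            rows.append(
                {"size_bin_center": center, "threshold_au": np.nan,
                 "defined": False, "reason": "unattained", "n": n}
            )
        else:
            rows.append(
                {"size_bin_center": center, "threshold_au": thr,
                 "defined": True, "reason": "", "n": n}
            )
    return ThresholdCurve(
        table=pd.DataFrame(rows), activity_cut=activity_cut, fraction=fraction
    )


#: genotype keys the decomposition expects
_REQUIRED = ("WT", "AF", "WT_ppa2d", "AF_ppa2d")


def decompose_synergy(
    curves: dict[str, ThresholdCurve], cap: float = 1000.0
) -> pd.DataFrame:
    """Subtractive decomposition of the four genotype threshold curves.

    Per size bin, with undefined thresholds substituted by ``cap``:

    * ``yphos_with_pp2a``  = WT - AF (tyrosine phosphorylation with PP2A)
    * ``yphos_no_pp2a``    = WT PP2AΔ - AF PP2AΔ (tyrosine phosphorylation alone)
    * ``pp2a_no_yphos``    = AF - AF PP2AΔ (PP2A alone)
    * ``recomposed``       = AF PP2AΔ + yphos_no_pp2a + pp2a_no_yphos
    * ``synergy``          = WT - recomposed

    With purely additive regulation the recomposed curve reproduces WT and
    the synergy is zero; a positive synergy means the combined restriction
    exceeds the sum of its parts.  Per-bin ``capped_*`` flags record every
    substitution; ``any_capped`` marks bins whose algebra involved a cap.
    """
    missing = [k for k in _REQUIRED if k not in curves]
    if missing:
        raise BinAlignmentError(f"missing genotype curves: {missing}")
    centers = curves["WT"].centers
    for k in _REQUIRED[1:]:
        if len(curves[k].centers) != len(centers) or not np.allclose(
            curves[k].centers, centers
        ):
            raise BinAlignmentError(f"size bins of {k!r} do not match WT")
    vals, flags = {}, {}
    for k in _REQUIRED:
        vals[k], flags[k] = curves[k].values_with_cap(cap)
    yphos_with = vals["WT"] - vals["AF"]
    yphos_no = vals["WT_ppa2d"] - vals["AF_ppa2d"]
    pp2a_no = vals["AF"] - vals["AF_ppa2d"]
    recomposed = vals["AF_ppa2d"] + yphos_no + pp2a_no
    synergy = vals["WT"] - recomposed
    out = pd.DataFrame(
        {
            "size_bin_center": centers,
            "wt": vals["WT"],
            "af": vals["AF"],
            "wt_ppa2d": vals["WT_ppa2d"],
            "af_ppa2d": vals["AF_ppa2d"],
            "yphos_with_pp2a": yphos_with,
            "yphos_no_pp2a": yphos_no,
            "pp2a_no_yphos": pp2a_no,
            "recomposed": recomposed,
            "synergy": synergy,
        }
    )
    for k in _REQUIRED:
        out[f"capped_{k.lower()}"] = flags[k]
    out["any_capped"] = np.logical_or.reduce([flags[k] for k in _REQUIRED])
    return out
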