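"""Time-lapse lineage analysis.

A :class:`LineageTrace` holds the per-frame measurements of one tracked cell
(time, size, C-CDK level, optionally CDK activity).  The operations here
detect the two events that structure the fission-yeast cycle in these data —
abrupt C-CDK degradation and cell division (a steep drop in size) — classify
degradation events that are not followed by division, align traces on peak
CDK activity, and call mitotic entry from the activity series.

Event-detection thresholds are fractional drops, so all detectors are
invariant to rescaling the level or size series by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import CdkSizeError

__all__ = [
    "LineageEvent",
    "LineageTrace",
    "AlignedTrace",
    "SkipDivisionSummary",
    "detect_degradation",
    "detect_division",
    "classify_skipped_divisions",
    "align_to_peak",
    "detect_mitotic_entry",
]

DEGRADATION = "degradation"
DIVISION = "division"
DEGRADATION_WITHOUT_DIVISION = "degradation_without_division"


@dataclass(frozen=True)
class LineageEvent:
    frame: int
    kind: str


@dataclass
class LineageTrace:
    """One tracked cell: uniformly sampled frames plus (optional) events.

    ``frames`` columns: ``time_min``, ``size``, ``level`` and optionally
    ``activity``.  ``events`` carries ground-truth events when the trace
    comes from the simulator; detectors ignore it.
    """

    cell_id: str
    frames: pd.DataFrame
    frame_interval_min: float
    events: list[LineageEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = np.asarray(self.frames["time_min"], dtype=float)
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("frame times must be strictly increasing and uniform")
        for ev in self.events:
            if not 0 <= ev.frame < len(self.frames):
                raise ValueError(f"event frame {ev.frame} out of range")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def series(self, name: str) -> np.ndarray:
        return np.asarray(self.frames[name], dtype=float)


def _drop_events(values: np.ndarray, drop_frac: float, window: int) -> list[int]:
    """Frames where ``values`` falls by >= drop_frac of the recent maximum.

    The reference is the maximum over the preceding ``window`` frames, so a
    drop spread over two frames is still caught.  Events closer than
    ``window`` frames to the previous event are suppressed (one event per
    physical drop).
    """
    events: list[int] = []
    last = -np.inf
    for t in range(1, len(values)):
        pre = np.max(values[max(0, t - window) : t])
        if pre > 0 and values[t] <= (1.0 - drop_frac) * pre:
            if t - last > window:
                events.append(t)
                last = t
    return events


def detect_degradation(trace: LineageTrace, drop_frac: float = 0.5, window: int = 2) -> list[int]:
    """Frames at which the C-CDK level collapses (mitotic degradation).

    A frame qualifies when the level is down by at least ``drop_frac`` of the
    running pre-drop maximum within ``window`` frames.
    """
    return _drop_events(trace.series("level"), drop_frac, window)


def detect_division(trace: LineageTrace, drop_frac: float = 0.3) -> list[int]:
    """Frames with a steep frame-to-frame size decrease (cell division)."""
    size = trace.series("size")
    out: list[int] = []
    for t in range(1, len(size)):
        if size[t - 1] > 0 and size[t] <= (1.0 - drop_frac) * size[t - 1]:
            out.append(t)
    return out


@dataclass(frozen=True)
class SkipDivisionSummary:
    """Per-event labels plus the population fraction of unpaired degradations."""

    labels: pd.DataFrame  # columns: cell_id, frame, kind
    n_degradation: int
    n_skipped: int
    fraction: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def defined(self) -> bool:
        return self.fraction is not None


def classify_skipped_divisions(
    traces: list[LineageTrace],
    lag_max: int = 3,
    degradation_drop_frac: float = 0.5,
    division_drop_frac: float = 0.3,
) -> SkipDivisionSummary:
    """Label degradation events lacking a division within ``lag_max`` frames.

    Returns all degradation events labelled either ``division`` (a division
    was found within +-lag_max frames) or ``degradation_without_division``,
    together with the skipped fraction and its 95% Wilson binomial CI.  With
    no degradation events the fraction is undefined (``None``).
    """
    rows = []
    n_skip = 0
    for tr in traces:
        deg = detect_degradation(tr, drop_frac=degradation_drop_frac)
        div = detect_division(tr, drop_frac=division_drop_frac)
        for f in deg:
            paired = any(abs(d - f) <= lag_max for d in div)
            kind = DIVISION if paired else DEGRADATION_WITHOUT_DIVISION
            if not paired:
                n_skip += 1
            rows.append({"cell_id": tr.cell_id, "frame": f, "kind": kind})
    labels = pd.DataFrame(rows, columns=["cell_id", "frame", "kind"])
    n = len(labels)
    if n == 0:
        return SkipDivisionSummary(labels, 0, 0, None, None, None)
    lo, hi = proportion_confint(n_skip, n, alpha=0.05, method="wilson")
    return SkipDivisionSummary(labels, n, n_skip, n_skip / n, float(lo), float(hi))


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if window <= 1:
        return values.astype(float)
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


@dataclass
class AlignedTrace:
    trace: LineageTrace
    time_min: np.ndarray  # shifted so the smoothed-activity peak is at 0
    activity: np.ndarray
    shift_min: float
    aligned: bool


def align_to_peak(traces: list[LineageTrace], smooth_window: int = 3) -> list[AlignedTrace]:
    """Shift each trace so its smoothed CDK-activity maximum sits at 0 min.

    Traces with flat activity cannot be aligned and are returned with
    ``aligned=False`` and zero shift.
    """
    out = []
    for tr in traces:
        act = tr.series("activity")
        t = tr.series("time_min")
        sm = _smooth(act, smooth_window)
        if np.ptp(sm) <= 1e-12 * max(1.0, np.abs(sm).max()):
            out.append(AlignedTrace(tr, t.copy(), act, 0.0, False))
            continue
        peak = int(np.argmax(sm))
        shift = float(t[peak])
        out.append(AlignedTrace(tr, t - shift, act, shift, True))
    return out


def detect_mitotic_entry(
    trace: LineageTrace, k: float = 3.0, smooth_window: int = 3
) -> int | None:
    """First frame of the sustained activity rise preceding the peak.

    The baseline is the median of the first quartile of frames of the
    smoothed activity; its robust sd (scaled MAD) sets a threshold of
    ``baseline + k*sd``.  The entry frame is the first frame above threshold
    from which the trace reaches its global peak without falling back below
    baseline.  Returns None when no frame qualifies (e.g. flat traces).
    """
    act = trace.series("activity")
    if len(act) < 4:
        return None
    sm = _smooth(act, smooth_window)
    nq = max(3, len(sm) // 4)
    base = float(np.median(sm[:nq]))
    mad = float(np.median(np.abs(sm[:nq] - base)))
    sd = 1.4826 * mad
    # guard against an exactly-flat baseline window: require a genuine rise
    sd = max(sd, 1e-3 * max(abs(base), 1.0))
    thr = base + k * sd
    peak = int(np.argmax(sm))
    if sm[peak] <= thr:
        return None
    for t in range(peak + 1):
        if sm[t] > thr and np.min(sm[t : peak + 1]) > base:
            return t
    return None
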