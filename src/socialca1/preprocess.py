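"""Raw fluorescence -> dF/F0 -> thresholded calcium-event traces.

Per neuron the pipeline is: order-3 median filter of each trial's trace,
concatenation of the trials into one session-long trace, slow-drift removal
by subtracting a running 5th percentile (900-frame centered window), mode-of-
KDE baseline F0, dF/F0 = (F - F0)/F0, and a two-pass robust event threshold
estimated from the pre-window-opening (quiescent) epochs: a first
3-interquartile threshold over all trials, exclusion of trials whose
pre-opening trace ever exceeds it, and a final threshold from the remaining
trials.  The event trace keeps dF/F0 where it exceeds the threshold and is
zero elsewhere.  A false-positive ratio (negative-going excursions below -T
divided by positive events) summarizes threshold quality per neuron.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, median_filter

THRESHOLD_MODES = ("median+3iqr", "3iqr", "q3+3iqr")


@dataclass
class EventTrace:
    """dF/F0 and thresholded event traces for a population."""

    dff: np.ndarray  # (n_neurons, n_frames, n_trials)
    f0: np.ndarray  # (n_neurons,)
    threshold: np.ndarray  # (n_neurons,)
    events: np.ndarray  # (n_neurons, n_frames, n_trials)
    fp_ratio: np.ndarray  # (n_neurons,) NaN when no positive events
    excluded_trials_pass1: list[np.ndarray] = field(default_factory=list)
    threshold_fallback: np.ndarray | None = None  # pass-1 threshold reused
    baseline_offset_applied: np.ndarray | None = None


# ---------------------------------------------------------------------------
# trace conditioning
# ---------------------------------------------------------------------------
def condition_trace(
    F: np.ndarray,
    median_order: int = 3,
    drift_window: int = 900,
    percentile: float = 0.05,
) -> np.ndarray:
    """Median-filter per trial, concatenate, subtract the running percentile.

    ``F`` is (n_neurons, n_frames, n_trials); returns conditioned traces of
    shape (n_neurons, n_frames * n_trials), trials concatenated in order.
    The percentile window is centered, covering concatenated frames
    ``[i - w//2, i + (w+1)//2)`` truncated at the trace edges.
    """
    if median_order % 2 != 1:
        raise ValueError("median_order must be odd")
    if drift_window < 1:
        raise ValueError("drift_window must be >= 1")
    n_neurons, n_frames, n_trials = F.shape
    total = n_frames * n_trials
    if drift_window > total:
        warnings.warn("drift_window longer than trace; clipped to trace length")
        drift_window = total
    # median filter along frames, independently per trial and neuron
    filt = median_filter(F, size=(1, median_order, 1), mode="nearest")
    concat = filt.transpose(0, 2, 1).reshape(n_neurons, total)
    baseline = (
        pd.DataFrame(concat.T)
        .rolling(drift_window, center=True, min_periods=1)
        .quantile(percentile)
        .to_numpy()
        .T
    )
    return concat - baseline


def estimate_baseline(trace: np.ndarray, grid_points: int = 512) -> float:
    """F0 = mode of a Gaussian kernel density estimate of the trace values.

    Silverman-bandwidth KDE evaluated on a ``grid_points`` grid spanning
    [min, max] via linear binning plus Gaussian smoothing (accurate to grid
    resolution, and fast enough for session-length traces).
    """
    x = np.asarray(trace, dtype=float).ravel()
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("trace must be nonempty and finite")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return float(lo)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    bw = 0.9 * scale * x.size ** (-0.2)
    grid = np.linspace(lo, hi, grid_points)
    dx = grid[1] - grid[0]
    # linear binning: split each sample's mass between neighbouring grid nodes
    pos = (x - lo) / dx
    left = np.clip(pos.astype(int), 0, grid_points - 2)
    frac = pos - left
    hist = np.bincount(left, weights=1 - frac, minlength=grid_points)
    hist += np.bincount(left + 1, weights=frac, minlength=grid_points)
    density = gaussian_filter1d(hist, max(bw / dx, 1e-9), mode="constant")
    return float(grid[int(np.argmax(density))])


def compute_dff(trace: np.ndarray, f0: float, neuron: int | None = None) -> np.ndarray:
    """(F - F0) / F0 elementwise; F0 must be positive."""
    if not f0 > 0:
        who = f" for neuron {neuron}" if neuron is not None else ""
        raise ValueError(f"non-positive baseline F0={f0}{who}")
    return (np.asarray(trace, dtype=float) - f0) / f0


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------
def _iqr_threshold(values: np.ndarray, mode: str) -> float:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    if mode == "median+3iqr":
        return float(med + 3.0 * iqr)
    if mode == "3iqr":
        return float(3.0 * iqr)
    if mode == "q3+3iqr":
        return float(q3 + 3.0 * iqr)
    raise ValueError(f"unknown threshold mode {mode!r}; options: {THRESHOLD_MODES}")


def detect_events(
    dff: np.ndarray,
    pre_open_frames: int,
    mode: str = "median+3iqr",
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Two-pass event threshold for one neuron.

    ``dff`` is (n_frames, n_trials); the first ``pre_open_frames`` frames of
    each trial are the quiescent pre-opening epoch.  Pass 1 pools all trials'
    pre-opening values into a threshold T1; trials whose pre-opening trace
    exceeds T1 anywhere are excluded from (only) the second estimate.  If
    every trial is excluded, T1 itself is used and flagged.

    Returns ``(events, threshold, excluded_trials, fallback)`` where
    ``events`` keeps dff strictly above threshold and is zero elsewhere.
    """
    if pre_open_frames < 1:
        raise ValueError("pre-opening period is empty")
    pre = dff[:pre_open_frames, :]
    t1 = _iqr_threshold(pre.ravel(), mode)
    bad = np.flatnonzero((pre > t1).any(axis=0))
    fallback = len(bad) == dff.shape[1]
    if fallback:
        thr = t1
    else:
        keep = np.setdiff1d(np.arange(dff.shape[1]), bad)
        thr = _iqr_threshold(pre[:, keep].ravel(), mode)
    events = np.where(dff > thr, dff, 0.0)
    return events, thr, bad, fallback


def count_excursions(x: np.ndarray, threshold: float) -> int:
    """Number of contiguous runs of ``x > threshold`` in a 1-D trace."""
    above = np.asarray(x).ravel() > threshold
    if not above.any():
        return 0
    return int(above[0]) + int(np.sum(above[1:] & ~above[:-1]))


def false_positive_ratio(dff: np.ndarray, threshold: float) -> float:
    """Negative excursions below -T divided by positive excursions above +T,
    counted on the concatenated trace; NaN when there are no positive events."""
    flat = np.asarray(dff).T.ravel() if np.ndim(dff) == 2 else np.asarray(dff).ravel()
    pos = count_excursions(flat, threshold)
    if pos == 0:
        return float("nan")
    neg = count_excursions(-flat, threshold)
    return neg / pos


# ---------------------------------------------------------------------------
# whole-session driver
# ---------------------------------------------------------------------------
def preprocess_session(
    session,
    median_order: int = 3,
    drift_window: int = 900,
    percentile: float = 0.05,
    threshold_mode: str = "median+3iqr",
) -> EventTrace:
    """Run the full preprocessing chain on a
    :class:`~socialca1.synthgen.SessionRecord` (or any object with ``F``,
    ``epoch_frames``).

    Drift correction can leave a non-positive baseline (the running 5th
    percentile is subtracted); in that case the neuron's global 5th
    percentile of the raw trace is added back before F0 estimation and the
    neuron is flagged.
    """
    F = session.F
    n_neurons, n_frames, n_trials = F.shape
    pre_open = session.epoch_frames["open"]
    cond = condition_trace(F, median_order, drift_window, percentile)

    dff = np.empty_like(F)
    f0 = np.empty(n_neurons)
    thr = np.empty(n_neurons)
    events = np.empty_like(F)
    fp = np.empty(n_neurons)
    excluded: list[np.ndarray] = []
    fb = np.zeros(n_neurons, dtype=bool)
    offset_applied = np.zeros(n_neurons, dtype=bool)

    for n in range(n_neurons):
        trace = cond[n]
        base = estimate_baseline(trace)
        if base <= 0:
            offset = np.percentile(F[n], 5)
            trace = trace + offset
            base = estimate_baseline(trace)
            offset_applied[n] = True
        d = compute_dff(trace, base, neuron=n).reshape(n_trials, n_frames).T
        ev, t, bad, flag = detect_events(d, pre_open, threshold_mode)
        dff[n], events[n], thr[n], fb[n] = d, ev, t, flag
        f0[n] = base
        fp[n] = false_positive_ratio(d, t)
        excluded.append(bad)

    return EventTrace(dff, f0, thr, events, fp, excluded, fb, offset_applied)
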