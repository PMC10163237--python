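"""Behavioral scoring: trial outcomes, performance rates, high-performance
periods, response times, and reversed session pairing.

Outcome definitions (set purely by response-window licking):

* reward trial with a lick in ``[t_response, t_close)``  -> hit
* reward trial without such a lick                       -> miss
* no-reward trial with such a lick                       -> false alarm (FA)
* no-reward trial without one                            -> correct rejection (CR)

Licks during the grace period (before ``t_response``) have no consequence;
licks exactly at ``t_close`` fall outside the half-open response window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import CR, FA, HIT, MISS, NO_REWARD, REWARD

HIGH_PERF_WINDOW = 50
HIGH_PERF_RATE = 0.8
HIGH_PERF_MIN_TRIALS = 200


@dataclass
class PerformanceSeries:
    """Sliding-window performance of one session.

    ``hit_rate``/``cr_rate``/``correct_rate`` have one entry per window
    (a single entry when computed over the whole session); the
    high-performance mask marks every trial covered by a qualifying window.
    """

    hit_rate: np.ndarray
    cr_rate: np.ndarray
    correct_rate: np.ndarray
    window: int
    high_performance_mask: np.ndarray | None = None
    session_high_performance: bool | None = None


def _response_window_lick(row) -> bool:
    return any(row["t_response"] <= t < row["t_close"] for t in row["lick_times"])


def score_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Set ``outcome`` and ``rewarded`` from lick times and epochs."""
    needed = {"t_response", "t_close", "lick_times", "category"}
    if not needed.issubset(trials.columns):
        raise ValueError(f"trials missing columns: {sorted(needed - set(trials.columns))}")
    out = trials.copy()
    licked = out.apply(_response_window_lick, axis=1).to_numpy(dtype=bool)
    is_go = (out["category"] == REWARD).to_numpy()
    outcome = np.where(is_go, np.where(licked, HIT, MISS), np.where(licked, FA, CR))
    out["outcome"] = outcome
    out["rewarded"] = outcome == HIT
    return out


def compute_rates(trials: pd.DataFrame, window: int | str = "all") -> PerformanceSeries:
    """Hit, CR and correct rates, overall or in sliding windows (stride 1).

    hit rate = hits / reward trials; CR rate = CRs / no-reward trials;
    correct rate = (hits + CRs) / total trials.  A window with no trials of
    a category yields a NaN rate for that category.
    """
    if (trials["outcome"] == "").any():
        raise ValueError("outcomes not set; run score_trials first")
    hits = (trials["outcome"] == HIT).to_numpy(dtype=float)
    crs = (trials["outcome"] == CR).to_numpy(dtype=float)
    go = (trials["category"] == REWARD).to_numpy(dtype=float)
    nogo = (trials["category"] == NO_REWARD).to_numpy(dtype=float)
    n = len(trials)

    if window == "all" or (isinstance(window, int) and window >= n):
        if window != "all" and window > n:
            warnings.warn("window larger than session; computing a single overall value")
        window = n

    w = int(window)

    def rolling_sum(x: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(x)])
        return c[w:] - c[:-w]

    with np.errstate(invalid="ignore", divide="ignore"):
        hit_rate = rolling_sum(hits) / rolling_sum(go)
        cr_rate = rolling_sum(crs) / rolling_sum(nogo)
        correct_rate = (rolling_sum(hits) + rolling_sum(crs)) / w
    return PerformanceSeries(hit_rate, cr_rate, correct_rate, w)


def find_high_performance(trials: pd.DataFrame, window: int = HIGH_PERF_WINDOW) -> PerformanceSeries:
    """High-performance periods: the union of all ``window``-trial windows
    whose hit rate and CR rate both exceed 80%; the session qualifies when
    more than 200 trials fall in that union."""
    n = len(trials)
    if n < window:
        perf = compute_rates(trials, "all")
        perf.high_performance_mask = np.zeros(n, dtype=bool)
        perf.session_high_performance = False
        return perf
    perf = compute_rates(trials, window)
    good = (perf.hit_rate > HIGH_PERF_RATE) & (perf.cr_rate > HIGH_PERF_RATE)
    mask = np.zeros(n, dtype=bool)
    for start in np.flatnonzero(good):
        mask[start : start + window] = True
    perf.high_performance_mask = mask
    perf.session_high_performance = bool(mask.sum() > HIGH_PERF_MIN_TRIALS)
    return perf


def response_times(trials: pd.DataFrame) -> np.ndarray:
    """Time to the first lick in each trial, relative to window opening
    (NaN for lick-free trials)."""
    out = np.full(len(trials), np.nan)
    for i, (licks, t_open) in enumerate(zip(trials["lick_times"], trials["t_open"])):
        if licks:
            out[i] = min(licks) - t_open
    return out


def analysis_trial_mask(trials: pd.DataFrame, perf: PerformanceSeries | None = None) -> np.ndarray:
    """Correct trials (hit or CR) inside high-performance periods - the
    trial set all calcium analyses are restricted to."""
    if perf is None:
        perf = find_high_performance(trials)
    correct = trials["outcome"].isin([HIT, CR]).to_numpy()
    return correct & perf.high_performance_mask


def pair_reversed_sessions(sessions: list, max_gap_days: int = 1) -> list[tuple[int, int]]:
    """Ordered index pairs (earlier, later) of high-performance sessions with
    reversed category maps and a day gap of at most ``max_gap_days``.

    Each session must expose ``day``, ``category_map`` and ``trials``
    (:class:`~socialca1.synthgen.SessionRecord` does).
    """
    flags = [find_high_performance(s.trials).session_high_performance for s in sessions]
    pairs = []
    for i, si in enumerate(sessions):
        for j, sj in enumerate(sessions):
            if sj.day <= si.day or sj.day - si.day > max_gap_days:
                continue
            if not (flags[i] and flags[j]):
                continue
            if _is_reversed(si.category_map, sj.category_map):
                pairs.append((i, j))
    return pairs


def _is_reversed(map1: dict[str, str], map2: dict[str, str]) -> bool:
    if set(map1) != set(map2):
        return False
    flip = {REWARD: NO_REWARD, NO_REWARD: REWARD}
    return all(map2[s] == flip[c] for s, c in map1.items())
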