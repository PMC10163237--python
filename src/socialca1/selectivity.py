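"""Per-neuron responsiveness and Go/NoGo (or stimulus) discriminability.

The discriminability index between two trial conditions is

    d' = (mu1 - mu2) / sqrt((sigma1^2 + sigma2^2) / 2)

where mu and sigma are the mean and (sample, n-1) standard deviation of the
per-trial calcium response amplitudes of each condition.  Response amplitude
is the mean of the thresholded event trace over the analysis window:
window opening -> response-window start for Go/NoGo discrimination, window
opening -> closing for mouse-identity discrimination.  Significance comes
from a two-sided permutation test: condition labels are shuffled across
trials (1000 surrogates), and the observed d' must fall strictly beyond the
2.5% tails of the null (per-comparison tails shrink under Bonferroni).

Responsiveness is separate from discriminability: a neuron is "activated"
("inhibited") for a trial type when its event area in the stimulus period
(window fully open -> response start) exceeds (falls below) its pre-stimulus
area (trial start -> opening) by a paired two-sided Wilcoxon signed-rank
test at p < 0.05.  The response score sums +1/-1/0 codes over Go and NoGo.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .task import NO_REWARD, REWARD

GO_PREFERRING = "Go"
NOGO_PREFERRING = "NoGo"
NONE_LABEL = "none"


# ---------------------------------------------------------------------------
# d-prime
# ---------------------------------------------------------------------------
def dprime(responses_1, responses_2, ddof: int = 1) -> float:
    """Discriminability index between two groups of per-trial amplitudes.

    Returns NaN when both groups have zero variance (undefined).
    """
    x1 = np.asarray(responses_1, dtype=float)
    x2 = np.asarray(responses_2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 trials")
    v1, v2 = x1.var(ddof=ddof), x2.var(ddof=ddof)
    denom = np.sqrt(0.5 * (v1 + v2))
    if denom == 0:
        return float("nan")
    return float((x1.mean() - x2.mean()) / denom)


def trial_amplitudes(trace: np.ndarray, frame_lo: int, frame_hi: int) -> np.ndarray:
    """Mean trace value over ``[frame_lo, frame_hi)`` per trial.

    ``trace`` is (n_frames, n_trials).
    """
    return trace[frame_lo:frame_hi, :].mean(axis=0)


def pointwise_dprime(trace: np.ndarray, labels: np.ndarray, ddof: int = 1) -> np.ndarray:
    """d' per frame; ``trace`` is (n_frames, n_trials), ``labels`` boolean
    (True = condition 1).  Frames where both conditions are constant are NaN.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each condition needs at least 2 trials")
    x1, x2 = trace[:, labels], trace[:, ~labels]
    v = 0.5 * (x1.var(axis=1, ddof=ddof) + x2.var(axis=1, ddof=ddof))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (x1.mean(axis=1) - x2.mean(axis=1)) / np.sqrt(v)
    d[v == 0] = np.nan
    return d


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------
def _null_dprimes(
    amplitudes: np.ndarray, n1: int, n_shuffles: int, rng: np.random.Generator,
    ddof: int = 1,
) -> np.ndarray:
    """d' of ``n_shuffles`` random splits of ``amplitudes`` into groups of
    n1 and n-n1 trials (vectorized label shuffles preserving group sizes)."""
    x = np.asarray(amplitudes, dtype=float)
    n = x.size
    perm = np.tile(np.arange(n), (n_shuffles, 1))
    perm = rng.permuted(perm, axis=1)
    g1 = np.zeros((n_shuffles, n))
    np.put_along_axis(g1, perm[:, :n1], 1.0, axis=1)
    n2 = n - n1
    s1, s2 = g1 @ x, (1 - g1) @ x
    q1, q2 = g1 @ (x * x), (1 - g1) @ (x * x)
    m1, m2 = s1 / n1, s2 / n2
    v1 = (q1 - n1 * m1**2) / (n1 - ddof)
    v2 = (q2 - n2 * m2**2) / (n2 - ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (m1 - m2) / np.sqrt(0.5 * (v1 + v2))
    return d


def permutation_test(
    amplitudes: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 1000,
    bonferroni_m: int = 1,
    seed: int | np.random.Generator = 0,
    ddof: int = 1,
) -> tuple[float, float, str]:
    """Two-sided shuffle test of d' between the two label groups.

    Labels are permuted across trials ``n_shuffles`` times (group sizes
    preserved); the observed d' is significant when it strictly exceeds the
    ``1 - 0.025/m`` null quantile (Go-preferring) or falls strictly below
    the ``0.025/m`` quantile (NoGo-preferring).  Returns
    ``(d_prime, p_perm, label)`` with a conservative two-sided
    ``p = 2 * min(tail fractions)`` using the (1+B)/(1+N) estimator.
    """
    labels = np.asarray(labels, dtype=bool)
    x = np.asarray(amplitudes, dtype=float)
    obs = dprime(x[labels], x[~labels], ddof=ddof)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = _null_dprimes(x, int(labels.sum()), n_shuffles, rng, ddof=ddof)
    null = null[np.isfinite(null)]
    if not np.isfinite(obs) or null.size == 0 or np.ptp(null) == 0:
        return obs, float("nan"), NONE_LABEL
    hi = np.quantile(null, 1 - 0.025 / bonferroni_m)
    lo = np.quantile(null, 0.025 / bonferroni_m)
    p_hi = (1 + np.sum(null >= obs)) / (1 + null.size)
    p_lo = (1 + np.sum(null <= obs)) / (1 + null.size)
    p = min(1.0, 2 * min(p_hi, p_lo))
    if obs > hi:
        return obs, p, GO_PREFERRING
    if obs < lo:
        return obs, p, NOGO_PREFERRING
    return obs, p, NONE_LABEL


# ---------------------------------------------------------------------------
# responsiveness (activated / inhibited / none)
# ---------------------------------------------------------------------------
@dataclass
class ResponseProfile:
    """Activated/inhibited/none codes per trial type for one neuron."""

    codes: dict[str, str]  # trial type -> code
    p_values: dict[str, float]

    @property
    def score(self) -> int:
        value = {"activated": 1, "inhibited": -1, "none": 0}
        return sum(value[c] for c in self.codes.values())


def classify_response(
    events: np.ndarray,
    trial_mask: np.ndarray,
    epoch_frames: dict[str, int],
    alpha: float = 0.05,
) -> tuple[str, float]:
    """Code one neuron's response to one trial type.

    ``events`` is the (n_frames, n_trials) event trace; ``trial_mask``
    selects the (correct, high-performance) trials of the type.  Pre-stimulus
    area (trial start -> opening) is compared with the stimulus-period area
    (opening complete -> response start) by a paired two-sided Wilcoxon
    signed-rank test across trials.
    """
    sel = np.flatnonzero(np.asarray(trial_mask, dtype=bool))
    if sel.size < 2:
        raise ValueError("need at least 2 trials of the type")
    pre = events[: epoch_frames["open"], sel].sum(axis=0)
    stim = events[epoch_frames["open_complete"] : epoch_frames["response"], sel].sum(axis=0)
    diff = stim - pre
    if np.all(diff == 0):
        return "none", 1.0
    try:
        p = float(stats.wilcoxon(stim, pre, zero_method="wilcox").pvalue)
    except ValueError:
        return "none", 1.0
    if p < alpha:
        # direction from the median paired difference; with sparse event
        # traces the median is often exactly 0, so fall back to the mean
        med = float(np.median(diff)) or float(np.mean(diff))
        if med > 0:
            return "activated", p
        if med < 0:
            return "inhibited", p
    return "none", p


def response_profile(
    events: np.ndarray,
    trials: pd.DataFrame,
    analysis_mask: np.ndarray,
    epoch_frames: dict[str, int],
    alpha: float = 0.05,
) -> ResponseProfile:
    """Codes for both trial types (Go = reward, NoGo = no-reward) plus score."""
    codes, ps = {}, {}
    for name, cat in ((GO_PREFERRING, REWARD), (NOGO_PREFERRING, NO_REWARD)):
        mask = analysis_mask & (trials["category"] == cat).to_numpy()
        code, p = classify_response(events, mask, epoch_frames, alpha)
        codes[name], ps[name] = code, p
    return ResponseProfile(codes, ps)


def response_score(profile: ResponseProfile) -> int:
    """Sum of +1 (activated), -1 (inhibited), 0 (none) over the trial types."""
    return profile.score


# ---------------------------------------------------------------------------
# population drivers
# ---------------------------------------------------------------------------
def trial_type_selectivity(
    events: np.ndarray,
    trials: pd.DataFrame,
    analysis_mask: np.ndarray,
    epoch_frames: dict[str, int],
    n_shuffles: int = 1000,
    seed: int = 0,
    window: str = "O-R",
    label_values: tuple = (REWARD, NO_REWARD),
    label_field: str = "category",
) -> pd.DataFrame:
    """d', permutation p, and preference label per neuron.

    ``window`` selects the amplitude window: "O-R" (opening -> response
    start; trial-type discrimination) or "O-C" (opening -> closing;
    identity discrimination).  ``label_field``/``label_values`` generalize
    from Go/NoGo to any two-condition comparison (e.g. two stimulus mice).
    """
    lo = epoch_frames["open"]
    hi = epoch_frames["response"] if window == "O-R" else epoch_frames["close"]
    cond = trials[label_field].to_numpy()
    use = np.asarray(analysis_mask, dtype=bool) & np.isin(cond, label_values)
    labels = cond[use] == label_values[0]
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x5E1EC7]))
    for n in range(events.shape[0]):
        amps = trial_amplitudes(events[n][:, use], lo, hi)
        d, p, lab = permutation_test(amps, labels, n_shuffles, seed=rng)
        rows.append({"neuron": n, "d_prime": d, "p_perm": p, "label": lab})
    return pd.DataFrame(rows)


def passive_pairwise_dprime(
    events: np.ndarray,
    trials: pd.DataFrame,
    analysis_mask: np.ndarray,
    epoch_frames: dict[str, int],
    n_shuffles: int = 1000,
    bonferroni_m: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean pairwise d' over all C(4,2)=6 stimulus pairs (passive condition).

    Amplitudes span the full interaction window (O -> C).  Significance: the
    observed mean |d'| must strictly exceed the ``1 - 0.025/m`` quantile of
    a null built by shuffling stimulus labels across trials (m defaults to
    the number of pairs, the Bonferroni family).
    """
    stimuli = sorted(trials["stimulus"].unique())
    if len(stimuli) != 4:
        raise ValueError("passive pairwise d' expects 4 stimuli")
    pairs = list(combinations(stimuli, 2))
    m = bonferroni_m if bonferroni_m is not None else len(pairs)
    lo, hi = epoch_frames["open"], epoch_frames["close"]
    use = np.asarray(analysis_mask, dtype=bool)
    stim = trials["stimulus"].to_numpy()[use]
    for s in stimuli:
        if (stim == s).sum() < 2:
            raise ValueError(f"stimulus {s!r} has fewer than 2 trials")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x9A551E]))

    def mean_abs_and_pairs(amps: np.ndarray, labels: np.ndarray):
        ds = [dprime(amps[labels == a], amps[labels == b]) for a, b in pairs]
        return float(np.nanmean(np.abs(ds))), ds

    rows = []
    for n in range(events.shape[0]):
        amps = trial_amplitudes(events[n][:, use], lo, hi)
        obs_stat, ds = mean_abs_and_pairs(amps, stim)
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            null[s] = mean_abs_and_pairs(amps, rng.permutation(stim))[0]
        null = null[np.isfinite(null)]
        if not np.isfinite(obs_stat) or null.size == 0 or np.ptp(null) == 0:
            sig = False
        else:
            sig = obs_stat > np.quantile(null, 1 - 0.025 / m)
        row = {"neuron": n, "mean_dprime": float(np.nanmean(ds)),
               "mean_abs_dprime": obs_stat, "significant": bool(sig)}
        row.update({f"d_{a}_{b}": d for (a, b), d in zip(pairs, ds)})
        rows.append(row)
    return pd.DataFrame(rows)
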