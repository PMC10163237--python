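"""Time-resolved linear population decoding with permutation inference.

At every frame an independent linear support vector machine is trained on
per-neuron activity (features standardized with training-fold statistics)
and evaluated in leave-one-trial-out cross-validation; accuracy is the
fraction of held-out trials classified correctly.  Four-way stimulus
decoding uses one-vs-rest classifiers combined winner-takes-all (chance
25%).  Cross-day decoding trains on all trials of one session and tests on
every trial of the other, restricted to registered neurons.  Significance
of an accuracy time course comes from a cluster-based permutation test:
trial labels are shuffled, time courses recomputed, frames exceeding the
pointwise 97.5th null percentile form contiguous clusters scored by summed
deviation from chance, and each observed cluster is compared against the
permutation distribution of the maximum cluster score (both directions).

The SVM solver is libsvm via scikit-learn.  The tight LOO x frames x
permutation loops call the solver through ``sklearn.svm._libsvm`` (the
exact solver behind :class:`sklearn.svm.SVC`) to avoid per-fit estimator
overhead; equality of decision values with ``SVC`` is asserted in the unit
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import _libsvm

_libsvm.set_verbosity_wrap(0)

CHANCE_BINARY = 0.5
CHANCE_FOUR_WAY = 0.25


@dataclass(frozen=True)
class DecoderSpec:
    """Linear-kernel decoder configuration."""

    standardize: bool = True
    C: float = 1.0
    seed: int = 0


@dataclass
class DecodingResult:
    """Per-frame decoding accuracy and its significance summary."""

    frames: np.ndarray  # frame indices decoded
    accuracy: np.ndarray  # fraction correct per decoded frame
    chance: float
    n_trials_used: int
    shuffle_lo: np.ndarray | None = None  # per-frame 2.5% shuffle quantile
    shuffle_hi: np.ndarray | None = None  # per-frame 97.5% shuffle quantile
    clusters: list[dict] = field(default_factory=list)
    mean_deviation: float | None = None  # mean (accuracy - chance)

    @property
    def peak_accuracy(self) -> float:
        return float(np.max(self.accuracy))


# ---------------------------------------------------------------------------
# linear SVM primitive (libsvm through scikit-learn)
# ---------------------------------------------------------------------------
def fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> tuple[np.ndarray, float]:
    """Fit a binary linear SVM; returns (w, b) with the :class:`SVC`
    decision convention: ``X @ w + b > 0`` predicts the larger class label.

    ``y`` must contain exactly the values 0 and 1.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    out = _libsvm.fit(X, y, svm_type=0, kernel="linear", C=float(C))
    sv_coef, intercept = out[3], out[4]
    support_vectors = out[1]
    w_raw = (sv_coef @ support_vectors).ravel()
    # libsvm's raw binary decision is the negative of sklearn's convention
    return -w_raw, float(-intercept[0])


def _standardize_pair(Xtr: np.ndarray, Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _binary_decision(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, spec: DecoderSpec,
    rng: np.random.Generator, prestandardized: bool = False,
) -> np.ndarray:
    """Decision values for the test rows (positive -> class 1).

    Degenerate folds (single training class, or no feature varying) fall
    back to the majority training label, ties broken at random.
    """
    if spec.standardize and not prestandardized:
        Xtr, Xte = _standardize_pair(Xtr, Xte)
    classes = np.unique(ytr)
    if classes.size < 2:
        return np.full(len(Xte), 1.0 if classes[0] == 1 else -1.0)
    if not np.any(Xtr.std(axis=0) > 0):
        n1, n0 = np.sum(ytr == 1), np.sum(ytr == 0)
        if n1 != n0:
            return np.full(len(Xte), 1.0 if n1 > n0 else -1.0)
        return np.where(rng.random(len(Xte)) < 0.5, 1.0, -1.0)
    w, b = fit_linear_svm(Xtr, ytr, spec.C)
    return Xte @ w + b


# ---------------------------------------------------------------------------
# trial balancing
# ---------------------------------------------------------------------------
def balance_trials(
    trials: pd.DataFrame | np.ndarray, label_field: str | None = None, seed: int = 0
) -> np.ndarray:
    """Indices of a label-balanced trial subset (order preserved).

    Each label is down-sampled without replacement to the minimum class
    count.  Accepts a trial table plus ``label_field``, or a bare label
    array.
    """
    labels = (
        np.asarray(trials[label_field]) if isinstance(trials, pd.DataFrame)
        else np.asarray(trials)
    )
    values, counts = np.unique(labels, return_counts=True)
    if values.size < 2:
        raise ValueError("need at least 2 labels to balance")
    if (counts == 0).any():
        raise ValueError("a label has zero trials")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for v in values:
        idx = np.flatnonzero(labels == v)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


# ---------------------------------------------------------------------------
# decoding drivers
# ---------------------------------------------------------------------------
def _as_features(population: np.ndarray, frame: int) -> np.ndarray:
    """(trials, neurons) feature matrix at one frame from a
    (neurons, frames, trials) activity array."""
    return population[:, frame, :].T


def decode_timecourse(
    population: np.ndarray,
    labels: np.ndarray,
    spec: DecoderSpec = DecoderSpec(),
    frames: np.ndarray | None = None,
) -> DecodingResult:
    """Leave-one-trial-out binary decoding at each frame.

    ``population`` is (neurons, frames, trials) activity (event traces by
    default); ``labels`` the per-trial condition (2 classes).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("binary decoding needs exactly 2 classes")
    y = (labels == classes[1]).astype(float)
    n_trials = population.shape[2]
    if n_trials != len(labels):
        raise ValueError("labels length must match trial count")
    frames = np.arange(population.shape[1]) if frames is None else np.asarray(frames)
    rng = np.random.default_rng(spec.seed)
    acc = np.empty(len(frames))
    for k, f in enumerate(frames):
        X = _as_features(population, f)
        correct = 0
        for i in range(n_trials):
            tr = np.arange(n_trials) != i
            dec = _binary_decision(X[tr], y[tr], X[i : i + 1], spec, rng)
            correct += (dec[0] > 0) == (y[i] == 1)
        acc[k] = correct / n_trials
    return DecodingResult(frames, acc, CHANCE_BINARY, n_trials)


def _ovr_predict(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, classes: np.ndarray,
    spec: DecoderSpec, rng: np.random.Generator,
) -> np.ndarray:
    """Winner-takes-all one-vs-rest prediction (ties -> lowest class index)."""
    if spec.standardize:
        Xtr, Xte = _standardize_pair(Xtr, Xte)
    dec = np.empty((len(Xte), len(classes)))
    for k, c in enumerate(classes):
        dec[:, k] = _binary_decision(
            Xtr, (ytr == c).astype(float), Xte, spec, rng, prestandardized=True
        )
    return classes[np.argmax(dec, axis=1)]  # argmax takes the first maximum


def multiclass_decode(
    population: np.ndarray,
    labels: np.ndarray,
    spec: DecoderSpec = DecoderSpec(),
    frames: np.ndarray | None = None,
) -> DecodingResult:
    """Leave-one-trial-out four-way (one-vs-rest, winner-takes-all) decoding."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    n_trials = population.shape[2]
    frames = np.arange(population.shape[1]) if frames is None else np.asarray(frames)
    rng = np.random.default_rng(spec.seed)
    acc = np.empty(len(frames))
    for k, f in enumerate(frames):
        X = _as_features(population, f)
        correct = 0
        for i in range(n_trials):
            tr = np.arange(n_trials) != i
            pred = _ovr_predict(X[tr], labels[tr], X[i : i + 1], classes, spec, rng)
            correct += pred[0] == labels[i]
        acc[k] = correct / n_trials
    return DecodingResult(frames, acc, 1.0 / classes.size, n_trials)


def crossday_decode(
    train_population: np.ndarray,
    train_labels: np.ndarray,
    test_population: np.ndarray,
    test_labels: np.ndarray,
    regmap=None,
    day_i: int = 0,
    day_j: int = 1,
    spec: DecoderSpec = DecoderSpec(),
    frames: np.ndarray | None = None,
    n_shuffle_band: int = 0,
) -> DecodingResult:
    """Train at each frame on all day-i trials, test on every day-j trial.

    Only neurons registered on both days are used (``regmap=None`` means
    the populations are already aligned).  ``n_shuffle_band > 0`` adds a
    per-frame 2.5%/97.5% accuracy band from decoders trained on shuffled
    labels, and the mean signed deviation of accuracy from chance is
    reported over the decoded frames.
    """
    if regmap is not None:
        idx_i, idx_j = regmap.linked(day_i, day_j)
        if len(idx_i) == 0:
            raise ValueError("registration map links no neurons across the days")
        train_population = train_population[idx_i]
        test_population = test_population[idx_j]
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    classes = np.unique(train_labels)
    if classes.size != 2:
        raise ValueError("binary decoding needs exactly 2 classes")
    ytr = (train_labels == classes[1]).astype(float)
    yte = (test_labels == classes[1]).astype(float)
    frames = np.arange(train_population.shape[1]) if frames is None else np.asarray(frames)
    rng = np.random.default_rng(spec.seed)

    def run(y_train: np.ndarray) -> np.ndarray:
        a = np.empty(len(frames))
        for k, f in enumerate(frames):
            dec = _binary_decision(
                _as_features(train_population, f), y_train,
                _as_features(test_population, f), spec, rng,
            )
            a[k] = np.mean((dec > 0) == (yte == 1))
        return a

    acc = run(ytr)
    lo = hi = None
    if n_shuffle_band > 0:
        null = np.empty((n_shuffle_band, len(frames)))
        for s in range(n_shuffle_band):
            null[s] = run(rng.permutation(ytr))
        lo = np.quantile(null, 0.025, axis=0)
        hi = np.quantile(null, 0.975, axis=0)
    return DecodingResult(
        frames, acc, CHANCE_BINARY, len(test_labels),
        shuffle_lo=lo, shuffle_hi=hi,
        mean_deviation=float(np.mean(acc - CHANCE_BINARY)),
    )


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------
def _clusters_above(values: np.ndarray, thresh: np.ndarray, chance: float, sign: int):
    """Contiguous suprathreshold runs with summed deviation-from-chance scores."""
    above = values > thresh if sign > 0 else values < thresh
    out = []
    start = None
    for i, a in enumerate(np.append(above, False)):
        if a and start is None:
            start = i
        elif not a and start is not None:
            seg = values[start:i]
            score = float(np.sum(seg - chance) if sign > 0 else np.sum(chance - seg))
            out.append({"start": start, "end": i, "score": score, "direction": sign})
            start = None
    return out


def cluster_permutation_test(
    timecourse_fn,
    labels: np.ndarray,
    chance: float,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[list[dict], DecodingResult | np.ndarray]:
    """Cluster-based permutation significance for an accuracy time course.

    ``timecourse_fn(labels) -> per-frame accuracy`` is re-run on ``n_perm``
    label shuffles.  Cluster-forming thresholds are the pointwise 2.5th and
    97.5th percentiles of the null; observed clusters (summed
    accuracy-minus-chance score) are compared with the null distribution of
    the maximum cluster score over both directions, giving family-wise
    two-sided control.  Cluster p = (1 + #{null max >= score}) / (1 + n_perm).
    """
    labels = np.asarray(labels)
    observed = np.asarray(timecourse_fn(labels), dtype=float)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(observed)))
    for s in range(n_perm):
        null[s] = timecourse_fn(rng.permutation(labels))
    hi = np.quantile(null, 0.975, axis=0)
    lo = np.quantile(null, 0.025, axis=0)

    def max_score(series: np.ndarray) -> float:
        cl = _clusters_above(series, hi, chance, +1) + _clusters_above(series, lo, chance, -1)
        return max((c["score"] for c in cl), default=0.0)

    null_max = np.array([max_score(null[s]) for s in range(n_perm)])
    clusters = _clusters_above(observed, hi, chance, +1) + _clusters_above(
        observed, lo, chance, -1
    )
    for c in clusters:
        c["p"] = float((1 + np.sum(null_max >= c["score"])) / (1 + n_perm))
        c["significant"] = c["p"] < alpha
    return clusters, observed


def performance_decoding_correlation(
    peak_accuracies, correct_rates
) -> tuple[float, float]:
    """Pearson correlation between per-session peak decoding accuracy and
    behavioral correct rate; (NaN, NaN) when either vector is constant."""
    x = np.asarray(peak_accuracies, dtype=float)
    y = np.asarray(correct_rates, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 sessions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)
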