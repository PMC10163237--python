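"""Synthetic Go-NoGo sessions with planted ground truth.

This module fabricates everything the real experiment records: a
pseudo-random stimulus schedule (no stimulus more than three times in a row,
running counts balanced to within ten), a behaving agent whose hit and
false-alarm rates follow a logistic acquisition curve, and a population of
GCaMP6f-like fluorescence traces in which neuron classes are planted:

``reward`` / ``no-reward``
    trial-type-tuned neurons whose modulation follows the reward category,
    so their preferred *stimulus* flips when the contingency is reversed;
``identity:<stimulus>``
    stimulus-tuned neurons whose preference follows one stimulus mouse;
``none``
    non-responsive neurons.

Each responsive neuron is either ``activated`` (extra calcium events in the
stimulus epoch of preferred trials) or ``inhibited`` (elevated tonic event
rate that is suppressed in the preferred epoch - suppression is only
observable against nonzero baseline activity).  Because the classes are
planted, every downstream stage can be validated by recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from . import behavior
from .task import NO_REWARD, REWARD, TaskSpec, rng_for

MAX_RUN = 3
MAX_IMBALANCE = 10

ACTIVATED = "activated"
INHIBITED = "inhibited"


# ---------------------------------------------------------------------------
# ground truth and parameter containers
# ---------------------------------------------------------------------------
@dataclass
class NeuronTruth:
    """Planted identity of one synthetic neuron."""

    label: str = "none"  # "reward" | "no-reward" | "identity:<stim>" | "none"
    polarity: str = "none"  # "activated" | "inhibited" | "none"
    amplitude: float = 0.0  # peak transient size, dF/F0 units
    event_rate: float = 0.0  # planted events/trial in the responsive epoch
    stable: bool = True  # keeps its tuning on the next day

    def preferred_trials(self, trials: pd.DataFrame) -> np.ndarray:
        """Boolean mask of the trials this neuron is tuned to."""
        if self.label == REWARD:
            return (trials["category"] == REWARD).to_numpy()
        if self.label == NO_REWARD:
            return (trials["category"] == NO_REWARD).to_numpy()
        if self.label.startswith("identity:"):
            return (trials["stimulus"] == self.label.split(":", 1)[1]).to_numpy()
        return np.zeros(len(trials), dtype=bool)


@dataclass
class GroundTruth:
    """Planted classes for a whole population."""

    neurons: list[NeuronTruth]

    def __len__(self) -> int:
        return len(self.neurons)

    def labels(self) -> list[str]:
        return [n.label for n in self.neurons]

    @classmethod
    def build(
        cls,
        n_reward: int = 20,
        n_no_reward: int = 10,
        n_identity: int = 20,
        n_none: int = 150,
        stimuli: tuple[str, ...] = ("A", "B"),
        amplitude: float = 1.5,
        event_rate: float = 2.0,
        frac_inhibited: float = 0.0,
        stable: bool = True,
        seed: int = 0,
    ) -> "GroundTruth":
        """Assemble a population with the given planted class counts.

        Identity neurons are distributed round-robin over ``stimuli``;
        a fraction ``frac_inhibited`` of each responsive class is planted
        with inhibited polarity.
        """
        rng = rng_for(seed, "truth")
        neurons: list[NeuronTruth] = []

        def polarity() -> str:
            return INHIBITED if rng.random() < frac_inhibited else ACTIVATED

        for _ in range(n_reward):
            neurons.append(
                NeuronTruth(REWARD, polarity(), amplitude, event_rate, stable)
            )
        for _ in range(n_no_reward):
            neurons.append(
                NeuronTruth(NO_REWARD, polarity(), amplitude, event_rate, stable)
            )
        for i in range(n_identity):
            stim = stimuli[i % len(stimuli)]
            neurons.append(
                NeuronTruth(f"identity:{stim}", polarity(), amplitude, event_rate, stable)
            )
        for _ in range(n_none):
            neurons.append(NeuronTruth())
        return cls(neurons)

    def to_records(self) -> list[dict]:
        return [dataclasses.asdict(n) for n in self.neurons]

    @classmethod
    def from_records(cls, records: list[dict]) -> "GroundTruth":
        return cls([NeuronTruth(**r) for r in records])


@dataclass(frozen=True)
class AgentParams:
    """Logistic-acquisition behavioral agent.

    The probability of a Go response (licking in the response window)
    follows ``p = 0.5 +/- (asymptote - 0.5) * a(t)`` where
    ``a(t) = 1 / (1 + exp(-learn_rate * (t - midpoint_trial)))``; the sign
    depends on whether the agent believes the stimulus is rewarded.
    """

    learn_rate: float = 0.2
    midpoint_trial: float = 20.0
    asymptote_hit: float = 0.96
    asymptote_fa: float = 0.04
    lick_latency_mean_s: float = 0.25
    lick_latency_sd_s: float = 0.12

    def __post_init__(self) -> None:
        if not self.asymptote_hit > self.asymptote_fa:
            raise ValueError("asymptote_hit must exceed asymptote_fa")
        if self.lick_latency_mean_s < 0 or self.lick_latency_sd_s < 0:
            raise ValueError("lick latency parameters must be >= 0")

    def acquisition(self, trial_idx: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.learn_rate * (trial_idx - self.midpoint_trial)))


@dataclass(frozen=True)
class NoiseSpec:
    """Fluorescence model parameters.

    baseline is in raw-fluorescence units; drift amplitude, transient
    amplitudes and white noise sd are fractions of baseline (dF/F0 units).
    Transients use a double-exponential kernel (GCaMP6f-like: 50 ms rise,
    600 ms decay), peak-normalized to 1.
    """

    baseline: float = 100.0
    drift_amplitude: float = 0.10
    drift_timescale_s: float = 20.0
    white_sd: float = 0.05
    rise_s: float = 0.05
    decay_s: float = 0.6
    background_rate_hz: float = 0.02  # spontaneous events/s everywhere
    background_amp: float = 1.0
    inhibited_keep: float = 0.1  # fraction of tonic events surviving suppression
    lick_artifact_amp: float = 0.0  # optional post-R motor/lick transient

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ValueError("kernel time constants must be positive")


@dataclass
class SessionRecord:
    """One session: trial table plus neurons x frames x trials fluorescence."""

    trials: pd.DataFrame
    F: np.ndarray  # (n_neurons, n_frames, n_trials)
    frame_rate_hz: float
    epoch_frames: dict[str, int]
    day: int = 0
    category_map: dict[str, str] = field(default_factory=dict)
    truth: GroundTruth | None = None

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    @property
    def n_trials(self) -> int:
        return self.F.shape[2]


@dataclass
class RegistrationMap:
    """Cross-day links between neuron indices.

    ``links[i, d]`` is the index of planted neuron ``i`` in the day-``d``
    session (-1 if absent that day).  ``stable`` records which links were
    planted as tuning-stable (synthetic ground truth only).
    """

    links: np.ndarray  # (n_neurons, n_days) int
    stable: np.ndarray  # (n_neurons,) bool

    @property
    def n_days(self) -> int:
        return self.links.shape[1]

    def linked(self, day_i: int, day_j: int) -> tuple[np.ndarray, np.ndarray]:
        """Index pairs of neurons present on both days (one-to-one)."""
        ok = (self.links[:, day_i] >= 0) & (self.links[:, day_j] >= 0)
        return self.links[ok, day_i], self.links[ok, day_j]

    def to_json_dict(self) -> dict:
        return {"links": self.links.tolist(), "stable": self.stable.tolist()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "RegistrationMap":
        return cls(np.asarray(d["links"], dtype=int), np.asarray(d["stable"], dtype=bool))

    @classmethod
    def identity(cls, n_neurons: int, n_days: int, stable=None) -> "RegistrationMap":
        links = np.tile(np.arange(n_neurons)[:, None], (1, n_days))
        if stable is None:
            stable = np.ones(n_neurons, dtype=bool)
        return cls(links, np.asarray(stable, dtype=bool))


# ---------------------------------------------------------------------------
# trial schedule
# ---------------------------------------------------------------------------
def generate_trial_sequence(
    task: TaskSpec, n_trials: int, seed: int = 0, day: int = 0
) -> pd.DataFrame:
    """Pseudo-random stimulus schedule with the two presentation constraints.

    No stimulus appears more than three times in a row, and at every prefix
    the accumulated counts of any two stimuli differ by at most ten.  Each
    trial's stimulus is drawn uniformly from the set of stimuli that violate
    neither constraint (for >= 2 stimuli this set is never empty).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = rng_for(seed, "schedule", day)
    stimuli = list(task.stimuli)
    counts = {s: 0 for s in stimuli}
    seq: list[str] = []
    run = 0
    for _ in range(n_trials):
        lo = min(counts.values())
        allowed = [
            s
            for s in stimuli
            if not (run >= MAX_RUN and seq and s == seq[-1])
            and counts[s] - lo < MAX_IMBALANCE
        ]
        if not allowed:  # unreachable for >= 2 stimuli; guard for 1 stimulus
            allowed = [s for s in stimuli if counts[s] - lo < MAX_IMBALANCE] or stimuli
        choice = allowed[rng.integers(len(allowed))]
        run = run + 1 if seq and choice == seq[-1] else 1
        seq.append(choice)
        counts[choice] += 1

    return pd.DataFrame(
        {
            "trial_idx": np.arange(n_trials),
            "day": day,
            "stimulus": seq,
            "category": [task.category_map[s] for s in seq],
            "t_open": task.t_open,
            "t_open_complete": task.t_open_complete,
            "t_response": task.t_response,
            "t_close": task.t_close,
            "lick_times": [[] for _ in range(n_trials)],
            "outcome": "",
            "rewarded": False,
        }
    )


# ---------------------------------------------------------------------------
# behaving agent
# ---------------------------------------------------------------------------
def generate_behavior(
    trials: pd.DataFrame,
    agent: AgentParams,
    seed: int = 0,
    perceived_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Fill lick times and outcomes for a scheduled session.

    ``perceived_map`` lets the agent act on a stale stimulus-reward belief
    (e.g. the pre-reversal map on a reversal day); by default it licks
    according to the true category of each trial.
    """
    if not {"t_response", "t_close"}.issubset(trials.columns):
        raise ValueError("trials must carry epoch timestamps")
    day = int(trials["day"].iloc[0]) if len(trials) else 0
    rng = rng_for(seed, "behavior", day)
    out = trials.copy()
    acq = agent.acquisition(out["trial_idx"].to_numpy(dtype=float))
    if perceived_map is None:
        believes_reward = (out["category"] == REWARD).to_numpy()
    else:
        believes_reward = np.array(
            [perceived_map[s] == REWARD for s in out["stimulus"]], dtype=bool
        )
    p_go = np.where(
        believes_reward,
        0.5 + (agent.asymptote_hit - 0.5) * acq,
        0.5 - (0.5 - agent.asymptote_fa) * acq,
    )
    goes = rng.random(len(out)) < p_go
    licks: list[list[float]] = []
    for i, go in enumerate(goes):
        row_licks: list[float] = []
        # occasional inconsequential grace-period lick
        if rng.random() < 0.05:
            row_licks.append(
                float(out["t_open"].iloc[i] + rng.uniform(0, 0.9) * (
                    out["t_response"].iloc[i] - out["t_open"].iloc[i]
                ))
            )
        if go:
            t_resp = out["t_response"].iloc[i]
            t_close = out["t_close"].iloc[i]
            window = t_close - t_resp
            lat = rng.normal(agent.lick_latency_mean_s, agent.lick_latency_sd_s)
            lat = float(np.clip(lat, 0.02, window - 0.05))
            first = t_resp + lat
            row_licks.extend(
                t for t in (first, first + 0.15, first + 0.30) if t < t_close
            )
        licks.append(sorted(row_licks))
    out["lick_times"] = licks
    return behavior.score_trials(out)


# ---------------------------------------------------------------------------
# fluorescence synthesis
# ---------------------------------------------------------------------------
def _transient_kernel(noise: NoiseSpec, frame_rate_hz: float) -> np.ndarray:
    dt = 1.0 / frame_rate_hz
    t = np.arange(0.0, 5.0 * noise.decay_s + dt, dt)
    k = np.exp(-t / noise.decay_s) - np.exp(-t / noise.rise_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def generate_population(
    trials: pd.DataFrame,
    truth: GroundTruth,
    noise: NoiseSpec,
    task: TaskSpec,
    seed: int = 0,
) -> SessionRecord:
    """Raw fluorescence for a whole population over one session.

    ``F = baseline * (1 + drift + transients + white noise)``.  Transient
    event times are Poisson; activated neurons gain events (expected
    ``event_rate`` per preferred trial) in the stimulus epoch
    (open-complete to response start) of their preferred trials, while
    inhibited neurons carry a tonic event rate of ``event_rate`` per trial
    that is thinned to ``inhibited_keep`` in that epoch.
    """
    n_neurons = len(truth)
    n_frames, n_trials = task.n_frames, len(trials)
    day = int(trials["day"].iloc[0]) if n_trials else 0
    rng = rng_for(seed, "population", day)
    fr = task.frame_rate_hz
    kern = _transient_kernel(noise, fr)
    ef = task.epoch_frames()
    epoch_lo, epoch_hi = ef["open_complete"], ef["response"]
    # inhibition spans the whole interaction window, so that no tonic-event
    # tail from the grace period leaks into the measured stimulus epoch
    supp_lo, supp_hi = ef["open"], ef["close"]

    F = np.empty((n_neurons, n_frames, n_trials))
    t_total = task.trial_duration_s
    for n, nt in enumerate(truth.neurons):
        impulses = np.zeros((n_frames, n_trials))
        pref = nt.preferred_trials(trials)
        for tr in range(n_trials):
            # spontaneous background events anywhere in the trial
            n_bg = rng.poisson(noise.background_rate_hz * t_total)
            for _ in range(n_bg):
                f = int(rng.uniform(0, n_frames))
                impulses[f, tr] += noise.background_amp * rng.uniform(0.9, 1.1)
            if nt.polarity == ACTIVATED and pref[tr]:
                n_ev = rng.poisson(nt.event_rate)
                for _ in range(n_ev):
                    f = int(rng.uniform(epoch_lo, epoch_hi))
                    impulses[f, tr] += nt.amplitude * rng.uniform(0.9, 1.1)
            elif nt.polarity == INHIBITED:
                n_ev = rng.poisson(nt.event_rate)
                for _ in range(n_ev):
                    f = int(rng.uniform(0, n_frames))
                    in_window = supp_lo <= f < supp_hi
                    if pref[tr] and in_window and rng.random() > noise.inhibited_keep:
                        continue  # suppressed while the window is open
                    impulses[f, tr] += nt.amplitude * rng.uniform(0.9, 1.1)
        if noise.lick_artifact_amp > 0:
            resp_f = ef["response"]
            for tr in range(n_trials):
                if trials["lick_times"].iloc[tr]:
                    impulses[min(resp_f, n_frames - 1), tr] += noise.lick_artifact_amp
        sig = fftconvolve(impulses, kern[:, None], axes=0)[:n_frames]
        dff = sig
        if noise.drift_amplitude > 0:
            white = rng.standard_normal(n_frames * n_trials)
            drift = gaussian_filter1d(white, noise.drift_timescale_s * fr, mode="reflect")
            sd = drift.std()
            if sd > 0:
                drift = drift / sd * noise.drift_amplitude
            dff = dff + drift.reshape(n_trials, n_frames).T
        if noise.white_sd > 0:
            dff = dff + noise.white_sd * rng.standard_normal((n_frames, n_trials))
        F[n] = np.maximum(noise.baseline * (1.0 + dff), 1e-9)

    return SessionRecord(
        trials=trials.reset_index(drop=True),
        F=F,
        frame_rate_hz=fr,
        epoch_frames=ef,
        day=day,
        category_map=dict(task.category_map),
        truth=truth,
    )


def generate_session(
    task: TaskSpec,
    truth: GroundTruth,
    n_trials: int = 300,
    seed: int = 0,
    agent: AgentParams | None = None,
    noise: NoiseSpec | None = None,
    day: int = 0,
    perceived_map: dict[str, str] | None = None,
) -> SessionRecord:
    """Schedule + agent + population in one call."""
    agent = agent or AgentParams()
    noise = noise or NoiseSpec()
    trials = generate_trial_sequence(task, n_trials, seed=seed, day=day)
    trials = generate_behavior(trials, agent, seed=seed, perceived_map=perceived_map)
    return generate_population(trials, truth, noise, task, seed=seed)


# ---------------------------------------------------------------------------
# multi-day series with reversals and drift
# ---------------------------------------------------------------------------
def _retuned(truth: GroundTruth, stimuli: tuple[str, ...], rng: np.random.Generator) -> GroundTruth:
    """Re-tune the unstable subset: permute their planted identities among
    themselves and redraw identity-neuron stimulus preferences, modelling
    day-to-day representational drift while preserving class proportions."""
    neurons = [dataclasses.replace(n) for n in truth.neurons]
    unstable = [i for i, n in enumerate(neurons) if not n.stable]
    perm = rng.permutation(len(unstable))
    shuffled = [dataclasses.replace(neurons[unstable[j]]) for j in perm]
    for i, n in zip(unstable, shuffled):
        if n.label.startswith("identity:"):
            n.label = f"identity:{stimuli[rng.integers(len(stimuli))]}"
        neurons[i] = n
    return GroundTruth(neurons)


def generate_multiday(
    task: TaskSpec,
    truth: GroundTruth,
    n_days: int,
    reversal_schedule: list[dict[str, str]],
    seed: int = 0,
    agent: AgentParams | None = None,
    noise: NoiseSpec | None = None,
    n_trials: int = 300,
) -> tuple[list[SessionRecord], RegistrationMap]:
    """Generate consecutive daily sessions under a per-day category map.

    Reward / no-reward neurons follow the trial type (their preferred
    stimulus flips under reversal); identity neurons follow their stimulus.
    Neurons planted as unstable are re-tuned before each new day.  The
    returned registration map links indices across all days (identity links;
    the registration algorithm itself is out of scope) and records the
    planted stability flags.
    """
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    if len(reversal_schedule) != n_days:
        raise ValueError("reversal_schedule must list one category_map per day")
    sessions = []
    day_truth = truth
    for d in range(n_days):
        day_task = dataclasses.replace(task, category_map=dict(reversal_schedule[d]))
        if d > 0:
            day_truth = _retuned(day_truth, task.stimuli, rng_for(seed, "drift", d))
        sessions.append(
            generate_session(
                day_task, day_truth, n_trials=n_trials, seed=seed,
                agent=agent, noise=noise, day=d,
            )
        )
    stable = np.array([n.stable for n in truth.neurons], dtype=bool)
    return sessions, RegistrationMap.identity(len(truth), n_days, stable)
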