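# socialca1

Analysis pipeline for two-photon calcium imaging of dorsal hippocampal CA1
during head-fixed Go-NoGo social discrimination tasks, in which a subject
mouse learns that licking upon one familiar stimulus mouse (Go) yields a
water reward while licking upon another (NoGo) does not. The scientific
question the pipeline addresses: when a CA1 neuron fires differently on Go
and NoGo trials, is it coding the *expected reward* or the *identity of the
stimulus mouse*? Reversing the stimulus-reward contingency between days
dissociates the two — a neuron that keeps its Go/NoGo preference across the
reversal tracks reward expectation, while one that flips tracks the
stimulus.

The package is aimed at systems-neuroscience analysts: it takes per-trial
fluorescence arrays (neurons × frames × trials) plus behavioral trial
tables and produces event traces, per-neuron selectivity, cross-day neuron
classes, and population decoding time courses. Because the real data for
this paradigm are not publicly deposited, the package ships a first-class
synthetic-session generator that plants known neuron classes, so every
stage of the analysis is validated by recovery of planted ground truth.

## What it computes

- **Behavior** — hit / miss / false-alarm / correct-rejection scoring from
  response-window licks; hit, CR and correct rates overall and in sliding
  50-trial windows; high-performance periods (both rates > 80%, session
  qualifying with > 200 such trials); reversed session pairing.
- **Preprocessing** — per-trial median filtering, running-percentile drift
  correction, mode-of-KDE baseline F₀, ΔF/F₀ = (F − F₀)/F₀, and a two-pass
  robust calcium-event threshold (median + 3·IQR of quiescent pre-opening
  epochs) with a per-neuron false-positive ratio.
- **Selectivity** — the discriminability index between trial conditions,

      d′ = (μ₁ − μ₂) / √((σ₁² + σ₂²)/2),

  on per-trial calcium response amplitudes, with a two-sided 1000-shuffle
  permutation test (2.5% tails; Bonferroni for multi-pair comparisons);
  activated / inhibited / non-responsive codes from paired Wilcoxon tests
  on event areas, and the −2…+2 response score.
- **Reversal classification** — reward-, no-reward-, and mouse-selective
  neuron classes across registered, contingency-reversed session pairs;
  3×3 chi-square contingency inference with Haberman adjusted residuals
  and planned comparisons at p < 0.0125; stability fractions vs chance.
- **Decoding** — frame-by-frame linear-SVM population decoding
  (leave-one-trial-out, training-fold standardization, class-balanced),
  binary and four-way winner-takes-all (chance 25%), within- and
  cross-day, with cluster-based permutation significance.

See `docs/methods.md` for the full model and every numerical choice.

## Worked example

Generate a two-day reversed pair with planted classes (8 reward, 4
no-reward, 8 identity, 40 non-responsive neurons; 300 trials/day), run the
full analysis, and classify neurons across the reversal:

```python
import numpy as np
from socialca1 import synthgen, behavior, preprocess, selectivity, reversal
from socialca1.task import TaskSpec

task = TaskSpec()  # 2 stimuli, 30 Hz, 180 frames/trial, 1.3 s grace
truth = synthgen.GroundTruth.build(
    n_reward=8, n_no_reward=4, n_identity=8, n_none=40, seed=0)
sessions, regmap = synthgen.generate_multiday(
    task, truth, 2, [dict(task.category_map), task.reversed_map()],
    seed=7, n_trials=300)

labels = []
for s in sessions:
    perf = behavior.find_high_performance(s.trials)
    rates = behavior.compute_rates(s.trials, "all")
    print(f"day {s.day}: hit {rates.hit_rate[0]:.2f}, CR {rates.cr_rate[0]:.2f}, "
          f"{perf.high_performance_mask.sum()} high-performance trials")
    ev = preprocess.preprocess_session(s)
    mask = behavior.analysis_trial_mask(s.trials, perf)
    tab = selectivity.trial_type_selectivity(
        ev.events, s.trials, mask, s.epoch_frames, seed=7)
    print(f"  Go-preferring {(tab.label == 'Go').sum()}, "
          f"NoGo-preferring {(tab.label == 'NoGo').sum()}")
    labels.append(tab["label"].to_numpy())

cls = reversal.classify_across_reversal(labels[0], labels[1], regmap)
print("cross-reversal classes:", cls.class_counts)
inf = cls.inference
print(f"3x3 chi-square = {inf.chi2:.1f}, p = {inf.p:.2e}")
```

Output:

```
day 0: hit 0.92, CR 0.93, 296 high-performance trials
  Go-preferring 14, NoGo-preferring 8
day 1: hit 0.93, CR 0.91, 291 high-performance trials
  Go-preferring 12, NoGo-preferring 10
cross-reversal classes: {'none': 40, 'reward-selective': 8, 'mouse-selective': 8, 'no-reward-selective': 4}
3x3 chi-square = 46.6, p = 1.81e-09
```

Both days qualify as high-performance sessions. On each day, Go-preferring
neurons comprise the planted reward neurons plus the identity neurons whose
preferred mouse is currently rewarded (hence 14 ≈ 8 + 8/2 − noise).
Crossing the reversal disambiguates them: all 8 planted reward neurons keep
their Go preference (reward-selective), all 8 identity neurons flip it
(mouse-selective), and independence of day-1 and day-2 preferences is
firmly rejected.

The same flow is available from the shell:

```sh
socialca1 run-all --out run/ --seed 7
socialca1 behavior --in run/day0_trials.csv
socialca1 decode --in run/day0_trials.csv --fluo run/day0_fluorescence.h5 \
    --events run/day0_events.h5 --out run/day0_decode.csv
```

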