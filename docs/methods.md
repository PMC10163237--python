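# Methods

This note documents the models, statistics, and numerical choices behind
`socialca1`, in the order the pipeline runs them.

## Task model

A session is a sequence of head-fixed Go-NoGo trials. Imaging of each trial
spans 6 s at 30 frames/s (180 frames): 1.2 s before the interaction window
opens (`O`, frame 36), a 0.4 s opening motion (fully open at frame 48), a
grace period until the response window starts (`R`; grace 0.8–1.3 s,
default 1.3 s, frame 75), and closure 4 s after opening (`C`, frame 156)
plus 0.8 s of post-close imaging. Licking during `[R, C)` on a
reward-category trial is a hit and delivers a reward; on a no-reward trial
it is a false alarm. Grace-period licks have no consequence; a lick exactly
at `C` falls outside the half-open response window. Trials repeat every
12 s (the inter-trial gap is not imaged or modeled beyond its duration).

The stimulus schedule is pseudo-random under two constraints: no stimulus
appears more than three times in a row, and at every prefix the accumulated
counts of any two stimuli differ by at most ten. Each trial draws uniformly
from the stimuli violating neither constraint. This is distributionally
identical to per-trial rejection sampling but never loops; one can show the
feasible set is never empty for two or more stimuli (a stimulus can only
reach the imbalance cap by having just been presented, and the
minimum-count stimulus is never at the cap).

## Synthetic sessions

**Agent.** The probability of a Go response follows a logistic acquisition
curve `a(t) = 1/(1 + exp(-r (t - t0)))` in trial index `t`, interpolating
between 0.5 (chance) and the asymptotic hit rate on reward trials, and
between 0.5 and the asymptotic false-alarm rate on no-reward trials.
Defaults (`r = 0.2`, `t0 = 20`, hit 0.96, FA 0.04) describe a well-trained
animal that re-acquires a reversed contingency within a few tens of trials,
so that a 300-trial session accumulates the >200 high-performance trials
the downstream analyses require. Lick latencies are Gaussian
(mean 0.25 s, sd 0.12 s after `R`, clipped into the response window), with
two follow-up licks at 150 ms spacing and occasional inconsequential
grace-period licks. An optional `perceived_map` lets the agent act on a
stale stimulus-reward belief, producing the below-chance performance seen
at the start of an unlearned reversal.

**Fluorescence.** `F = baseline · (1 + drift + transients + noise)`, with
baseline 100 (arbitrary raw units), slow drift as Gaussian-filtered white
noise (timescale 20 s, amplitude 0.10 of baseline), and white noise sd 0.05.
Transients are Poisson-timed double-exponential kernels (rise 50 ms, decay
600 ms, peak-normalized — GCaMP6f-like, spanning several frames at 30 Hz),
with spontaneous background events at 0.02 events/s everywhere.
Planted classes:

- *reward* / *no-reward* neurons follow the trial's reward category, so
  their preferred stimulus flips under contingency reversal;
- *identity* neurons follow one stimulus mouse;
- *activated* polarity adds events (default 2 expected events per preferred
  trial, amplitude 1.5 ΔF/F₀) in the stimulus epoch (fully-open → `R`);
- *inhibited* polarity carries a tonic event rate over the whole trial that
  is thinned to 10% while the interaction window is open on preferred
  trials. Suppression spans the whole open window (not just the measured
  stimulus epoch) so that no tonic-event tail from the grace period leaks
  into the epoch; suppression is only observable against nonzero baseline
  activity, and because tonic transients also contaminate the pre-opening
  threshold epoch, inhibited neurons are planted sparser (a few large
  events per trial) — a regime in which the event threshold remains sane.
  Tonic rates much above ~1 event/s saturate the pre-opening interquartile
  range and make any neuron effectively undetectable; this mirrors a real
  limitation of quiescent-epoch thresholding.

Transient kernels are truncated at trial boundaries (the 0.8 s post-close
imaging absorbs most of the tail; no cross-trial bleed is modeled).

**Multi-day series.** Each day re-generates schedule, behavior, and
fluorescence under that day's category map. Stability is a per-neuron flag
applied to every consecutive day pair: stable neurons keep their tuning;
unstable neurons are re-tuned before each new day by permuting their
planted identities among the unstable subset (preserving class
proportions) and redrawing identity-neuron stimulus preferences. This
models day-to-day representational drift in which the population-level
code persists while its carriers change. The registration map across days
is the identity (cell registration itself is out of scope) and records the
planted stability flags as ground truth.

**Seeding.** A single global seed expands into per-stage child seeds via
`SeedSequence([seed, crc32(stage label), ...])`, so any stage can be
reproduced in isolation; the whole pipeline is a pure function of
(config, seed).

## Behavioral scoring

Hit rate = hits / reward trials, CR rate = CRs / no-reward trials, correct
rate = (hits + CRs) / trials, computed overall or in sliding windows of 50
trials advancing by one trial (the maximal-information reading of a
"sliding window"; the stride is configurable). The high-performance period
is the union of all windows with hit rate and CR rate both strictly above
80%; a session qualifies with strictly more than 200 such trials. All
calcium analyses are restricted to correct trials inside high-performance
periods. Reversed session pairs are ordered (earlier day first), require
both sessions to qualify, exactly swapped category maps, and a day gap
within the configured maximum (default 1).

## Preprocessing

Per neuron: order-3 median filter within each trial (edge-replicating),
concatenation of trials in order, and slow-drift removal by subtracting a
running 5th percentile over a 900-frame centered window. The window covers
concatenated frames `[i - w//2, i + (w+1)//2)`, truncated at the trace
edges (windows longer than the trace are clipped with a warning).

Baseline F₀ is the mode of a Gaussian KDE of the conditioned trace:
Silverman bandwidth `0.9 · min(sd, IQR/1.349) · n^(-1/5)`, evaluated on a
512-point grid over `[min, max]` by linear binning plus Gaussian smoothing
(a standard fast KDE; accurate to grid resolution and fast enough for
hundreds of session-length traces). Because the drift step subtracts a
percentile, F₀ can come out non-positive; in that case the neuron's global
5th percentile of the raw trace is added back and the neuron flagged.
ΔF/F₀ = (F − F₀)/F₀.

The event threshold is a two-pass robust estimate from the quiescent
pre-opening epochs: pass 1 pools all trials' pre-opening ΔF/F₀ into a
"three-interquartile" threshold, trials whose pre-opening trace ever
exceeds it are excluded, and pass 2 recomputes the threshold from the
remaining trials (falling back to the pass-1 value, flagged, if every
trial is excluded). "Three-interquartile value" is read as
median + 3·IQR of the pooled values — a robust z ≈ 4 cut, ≈ 4.05 on
standard-normal noise; since pre-opening ΔF/F₀ is near-zero-median the
plain `3·IQR` and `Q3 + 3·IQR` readings nearly coincide and both are
available as `threshold_mode` options. Excluded trials are dropped only
from threshold estimation, never from analysis. The event trace keeps
ΔF/F₀ strictly above threshold and is zero elsewhere. The false-positive
ratio counts contiguous excursions below −T against those above +T on the
concatenated trace (missing when there are no positive events); symmetric
noise gives ≈ 1, and the planted-transient regime gives a median well
under 5%.

## Selectivity

Response amplitude of a trial is the mean event-trace value over the
analysis window: opening → `R` for trial-type (Go/NoGo) discrimination,
opening → `C` for mouse-identity discrimination. The discriminability
index is `d' = (μ₁ − μ₂) / sqrt((σ₁² + σ₂²)/2)` with sample (n−1)
standard deviations (population sd available via `ddof`); `d'` is
undefined (NaN, excluded from selective counts) when both variances are
zero. Significance: 1000 label shuffles preserving group sizes; the
observed `d'` must fall strictly beyond the empirical 2.5% tails
(tails shrink to 2.5%/m under Bonferroni, used for the passive condition's
six stimulus pairs). Ties break conservatively (strict inequality against
the quantile), and the reported p uses the (1+B)/(1+N) estimator. Under
the null ≈5% of neurons come out selective per session by construction.

Responsiveness is coded separately per trial type by comparing per-trial
event areas in the pre-stimulus window (trial start → opening, 1.2 s)
against the stimulus period (fully open → `R`, 0.9 s at default grace)
with a paired two-sided Wilcoxon signed-rank test at p < 0.05; direction
comes from the median paired difference, falling back to the mean when the
median is exactly zero (common with sparse event traces). Note the two
windows have unequal durations — areas, not rates, are compared, following
the stimulus-period definition. The response score sums +1 / −1 / 0
(activated / inhibited / none) over Go and NoGo.

## Reversal classification

Across a reversed, registered session pair: Go→Go = reward-selective,
NoGo→NoGo = no-reward-selective, Go→NoGo or NoGo→Go = mouse-selective
(stimulus-preserving under reversal), anything involving "none" = none.
Day 1 is always the earlier session. Population inference uses the 3×3
day-1 × day-2 preference table: chi-square test of independence without
continuity correction (computed directly as Σ(O−E)²/E over cells with
positive expected count, degrees of freedom from nonzero margins, so zero
margins are tolerated; a warning is emitted when expected counts drop
below 5), Haberman adjusted residuals
`(O − E)/sqrt(E(1 − row frac)(1 − col frac))`, and planned two-sided
normal comparisons on the four maintained/reversed cells at p < 0.0125
(Bonferroni over the planned family; simulated family-wise error under an
independent-label null stays ≤ 5%). Stability fractions follow day-1
selective neurons forward: stable = same significant preference on day 2,
reversed = opposite, chance = the overall day-2 prevalence of the
preference.

## Decoding

Per frame, an independent linear SVM (C = 1, the solver's conventional
default; configurable) is trained on per-neuron event-trace values with
features z-scored using training-fold statistics only (no leakage) and
evaluated leave-one-trial-out. Trial counts are balanced per label by
down-sampling to the minimum class count once per session (not per frame).
Four-way decoding trains one-vs-rest classifiers and predicts by
winner-takes-all on decision values, ties resolved to the lowest class
index (deterministic). Degenerate folds — a single training class, or no
feature with variance — predict the majority training label, ties broken
by the seeded generator. Cross-day decoding trains on all day-1 trials and
tests every day-2 trial over registration-linked neurons, and reports the
mean signed deviation of accuracy from chance; an optional per-frame
2.5%/97.5% band from label-shuffled decoders provides the chance envelope.

The SVM solver is libsvm via scikit-learn. The tight
LOO × frames × permutations loops call it through `sklearn.svm._libsvm`
(the identical solver behind `SVC`) to avoid ~1 ms/fit estimator overhead;
the unit suite asserts decision-value equality with `SVC` on random
problems.

Cluster-based permutation test: trial labels are shuffled (default 1000
permutations) and the accuracy time course recomputed; cluster-forming
thresholds are the pointwise 2.5th/97.5th percentiles of the null;
contiguous suprathreshold frames form clusters scored by summed deviation
from chance (the summed-exceedance statistic in the Maris–Oostenveld
style; the summed-exceedance form is the field's usual default); each
observed cluster's p is
`(1 + #{null max ≥ score})/(1 + N)` against the null maximum cluster score
over both directions, giving two-sided family-wise control. The
conservative `(1+B)/(1+N)` estimator keeps the realized type-I rate at or
slightly below nominal.

## Validation strategy and problem sizes

Because every neuron class is planted, each stage is validated by
recovery. The suite's end-to-end checks run at desk scale, chosen to keep
statistical power high while the full suite completes in minutes:
permutation-test calibration on 500 null neurons (100 + 100 trials each);
four-way chance calibration on a balanced ~224-trial noise session with 20
neurons over the stimulus-epoch frames; brute-force oracle equivalence on
100 random fixtures at 1e−12 relative tolerance; reversal-class recovery
on a 2-day reversed pair with 200 neurons (20 reward, 10 no-reward, 20
identity, 150 none) and 300 trials/day; stability discrimination with 64
neurons (32 identity) at planted stability 100% vs 0%, decoding every 4th
frame of the open window; and cluster-test calibration over 100 null
sessions with a 200-permutation inner loop.

## What the generator does and does not emulate

It reproduces the task's trial structure and schedule constraints,
acquisition-shaped behavior, GCaMP6f-like transient kinetics with drift
and noise, reward-category and identity tuning with both polarities,
contingency reversal, and parametric day-to-day drift. It does not model:
motion artifacts, neuropil contamination, or ROI segmentation errors
(upstream of this pipeline); spike-to-fluorescence nonlinearity and
indicator saturation; lick/reward-consumption motor artifacts (off by
default; a post-`R` artifact can be enabled for robustness testing);
correlated noise across neurons; or within-session non-stationarity other
than slow drift. Passing recovery tests therefore shows the analysis
chain is correct and calibrated under these statistics, not that it is
robust to every pathology of real imaging data.

## Known limitations

- Tonically very active neurons inflate the quiescent-epoch threshold
  (see above); their events, and hence their inhibition, can become
  undetectable. This is a property of the thresholding method itself.
- The pre-stimulus and stimulus windows of the responsiveness test have
  unequal durations, slightly biasing tonic neurons toward "inhibited".
- The drift model re-tunes neurons by permutation, so exact class
  proportions are preserved across days; real drift need not do this.
- Chi-square inference on sparse tables (expected counts < 5) is flagged
  but not replaced by an exact test.
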