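# Methods

## The behavioral model

A larva's routine-turn sequence on one trial is modeled as a two-state
Markov chain over directions {left = −1, right = +1}.  The chain has two
parameters:

- **p_same** — the probability that a turn repeats the direction of the
  previous turn.  This is the lock index L rescaled from its 0–100
  persistence scale: `p_same = (100 + L)/200`.  In the dark L = 62.8
  (p_same = 0.814); under baseline illumination L = 13.2 (p_same = 0.566).
- **π (bias_strength)** — the probability that the *first* turn of each
  trial goes to the larva's latent preferred side.  π = 0.5 is the unbiased
  null; the chain then reduces exactly to the null simulator used by the
  Monte-Carlo test (first turn a fair coin).

Bias is injected only through the first turn of each trial because the
persistence term already propagates it through the rest of the trial; this
is the minimal biased extension of the null chain.  A consequence worth
knowing: persistence dilutes the injected bias, so even π = 0.95 yields a
per-larva mean %rightward of only ≈ 64% at p_same = 0.814.  Effects on the
cohort mean Match Index are a few points per 0.2 of π, which is why the
parameter-recovery sweep (below) uses large cohorts.

### Metrics and exclusion rules

- **NTA** (net turn angle): signed sum of heading changes over the 30-s
  window; **absolute NTA**: sum of unsigned changes.  A trial is excluded
  when it holds less than 10 s of data.  The data span is estimated as
  (sample count) × (median inter-sample interval), which is robust to a
  dropout in the middle of the window where `t_max − t_min` is not.
- **Match Index**: fraction of valid follow-up trials (2–4) whose NTA sign
  matches trial 1.  Denominator convention: excluded trials are dropped
  from the denominator, not scored as mismatches; at least 2 valid
  follow-ups are required, else the MI is missing.  **Ties**: a zero NTA on
  trial 1 leaves the larva unclassified and without an MI; a zero NTA on a
  follow-up trial carries no direction and is likewise dropped from the
  denominator.  The second rule is forced by symmetry — scoring sign-less
  trials as mismatches drags the null-cohort mean MI visibly below 0.5
  (≈ 0.47 with Poisson-8 turn counts), breaking the calibration of the
  permutation test.  Ties are measure-zero on real trajectory data but
  common on small integer event counts.
- **%rightward**: per-trial percentage of +1 turns; the larva's statistic
  is the unweighted mean over its four trials.  Larvae with fewer than 3
  turns on any of the 4 required trials are excluded.  Classification:
  < 33% left-biased, > 66% right-biased.  The breeder-selection filter
  keeps larvae in the outer quartiles of mean %R (inclusive,
  linear-interpolation quantiles) whose four per-trial net directions are
  identical and nonzero.

### The Monte-Carlo bias test

10,000 cohorts (default) are simulated from the null chain with the same
larva count and the same per-larva per-trial turn counts as the data.
Thresholds are the tail/2 and 1 − tail/2 quantiles (default tail 10%) of
the pooled simulated per-larva %R — so by construction ~10% of unbiased
larvae fall outside them; with Poisson-8 counts and p_same = 0.814 the
thresholds land near 23% and 77%.  Larvae strictly outside the open
interval count as biased.  The p-value is the fraction of simulated
cohorts whose exceedance count reaches the observed one; zero exceedances
are reported as the bound p < 1/n_sims rather than 0.

### The Match Index permutation test

Under the null each larva matches trial 1 with probability 0.5 on each of
its k valid follow-ups, so its null MI is Binomial(k, 0.5)/k — sampled per
larva with its own k, which handles exclusion-depleted larvae exactly.
The statistic is the cohort mean; the default two-sided p-value counts
null means with |mean − 0.5| ≥ |observed − 0.5| (one-sided options
available).

## Calcium responder analysis

Traces are averaged across the (default 3) trials frame-wise, then
normalized: ΔF/F = (Fₜ − F₀)/F₀ with F₀ the mean raw intensity over the
first light epoch; S is the sd (ddof = 1) of ΔF/F over the same frames.
A per-trial classification mode is available (`average_trials=False`)
since applying the criterion before or after averaging is a genuinely open
choice; the averaged mode is the default and the one the tests certify.

Responder rule: ΔF/F > 3S on ≥ 3 successive frames; onset is the first
frame of the earliest qualifying run.  Onset in a dark epoch → OFF
responder; onset in a light epoch that follows a dark epoch → ON
responder; an excursion inside the initial baseline epoch is "none".
If S = 0 on a nonconstant trace (possible on noise-free synthetic input)
the rule stays defined with threshold 0 and the call is flagged
`degenerate_baseline`.

Timing: the peak is the maximum ΔF/F in the epoch initiated by the
stimulus transition; latency is onset − stimulus; time-to-half-max is
measured from the stimulus to the first post-peak crossing of peak/2, with
linear interpolation between the bracketing frames (at ~0.96 Hz sampling
the interpolation matters).  Cohort summaries report fractions over all
neurons, the OFF return-within-30-s fraction over OFF responders only, and
percentages rounded half-up to one decimal with raw counts retained.

## The synthetic generators

- **Turn cohorts**: preferred direction Bernoulli(0.5) per larva; turn
  counts per trial from Poisson(λ = 8) truncated from below at 3 (matching
  the ≥ 3-turn analysis filter; the field's 10-s dark trials typically hold
  a handful of routine turns, and λ is a sensitivity knob, not an
  estimate); event times uniform over the 10-s trial.  Defaults: 4 trials,
  p_same = 0.814.
- **Heading series**: Gaussian per-sample heading change (default sd
  12°/sample at 10 Hz — small frequent path corrections punctuated by
  turns; chosen so a +2°/sample drift is detectable in ≥ 99% of 30-s
  windows), with dropout intervals that emit no samples.
- **Calcium traces**: baseline 100 intensity units + Gaussian noise
  (sd 2 raw units ⇒ baseline ΔF/F noise ≈ 0.02, so the 3S threshold sits
  near 0.06 against a planted peak of 1.0 ΔF/F).  Response kernel: linear
  rise over 2 frames to the peak, then exponential decay with τ = 30 s.
  The closed form for the planted time-to-half-max,
  (rise − 1)/rate + τ·ln 2 ≈ 21.8 s, sits on the ~22 s scale observed for
  dark-responsive neurons, and is what the timing tests check against.
  The default epoch plan is one 60-s-light / 60-s-dark cycle at 0.96 Hz
  (115 frames).  ON responders need a dark→light transition, so planting
  them requires a plan with a trailing light epoch (the pipeline default
  uses light/dark/light); with the two-epoch default plan `frac_on` is 0.

  What the generator does *not* emulate: photobleaching and slow baseline
  drift, neuropil contamination, motion artifacts, correlated noise across
  neurons, and trial-to-trial response variability (the kernel is
  identical each trial).  Passing recovery tests therefore certify the
  classifier's logic and thresholds, not its robustness to those real-data
  nuisances.
- **Random-number policy**: one master seed; per-larva and per-neuron
  substreams spawned from a `SeedSequence`, so growing a cohort leaves
  already-generated individuals byte-identical.

## Calibration and problem sizes

- Type-I error: 500 unbiased replicates of a 39-larva cohort at
  p_same = 0.566 (the constant-illumination condition), with 1,000 null
  simulations per Monte-Carlo test and 2,000 permutation draws.  Cohort
  size matters here because exceedance counts are discrete: at 30 larvae
  the largest attainable rejection level below 0.05 is ≈ 0.026, while near
  39–40 it is ≈ 0.042 — a cohort that small would make the test look
  miscalibrated when it is merely conservative.  Measured rates: ≈ 0.044
  for both tests.  Uniformity of permutation p-values is checked as
  rejection-rate-tracks-α at α ∈ {0.05, 0.2, 0.5}, which is robust to the
  discreteness of the binomial null.
- Parameter recovery: π ∈ {0.6, 0.8, 1.0} at 1,000 larvae per cohort.
  Adjacent settings differ by only ~0.03 in expected mean MI against a
  per-larva MI sd of ~0.37, so ≥ 2σ separation of the sweep needs cohorts
  of this order; at 60 larvae the ordering would be noise.
- The null-tail check simulates 10,000 cohorts of 89 larvae (the dark
  condition's cohort size) in a few seconds via a vectorized
  cumulative-product formulation of the chain.

## Known limitations

- The MI denominator convention (dropping excluded trials) is one of two
  defensible readings; it is recorded in report metadata and configurable
  through `min_valid_followups`.
- Tail thresholds are always derived from the simulated distribution,
  never hard-coded, so printed threshold values vary slightly with the
  seed and the turn-count table.
- Effect sizes for ANOVA designs take sums of squares as inputs; the
  package does not fit mixed models.
- No analytic p-values are offered; everything is resampling-based by
  design, since turn-sequence dependence is the entire point of the null
  model.
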