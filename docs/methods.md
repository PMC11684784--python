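# Methods

`tonepredict` re-implements, as a tested pipeline over synthetic data, a
paradigm for measuring *anticipatory* (pre-stimulus) representations of
upcoming tones in multichannel neural recordings, and for contrasting their
strength between a tinnitus-like and a control-like group.  This note
documents the models, defaults and numerical choices, and what the synthetic
generator can and cannot show.

## Stimulus model

Four pure tones are presented at a constant 3 Hz rate (SOA = 333 ms).  Tone
order follows a first-order Markov chain whose transition matrix sets the
sequence's regularity:

* **random** — all transitions 1/4 (row entropy 2.0 bits);
* **ordered** — each tone is followed by one designated successor (tone
  *i* → *i*+1 mod 4) with probability 0.75 (row entropy 0.811 bits);
* **midminus / midplus** — the successor probability is interpolated linearly
  at 1/3 and 2/3 of the way between those endpoints (0.4167 and 0.5833),
  with the remainder split evenly over the other two tones.

The diagonal (self-repetition) probability is pinned at 0.25 in every
condition, so repetition effects cannot mimic a regularity effect.  The mid
matrices' exact interpolation is a design choice of this package: only the two
endpoint matrices are fully constrained by the design constants; linear
interpolation of successor mass is the simplest scheme that preserves the
pinned diagonal and a strictly monotone entropy gradient
(2.0 → 1.888 → 1.551 → 0.811 bits).

Two study presets are built in.  *study1*: carriers {200, 431, 928, 2000} Hz
(log-spaced over 3.3 octaves), four condition blocks of 1000 stimuli each,
10% of stimuli omitted uniformly at random (exactly round(0.1·n), giving
900 sounds + 100 omissions per block), epochs −1.0…+1.0 s.  *study2*:
carriers {440, 587, 782, 1043} Hz (1.3 octaves), random and ordered only,
1500 stimuli per condition arranged in two blocks of three 500-stimulus
segments (random/ordered/random and ordered/random/ordered), no omissions,
epochs −0.4…+0.5 s.  Block order within study1 and cross-segment chaining
within study2 blocks are not constrained by the design; blocks run in fixed
order random→midminus→midplus→ordered, and each segment starts its own chain
with a uniformly drawn first tone.

## Synthetic sensor data

Epochs are generated directly on the analysis grid (100 Hz, matching the
downsampled rate the decoding operates at); no continuous raw recording or
filtering chain is emulated.  Each of the K tones has a fixed unit-norm
spatial topography over `n_channels` (default 102, the magnetometer count of
a whole-head array) drawn as a spatially smooth Gaussian pattern and rejected
until all pairwise |cosine| < 0.8.  A tone's response is its topography times
a causal kernel with two Gaussian components: early (peak 100 ms,
σ = 25 ms, amplitude 1.0) and late (peak 450 ms, σ = 50 ms, amplitude 0.6).
Every tone overlapping the epoch window contributes — at a 333 ms SOA the
neighbours' responses bleed into each epoch by design, as in the real
paradigm.

The anticipatory effect is injected only on ordered-condition trials: the
topography of the *predicted* tone — the designated cyclic successor of the
preceding tone, i.e. the prediction follows the learned regularity, not the
actually presented tone — is added with gain `alpha_pre · a_late` under a
Gaussian bump centred at −380 ms (σ = 50 ms) in the pre-stimulus interval.
Group defaults follow the interpretation that the group difference is driven
by *deactivation* in controls: `alpha_pre = −0.3` (in units of the late
amplitude) for control-like subjects and `0.0` for tinnitus-like subjects.
Both signs and any magnitude are configurable.

Noise is stationary Gaussian, spatially correlated (squared-exponential
covariance mixed 50/50 with white noise), temporally white, with per-channel
standard deviation `a_early / snr`.  The default `snr = 2.5` was calibrated
once so that (i) a single subject's post-stimulus decoding peaks well above
chance at a few hundred trials (peak ≈ 0.55 at 100 ms with 400 trials per
condition) and (ii) the default group effect is recoverable from cohorts of
20 + 20 subjects at desk-scale trial counts; it was then frozen.  The
generator's defaults are calibration targets for exercising the pipeline,
not claims about effect sizes in real sensor data.

Per subject the generator also draws an audiogram (8 standard frequencies,
125–8000 Hz, both ears, shared distribution across groups so the groups are
hearing-matched by construction, with a mild high-frequency slope) and — for
tinnitus-like subjects only — a Mini-TQ distress score (clipped normal,
mean 11, sd 5, range 0–24).  `pta4` averages thresholds at 500/1000/2000/4000
Hz (ear-averaged), `pta_extended` adds 6000/8000 Hz, and the hearing-loss
flag is any threshold strictly above 30 dB HL.

### What the generator does *not* emulate

1/f and physiological noise, artifacts, head movement, sensor gain
differences, source geometry, latency jitter, and learning dynamics (the
anticipatory gain is constant from the first ordered trial).  The early and
late response components share one topography per tone, so the late-window
training specificity of the real effect is not reproduced — any post-stimulus
training time can read out the pre-activation.  Passing tests therefore
demonstrate the correctness and calibration of the *pipeline*, not the
existence or size of the effect in real recordings.

## Decoding

Tone identity is decoded per time point with multiclass LDA (scikit-learn,
`solver="lsqr"`), shrinkage-regularized with automatic Ledoit–Wolf shrinkage
by default — the design does not pin a particular regularization, and analytic
shrinkage is the standard stable choice at trials ≈ channels.  Classifiers are always trained on random-condition
trials; omission trials are excluded everywhere.

* **Within the random condition** evaluation uses stratified fivefold CV
  (stratification by tone with a fixed fold seed).  Temporal generalization
  applies each training-time classifier to every testing time of the held-out
  folds; the accuracy time course is the matrix diagonal by construction, and
  pre-stimulus testing of post-stimulus classifiers reuses the same held-out
  folds (no leakage).
* **Across conditions** (testing on ordered / mid conditions) classifiers are
  fit once per training time on all random trials — train/test sets are
  disjoint by condition, so no CV is needed.

The confusion tensor is accumulated from the diagonal (train time = test
time) held-out predictions.  The **bias score** per testing time is the mean
row-normalized confusion mass on predicted = true+1 minus that on
predicted = true+2, diagonals taken *cyclically* along the designated
transition direction by default (the transition structure wraps at K); a
strictly-upper-diagonal variant is available via `cyclic=False`.

## Prediction scores

Per-condition temporal-generalization matrices are collapsed to one score
matrix per subject: pointwise OLS slope of accuracy on the condition code
(four-condition mode; default coding 0,1,2,3 from random to ordered, the
coding is configurable and reported) or the ordered-minus-random difference
(two-condition mode; identical to the slope under {0,1} coding).  For
inference the matrix is averaged over the 470–570 ms training window and read
out on the −400–0 ms testing interval, optionally at a single named testing
time (−380 ms, nearest sample).  When a window exceeds the epoch — the
470–570 ms training window against study2 epochs that end at +500 ms — it is
clipped to the epoch with a warning; the epoch window is configurable so a
longer-epoch reading is also runnable.

## Statistics

* **Pointwise tests vs chance**: one-sample t per time point against 1/K,
  Bonferroni over time points; zero-variance points are reported
  non-significant with a warning.
* **Cluster-based permutation test** (1D time courses and 2D time-by-time
  grids): pointwise t (pooled-variance independent-samples, or one-sample
  with sign-flip permutations), thresholded at the parametric t quantile for
  `cluster_alpha = 0.05` respecting the tail; contiguous supra-threshold
  points (time adjacency in 1D, 4-neighborhood in 2D) form clusters scored by
  summed t; the null is the maximum cluster score over 1000 random
  relabelings; p = (b+1)/(m+1), which cannot be zero and is bounded below by
  1/(m+1).  `cluster_alpha` serves as both the cluster-forming and the
  cluster-level criterion (the convention of the standard nonparametric
  framework); both are configurable.  If fewer distinct relabelings exist
  than requested permutations the test refuses rather than recycling
  permutations.
* **JZS Bayes factors** (one- and two-sample): Cauchy prior on the
  standardized effect (default scale √2/2) represented as a normal scale
  mixture, marginal likelihood integrated over g by adaptive quadrature;
  integration failures raise with diagnostics.  Tests cross-check against an
  independent marginalization over effect size and against `pingouin`.
* **TOST equivalence**: two one-sided Welch tests against ±δ; δ defaults to
  0.5 pooled-sd units (the bounds are a package default, always reported
  alongside the decision) and can be given in raw units.
* **Welch t** and **Spearman** wrap scipy with explicit degenerate-input
  handling.
* **Logistic model**: tinnitus status on the windowed prediction score with
  an optional PTA covariate (standard or extended), ML fit via statsmodels;
  perfect separation raises rather than silently diverging; the odds ratio is
  reported per 1 sd of the score; the reversed linear model (score on group)
  is fitted alongside.
* **Trial-subsampling curve**: for each requested per-condition trial count,
  trials are redrawn balanced per carrier frequency (count/K each) in both the
  training and testing conditions (a class whose pool falls short of the
  per-class target contributes all of it; a count above the condition's total
  is skipped with a warning), decoding + scoring is rerun and the two-sample
  Bayes factor on the group difference recomputed.  The per-subject summary
  defaults to the score at −380 ms — the peak-difference readout the curve
  accompanies — because averaging over the whole −400–0 ms window dilutes a
  bump-shaped effect; the window mean is available as an option.
* No additional correction is applied across the several distinct analyses;
  each analysis corrects within itself (Bonferroni over time points, cluster
  control over the grid).

## Reproducibility and problem sizes

Every random step takes an explicit seed; master seeds are split into
per-stage and per-subject seeds with `numpy.random.SeedSequence`, so a run
configuration determines every output byte (`run_all` writes per-stage seeds,
durations and artifact hashes into `run_report.json`).

Tests and the acceptance script run at desk scale as the package's own
choice of problem size: sequence statistics use 10^5-tone chains; chance
calibration uses one 800-trial subject with shuffled labels; cluster-test
type-I calibration uses 400 null datasets of 10+10 subjects on 40-point
grids at 250 permutations; effect recovery uses cohorts of 20+20 subjects at
240 stimuli per condition with 10 replicate cohorts per arm (effect present /
absent).  The recovery power at these settings was measured at 1.0 over 20
development cohorts; the test asserts the ≥80% criterion.

## Known limitations

* The mid-entropy matrices and the Study-1 condition coding are
  underdetermined by the design constants; both are explicit, documented
  defaults.
* The bias score's "upper diagonals" are read cyclically by default; the
  non-cyclic reading is available but changes the score whenever mass sits on
  the wrap-around cells.
* The equivalence bounds and the logistic-model effect sizes observed on
  synthetic cohorts have no quantitative correspondence to real-data values;
  only signs, calibration rates and internal consistency are meaningful here.
* 2D (time-by-time) cluster tests default to two-sided inference and the 1D
  replication-window test to one-sided positive, mirroring the analysis
  structure the pipeline reproduces; both are configurable per call.
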