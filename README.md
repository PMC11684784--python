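# tonepredict

Do people with chronic tinnitus *anticipate* upcoming sounds more strongly
than people without?  One way to ask this with MEG: present four pure tones at
3 Hz in sequences whose regularity is controlled by Markov transition matrices
(from fully random to strongly ordered, with self-repetitions pinned at 25% in
every condition), train a multiclass linear discriminant classifier on each
post-stimulus time point of the *random* sequences, and test it — across time
and across conditions — on the *pre-stimulus* interval.  Above-chance decoding
of a tone's identity before its onset is evidence of stimulus-specific
anticipation; its modulation by sequence regularity, summarized per subject as
a **neural prediction score**, can then be compared between groups.

`tonepredict` implements that pipeline end to end for researchers who want to
study, extend or power such designs without access to recordings:

* **sequences** — entropy-graded transition matrices (row entropy 2.0 →
  0.81 bits across random / midminus / midplus / ordered), tone-sequence
  sampling, omissions, and the block structures of a four-condition and a
  two-condition study preset;
* **simulate** — synthetic epoched sensor data (trials × 102 channels ×
  time at 100 Hz): per-tone topographies, early (~100 ms) and late (~450 ms)
  response components, spatially correlated noise, and a controllable
  group-dependent pre-stimulus (de)activation of the *predicted* tone's late
  pattern in ordered sequences; plus audiograms (PTA-4) and Mini-TQ distress
  scores;
* **decoding** — time-resolved shrinkage-LDA with stratified fivefold CV,
  temporal generalization, cross-condition decoding, confusion tensors and
  the confusion-bias score;
* **scores** — prediction-score matrices: pointwise β-slopes of accuracy over
  entropy conditions, or ordered−random differences; windowing (train
  470–570 ms, test −400–0 ms, readout at −380 ms);
* **stats** — pointwise t-tests vs 25% chance with Bonferroni correction,
  cluster-based permutation t-tests (1D and 2D, maxsum, 1000 permutations),
  Spearman correlations, JZS Bayes factors, TOST equivalence, Welch tests,
  logistic regression of tinnitus status on the prediction score with a
  hearing covariate, and the trial-subsampling Bayes-factor curve.

For the score at each training time *t* and testing time *t′*, with per-
condition accuracies *a_c(t, t′)* and condition codes *x_c*:

    beta(t, t')  = argmin_b sum_c [ a_c(t,t') - a - b x_c ]^2      (4 conditions)
    score(t, t') = a_ordered(t,t') - a_random(t,t')                (2 conditions)

and the group contrast on the windowed score time course uses the
nonparametric max-cluster-sum permutation test with the (b+1)/(m+1) p
estimator.

See `docs/methods.md` for the full model, defaults, and limitations.  The
synthetic generator is a calibration target for the pipeline, not a model of
real effect sizes.

## Worked example

`analysis/` contains numbered drivers.  `03_group_pipeline.py` simulates a
matched cohort (20 tinnitus-like + 20 control-like subjects, 240 stimuli per
condition, controls carrying a pre-stimulus deactivation of the predicted
tone's pattern at −0.3 of the late-response amplitude) and runs the full
analysis:

```text
$ python analysis/03_group_pipeline.py
pre-stimulus group contrast (tinnitus - control, one-sided):
  cluster t_sum=36.75  p=0.001  extent -400..-300 ms
  cluster t_sum=2.06  p=0.567  extent -70..-70 ms
  ...
group BF10 on windowed scores: 42.04
control analysis on random-condition (post-stimulus) decoding:
  Welch: t=-0.67, p=0.510
logistic model: score b=190.37 (p=0.007), OR per 1 sd = 4.93
distress correlation: rho=-0.25, p=0.283
```

Reading this output: the injected anticipatory group difference is recovered
as a significant pre-stimulus cluster spanning −400…−300 ms around the true
effect latency (−380 ms), with a Bayes factor strongly supporting a group
difference; general (post-stimulus, random-condition) tone processing does not
differ between groups, so the effect is specific to the regularity
manipulation; the prediction score predicts group membership even though the
two groups' audiograms come from one distribution; and the effect is unrelated
to tinnitus distress, which carries no signal in the generator.

The other drivers audit the stimulus design (`01`, e.g. a 100 000-tone ordered
chain shows 25.03% self-repetitions and 74.97% designated-successor
transitions), single-subject decoding (`02`: peak accuracy 0.55 at 100 ms with
400 trials; 25.3% under label permutation), and the dependence of the group
Bayes factor on trial count (`04`: BF10 rises 0.42 → 1.09 → 3.34 across
120 → 240 → 400 trials per condition).

The same stages are scriptable via the CLI:

```bash
tonepredict sequences --design study1 --seed 1 --out results/seq
tonepredict run-all --seed 1 --out results/run --n-per-group 10
```

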