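#!/usr/bin/env python
"""Trial-subsampling Bayes-factor curve on a synthetic cohort.

How many trials does the group effect need?  Simulates one cohort with the
default anticipatory effect, then redraws balanced trial subsets of increasing
size per carrier frequency, reruns decoding + scoring, and recomputes the
group-difference Bayes factor at each count.  Writes results/subsampling/.
"""

import json
from pathlib import Path

from tonepredict.pipeline import RunConfig, _scaled_design
from tonepredict.simulate import ResponseKernel, simulate_cohort
from tonepredict.stats import subsample_bf_curve

OUT = Path("results/subsampling")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

cfg = RunConfig(design="study2", n_per_group=15, n_trials_per_condition=480)
design = _scaled_design(cfg)
group_params = {
    "tinnitus": {"alpha_pre": cfg.alpha_pre_tinnitus, "snr": cfg.snr},
    "control": {"alpha_pre": cfg.alpha_pre_control, "snr": cfg.snr},
}
cohort = simulate_cohort(design, cfg.n_per_group, group_params, seed=SEED,
                         kernel=ResponseKernel())

curve = subsample_bf_curve(cohort, trial_counts=(120, 240, 400), seed=SEED)
(OUT / "bf_curve.json").write_text(json.dumps(curve, indent=1))

print("group-difference BF10 by per-condition trial count:")
for count, bf in sorted(curve.items()):
    marker = "  <- supportive (BF > 3)" if bf > 3 else ""
    print(f"  {count:5d} trials: BF10 = {bf:8.2f}{marker}")
print(f"outputs in {OUT}")
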