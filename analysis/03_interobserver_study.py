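#!/usr/bin/env python
"""The simulated two-observer cohort study.

Runs the full pipeline on the default 20-subject cohort (5 HV, 5 HF, 10 Tx;
0.5 mm contour jitter between observers) and prints the interobserver
reproducibility grid, the within-ROI spread report and the pairwise group
differences.  Findings mirror the qualitative pattern of the reference
cohort: whole-kidney and cortex ROI means are highly reproducible
(ICC near 1, CoV well under 5%), the small user-placed representative-
cortex disc is the least reproducible perfusion ROI, and the whole-kidney
mean is drawn from a far wider within-ROI spread than any cortex ROI.

Writes results/cohort/{measurements,repro,group_differences,sd_fractions,
ground_truth}.csv plus config and seed manifest.
"""

import warnings

from renalquant import StudyConfig
from renalquant.pipeline import run_pipeline

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    bundle = run_pipeline(StudyConfig(seed=0), out_dir="results/cohort")

print("interobserver reproducibility (jitter 0.5 mm):")
print(bundle["repro"][["sequence", "roi", "mean", "icc", "cov_percent",
                       "bias", "n_subjects"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))

print("\nwithin-ROI SD as % of mean (pooled over subjects and observers):")
print(bundle["sd_fractions"][["sequence", "roi", "roi_sd_pct_of_mean"]]
      .to_string(index=False))

gd = bundle["group_differences"]
t1_cx = gd[(gd.sequence == "T1") & (gd.roi == "Cx")]
print("\npairwise cortical-T1 group differences (ms):")
print(t1_cx[["group_a", "group_b", "mean_difference", "p"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))

rep = bundle["repro"].set_index(["sequence", "roi"])
for seq in ("T1", "pCASL", "ADC"):
    wk = rep.loc[(seq, "WK"), "cov_percent"]
    rc = rep.loc[(seq, "repCx"), "cov_percent"]
    print(f"\n{seq}: CoV whole kidney {wk:.2f}% vs representative cortex "
          f"{rc:.2f}% -> small ROIs are more placement-sensitive")
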