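#!/usr/bin/env python
"""Every-slice vs alternate-slice kidney volumetry across 20 phantoms.

For each phantom the whole-kidney contours are traced on every slice, the
volume computed with both protocols, and the pair compared (paired t-test,
Bland–Altman).  Finding: contouring alternate slices systematically
underestimates the every-slice volume by a small amount — the cross-
sectional area profile of an ellipsoid-like kidney is dome-shaped, so the
interpolated chords sit under the curve.

Writes results/volumetry_protocols.csv (per-subject volumes) and
scratch/volumetry_bland_altman.png.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from renalquant import make_kidney_labelmap
from renalquant.phantom import kidney_contours
from renalquant.reproducibility import (RaterMatrix, bland_altman,
                                        bland_altman_plot, paired_ttest)
from renalquant.volumetry import volume_alternate_slice, volume_every_slice

N_SUBJECTS = 20
rng = np.random.default_rng(2)

rows = []
for i in range(N_SUBJECTS):
    target = float(np.clip(rng.normal(195.8, 56.8), 80, 350))
    lm = make_kidney_labelmap((26, 46, 46), (4.0, 2.5, 2.5),
                              seed=int(rng.integers(2 ** 31)),
                              target_volume_ml=target)
    wk = kidney_contours(lm)
    every = volume_every_slice(wk)
    slices = wk.slices()
    keep = set(slices[::2]) | {slices[0], slices[-1]}
    alt = replace(wk, contours=[c for c in wk.contours
                                if c.slice_index in keep])
    rows.append({
        "subject": f"S{i:03d}",
        "voxel_volume_ml": lm.kidney_mask().sum() * lm.voxel_volume_ml(),
        "every_ml": every,
        "alternate_ml": volume_alternate_slice(alt),
    })

table = pd.DataFrame(rows)
table.to_csv("results/volumetry_protocols.csv", index=False,
             float_format="%.6g")

diff = table.every_ml - table.alternate_ml
t, p = paired_ttest(table.every_ml, table.alternate_ml)
m = RaterMatrix(values=table[["every_ml", "alternate_ml"]].to_numpy(),
                rater_ids=("every", "alternate"), units="ml")
ba = bland_altman(m)
Path("scratch").mkdir(exist_ok=True)
bland_altman_plot(ba, "scratch/volumetry_bland_altman.png",
                  title="every vs alternate slice", units="ml")

print(table.describe().loc[["mean", "std"]].to_string())
print(f"\nmean every-minus-alternate difference: {diff.mean():.2f} ml "
      f"(paired t = {t:.2f}, p = {p:.2g})")
print(f"Bland–Altman bias {ba.bias:.2f} ml, "
      f"LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}] ml")
assert (diff >= 0).all(), "alternate-slice protocol should not overestimate"
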