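# renalquant

Multi-parametric renal MRI produces quantitative maps — longitudinal
relaxation time T1 (MOLLI), apparent diffusion coefficient (ADC) and tissue
perfusion (pCASL) — whose reported values depend heavily on *where* the
reader draws the region of interest: whole kidney, whole cortex, a small
user-placed disc of "representative" cortex, polar cortex or medulla.
`renalquant` implements the full analysis chain used to study that
dependence, and pairs it with a synthetic kidney phantom so every stage can
be validated against known ground truth without patient data:

- **Map computation** (`renalquant.qmap`)
  - T1 from signed inversion-recovery series: per-voxel fit of
    S(TI) = A − B·exp(−TI/T1\*) with Look-Locker correction
    T1 = T1\*·(B/A − 1), at the 14-TI schedule 180…5680 ms;
  - ADC from the mono-exponential fit S(b) = S₀·exp(−b·ADC) across ten
    b-values (0–1000 s/mm²);
  - perfusion f (ml/100 g/min) by exact inversion of the single-compartment
    pCASL model
    ΔM = f·(2M₀/λ)·T1′·α·exp(−Δt/T1ᵦ)·exp(−(t−τ−Δt)/T1′)·(1−exp(−τ/T1′)),
    with t = 3000 ms, τ = 1500 ms, Δt = 750 ms, α = 0.98, λ = 0.9 ml/g,
    T1ᵦ = T1′ = 1250 ms by default.
- **Volumetry** (`renalquant.volumetry`) — kidney volume from per-slice
  polygon contours, with both the *every-slice* and the *alternate-slice*
  protocol (linear interpolation of cross-sectional area on non-contoured
  slices).
- **ROI statistics** (`renalquant.roistats`) — the six-region taxonomy
  (WK, Cx, rep-Cx, sup-Cx, inf-Cx, Med), polygon rasterisation, within-ROI
  mean/SD summaries, cortex:medulla ratios and SD-as-fraction-of-mean
  reports.
- **Reproducibility statistics** (`renalquant.reproducibility`) —
  ICC(2,k) (two-way random effects, average measures, from the ANOVA mean
  squares), interobserver CoV, Bland–Altman bias and limits of agreement,
  plus paired/two-sample t-tests, Pearson correlation and one-way ANOVA.
- **Synthetic phantom** (`renalquant.phantom`) — an ellipsoidal kidney with
  cortex shell, medullary pyramids and pelvis, simulated acquisitions with
  the exact forward models above, and simulated observers that displace
  contour vertices along the boundary normal (bias + Gaussian jitter).
- **Pipeline** (`renalquant.pipeline`) — a seeded 20-subject two-observer
  cohort study producing tidy CSV tables end to end.

## Worked example

```python
import numpy as np
from renalquant import (TissueParams, make_kidney_labelmap, fit_t1_map,
                        simulate_molli_series, forward_asl_signal)

lm = make_kidney_labelmap((12, 64, 64), (4.0, 1.5, 1.5), seed=7)
t1 = fit_t1_map(simulate_molli_series(lm, TissueParams(), noise_sd=0))
print(np.nanmean(t1.values[lm.labels == 1]))   # 1630.2  (cortical T1, ms)
print(np.nanmean(t1.values[lm.labels == 2]))   # 1975.8  (medullary T1, ms)
print(forward_asl_signal(200.0, 1.0))          # 0.019099 (ASL dM per unit M0)
```

The cortical and medullary T1 printed above are exactly the phantom's
ground-truth values — the noiseless fit recovers them to machine precision —
and the last line evaluates the pCASL forward model at f = 200 ml/100 g/min
with the default constants.

The numbered scripts under `analysis/` run the study-level analyses and
write their tables to `results/`:

```bash
python analysis/01_phantom_roundtrip.py      # map validation vs ground truth
python analysis/02_volumetry_protocols.py    # every vs alternate slices
python analysis/03_interobserver_study.py    # 20-subject two-observer cohort
python analysis/04_reference_table_checks.py # reference-table arithmetic
```

For example, `02_volumetry_protocols.py` reports a mean every-minus-
alternate volume difference of **1.54 ml** (paired t = 31.3) over 20
phantoms: interpolating alternate slices slightly underestimates a
dome-shaped area profile.

A thin CLI mirrors the library (`renalquant phantom | fit-t1 | fit-adc |
fit-asl | volume | repro | run`); images travel as NIfTI volumes with JSON
sidecars and contours as a versioned JSON schema.

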