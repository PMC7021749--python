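# Methods

## Signal models

**Inversion recovery (T1).** Signed (phase-sensitive) voxel signal is
modelled as S(TI) = A − B·exp(−TI/T1\*), fitted per voxel by bounded
nonlinear least squares (A, B, T1\* > 0; SciPy trust-region reflective,
ftol = xtol = 1e-12, at most 2000 evaluations), followed by the Look-Locker
correction T1 = T1\*·(B/A − 1).  This three-parameter model is the standard
description of a Look-Locker-style readout; scanner implementations fit
their maps inside vendor reconstruction software, so recovered values on
real data need not match any particular vendor pipeline — here the phantom
generates data from exactly this model, which is what makes the round-trip
test meaningful.  Initialisation: A from the longest-TI sample, B from
A − S(TI₁), T1\* from the interpolated zero crossing (the null point of
A − B·e^(−TI/T1\*) sits at TI = T1\*·ln(B/A)); a fallback of 1000 ms is used
when no crossing exists.  Voxels that fail to converge (including all-zero
series) are flagged NaN with the residual norm kept as a per-voxel quality
value, never raised.

The phantom's inversion-efficiency parameter β (B = 2βM₀) defaults to 1, so
the apparent T1\* equals the true T1 and the ground truth maps directly onto
the corrected estimate; it is configurable (β > 0.5) for robustness
experiments.  Noise is Gaussian on the signed signal.  Magnitude (Rician)
data are out of scope: the simulator emulates polarity-preserved
reconstruction throughout.

**Diffusion (ADC).** S(b) = S₀·exp(−b·ADC), fitted per voxel with S₀ > 0
and 0 ≤ ADC ≤ 0.1 mm²/s, initialised from the log-linear regression of the
positive samples.  A b = 0 frame is required (anchors S₀).  ADC is carried
in mm²/s inside maps; the conventional 10⁻⁶ mm²/s tabulation is applied
only at the reporting layer.  Fits that land on the ADC = 0 bound (constant
signal) are counted in the map's QC info.  Estimates below 1e-10 mm²/s are
snapped to the bound: the trust-region optimiser stops at interior points a
few ulp from an active bound, and 1e-10 mm²/s is twelve orders of magnitude
below tissue diffusivity.

**Perfusion (pCASL).** The single-compartment model
ΔM = f·(2M₀/λ)·T1′·α·e^(−Δt/T1ᵦ)·e^(−(t−τ−Δt)/T1′)·(1−e^(−τ/T1′)) is linear
in f and M₀, so the map is its exact algebraic inverse applied to
ΔM = control − label.  Perfusion is carried in ml/100 g/min (the
conversion to the model's internal ml/g/ms divides by 100·60000).  The
partition coefficient is λ = 0.9 ml/g — the conventional whole-kidney
value; quoting it "per 100 g" would shift computed perfusion by two orders
of magnitude out of the physiological range, so the per-gram reading is the
only self-consistent one.  Negative map values (noise can produce them) are
preserved, not clipped; their fraction inside the mask is reported as QC.
Under Gaussian image noise the inverse is unbiased by linearity, and the
negative fraction equals the Gaussian tail Φ(−ΔM/(√2σ)) — both are tested.
Constants default to t = 3000 ms, τ = 1500 ms, Δt = 750 ms, α = 0.98,
T1ᵦ = T1′ = 1250 ms and are validated at construction
(t ≥ τ + Δt, 0 < α ≤ 1).  A single label/control/M0 triple is analysed;
multi-repeat averaging belongs upstream of this package.

## Phantom

The kidney is an ellipsoid on a coronal (slice, row, col) grid: cortex is
the shell (normalised radius² in (0.55, 1]), medulla the core partitioned
into five angular wedges (cortical columns between them), and a small
central region (radius² ≤ 0.10) the pelvis.  Semi-axes leave at least one
kidney-free slice at each stack end and ~15% in-plane margin; a seed
jitters axes and wedge phase so subjects differ, and an optional target
volume rescales the axes.  No claim of anatomical realism is made beyond
the cortex-shell / medulla-core / pelvis topology — no respiratory motion,
coil profiles, partial-volume mixing at boundaries (labels are crisp), or
pulse-sequence physics.  Consequently the phantom validates *analysis*
behaviour (fitting, geometry, statistics), not acquisition robustness:
passing tests say nothing about motion sensitivity or vendor fitting on
real scans.

Compartment defaults follow the reference cohort's whole-cohort means
(cortical T1 1630.2 ms vs medullary 1975.8 ms; cortical perfusion
221.0 vs medullary 95.8 ml/100 g/min; ADC ≈ 1.68·10⁻³ mm²/s; M₀ = 1000
arbitrary units).  The pelvis is fluid-like (T1 2800 ms, ADC
2.8·10⁻³ mm²/s, perfusion 15 ml/100 g/min) — values chosen once as
physiologically plausible, since the reference tables exclude the pelvis.

**Simulated observers.** A reader is modelled as a displacement of every
contour vertex along the local outward normal by bias + N(0, jitter), with
self-intersecting results repaired through polygon buffering (largest valid
part kept).  Hole contours move oppositely so a positive bias always means
over-contouring.  Zero jitter and zero bias return the input unchanged, and
in the pipeline the two observers are then identical readers by
construction (same contours and same representative-cortex placement).  The
default jitter of 0.5 mm is a package choice — no contour-level
variability magnitude is published for human readers in this setting; it
was picked once as a plausible sub-pixel tracing error and produces
whole-kidney volume differences well under 5% between observers.

## Volumetry

Volume = Σ (net slice area × dz) / 1000, with holes subtracted from outer
contours, computed from shoelace polygon areas in continuous mm
coordinates.  The alternate-slice protocol interpolates the scalar
cross-sectional *area* linearly on non-contoured slices — not a morphed
shape — which makes it provably identical to the every-slice protocol for
area profiles affine in slice index and a strict underestimate for concave
(dome-shaped) profiles.  Protocol violations are hard errors: a missing
intermediate slice (every-slice), a gap of more than one slice or an
uncontoured end slice (alternate-slice).  Slice gap defaults to zero; a
configured gap would simply enter through dz.

## ROI taxonomy and statistics

On a single analysis slice (default: maximal kidney area, mirroring
single-slice reading practice): WK = cortex + medulla with the pelvis
excluded (the exclusion matches the volumetry rule and is applied uniformly
to all sequences); Cx = cortex; Med = the largest connected medullary
component; sup-Cx / inf-Cx = cortex within the top/bottom third of the
kidney's in-slice bounding box (no standard geometric rule exists for
"pole", so thirds are the package's definition); rep-Cx = a disc (default
radius 4 mm) placed uniformly at random among all positions whose distance
transform keeps the disc fully inside cortex, deterministically per seed.
Rasterisation includes a voxel iff its centre lies inside the polygon
(even-odd rule).

Within-ROI SD uses the population (n) divisor by default, mirroring common
imaging-software ROI statistics, with the sample (n−1) divisor available;
the choice is configuration, not hard-coded.  The SD-fraction report
averages within-ROI SDs across subjects and divides by the average of the
subject means, in percent to 1 dp.

## Reproducibility statistics

ICC(2,k) follows the Shrout–Fleiss two-way random-effects, average-measures
definition, (MSR − MSE)/(MSR + (MSC − MSE)/n), computed from an explicit
two-way ANOVA decomposition whose mean squares are retained in the result
for audit; negative estimates are reported as computed.  Interobserver CoV
is the per-subject SD (n−1 divisor) over the per-subject mean, averaged
across subjects (×100); RMS pooling is available because the
per-subject-vs-pooled convention is genuinely ambiguous in the field — with
two raters the per-subject SD is |difference|/√2, so the two conventions
differ and published CoV values cannot be recomputed exactly without the
raw data.  Bland–Altman uses bias ± 1.96·SD(differences, n−1), direction
fixed as observer A − observer B.  Classical tests (paired/two-sample t,
Pearson, one-way ANOVA) delegate to SciPy with explicit degeneracy errors;
group comparisons use Student's (equal-variance) t-tests.

## Cohort simulation

The default study is 20 subjects — 5 healthy volunteers, 5 heart-failure,
10 transplant, i.e. the reference cohort's 10/10/20 composition halved to
desk scale — with per-subject tissue parameters and kidney volumes drawn
from the reference group mean/SD tables (heart-failure ADC falls back to
the whole-cohort distribution because the reference cohort acquired no DWI
in that group, and the pipeline likewise simulates DWI only for healthy
volunteers and transplants).  Image noise defaults: SD 10 (MOLLI and DWI)
and 5 (ASL label/control) on M₀ ≈ 1000, i.e. roughly 1%/0.5% of the
proton-density signal — chosen once as moderate, realistic SNR.  Maps are
fitted on the analysis slice only, masked to renal tissue.  The default
phantom grid is 26×46×46 at 4×2.5×2.5 mm.  All randomness flows from the
single config seed through per-subject `SeedSequence` spawns; a seed
manifest is written with every run and CSV outputs are stable-ordered.

Because both observers read the *same* noisy map and differ only in
contours and disc placement, whole-kidney CoV comes out far smaller than in
human studies (boundary voxels are a tiny fraction of a big ROI), while the
small representative-cortex disc — nearly disjoint between observers —
shows much larger CoV.  The simulation therefore reproduces the *ordering*
of ROI reproducibility and the within-ROI spread pattern (whole-kidney SD
fraction ≫ cortical), not the absolute CoV/ICC magnitudes of human readers.

## Numerical and degenerate-input conventions

Distinct voxel time-courses are fitted once and broadcast (piecewise-
constant phantoms collapse to a handful of fits).  Mask/grid mismatches,
non-monotone TI lists, missing b = 0, invalid ASL constants, empty ROIs,
zero medullary means, zero-variance ICC matrices and subject mismatches
between observer tables are all hard errors with named offenders; per-voxel
fit failures are flagged, not raised.  Contour tracing works at the
half-voxel level (marching squares at level 0.5) with rings below half a
voxel area dropped and hole parity decided by point-in-polygon containment
depth probed at a ring vertex.

## Known limitations

Single kidney per subject; crisp compartment boundaries (no partial
volume); Gaussian (not Rician) noise; no motion or registration step —
inputs are assumed aligned; fixed T1 in the perfusion model rather than a
measured map; no automated segmentation.  Absolute reproducibility indices
from the simulation are optimistic relative to human interobserver data for
the reasons above.
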