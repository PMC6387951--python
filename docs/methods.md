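# Methods

## Asymmetry statistics

Both statistics compare the voxel-value distribution of one scalar
microstructural parameter between the contralesional (C) and
ipsilesional (I) instances of a region, canonically the PLIC.

**Mean difference.** `delta_mean = mean(C) − mean(I)`. It is
antisymmetric and shift-equivariant; its sign depends on the direction
of the pathological change (positive for parameters that fall
ipsilesionally, such as FA; negative for ODI, which rises).

**Half Kullback–Leibler divergence.** The two samples are binned on a
*shared* set of `n_bins` (default 10) equal-width edges spanning the
pooled min–max — a divergence is only meaningful on a common partition,
and pooled per-subject edges are the least committal choice. Bins are
half-open `[e_i, e_{i+1})` with the last bin closed (the numpy
convention); this matters because counts feed the statistic. Bin
probabilities are estimated with James–Stein shrinkage toward the
uniform target:

    theta_k = counts_k / N
    lambda* = (1 − Σ theta²) / ((N−1) · Σ (1/B − theta_k)²),  clipped to [0, 1]
    p_k = lambda*/B + (1 − lambda*) · theta_k

with a zero denominator (empirical already uniform) returning the
uniform. The statistic is

    delta_kld = ½ Σ p_C(k) · ln(p_C(k) / p_I(k))

in nats. The ½ prefactor and the single directional sum are implemented
as such; because the prefactor could equally indicate a symmetrized
two-term form, `symmetrized=True` computes ½[D(C‖I) + D(I‖C)]. The
default stays directional. Zero-probability policy: `0·ln(0/q) := 0`;
`p > 0` against `q = 0` yields `+inf` (the statistic's range is
(0, ∞)); an optional `eps_floor` (e.g. 1e-10, renormalized) makes it
finite, off by default. With shrinkage active (λ* > 0) all estimated
probabilities are strictly positive, so infinities only arise when a
sample concentrates entirely in some bins and λ* = 0. A zero pooled
range collapses to one degenerate bin (flagged) with divergence 0. The
downstream predictor is the natural log of `delta_kld`, undefined
(NaN, reported missing) when the divergence is 0.

## Combination validation

With n = 9 subjects, all C(9, 3) = 84 ways of holding out 3 subjects
are enumerated in lexicographic order of the test-index triple. Per
split: OLS fit on the 6 training points (slope, intercept, training
r²), then NRMSE of that line on the 3 held-out points. NRMSE divides
the RMS error by the *range of the observed outcome over the full
cohort* — the definition was an open choice; the range normalizer is
applied identically to per-split and final errors and yields magnitudes
of roughly 0.05–0.2 on FM-UE scales. The "best line" is the training
line whose test NRMSE is nearest (absolute distance) the mean test
NRMSE, ties to the earliest split; its NRMSE over all 9 points is the
final error. The optimism adjustment subtracts the mean *signed* excess
of training r² over the full-data r²:

    r2_adjusted = r2_full − mean_i(r2_train_i − r2_full)

Signed differences are the literal reading; with the usual
r²_train ≥ r²_full the adjustment shrinks r², which is what "optimism"
means. r² is never computed on 3-point test sets (unstable); test sets
are scored by NRMSE only. No randomness enters anywhere: repeated runs
are byte-identical. Subjects missing either variable are dropped with a
warning; fewer than five complete subjects is an error.

## Group comparisons

Per region × parameter: (1) paired two-tailed t-test of control left vs
right hemispheres, (2) paired test of stroke ipsilesional vs
contralesional, (3) Welch (heteroscedastic) two-sample test of stroke
ipsilesional means against a per-control reference. The control
reference defaults to the mean of a control's two hemispheres — one
number per control, avoiding double counting — with left-only /
right-only modes available. Welch degrees of freedom stay fractional in
computation. Holm's step-down adjustment is applied within a family
defined as all parameters sharing one region and one test kind; because
reasonable analyses differ on family choice, raw and adjusted p-values
are always reported side by side. t-tail probabilities come from the
Student-t survival function (regularized incomplete beta).

## Lesion metrics

Lesion volume is voxel count × voxel volume in mL. Lesion load is
100 × |mask ∩ region| / |region| per label; the whole-CST load uses the
union of the three ipsilesional CST labels (one defensible reading of
an otherwise undefined aggregate; a mean of per-region loads is the
alternative). All mask operations are voxel-index based on a shared
grid — no resampling; affine mismatch is an error. Correlations report
signed Pearson r alongside r², with the two-tailed p from
t = r·√((n−2)/(1−r²)).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not images: 9 stroke + 9 control subjects, three CST regions (cerebral
peduncle, PLIC, corona radiata) per hemisphere, 500 voxels per ROI by
default (the disk writer uses the label-box voxel count instead so maps
round-trip exactly), voxel dimensions 1.9 × 1.9 × 2.1 mm.

Per-ROI distributions: bounded indices (ODI, FA, GFA, RDI) are normals
truncated to [0, 1]; diffusivities (MD, AD, RD, in µm²/ms) are
moment-matched log-normals. In-ROI distributions of these parameters
are not published for this design, so the defaults are plausible
white-matter values chosen once — ODI 0.25 ± 0.05, FA 0.60 ± 0.08,
GFA 0.55 ± 0.08, RDI 0.45 ± 0.07, MD 0.75 ± 0.10, AD 1.20 ± 0.15,
RD 0.55 ± 0.10 — they are knobs, not claims.

Stroke subject j draws a severity δ_j ~ U[0, δ_max] (default
δ_max = 0.12, an ODI-scale shift); the ipsilesional sample of every
parameter is drawn from the contralesional distribution with its mean
shifted by `shift_sign · effect_scale · δ_j` (ODI, RDI, MD, RD up; FA,
GFA, AD down — the directions the analysis is designed to detect).
Controls draw both hemispheres from the same distribution; their left
hemisphere occupies the "ipsilesional" slot by convention so all code
paths run uniformly on both groups.

Outcomes: `fm_ue_tp2 = clamp(round(60 − 450·δ_j + ε), 0, 66)` with
ε ~ N(0, 6²) by default, giving follow-up scores spanning roughly 6–60
— the realistic FM-UE range for a moderately impaired cohort; baseline
uses intercept 45 with SD 8, clamped to the ≤ 50 inclusion criterion
(with a warning when the model would exceed it). `noise_sd_for_r2`
computes the noise SD that makes the generating severity–outcome
squared correlation equal a chosen r² (signal variance
(slope·δ_max)²/12 for the uniform severity).

Label volumes are six disjoint axis-aligned boxes (default 6³ voxels in
a 24³ grid), mirror-symmetric about the midsagittal plane. Lesion masks
cover exactly ⌊fraction × |region|⌋ voxels of a target label (first in
lexicographic order) plus an optional dilated halo restricted to
non-target voxels, so overlap counts are exact by construction. One
label grid is shared by all subjects (registration is out of scope).

What the generator does **not** emulate: spatial voxel correlation,
partial-volume and edge effects, registration error, region-dependent
parameter means, lesion-induced signal dropout inside ROIs, and any
relation between lesion location and the asymmetry shift. Passing tests
therefore demonstrate the correctness and calibration of the
*statistics*, not expected effect sizes on real scans.

## Numerical and design choices

- Natural logarithm throughout (divergence and its log transform).
- Seeded `numpy.random.Generator` everywhere; identical configs
  reproduce bit-for-bit. Cohorts are generated stroke-first, so
  changing the number of controls leaves stroke draws untouched.
- OLS via `numpy.polyfit`; t-tests via `scipy.stats` (paired t for
  identical inputs is defined as t = 0, p = 1); Holm via
  `statsmodels`; Pearson via `scipy.stats.pearsonr`. Each is
  cross-checked in the test suite against an independently coded
  textbook formula.
- Degenerate inputs: constant predictor is an error; constant outcome
  defines r² = 0 with a warning; zero-variance paired differences are
  an error unless the vectors are identical.
- Simulation scales: recovery checks use 100 seeded cohorts and the
  type-I calibration 200, with one or two parameters per cohort —
  enough for the binomial bounds asserted while keeping the default
  suite fast.

## Known limitations

- The KLD estimator inherits the bin-placement sensitivity of any
  histogram divergence; per-subject pooled-range edges (the default)
  make values comparable within subject but not across cohorts with
  different dynamic ranges.
- Optimism adjustment with 84 highly overlapping training sets is not
  an unbiased estimator of out-of-sample r²; at n = 9 its sampling
  variability is large, which is why recovery is asserted as a median
  corridor, not a point value.
- The Welch "stroke vs control" comparison averages control hemispheres
  by default; single-hemisphere modes change the effective control
  variance.
- NIfTI inputs must share grid and affine exactly; the package never
  resamples.
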