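# Methods

This note documents the models, parameter choices, and numerical
conventions of `hemiconn`, and what the synthetic-data experiments do and
do not establish.

## The analysis model

The package implements the region-of-interest resting-state connectivity
design for a two-group study (patients vs. matched controls) with a
bilateral seed pair, plus a diffusion arm and a behavioral arm.

**Connectivity.** For subject data $Y(v, t)$ on a left–right symmetric
grid and a seed mask $S$, the seed signal is the unweighted mean
$s(t) = |S|^{-1} \sum_{v \in S} Y(v, t)$ (the common practice; a
first-eigenvariate reduction is a possible alternative and is not
implemented). The connectivity map is the voxelwise Pearson correlation
$r(v)$ with $s$, variance-stabilized as $z(v) = \operatorname{atanh} r(v)$.
Correlations of exactly $\pm 1$ are clipped to $\pm(1 - 10^{-7})$ before
the transform — this keeps $z$ finite while moving any test statistic by a
negligible amount; clip counts are logged. Constant voxels receive $r = 0$
and are counted.

**Laterality.** The grid's first axis is the flip axis and must have even
extent, so mirroring (index $i \to N-1-i$) is an exact permutation with no
interpolation and no midline voxel. The per-subject laterality contrast is
$z_L - \operatorname{flip}(z_R)$: it compares each voxel's connectivity
with the left seed against its mirror voxel's connectivity with the right
seed. For data that are exactly mirror-symmetric the contrast vanishes
identically (bit-exactly for single-voxel seeds; to float summation-order
precision, about $10^{-12}$, for block seeds).

**Group inference.** Voxelwise one-sample, paired (one-sample on
differences — an exact identity, pinned by test), and two-sample $t$-maps;
pooled variance by default (this choice reproduces the study's printed FA
group $p = 0.014$ from its summary statistics), Welch by flag. Two-tailed
conventions throughout. Zero-variance voxels get $t = 0$ with a count
rather than $\pm\infty$.

**Cluster-extent correction.** Following the AlphaSim recipe: null
volumes of i.i.d. standard-normal noise are Gaussian-smoothed to a
configurable FWHM (default 6 mm — the smoothness is a parameter, not
estimated from residuals, because the emulated study does not report its
input), re-standardized within the analysis mask, thresholded two-tailed
at the voxel $p$, and the maximum cluster extent per iteration is
recorded. The corrected threshold $k^*(\alpha)$ is the smallest extent
whose null exceedance probability is $\le \alpha$. Observed $t$-maps are
thresholded at the same voxel $p$ (via the $t$ quantile at the map's df)
and clusters must *exceed* the extent cutoff to survive — "cluster size
> 14 voxels" is read as a strict inequality, applied consistently (14, 13,
10), so a pipeline using $k^*$ passes `min_extent = k* - 1`.

Null-volume smoothing uses periodic boundaries. Reflective boundaries make
the smoothed field non-stationary — edge voxels end up with ~2.4× the
nominal suprathreshold rate after global re-standardization on a 20³ grid —
which inflates null cluster sizes and biases $k^*$ upward; with periodic
smoothing the per-voxel rate is exact (measured 0.00095–0.0010 at nominal
0.001). Cluster connectivity defaults to face-adjacency (6-neighborhood),
configurable to include edges/corners.

Two regimes mirror the emulated study: within-group maps at voxel
$p<0.001$, extent > 14; between-group maps at $p<0.001$, extent > 10,
corrected *inside* the union of the two within-group significant maps
(union, not intersection — the source description is ambiguous; union is
implemented and flagged). Within-group asymmetry uses the two-criterion
rule: paired-$t$ clusters ($p<0.001$, extent > 10) intersected with the
union of the left-seed and flipped-right-seed significant maps; the
intersection is *not* re-checked against the extent cutoff (the correction
order is ambiguous in the source; this choice is pinned by test).
Between-group asymmetry: $p<0.01$, extent > 13, inside the explicit mask
from the two groups' corrected asymmetry maps.

**Diffusion arm.** FA is the standard normalized eigenvalue dispersion,
computed exactly from $(\lambda_1, \lambda_2, \lambda_3)$; zero-trace
voxels get FA 0; negative or unordered eigenvalues are rejected with a
count. Skeleton-style thresholding keeps voxels with mean FA strictly
above 0.2. The asymmetry index is
$\mathrm{AI} = (\text{right} - \text{left}) / [0.5\,(\text{right} +
\text{left})]$, negative for leftward asymmetry. Note that the AI of
group-*mean* FA values (e.g. $-0.1535$ for right 0.433 / left 0.505)
differs from the group mean of per-subject AIs (e.g. $-0.135$); study
tables report the latter. Nonlinear registration and skeleton projection
are out of scope: ROI masks are inputs (synthetic 99- and 135-voxel
boxes for left/right anterior cingulum, matching the emulated ROI sizes;
real tract ROIs are not mirror images, so neither are these).

**Behavioral arm.** Stroop interference = incongruent minus color-naming
completion time. Sex tables use the Pearson chi-square without continuity
correction (df 1). Sphere extraction around a group-difference peak
averages map values over voxels whose center is within the radius
*inclusive*, so a 3 mm radius on a 3 mm grid yields the 7-voxel
face-neighbor cross (pinned by test). The post-hoc direction analysis is
implemented as subject-level region means followed by a group one-sample
$t$ — the only per-subject computable version of "mean $t$ extracted from
within-group maps". Pearson correlations use pairwise deletion of missing
values (the generator plants one Stroop non-completer per group) and
Bonferroni adjustment $\min(1, m\,p)$ over the $m$ tested pairs.

## Preprocessing

Contract-level cleaning: polynomial detrend (order 0/1), band-pass by
masking real-FFT bins (default 0.01–0.08 Hz, the conventional resting
band; the brick-wall response is chosen for exactness and testability over
any filter design), and nuisance regression via reduced QR. Confounds and
the trend basis are band-pass filtered before the final regression; with
that, the composed cleaner is a single orthogonal projection and applying
it twice equals applying it once to machine precision. Global-signal
regression is on by default with a switch, reflecting its common-but-
debated status. The exact nuisance set of the emulated study is
unreported; these defaults are package choices. Motion correction, slice
timing, and spatial normalization are out of scope — synthetic data are
born on the common symmetric grid.

## The synthetic-data generator

The generator emulates the study design, not scanner physics: no motion,
physiological noise, or anatomical realism.

Per subject, each seed side has a latent unit-variance AR(1) series
(default $\rho = 0.3$, chosen to give realistic effective df; the source
is silent on the noise model). Seed voxels carry the latent plus AR(1)
noise of SD `noise_sd` (default 1); a target voxel coupled with weight $w$
carries $w\,s + \sqrt{1-w^2}\,\varepsilon$, so its population correlation
with the latent is exactly $w$ at unit noise SD, and with the *mean* seed
series it is $w / \sqrt{(w^2 + (1-w^2)\sigma^2)(1 + \sigma^2/K)}$ for a
$K$-voxel seed (the closed form used by the calibration tests). The left
and right latents are independent — homotopic seed coupling is not
modeled, which makes the planted right>left asymmetry the only systematic
laterality in the data.

Defaults encode the study conditions: a 24×28×24 grid of 3 mm isotropic
voxels (the emulated cluster volumes imply 27 mm³ voxels; an even flip
axis avoids a midline voxel), $T = 120$ timepoints at TR = 2 s (stand-ins
— the emulated acquisition parameters are not in the available text), 30
subjects per group in the functional arm and 29/24 in the diffusion arm.
Default couplings: a striatum-like bilateral target at $w = 0.5/0.6$
(left/right seed; the right>left asymmetry) reduced by 0.3 in patients,
and a PCC-like bilateral target at $w = -0.30/-0.35$ deepened to
$-0.50/-0.55$ in patients. ROI FA draws are truncated normals at the
study's printed means/SDs (left 0.525/0.505, right 0.471/0.433 for
controls/patients), giving leftward asymmetry in both groups and the
planted right-hemisphere deficit. In eigenvalue mode, prolate tensors
$(\lambda_1, \lambda_2, \lambda_2)$ with ratio
$x = (1 + \mathrm{FA}\sqrt{3 - 2\mathrm{FA}^2})/(1 - \mathrm{FA}^2)$ and
fixed trace realize each drawn FA exactly, so the FA computation recovers
it to $10^{-10}$ (round-trip test). Behavioral variables are drawn at the
printed Table means/SDs; a planted correlation $\rho$ (default $-0.532$
between the patients' AI and the PANSS negative subscale) is imposed as
$\rho\,z_{\text{img}} + \sqrt{1-\rho^2}\,\varepsilon$ rescaled to the
target moments, with PANSS subscales rounded to integers and the total
equal to their sum. All outputs are bit-reproducible from `rng_seed`
(per-subject spawned streams).

Because the generator's noise is temporally AR(1) but spatially white,
passing tests show that the *machinery* is correct under the planted
model; they do not certify behavior under spatially correlated
physiological noise or registration error.

## Replication experiments and problem sizes

`scripts/acceptance.py` (and the validation suite) run four experiments,
sized to complete in minutes on one CPU:

* **FWE calibration** — 20³ grid, 6 mm FWHM, voxel $p = 0.001$, $k^*$ from
  a 2000-iteration null, then 1000 null group analyses of 30 smooth
  Gaussian subject fields each (30 is the study's within-group size).
* **Coupling detection** — 100 simulation seeds at full study conditions
  (n = 30/30, T = 120, default grid), left-seed network, between-group
  correction inside the combined within-group mask.
* **FA-deficit power** — 500 replicate draws of the diffusion arm through
  the generator, pooled two-sample $t$ at $p < 0.05$.
* **AI–symptom sign recovery** — 500 replicate draws planting
  $\rho = -0.532$ at $n = 24$ patients.

## Known limitations

* **The Gaussian extent null is conservative for low-df $t$-maps.** At the
  calibration geometry the null max-extent distribution jumps from
  $P(\ge 6) \approx 0.068$ to $P(\ge 7) \approx 0.034$ (20 000-iteration
  estimate), so $k^* = 7$ and even an ideally matched Gaussian map family
  would show a family-wise rate of ~3.4%, not 5%. A $t$-map with df = 29
  additionally forms smaller clusters than a Gaussian field at the same
  per-voxel rate ($P(\ge 6) \approx 0.045$, $P(\ge 7) \approx 0.020$), so
  the measured family-wise rate on null groups is ~2% — the correction
  errs on the safe side. The rate approaches the Gaussian ceiling as df
  grows (~2.3% at df = 58, ~2.6% at df = 119). This is a property of the
  classic procedure itself (a Gaussian surrogate for a $t$-field plus a
  discrete extent threshold), not of this implementation.
* Extent thresholds from the emulated study (14/13/10 voxels) are not
  recoverable because its smoothness and mask inputs are unreported; the
  procedure, not the constants, is reproduced.
* The generator's spatially white noise makes within-group $t$-maps much
  cleaner than real data; detection rates here are upper bounds.
* Global-signal regression interacts with planted couplings (the latent
  is part of the global mean), so the detection experiment cleans without
  it; with GSR the recovered effect sizes shrink as expected.
* No surface-based analysis, no VBM arm, no atlas handling, no FDR or
  random-field alternatives to the Monte-Carlo correction.
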