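# Methods

This note documents the models, parameter choices and numerical conventions
behind `wmfcs`, and what the synthetic-data studies do and do not establish.

## Pipeline model

The analysed object is a subject's regions × frames matrix of mean BOLD
signals over a combined parcellation of 100 cortical, 14 subcortical and 50
white-matter regions.  Spatial preprocessing (bias-field correction,
segmentation, surface reconstruction, registration to a common space,
slice-timing correction) is upstream of this package: it is performed by
dedicated third-party tools and the parcellation is taken as already aligned
to the functional data.  Synthetic data are therefore generated directly at
region level; voxel rendering (`synthetic.render_voxel_data`) exists to
exercise the extraction path, not to model image formation.

Frame-level cleaning operates in a fixed order, recorded per series in a
`stages` provenance tuple:

1. **Initial-volume removal** — the first 5 volumes are discarded from both
   signal and motion (240 → 235 frames with the default acquisition).
2. **Framewise displacement** — Power's FD on the volume-dropped motion
   trace, so frame flags index exactly the analysed frames.  Rotations are
   converted to millimetres on a 50 mm sphere (the metric's standard
   convention; a degrees switch covers motion tools that emit degrees).
   FD of the first frame is defined as 0 rather than missing, keeping frame
   alignment trivial.
3. **Censoring** — frames with FD > 0.5 mm are replaced region-wise by
   linear interpolation between the nearest unflagged neighbours (edge
   frames take the nearest unflagged value).  Unflagged frames are untouched
   bit-for-bit and the operation is idempotent.  Censoring precedes
   nuisance regression, following the listed order of the cleaning chain.
4. **Nuisance regression + high-pass, as one joint projection.**  The
   nuisance set is the Friston 24-parameter motion model (parameters, their
   one-frame lags zero-padded at the first frame, both squared) plus linear
   and quadratic trends; the high-pass removes all discrete-cosine basis
   functions below 0.01 Hz together with the mean.  The trend columns and
   the slow DCT columns span overlapping subspaces, so *sequential*
   residualisation is not a projection — the second step reintroduces
   variance along the first step's columns.  The pipeline therefore
   projects once onto the orthogonal complement of the combined span; the
   cleaned data are exactly orthogonal to both the motion and the filter
   sets (verified to 1e−8 in the tests).  `nuisance_regress` and
   `highpass` remain available as standalone operations for modular use.
   Rank-deficient designs fall back to the minimum-norm least-squares
   solution with a warning; residual orthogonality to the full column space
   is unaffected.

Subject-level quality control excludes a subject when *any* of three rules
fires: Euler-number modified Z-score below −3.5 (median/MAD scores with a
mean-absolute-deviation fallback when the MAD is zero), mean FD above
0.5 mm, or motion-outlier ratio above 0.3.  The OR combination is the
conservative reading of two separately listed motion criteria and each
threshold is configurable.  Mean FD is written back onto the subject record
because it is a covariate of the group model.

## Connectivity statistics

The FC matrix is `z = atanh(r)` for all region pairs, with `|r|` clipped at
`1 − 1e−7` (clipping is warned about; it only fires for numerically
degenerate pairs such as duplicated series).  Zero-variance or missing
regions produce NaN rows/columns that propagate as missing FCS values and
are excluded pairwise from the family means, rather than excluding the
subject.  WW-FCS and GW-FCS average *raw* Fisher-z values, negative values
included — the literal reading of "average FC" on a z-matrix; an absolute
value variant was deliberately not made the default.

## Group inference

Each region's FCS is regressed on `[intercept, group (post = 1), age,
sex (male = 1), mean FD]` by OLS with listwise deletion; the reported t and
two-sided p belong to the group coefficient, so negative t means the
post-therapy group is lower.  Constant covariates are dropped with a
warning (the model then reduces exactly to the pooled two-sample t, which
the tests verify to 1e−10); genuinely collinear designs are an error.

BH-FDR is applied within family with family sizes m = 50 (WW) and m = 114
(GW).  The step-up implementation accepts a family size larger than the
number of supplied p-values so that printed table subsets (known to contain
the smallest p-values of their family) can be adjusted correctly.  The
published GW adjusted values are not reproducible from the printed raw
p-values under BH with m = 114, so the GW family size is configurable and
no fixed-point check is attached to GW adjusted values.

Partial correlations residualise both variables on `[intercept,
covariates]` and use df = n − 2 − g (the convention of the standard
partial-correlation packages).  Post hoc power for a two-sided pooled
t-test is evaluated from the noncentral t distribution with noncentrality
`d·sqrt(n1·n2/(n1+n2))`, `d = |m1 − m2| / pooled SD`; at d = 0 it returns
exactly α.  Demographics rows use the pooled t for continuous variables,
the Yates-corrected chi-square for the 2 × 2 sex table, the uncorrected
chi-square for clinical staging over available cases (missing counts
footnoted), and Fisher's exact test when a category is empty.

## Synthetic cohort generator

The generator emulates the *study conditions*, not patient physiology.
Defaults: 47 pre- and 64 post-therapy subjects; 164 regions; 240 frames at
TR 2.4 s; group age distributions 46.70 (9.55) vs 43.39 (9.93) years and
roughly 3:1 male:female; Euler numbers N(−45, 15²).

**Signal model.**  Region signals are zero-mean stationary Gaussian draws
from a target correlation matrix with hierarchical baselines: within-tissue
correlation 0.35 (WM–WM and GM–GM) above cross-tissue correlation 0.28.
The hierarchy is both empirically sensible (within-tissue coupling is
stronger in resting-state FC) and geometrically necessary: with a single
global correlation level the whole matrix is driven by one common factor,
and reducing a region's correlation with one tissue family while preserving
the other is infeasible — the Table-matched effect map below leaves the
positive-definite cone under a flat baseline.  No temporal autocorrelation
is modelled; the FC statistics are invariant to region-wise affine scaling,
so signal units are arbitrary.

**Group effects.**  The post group's matrix subtracts a configured amount
from the Fisher-z of each affected region's family edges: 0.06–0.08 for the
five WM regions and 0.06–0.08 for the six GM regions whose published group
means differ by those amounts.  When several affected WM regions share
edges, the per-edge reductions are decomposed as `a_k + a_j` and the small
linear system is solved so every region's family-mean z drops by *exactly*
its configured amount (checked to 1e−12).  The construction is validated
against an eigenvalue floor of 0.01: a target matrix with a smaller minimum
eigenvalue is treated as degenerate, because subject-level offsets and
Cholesky factorisation need headroom inside the PD cone.

**Between-subject variability.**  Each subject adds a common offset to all
off-diagonal z values, drawn from N(0, 0.103²) winsorised at ±2 SD (a large
negative common offset would push all correlations uniformly negative,
which is infeasible at 164 regions).  The winsorised offset SD (≈ 0.099)
combines with correlation-estimation noise over 235 frames (≈ 0.035) to a
subject-level FCS SD of ≈ 0.105 — chosen analytically to match the
published group SDs (0.10–0.15), which also makes the empirical detection
rate of the group test comparable to the noncentral-t power computed from
the published summaries (≈ 0.84 for the superior-cerebellar-peduncle
configuration).

**Motion.**  Rigid parameters follow a Gaussian random walk whose increment
scales give a baseline mean FD of ≈ 0.14 mm, far below the 0.5 mm
threshold; a per-subject lognormal motion scale (σ = 0.4) spreads
subject-mean FD with SD ≈ 0.06, matching the published 0.16 (0.07).
Censorable events are persistent ≥ 0.7 mm jumps on one translation axis
injected with per-frame probability `motion_spike_rate` (default 0.02);
spiked frame indices are returned as a test oracle and each produces FD
> 0.5 mm at exactly that frame.

**Dose variables.**  For a random subset of 37 post-therapy subjects, each
dose variable is an affine combination of the covariate-residualised target
region GW-FCS (weight ρ) and covariate-residualised independent noise
(weight sqrt(1 − ρ²)), scaled to a Gray range (means 62/66 Gy, SDs
6/7 Gy — plausible maximum doses for brainstem and temporal lobe in
nasopharyngeal radiotherapy).  The population partial correlation given the
covariates is exactly ρ (defaults −0.35 and −0.46) and the sample estimate
fluctuates with SD ≈ (1 − ρ²)/√n.  Each dose variable targets a single
region: one variable cannot satisfy two exact partial correlations, so
configurations that try are rejected.

**Seeding.**  A single cohort seed drives one generator stream from which
all subject-level draws derive; every stochastic operation accepts an
explicit seed or generator, and pipeline reruns with the same seed are
bit-identical (hash-verified in the manifest).

## What the synthetic studies show — and what they do not

Against this generator the test suite establishes: type-I error of the
covariate-adjusted per-region test at 5% (0.05 ± 0.02 pooled over 500 null
cohorts), essentially zero BH-significant regions under the null, unbiased
recovery of configured Fisher-z reductions (±0.01 at 500 + 500 subjects
over 20 replicates), dose partial-correlation recovery (±0.04 at n = 2000),
and agreement between empirical detection and noncentral-t power within
Monte-Carlo error.  The acceptance script reruns scaled versions (300
cohorts for the calibration and power studies) chosen to keep a full
reproduction in the minutes range on one CPU.

Real data differ in ways the generator does not emulate: temporal
autocorrelation and aliased physiology, spatially structured noise and
registration error, region-specific baseline connectivity (here all WW
baselines are equal, whereas the published pre-therapy means span
0.22–0.43), heavy-tailed motion, and any dependence of FCS on age, sex or
motion (covariates are generated independent of FCS, so covariate
adjustment here only costs degrees of freedom).  Passing these studies
validates the statistical machinery and its calibration, not the biology.

## Known limitations

* The subject-level offset model makes group differences strongly
  correlated across regions (one global FC factor); per-cohort significant
  counts are therefore overdispersed relative to independent tests, which
  is realistic but means single-cohort results vary more than naive
  binomial intuition suggests.
* GW-family FDR with m = 114 is one defensible choice among several; it is
  configurable per family.
* The voxel renderer assigns equal-sized contiguous blocks; it tests
  extraction arithmetic, not anatomical geometry.
* Whether censored frames should be interpolated before or after nuisance
  regressor construction is ambiguous in the cleaning chain as listed;
  censor-then-regress is implemented.
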