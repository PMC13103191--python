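# Methods

## The measurement model

A stricture section is analysed on a region of interest (ROI) covering the
entire bowel wall on a single slice.  Two voxel-wise models are fitted:

**T2\* relaxometry.**  `S(TE) = S0 · exp(−TE/T2*)` over the first six
echoes (2.0, 5.1, 8.3, 11.4, 14.6, 17.7 ms) of a 16-echo spoiled
gradient-echo train.  Later echoes are discarded: most bowel-wall signal
has decayed after six echoes and residual enhancements at long TE produce
unstable, implausibly long T2\* estimates.  The fit is unweighted least
squares on the magnitude data — at six short echoes the Rician noise floor
is not modelled.

**Segmented IVIM.**  `S(b) = S0 · [f·exp(−b·D*) + (1−f)·exp(−b·D)]` over
the 18-b-value scheme 0 (9 averages), 1, 2, 5, 10, 20, 30, 40, 50, 75,
100, 150, 200, 300, 400, 500, 600, 700 s/mm² (3 averages each); every
average is a separate frame (60 in total) and enters the fit as an
independent observation.  `D*` is the full decay rate of the
pseudodiffusion term, not an increment on top of `D` — the alternative
convention is a one-line change in `ivim_signal`.

## Fitting algorithms and numerical choices

**T2\*** is solved by variable projection: for fixed T2\* the optimal S0
is the closed form `Σ S_i e_i / Σ e_i²` (with `e_i = exp(−TE_i/T2*)`),
reducing the problem to a bounded 1-D minimisation over
T2\* ∈ (0.1, 200] ms with S0 capped at 10× the peak signal.  Compared with
a generic two-parameter solver this needs no starting guess, is exactly
scale-equivariant (scaling the signal by c scales S0 by c and leaves T2\*
bit-for-bit unchanged), and is several times faster.  The bounded Brent
search (xatol 1e−11) is followed by a gradient-root polish — Brent's
bounded minimiser cannot localise beyond `sqrt(eps)·|x|` ≈ 1e−6, and the
polish restores machine-precision determinism.  Minima at the bounds are
snapped exactly to the bound.  Voxels with no positive sample return NaN
with `fit_ok = False`; per-voxel failures are counted and logged, never
raised, mirroring the exclude-then-aggregate workflow.

**Segmented IVIM** runs in three deterministic steps: (1) a log-linear fit
over the frames with b ≥ cutoff gives `D` (clipped to [1e−5, 5e−3] mm²/s)
and the extrapolated intercept `A`; (2) `f = clamp(1 − A/S̄(b=0), 0, 1)`;
(3) with `D` and `f` fixed, a bounded 1-D search over all frames gives
`D*` ∈ [5e−3, 0.5] mm²/s, and `S0` is the mean b = 0 signal.  The cutoff
defaults to 200 s/mm²: at a typical bowel-wall `D*` of 0.06 mm²/s the
pseudodiffusion term has decayed by e⁻¹² there.  When `D*` is slow
(≈ 0.02 mm²/s) its tail still contaminates step 1 by a few percent, so one
refinement pass subtracts the estimated pseudodiffusion signal and repeats
the three steps; this drives the worst-case noiseless recovery error over
D ∈ [0.0008, 0.002], f ∈ [0.05, 0.3], D\* ∈ [0.02, 0.12] below 0.6% while
keeping the segmented structure — `D*` remains a 1-D problem and there is
never a joint multi-parameter refit, so the estimate stays deterministic.
Voxels with `f < 0.001` are excluded from all pseudodiffusion summaries
(strict inequality, `f = 0.001` is kept): `D*` is undefined in an
unperfused voxel.

## ROI aggregation and exclusions

The effective analysis region is wall ∧ ¬artifact.  Gas–tissue transition
zones shorten the apparent T2\*, so the artifact mask is subtracted before
T2\* summaries; the IVIM maps use the full wall mask.  Per section and
parameter the median and 25th/75th percentiles (linear interpolation
between order statistics) are reported over the finite in-mask voxels —
the median is robust against the outliers left by partial voluming, noise
and residual motion.  Section volume is voxel count × voxel volume, with
no surface smoothing.  A section whose effective mask is empty, or whose
map holds no finite value, is flagged excluded with a reason
(`artifact-obscured`, `no-valid-voxels`); the exclusion log always
balances: records in = analysed + excluded.

Frame-to-frame motion is handled by a translational aligner: per frame the
integer in-plane shift maximising the FFT cross-correlation with the
reference frame is estimated and undone.  This is a deliberate
simplification — the phantom's motion model is integer translation, and
the aligner only has to restore mask validity; deformable registration is
out of scope.

## Statistics

The four primary endpoints (per-section medians of T2\*, D, D\*, f) are
compared between inflammatory (inflammatory + mixed phenotypes) and
noninflammatory (chronic) groups with a two-sided Mann–Whitney U test at
α = 0.01 (Bonferroni for four tests).  The p-value is exact (full
enumeration) when the pooled sample is ≤ 16 and tie-free, otherwise the
normal approximation with tie and continuity corrections.  The
significance boundary is non-strict (p ≤ α), so an endpoint at exactly
p = 0.010 counts as significant; a normality-gated t-test alternative is
exposed (`test="auto"`) but the skewed endpoints default to Mann–Whitney.

ROC curves use the trapezoidal AUC over all unique thresholds (hence
AUC ≡ U/(n₁n₂) including ties), a DeLong placement-variance 95% CI, and a
Youden-index threshold swept over midpoints between adjacent unique
scores; among ties the higher-sensitivity threshold wins.  Orientation
(whether high or low scores mark the inflammatory class) is always an
explicit argument — auto-flipping would hide directionality errors.  In
the pipeline, ROC output is gated on significance.

Weighted κ uses quadratic weights `w_ij = (i−j)²/(k−1)²` with the expected
table from marginal products; two constant, identical raters define κ = 1
with a warning (the disagreement-weight denominator vanishes).  ICC(2,1)
is the two-way random-effects, absolute-agreement, single-rater
coefficient (computed via pingouin).  The trend test is the
Cochran–Armitage score test (1 df), invariant to affine rescaling of the
category scores.  No correction for the clustering of multiple sections
within a patient is applied, and no post-hoc corrections beyond the stated
Bonferroni adjustment.

## The digital phantom

The phantom emulates what the downstream analysis consumes, not the
scanner: a single-slice annulus (lumen radius + wall thickness, replicated
in z) partitioned into equal angular wedges, one per section, each wedge
carrying one set of true tissue parameters.  Signals follow the two decay
models exactly; Rician noise `|S + n₁ + i·n₂|` is applied at
σ = S0_wall/SNR (SNR defined at the shortest TE / b = 0); motion is an
integer per-frame in-plane translation; and a configurable fraction of the
wall voxels bordering the lumen get their T2\* replaced by a short
`gas_t2star` (default 3 ms), emulating the gas-transition artifact as a
value perturbation rather than a susceptibility-field simulation.  There
is no k-space, coil, or partial-volume modelling and tissue within a
section is homogeneous, so passing tests demonstrate correctness of the
estimation and bookkeeping chain — not robustness to heterogeneous
pathology, deformable motion or field inhomogeneity in real acquisitions.

The default simulated cohort mirrors the study composition: 71 sections
(8 predominantly inflammatory, 30 mixed, 33 predominantly chronic →
groups of 38 vs 33), with per-section parameters drawn from lognormal
distributions whose median and quartiles match the reported group values
(T2\* 25.4 [19.0–33.1] vs 18.6 [14.5–27.8] ms; D 0.0012 [0.0010–0.0014]
vs 0.0014 [0.0011–0.0019] mm²/s; D\* 0.06 [0.03–0.08] vs 0.06 [0.03–0.11]
mm²/s; f 0.15 [0.09–0.20] vs 0.18 [0.11–0.24]).  Per-section geometry
(2×2×2.3 mm voxels, 5 mm lumen radius, 7.5 mm wall on one slice) gives
single-slice wall segmentations of ≈ 950 mm³, on the scale of the reported
median segmentation volume.  Cohort SNR defaults to 50 — bowel wall at 3 T
with these protocols is comfortably above the noise floor at the shortest
TE — and 25% of the inner rim is gas-perturbed.  Because the scanner's
combination of the 3/9 averages per b-value is not recoverable from
magnitude exports, repeats enter the fit as independent frames by default;
`collapse_repeats` averages them arithmetically first.

## Reproducibility

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning (per-section streams, separate noise
streams per series), so a pipeline re-run with the same configuration and
seed is byte-identical in every CSV/JSON result file; the run manifest
records a hash over every numerically relevant option, the seed and the
package version.  Monte-Carlo test sizes (10⁴ voxels per SNR level for the
noise-behaviour suite, 2 000 replicates for the type-I calibration) were
chosen to make the asserted orderings statistically unambiguous while
keeping the default test run fast.

## Known limitations

- The translational aligner cannot represent deformation or through-plane
  motion.
- The Rician noise floor is not modelled in either fit; at very low SNR
  (≲ 10) the high-b IVIM frames and late echoes acquire a positive bias.
- `D*` estimates are intrinsically unstable (the test suite asserts that
  their error exceeds that of `D` at every SNR); per-voxel `D*` maps
  should only be consumed through the f-filtered per-section median.
- The exact b-value cutoff and repeat-combination scheme used by any given
  scanner reconstruction are acquisition details the package exposes as
  options rather than fixes.
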