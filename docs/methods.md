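# Methods

## The decoding model

The framework treats each stimulus presentation (one audio excerpt heard by
one subject) as one fMRI run of `n_volumes` BOLD volumes sampled at interval
TR. Two classifiers operate at different granularities:

1. a **spatial predictive model** — a linear SVM on whole-mask activation
   patterns — that asks whether the *pattern across voxels* separates the two
   audio categories and which voxels drive the separation, and
2. a **temporal model** — a 1D CNN on single-voxel time series — that asks
   which *individual voxels* carry category information in their temporal
   dynamics, and in which frequency band that information lives.

Both are evaluated by cross-validation schemes that respect the data's
exchangeability structure: leave-one-subject-out for the spatial model (the
unit of generalization is the person) and leave-one-excerpt-out for the
temporal model (the unit is the stimulus presentation).

### First-level GLM

Per voxel, ordinary least squares of the BOLD series on a design with an
HRF-convolved task regressor, Legendre polynomial drift terms (order 1 by
default) and an intercept. The HRF is the canonical double-gamma: response
gamma peaking at 6 s, undershoot peaking at 16 s, undershoot ratio 1/6,
normalized to unit peak. The boxcar is built on a 10× oversampled grid and
decimated to volume times. Outputs are the contrast-effect map (c'β̂) and the
t map, t = c'β̂ / √(σ̂² c'(X'X)⁻¹c) with σ̂² = RSS/(T − p).

The **contrast-effect (COPE) map is the default activation pattern** fed to
the predictive model. Rationale: t is invariant to rescaling a voxel's
series, so under multiplicative (signal-proportional) noise — which the
generator uses, see below — the amplitude information that distinguishes
categories lives in β̂, not t. Both maps are produced; either is a standard
first-level output.

No prewhitening or spatial smoothing is applied; with AR(1) noise the
per-voxel t statistics are therefore mildly miscalibrated in absolute terms,
which is immaterial here because the maps are used as classifier features,
not thresholded inferentially. The null-calibration test drives the GLM with
white noise, where OLS t statistics are exact.

Degenerate voxels (zero residual variance, e.g. noiseless simulations or
all-zero background) get t capped at ±1e6 rather than ±∞.

### Spatial feature identification

- **Bootstrap stability**: B (default 200, minimum 100) class-stratified
  resamples of the runs with replacement; the SVM is refit on each; per
  voxel z = mean(w)/sd(w), two-sided normal p, Benjamini–Hochberg FDR at
  α = 0.05. The FDR threshold is a package choice (the level itself is a
  free parameter).
- **RFE**: iteratively drop the 10% of surviving features with smallest
  |w| until `n_keep` remain; the final step truncates to land exactly on
  `n_keep`. `n_keep` defaults to 1% of the mask at whole-brain scale; the
  demo config sets it to the planted activation extent (64 voxels), since
  the recovery oracle is only meaningful when the kept count matches the
  planted count's order of magnitude.

Signs (which category a voxel's weight favors) are taken from the mean
bootstrap weight or the final RFE refit.

### ROS selection

Region score r_i = n_i / m_i: selected feature voxels over in-mask region
size, computed separately per sign. The ROS set is the union of top-k
regions per (sign × method) list; per-sign cross-method intersections are
reported alongside. Regions with zero selected voxels are never eligible —
a region with no features cannot be a "region of significance". Ties at
rank k break toward the lower region id, deterministically. k defaults to 6
per list at atlas scale and scales down for toy atlases
(k = min(6, ⌈n_regions/3⌉)); the demo config pins k = 2, matched to its
four planted regions split evenly between signs. Ranking by raw count n
instead of ratio r is available by flag.

### Temporal CNN

Architecture (fixed): five 1D conv layers with 40/32/24/16/8 filters,
kernel size 7, stride 1, same padding, ReLU; max-pool of size 2 after conv
layers 2–5 (odd lengths pool with floor: 60 → 30 → 15 → 7 → 3); a 2-unit
softmax dense head (8 × 3 = 24 inputs). Loss is cross-entropy; optimizer is
plain SGD, batch size 64. The network is implemented directly on numpy:
convolutions are lowered to BLAS matrix products via im2col, and gradients
are hand-derived. Weights are He-initialized from the spec seed, so a fixed
seed reproduces training bit-for-bit on one CPU.

Two training choices matter:

- **Class-balanced loss.** Leave-one-excerpt-out folds are inherently
  imbalanced (15 vs 16 training excerpts), and an unweighted loss biases the
  model *against* the held-out class, pushing the null accuracy of
  uninformative voxels measurably below chance. Samples are therefore
  weighted inversely to their class frequency (standard balancing), which
  restores the chance-level null.
- **Learning rate / epochs.** The library default is lr 1e-4 with up to 50
  epochs and early stopping on a training-loss plateau (patience 5,
  min-delta 1e-4). The demo and acceptance configs use lr 0.05 for ~10
  epochs: at their problem size (hundreds of training series) the small
  step makes no visible progress within a tractable epoch budget, while
  the larger step converges in 2–3 epochs on the planted signatures.

Per region, all in-mask voxels' per-series z-normalized signals are pooled
into one training set per fold (one shared model per fold; per-voxel
predictions on the held-out excerpt). Raw-intensity mode is available by
flag. A voxel is a VOS when its held-out predictions are correct in ≥ 60%
of folds, counting correct classifications of either category; the region's
VOS proportion is |VOS| / |region ∩ mask|.

### Kernel frequency analysis

Each of the 8 final-layer kernels feeds 3 feature-map positions into the
dense head; summing the dense weights over those positions gives one weight
per class, and the larger assigns the kernel's category (exact ties are left
unassigned). Kernel taps (length 7, averaged over the 16 input channels;
per-channel mode by flag) are Fourier-transformed; the three non-DC
magnitudes X(1..3) form the kernel's spectrum — for a 7-tap real kernel
these are the only independent oscillatory frequencies, and the DC term is
excluded because the shape analysis concerns oscillatory content.

The shape taxonomy is defined by the sign pattern of X(n) − mean(X):

| pattern | shape | band |
|---|---|---|
| (+,−,−) | L  | low  |
| (−,−,+) | L′ | high |
| (+,−,+) | V  | mixed |
| (−,+,−) | V′ | mixed |
| (−,+,+) | Γ  | high |
| (+,+,−) | Γ′ | low  |

Deviations from the mean sum to zero, so all-above and all-below patterns
are infeasible: the six patterns plus a near-flat class partition every
spectrum. Near-flat means every |X(n) − mean| ≤ 1e-8 · max(X), or
max(X) ≤ 1e-12 (rounding-noise spectra, e.g. a constant kernel). Shape
counts are aggregated over cross-validation folds per (region, category);
the high/low ratios n_Γ/n_Γ′ and n_L′/n_L are reported with an explicit
defined-flag instead of infinities when a denominator is zero. V/V′
(mixed) kernels are counted but not interpreted.

### Acoustic features

Mel(f) = 2595·log₁₀(1 + f/700). MFCCs follow the classical five steps —
STFT (Hann window, frame 2048, hop 512), power spectrum onto a 40-band
Mel-spaced triangular filterbank, log with floor 1e-10, orthonormal DCT-II,
first 13 amplitudes. The spectral centroid is the magnitude-weighted mean
bin frequency per frame (power weighting and a rectangular window by flag);
all-zero frames yield NaN, never 0. These parameter values are conventional
defaults; none are statistically load-bearing.

## The synthetic-data generator

What it emulates: a block-design auditory study with
`n_subjects × n_excerpts_per_category × |categories|` runs (defaults
7 × 7 × 2 = 98), 60 volumes at TR 1.5 s, a box-shaped brain mask inside a
toy volume, and a contiguous-parcel atlas. Planted structure:

- **Spatial ground truth**: `planted_region_ids` (default 4 regions)
  respond to the stimulus with an HRF-convolved block response (15 s
  on / 15 s off; unit-peak regressor) of amplitude `effect_amplitude`
  (default 1.0) for the region's preferred category and a quarter of that
  for the other; preferences alternate across planted regions so both
  classifier signs carry signal.
- **Temporal ground truth**: within planted regions, a fraction
  `planted_voxel_fraction` (default 0.5) of voxels adds a sinusoid at the
  category's signature frequency (defaults 0.06 Hz for CLA, 0.25 Hz for
  SPE; both below the Nyquist limit 1/(2·TR) = 0.333 Hz) with amplitude
  2 × `effect_amplitude` — the factor 2 keeps the oscillation's bin-split
  DFT peak above the block response's low-frequency peak, so a planted
  voxel's periodogram peaks at its signature frequency.
- **Noise**: voxel-wise AR(1) (coefficient 0.3, stationary s.d. 0.5 by
  default), initialized from the stationary distribution, one deterministic
  stream per run seeded from (seed, subject, excerpt, category). In
  responsive voxels the noise is scaled proportionally to the response
  amplitude (multiplicative, physiological-like noise). This choice is
  load-bearing: it makes the variance-normalized series of a voxel with
  *only* spatial signal exactly class-independent, so the temporal channel
  carries nothing but the planted frequency signatures and VOS recovery is a
  well-posed oracle. With additive constant-variance noise instead, the
  class-dependent SNR of the block response leaks into the z-scored series
  and every voxel of a planted region becomes temporally classifiable.

The stimulus is modeled as alternating 15 s on/off blocks rather than one
continuous 90 s stimulus: a regressor that is constant over the run is
confounded with the intercept and the GLM contrast would be inestimable.

What it does **not** emulate: MR physics, motion, registration error,
spatial autocorrelation, subject-level random effects (runs are i.i.d.
across subjects), hemodynamic variability, or realistic audio. Passing
recovery tests therefore demonstrates the *pipeline's* correctness — that
each stage recovers exactly the structure it claims to detect — not
performance on real recordings, where effect sizes, confounds and
between-subject variability are far less benign.

Synthetic audio is a tone mixture per category: "dark"/CLA at
250–550 Hz (centroid ≈ 400 Hz) and "bright"/SPE at 700–1300 Hz with a 6 Hz
tremolo (centroid ≈ 1000 Hz), deterministic per seed, giving a documented
centroid ordering bright > dark.

## Pipeline and problem sizes

The pipeline config fans a single global seed out to per-stage seeds via
`SeedSequence([seed, stage_index])`. Each stage writes its artifacts plus a
completion marker with content hashes; completed stages are skipped (and
reloaded from disk) unless forced, and identical config + seed yields a
byte-identical report (NIfTI is written uncompressed to avoid gzip
timestamps).

The packaged demo runs 4 subjects × 4 excerpts × 2 categories on an 8×8×8
volume (216-voxel mask, 12 regions, 4 planted), analyses the top 2 ROS in
the temporal stage, and completes in about two minutes on one CPU; the
determinism check uses an even smaller 2 × 3 × 2 configuration. These sizes
were chosen so the full recovery loop — including 32-fold CNN
cross-validation per region — stays desk-scale while every recovery metric
remains well-posed (≥ 16 voxels per region, ≥ 8 planted and 8 null voxels
per analyzed region).

## Statistical notes

- The permutation-null tests permute labels *within subjects* (the
  exchangeability blocks of a leave-one-subject-out design). Unrestricted
  permutation induces training-fold imbalance that biases cross-validated
  accuracy below 0.5, which the binomial reference band does not describe.
- ROC curves pool decision values across folds into a single curve; AUC is
  the trapezoid rule, cross-checked in tests against the O(n²) pairwise
  rank-comparison estimator.
- Bootstrap selection under the global null is conservative (BH-FDR), so
  the null selection rate sits well below α.

## Known limitations

- The numpy CNN is CPU-bound and single-threaded by design; whole-atlas
  temporal analysis at paper scale (16 regions × 98 folds) is hours, not
  minutes. The architecture is faithful; only the problem sizes in the
  packaged configs are reduced.
- Bootstrap resampling is at the run level (not subject level); subject-level
  resampling is a plausible alternative the interface does not expose.
- The GLM omits prewhitening; t maps under AR(1) noise are features, not
  calibrated test statistics.
- The kernel-to-category mapping sums dense weights over a kernel's three
  feature-map positions; other aggregations (max, position-weighted) are
  defensible and unexplored.
- The 60% VOS threshold has a fat binomial tail at small fold counts: with 32
  held-out excerpts a chance-level voxel crosses it with probability ≈ 0.11
  (versus ≈ 0.02 at 98), and a fold's shared model correlates the outcomes of
  that fold's null voxels, so demo-scale VOS precision fluctuates around 0.9
  across seeds rather than sitting at 1.
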