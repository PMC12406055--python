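# Methods

This note documents the models, conventions, and design choices behind
`dfcfp`: what each stage computes, which parameters matter and why their
defaults are what they are, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Time series and filtering

`RoiTimeSeries` holds a (T, r) array of region-averaged BOLD signal and its
sampling period TR (seconds). Extraction from a 4-D volume plus an integer
label volume averages voxels per nonzero label, ordered by ascending label
value. Two deliberate strictnesses: a label expected but absent is an error
naming the label, and NaN voxels inside a label are rejected outright —
silently masking voxels changes ROI means in ways that cannot be reproduced
from the outputs.

Band-pass filtering uses a Butterworth design of prototype order 5 (10
poles) over 0.01–0.10 Hz, applied as a causal single pass by default: the
intended comparison point is a `butter` + `filter` style pipeline, which is
causal, not zero-phase. A `zero_phase=True` option applies a
forward-backward pass for users who prefer no group delay. The filter is
realized in second-order sections; for a narrow band at low frequency
relative to Nyquist (≈0.69 Hz at TR 0.72 s), the polynomial (b, a) form is
numerically fragile while SOS is stable. Filtering is linear and per-column,
so it commutes exactly with region subsetting.

Filtering order (voxel level before averaging vs ROI level after) is
configurable in principle; the package defaults to ROI-level filtering,
which is what the TSV-based interface naturally provides. For linear filters
the two orders differ only through voxel-level preprocessing that is out of
scope here.

## Sliding-window dFC

Windows are half-open, [kS, kS + w) for k = 0 … w̃−1 with
w̃ = ⌊(T−w)/S⌋ + 1; trailing timepoints that do not fill a window are
discarded (the floor in the formula implies exactly this). Each window's
Pearson correlation matrix is vectorized row-major over the upper triangle:
(1,2), (1,3), …, (1,r), (2,3), … — this pair order is stored with every dFC
and acts as the compatibility fingerprint for dictionaries.

Correlations are stored raw; no Fisher z-transform is applied anywhere in
the pipeline (none is part of the method being implemented). A region that
is exactly constant within a window has no defined correlation: the default
is a hard error naming region and frame, with an opt-in permissive mode that
writes zeros and logs. Constancy is detected by exact zero range rather than
a standard-deviation threshold, since the standard deviation of a constant
column rounds to ~1e−16 rather than 0.

Durations in seconds convert to timepoints by round(seconds/TR) — e.g. a
576 s window at TR 0.72 s is exactly 800 timepoints; for TRs that do not
divide the grid values evenly, rounding is a documented approximation.

## COBE dictionary learning

Training blocks are the dFC matrices of the training subjects. Each block is
scaled to unit Frobenius norm by default (`normalize_blocks`), so subjects
with more frames or globally stronger connectivity do not dominate; a flag
disables this.

Initialization is the canonical-correlation choice: the C leading
eigenvectors of the pooled covariance Σₙ YₙYₙᵀ over column-normalized
blocks, computed as the left singular vectors of the column-concatenated
blocks (an economy SVD — identical result, better complexity when
r̃ ≫ Σw̃ₙ). This is also what bounds the component count:
at most min(r̃, w̃) eigenvectors exist, so C ≤ min(r̃, minₙ w̃ₙ) is enforced
everywhere (training, grid search, CLI) with an error quoting the bound.

Components are extracted sequentially with deflation. For component j, with
accepted columns D₁..ⱼ₋₁, alternate

1. zₙ = Yₙᵀ d for every block,
2. d ← Σₙ Yₙ zₙ, re-orthogonalized against D₁..ⱼ₋₁ and normalized,

until ‖d_new − d_old‖ < tol (default 1e−8) or max_iter (default 500). This
is a power iteration on the deflated pooled covariance; its fixed points are
pooled-covariance eigenvectors, consistent with the initialization. On a
single block the learned span therefore equals the top-C left singular
subspace of that block. Non-convergence is recorded in metadata
(`converged=False`) and logged, not raised: the basis is orthonormal and
usable regardless, and slow tail convergence between near-degenerate
eigendirections is common and harmless. Each column's sign is fixed so its
largest-magnitude entry is positive, making results deterministic across
runs and BLAS implementations. Metadata records block count, window/stride,
per-component iteration counts, the final pooled residual
Σₙ‖Yₙ − DDᵀYₙ‖², and the normalization flag.

Application is exact projection: X = DᵀY, common = DX, specific = Y − DX.
The residual is orthogonal to span(D) to machine precision, and
common + specific re-adds to the input to within one ulp per entry (floating
point does not guarantee bit-exact a + (b − a) = b). Dictionaries refuse
inputs whose pair ordering differs from their fingerprint — that contract is
what makes a stored dictionary safely reusable on unseen subjects. When
trained on bare matrices (generic multiblock data without region pairs), a
placeholder fingerprint is synthesized so the compatibility check still
functions.

`network_average_basis` summarizes one basis column as an 8 × 8 table of
mean weights within and between networks; network pairs with no member
region pairs yield NaN and are logged.

## Identifiability scores

The identifiability matrix A correlates every session-1 frame with every
session-2 frame over the r̃ pair entries, full Pearson (mean removed): after
common-component subtraction a frame is an arbitrary vector, not a bounded
correlation pattern, so no centering shortcut is valid. Frames are
concatenated subject-major, giving w̃ × w̃ blocks; rows are session 1,
columns session 2.

dIdiff: each diagonal block's w̃² entries are sorted descending; dIself(j)
is the mean of the top j entries, averaged over subjects, for j = 1 … w̃.
The different-subject term mirrors the same procedure over off-diagonal
blocks ("similarly" is read as "the same sorting procedure"); an
`others="all"` variant instead averages all off-diagonal entries and is
constant in j. dIdiff(j) = dIself(j) − dIothers(j), reported ×100. The
headline scalar is dIdiff(1). dIself is non-increasing in j by construction
(means over enlarging top sets); dIdiff(1) ≥ dIdiff(j) is a tendency, not an
invariant, and is not asserted. A frame-wise reading of "most identifiable
frames" (ranking whole columns rather than entries) exists in the
literature; the entry-wise form is implemented as primary.

IR: each column's argmax row predicts the owning subject; ties break to the
lowest row index and are logged. Accuracy is frame-level (no per-subject
majority vote), reported as a percentage, with an nsub × nsub confusion
matrix whose rows (true subject) each sum to w̃. Scoring direction is
columns only — session-2 frames identified against session 1 — with a
`symmetric=True` option averaging both directions. IR is invariant under any
strictly increasing transform of A.

## Evaluation

The 5×2 CV test follows Dietterich: five random halvings of the subjects;
per replication, fold 1 trains the dictionary on one randomly chosen session
of half A and scores both sessions of half B, fold 2 swaps halves. With
paired fold differences d_i^(k) and per-replication variances
s_i² = (d_i^(1)−d̄_i)² + (d_i^(2)−d̄_i)²,

    t = d₁^(1) / sqrt((1/5) Σ s_i²),  5 df, two-sided p.

The numerator uses the first fold's difference as in the original test; a
`numerator="mean"` variant uses the grand mean. All per-replication
variances equal to zero is a hard error ("degenerate variance") at the
statistic level; the cohort-level runner records such comparisons as
degenerate instead of aborting, since saturated identical scores are a
legitimate outcome on easy data. Bonferroni correction is alpha/m. With an
odd subject count the first half receives the extra subject (logged).

Grid search partitions subjects into blocks (default 3); within each block
half the subjects (one random session) train and the other half's two
sessions are scored. Combinations violating C ≤ min(r̃, w̃) are skipped with
a logged reason. Selection maximizes block-mean IR of the subject-specific
dFC; dIdiff(1) is recorded alongside. Test subjects are asserted disjoint
from training subjects in every evaluation.

## Synthetic cohorts

The generator realizes each scan by latent-source mixing,
X = sources @ Mᵀ + ε, which keeps every implied covariance positive
semi-definite by construction (no PSD repair is ever needed) and produces
genuinely time-varying windowed correlations. Three ingredients:

* **Common structure** — `n_common` orthonormal region-space patterns shared
  by all subjects, each driven by its own latent source whose amplitude
  follows a slowly varying log-normal envelope (smoothing length T/8,
  mean 1) drawn per subject and session. Envelope drift is what gives the
  common connectivity frame-specific coefficients, the structure the
  dictionary is meant to capture.
* **Subject signature** — `n_subject_factors` unit mixing vectors per
  subject, identical across that subject's two sessions. This is the only
  cross-session stable individual signal, hence what makes subjects
  identifiable. Twin pairs blend signatures continuously:
  sig_twin = √s·sig_partner + √(1−s)·own (renormalized), so `twin_share`
  is exactly the shared variance fraction rather than a rounded number of
  whole factors.
* **Noise** — fresh latent draws per session, additive sensor noise of
  standard deviation `noise_sd`, and a per-session perturbation of the
  signature mixing vectors of magnitude 0.3·noise_sd, so cross-session
  self-similarity is high but imperfect (at noise_sd = 0 sessions differ
  only by latent sampling, and raw identification is perfect).

Defaults — 30 subjects, 40 regions, T = 600 at TR 0.72 s, n_common = 5,
3 signature factors, common_strength 1.0, subject_strength 0.45,
noise_sd 0.35 — were chosen once, while designing the generator, to emulate
the regime the method targets: raw dFC identifies roughly 9 of 10 held-out
subjects' frames and common-component removal closes most of the remaining
gap. The companion pipeline defaults are window 200, stride 50 (9 frames per
scan) and C = n_common. All of this runs in seconds on one CPU, so the
pipeline-level tests use these sizes directly.

What the generator does *not* emulate: hemodynamic response shape,
physiological noise spectra, spatial autocorrelation of real parcellations,
empirical FC distributions, or motion artifacts. Passing tests therefore
demonstrate the algorithmic claims (decomposition correctness, recovery of
planted structure, direction and testing of identifiability improvements) on
data with the right statistical skeleton — not performance on real fMRI.

Two ground-truth facilities exist at different levels of idealization:

* `planted_dfc_blocks` plants a shared orthonormal basis directly in pair
  space — the dictionary learner's exact data model. Individual coefficients
  are orthogonalized against the common coefficients and scaled below them,
  so at zero noise the pooled covariance splits exactly and training
  recovers the planted span to machine precision (the tight recovery tests
  use this).
* `ground_truth_check` compares a dictionary against a cohort's planted
  pair-space span (the orthonormalized vec(aᵢaᵢᵀ) patterns). At cohort level
  recovery is inherently approximate: Pearson normalization is nonlinear in
  the planted amplitudes and window sampling noise persists even at
  noise_sd = 0, so angles are judged against the random-subspace baseline
  (near π/2 in r̃ dimensions) rather than against zero. Increasing sensor
  noise can *reduce* these angles — it equalizes region variances and makes
  the normalization more uniform — so no monotonicity in noise is claimed.

## Known limitations

* Frames are treated as exchangeable; temporal contiguity of windows is
  ignored by the decomposition (scrambling frames changes nothing).
* dIdiff can mislead when off-diagonal correlations straddle zero and cancel
  toward a near-zero different-subject average; IR is the more robust
  headline metric and is what parameter selection maximizes.
* The 5×2 comparison of two separately generated cohorts (twin vs unrelated)
  pairs scores by fold index only; with near-ceiling scores its variance can
  be very small, so marginal p-values at particular seeds should not be
  over-read. The twin cohorts do score a few IR points below unrelated ones
  at twin_share = 0.5 — a real, mild confusability effect that the
  Bonferroni-corrected 5-df test does not flag.
* Seconds-to-timepoints rounding makes grid values exact only for TRs that
  divide them; the timepoint values used are always recorded in outputs.
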