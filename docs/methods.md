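# Methods

## The classification problem

Multicolour fluorescence in-situ hybridization (M-FISH) paints each human
chromosome class with a distinct combination of five fluorochromes, imaged as
five grayscale channels plus a DAPI counterstain in which all chromosomes are
visible.  Every chromosomal pixel therefore carries an n = 5 dimensional
intensity vector whose expected pattern is the binary fluorochrome code of its
class; classifying pixels into the m ≤ 24 chromosome classes turns the image
set into a karyotype map.  Noise, spectral mixing between dyes and uneven
hybridization blur the codes, so per-pixel decisions are error prone.

## Sparse-representation classification

A dictionary `A ∈ R^{n×N}` collects N training pixels as columns, partitioned
into per-class blocks `A = [A_1 … A_m]`.  A test pixel `y` is coded as
`x̂ = argmin ‖Ax − y‖₂ s.t. ‖x‖₀ ≤ K₀`, solved greedily by orthogonal
matching pursuit (OMP), and assigned to the class whose block best explains
it: `Class(y) = argmin_i ‖y − A_i x̂_i‖₂`, where `x̂_i` keeps only the
coefficients on class-i columns.

The joint (neighborhood) model codes the `n×s` matrix `Y` of a pixel and its
window simultaneously under a shared row support:
`X̂ = argmin ‖AX − Y‖_F s.t. ‖X‖₀,q ≤ K₀` with q = 2, solved by simultaneous
OMP (SOMP); the central pixel gets `argmin_i ‖Y − A_i X̂_i‖_F`.  The shared
support encodes the assumption that neighboring chromosome pixels belong to
the same class, which suppresses isolated single-pixel errors.

### Solver details

- Greedy selection scores every unselected atom by `‖a_kᵀR‖_q` against the
  current residual matrix; ties break to the lowest column index.
- The refit over the selected support uses an SVD-based least-squares solve
  (`numpy.linalg.lstsq`), not an explicit pseudo-inverse product; the refit
  over a growing support makes the Frobenius residual non-increasing.
- Stopping: `|support| = K₀` or residual ≤ `residual_tol` (default
  `1e-10·‖Y‖_F`), whichever first.  The early stop prevents selecting atoms
  against an exactly reproduced input.
- Dictionary columns are normalized to unit ℓ₂ norm at construction and the
  original norms kept; correlation-based atom selection is scale sensitive and
  unit atoms are the standard convention.  Class residuals are computed in the
  normalized frame, which does not change the argmin class.
- `omp_solve` literally delegates to `somp_solve` on an `n×1` matrix, so the
  two are bit-identical where they overlap.
- Greedy recovery is not exhaustive-search recovery: on highly coherent
  dictionaries (e.g. 8×24 Gaussian, mutual coherence ≈ 0.7–0.8) SOMP matches
  the exhaustive best 2-subset on roughly 92–93% of noiseless instances; the
  failures are inherent to one-atom-at-a-time selection at that coherence, not
  numerical defects.

### Dictionary construction

`build_dictionary` samples `⌈fraction·N_c⌉` pixels per class uniformly at
random (seeded), excluding background (0), overlap (255), and pixels that are
exactly zero in every channel (degenerate atoms).  The complement of the
training sample is returned as the held-out test partition so evaluation never
touches training pixels.  Optional screening by the sparsity concentration
index (SCI) re-codes each candidate over the other candidates (leave-one-out)
and resamples candidates below a threshold, up to 5 rounds; it is off by
default and, when enabled, defaults to threshold 0.2.  Class residuals reuse
the joint solution's coefficients per class (a literal reading of
`‖Y − A_i X̂_i‖`); a per-class least-squares refit is available via
`refit=True` for comparison.

### Neighborhoods and boundaries

Windows are square with odd side; `s` is the nominal size (1, 9, 25, …, 169).
Under the default `shrink` policy, out-of-image and out-of-mask pixels are
dropped, so background never contaminates the joint representation and
effective `s` shrinks at borders; `pad-replicate` substitutes the central
pixel's vector instead, keeping `s` nominal.  The central pixel is always
column 0.  Because the decision for the central pixel uses the whole-patch
residual, pixels at boundaries between touching or overlapping chromosomes
can take the majority class of the patch — the same mechanism that makes very
large windows counterproductive.

## Evaluation

RCC (ratio of correct classification) is the fraction of correctly labelled
pixels among evaluated pixels; per-class RCC restricts to one ground-truth
class.  Background and overlap pixels are excluded everywhere, and the default
evaluation set is the held-out test partition (training pixels excluded; an
all-labelled-pixels variant is available by passing those coordinates).  RCC
is stored as a fraction in [0, 1]; the CLI prints percent.  Model comparison
uses a two-sided paired t-test on per-cell RCC, reporting means ± sd in
percent; all-zero differences report t = 0, p = 1 and a constant nonzero
difference reports t = ±inf, p = 0.  Isolated spots are 8-connected components
of size 1 among misclassified in-mask pixels (ground-truth background/overlap
excluded, consistent with RCC).

## Synthetic cells

The generator places `regions_per_class` random rotated ellipses per class
(chromosome-like elongation), assigns each class the binary fluorochrome code
from a Gray-code table (consecutive classes differ in exactly one dye — a
documented, fixed worst case), and renders pixel signal =
`base_intensity · code`, optionally through a diagonally dominant crosstalk
matrix, plus i.i.d. Gaussian channel noise clipped at 0.  Where blobs of
different classes intersect, pixels become overlap (255) with probability
`overlap_fraction` (default 1) and carry the union of both codes.  DAPI is
`base_intensity` on all labelled pixels plus noise; `threshold_mask` applies
Otsu's between-class-variance threshold to it as a stand-in segmentation.

`bias_amplitude` (default 0) multiplies the clean signal by a smooth
per-channel bias field (bicubic upsampling of a coarse zero-mean grid, scaled
to 1 ± amplitude), emulating inhomogeneous background and uneven
hybridization.  This matters scientifically: without within-class signature
variability, one training pixel per class already represents its class and
training-sample size has no mechanism to influence accuracy.  With the field
on, larger training fractions genuinely cover more of the class manifold.

What the generator does not emulate: chromosome banding, optical blur/PSF,
channel misalignment, non-Gaussian camera noise.  Tests passing on these
cells therefore demonstrate the solver/decision logic and the direction of
parameter effects, not clinical-grade accuracy on microscope data.

### Study conditions (fixed defaults)

- Default cell: 128×128, m = 24 classes, 2 regions per class,
  `base_intensity` 1.0 — ≈ 3 300 labelled pixels per cell.
- Calibration noise: `noise_sd = 0.3` (`CALIBRATION_NOISE_SD`), chosen so the
  pixelwise classifier lands in the 0.6–0.9 RCC band on default cells
  (measured ≈ 0.67); model comparisons run 20 cells at this level with
  training fraction 0.1 and K₀ = 3 for both models.
- Small-blob preset (`small_blob_config`): 64×64, m = 12, blob half-axes
  ≈ 1.2–2.2 × 3.5–6.5 px, `noise_sd = 0.22`, `bias_amplitude = 0.6` on a 6×6
  bias grid — densely packed small chromosomes whose pixelwise RCC also falls
  in the calibration band.  Used for the training-fraction and window-size
  studies; 13×13 windows (s = 169) regularly reach neighboring chromosomes
  there, reproducing the oversized-window penalty.
- Parameter-grid presets: training fractions 1–50% (the published list),
  K₀ ∈ 1..10, s ∈ {1, 9, 25, 49, 81, 121, 169}.

## Defaults and tunables

| Parameter | Default | Why |
|---|---|---|
| `K₀` (sparsity level) | 3 | within the recommended K₀ ≤ 5; small K₀ is more accurate |
| `q` (selection norm) | 2 | row-ℓ₂ scoring of atom/residual correlation |
| `s` (neighborhood size) | 9 | the recommended 3×3 window |
| `residual_tol` | `1e-10·‖Y‖_F` | early stop on exact representation |
| training fraction | 0.1 | mid-range of the published sweep |
| `boundary_policy` | `shrink` | background must not enter the joint model |
| SCI screening | off (0.2 when on) | no published threshold; logged when enabled |

## Numerical and degenerate-input choices

- Argmax/argmin ties: lowest column index (atom selection), lowest class
  label (class decision) — fully deterministic.
- An all-zero input solves to an empty support with residual 0 and, if
  classified, takes the lowest class label (all residuals are 0).
- Residual-trace monotonicity is asserted with relative slack 1e-9 to absorb
  least-squares floating-point jitter.
- Zero-variance paired differences are reported explicitly rather than as NaN.
- `classify_image` is a per-pixel Python loop over small dense solves; problem
  sizes in the bundled studies (64–128 px cells, dictionaries of a few hundred
  atoms) run in seconds per cell.

## Known limitations

- One dictionary per cell (train/test split within a cell) is the default
  protocol; cross-cell training is possible by passing lists of cells but is
  not tuned.
- Overlap (255) pixels are excluded from training and scoring; no model for
  mixed signatures is provided.
- The joint decision labels boundary pixels by whole-patch majority, so
  accuracy at chromosome contact zones is structurally lower than in
  chromosome interiors, even without noise.
- Channel intensities are used raw; an optional per-channel min-max scaling
  exists but is off by default, and no denoising/registration preprocessing
  is included.
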