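# Methods

## Decoding model

A cell's hyperspectral signature is the concatenation of four acquisition
blocks (31 + 27 + 22 + 20 = 100 emission channels; lasers 405 / 458+561 /
488 / 514+594 nm). Channel k of a block is assigned the center wavelength
`emission_start + (k − 0.5) × 8.9 nm`; only the range endpoints and the
nominal ~8.9 nm bin width are physically meaningful, so the half-offset
convention is a package-internal choice that makes the simulator's channel
grid deterministic. No re-binning or calibration between schemes is
attempted.

Identity is decoded by maximum cosine similarity (MCS) against a reference
library. Cosine similarity is computed on raw (unnormalized) vectors via
the norm-ratio formula; explicit unit-norm conversion is exposed for
plotting but is mathematically redundant. Key conventions:

- **Zero-norm spectra raise** rather than scoring 0: a silent zero would
  masquerade as genuine orthogonality. Downstream, the decoder maps such
  cells to an `unclassified` label so cell counts always reconcile; they
  count as misclassified in error rates (the conservative reading).
- **Exact ties** at the maximum go to the first candidate in library order
  and set an `ambiguous` flag; ties essentially never occur with measured
  spectra but must be deterministic.
- **No minimum-MCS rejection by default** — every cell with signal gets a
  label; an optional `min_mcs` cutoff can reject low-confidence calls.
- Float comparisons in tests use a relative tolerance of 1e-9 unless a
  looser statistical band is the point of the test.

Accuracy statistics: the monoculture **error rate** is
`100 × #(predicted ≠ truth) / n_cells`; the FP-minus-one **false-positive
rate** is `100 × #(predicted = absent FP) / n_cells`. Intensity strata
(low/medium/high) are assigned by radiance *rank* and split into
equal-count groups (remainder to the lower strata), so duplicated radiance
values still partition.

## Reference library and dim-FP detection

A reference spectrum is the channel-wise mean over a monoculture's cells;
zero-radiance cells are excluded with a logged count. References are stored
unnormalized since MCS is scale-invariant. Brightness QC compares per-FP
distributions of per-cell log10 radiance (radiance = sum over the 100
channels) using pairwise 1-D empirical Wasserstein-1 distances and
average-linkage hierarchical clustering; the cluster with the lowest mean
is flagged dim. The linkage choice is ours (the distance is standard, the
linkage genuinely open); the cluster count is exposed as `n_groups`
(default 2) rather than hard-coded. No outlier or untransfected-cell
rejection is performed before averaging.

## Palette search

Feasibility is **strictly `CS < threshold`** (default 0.9); a configuration
flag switches to `<=` because either convention is defensible and the
boundary matters for pairs sitting exactly at the threshold. The search is
a depth-first extension over the compatibility graph with pruning; tests
verify it equals brute force over all subsets. Tie objectives break
lexicographically on FP names. Enumeration is capped (`max_results`,
default 10,000) with an explicit truncation flag since counts grow
combinatorially. A connected-component dedupe pre-filter (keep the
earliest-listed member of each group of mutually near-identical FPs) is
implemented but **off by default**: combined with pairwise feasibility it
is redundant, and it can silently drop FPs a user asked for.

The packaged seven-FP green-panel fixture encodes the similarity structure
of three qualitative spectral patterns (four pattern-1 FPs pairwise
0.95–0.99, two pattern-2 FPs pairwise 1.00, cross-pattern 0.81–0.87, and a
violet-excited outlier at 0.15–0.58 against everything); within-category
entries use the midpoint of each range. With it, exactly 8 feasible
3-tuples exist at threshold 0.9 and no 4-tuple or larger survives.

## Spatial-clone error model

Per-cell misclassification events are independent with probability P, so a
clone of N cells is entirely misdecoded with probability P^N. Clones live
on a 3×3 grid with the center always occupied and the other N−1 cells
uniform over the 8 outer squares: C(8, N−1) placements, summing to 256
over N = 1..9. Position does not influence the error draw (the placement
matters only for visualization and future spatially correlated
extensions); the Monte-Carlo simulator exists to validate the analytic
power law and as a hook for such extensions. No neighborhood-vote
relabeling of real images is performed.

## Synthetic data generator

The simulator stands in for microscope data; its defaults are the study
conditions of the test suite.

- **Spectra**: Gaussian excitation and emission profiles parameterized by
  maxima and FWHM (defaults 55 / 35 nm). Per block, channel intensity =
  brightness × Σ_lasers (excitation efficiency at the laser) × emission
  density at the channel center; channels below the block's highest laser
  line + 10 nm are zeroed (a notch guard approximating the detector's
  laser-exclusion margin; configurable). Real FP spectra are asymmetric —
  shape fidelity is irrelevant to the decoder's contracts, and measured
  spectra can be loaded as a library CSV instead.
- **Panel**: 15 built-in FPs spread over 420–695 nm with excitation maxima
  tracking the laser lines. Any panel of the first 12 has all pairwise
  model-spectrum similarities < 0.9 (measured max 0.80), emulating a
  resolvable 12-plex; a deliberately confusable pair (similarity ≈ 0.999)
  supports negative tests.
- **Scenes**: cells are non-overlapping discs (radius 3 px) on a jittered
  grid; per-pixel expected intensity is expression × model spectrum over a
  background of 5 units. Expression is log-normal, median 10^4.5 detector
  units with 0.3 decades spread, putting per-cell radiance in the
  10^4.5–10^5.5 range typical of bright FPs. Detector noise is additive
  Gaussian, default sd 20 units/pixel ("moderate": a few percent of peak
  signal after mask averaging), with optional Poisson shot noise. All
  outputs are pure functions of the scene seed.
- **Designs**: monoculture, equal mix (uniform identities), FP-minus-one
  (one panel member absent while still offered to the decoder), and clonal
  growth (one adjacency ring added per day, expression × 0.6 per day to
  emulate plasmid dilution across divisions).
- **Problem sizes** used by the default suite — monocultures of 30–60
  cells per FP, co-cultures of 120–3,000 cells, clone simulations of 10^6
  replicates — were chosen as the smallest scales at which the statistical
  assertions (binomial confidence bands, 4-sigma Monte-Carlo bands) are
  meaningful.

What passing synthetic tests does **not** show: robustness to segmentation
errors on real morphology, autofluorescence, spectral bleed between
touching cells, photobleaching, or detector nonlinearity — none of which
the generator models (no PSF, no chromatic aberration).

## Rendering

Decoded scenes render as the grayscale maximum-intensity projection with
cell masks pseudocolored by predicted FP. Per-cell brightness maps min–max
scaled log10 radiance to [0.3, 1.0] (gamma-adjustable); the 0.3 floor keeps
dim cells visible. The transfer function is a rendering convention, not a
measurement, and is excluded from quantitative tests. Outline color is the
componentwise complement (255−r, 255−g, 255−b). Hidden FPs and
unclassified cells keep the grayscale MIP. PNG export uses fixed encoder
settings so identical inputs are byte-identical.

## Segmentation fallback

External label masks are first-class inputs (any integer-label image). The
built-in fallback (Gaussian smooth → Otsu → connected components →
watershed on distance-transform maxima, discard < 20 px) exists so the
pipeline and tests need no external segmentation model; it is deliberately
simple and not a substitute for a purpose-trained segmenter on real data.
Pixels are 0-based row-major, background label 0. No background
subtraction or flat-field correction precedes mean-intensity extraction.

## Known limitations

- Per-cell mixtures (co-expression) are out of scope; the decoder assigns
  exactly one FP per cell and leaves within-cell unmixing to linear
  unmixing approaches.
- The clone model assumes spatially independent errors.
- The dim-FP flag depends on the cluster cut (`n_groups`); panels with a
  brightness continuum rather than a gap will split arbitrarily.
- Acquisition schemes are trusted as given; there is no wavelength
  re-binning, so libraries and cells must share a scheme.
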