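# Methods

This note records the models, parameter choices and numerical conventions
behind `flsquant`, and what the synthetic-data validation does and does not
demonstrate.

## Imaging model and coordinate conventions

A stack is a non-negative intensity volume indexed `(slice, row, column)`
with lateral calibration in µm/px and axial calibration in µm/slice.
Slice 0 is the base (membrane-proximal) plane; FLS are defined as
structures anchored there. Continuous coordinates are written `(x, y) =
(column, row)`; all indices are 0-based. Default calibration is 0.1 µm/px
and 1.0 µm/slice, matching a 100× objective with EMCCD sampling and
whole-structure confocal stacks; both are configurable, and the axial
spacing is deliberately exposed because acquisition conventions vary.

## Segmentation

Each slice is filtered with a 2D Difference of Gaussians,
`G(σ_small)∗I − G(σ_large)∗I`, with reflective boundary handling. Defaults
σ_small = 1.5 px, σ_large = 3 px select cross-sections of roughly 0.3–0.6 µm
diameter at 0.1 µm/px. The threshold is global per slice:
`mean + k·sd` of the DoG response with population sd (ddof = 0), default
k = 3. A global mean/sd rule was preferred over Otsu because many slices
legitimately contain no structures, and Otsu misbehaves on unimodal
histograms. Components are 8-connected; centroids are intensity-weighted
using the raw (unfiltered) slice.

`min_area_px` defaults to 8. The DoG response of pixel noise is spatially
correlated at the filter scale, so suprathreshold noise clusters of ~4–6 px
are common and a single-pixel floor is insufficient; at 8 px,
pure-background slices are component-free in practice while shaft
cross-sections (~13 px at the default geometry) are untouched. The
sensitivity of recovery to this parameter was checked: count, length,
straightness and base-area recovery on the standard synthetic stacks are
identical at 4, 6 and 8 px.

## Greedy tracing

Tracing is trace-major greedy and fully deterministic:

1. One trace is seeded per slice-0 component, processed in descending base
   area (ties by (y, x) centroid) — large bases mark the most confident
   structures and get first claim on ambiguous links.
2. A trace at slice `s` scans slices `s+1 … s+1+gap_tolerance` in order and
   claims, at the first slice offering one, the unclaimed component whose
   lateral centroid distance (µm) is smallest and ≤ `max_link_um`
   (ties by (y, x)).
3. The trace ends when the whole window offers no candidate. Components of
   discarded short traces (< `min_nodes`) stay claimed.

Defaults: `max_link_um` = 0.5 µm (about one shaft diameter per 1 µm axial
step), `gap_tolerance` = 1 slice (bridges single-slice segmentation
dropouts; the gap contributes its straight-line distance to length),
`min_nodes` = 2 (a structure must persist across two slices to count).
One rule ambiguity was settled deliberately: when the nearest slice of the
gap window holds only components beyond `max_link_um`, the tracer keeps
scanning the rest of the window rather than terminating. The rule set is
frozen by `trace_fls_reference`, a literal, unoptimized transcription used
as the test oracle; the two implementations are compared on thousands of
random instances.

Components unreachable from slice 0 are left untraced by design — a
structure without a base is not an FLS under the base-anchored definition.

## Morphometrics

Path length is the polygonal 3D arc length through node centroids with
anisotropic scaling — not a smoothed spline, which would be biased for the
generator's polyline truth and adds a free parameter. Straightness is
end-to-end distance over path length, the standard tortuosity-type index:
1 for straight structures, below 1 for curved ones; it is undefined (error)
for degenerate zero-length traces. Base area is the pixel count of the
slice-0 component scaled by the pixel area. Region summaries are the count
and arithmetic means over the structures of one imaging region.

## Phenotype features and embedding

The per-condition vector has exactly six features: median FLS count, median
per-region mean length, median per-region mean base area, each in the
no-added-actin and added-actin states. "Median average" is strictly
median-over-regions of mean-over-FLS, and a test asserts this composition
on data where the two orders disagree. Straightness is measured but
excluded from the embedding features. Features are standardised per column
(zero mean, unit population sd); a constant column maps to zeros with a
warning rather than NaNs. Rows are sorted by condition label before
embedding so results are independent of input order.

t-SNE runs at perplexity 2.49 and early exaggeration 12 with 2 output
dimensions. The low perplexity suits a screen of a few dozen conditions
where each condition has only a couple of true phenotypic neighbours.
Initialisation is random from the caller's seed (recorded in the result for
provenance), and identical seed + input reproduce coordinates bitwise.

## Linescan presence score

For each image, the threshold is the mean of the background-linescan maxima
plus one sample sd (ddof = 1) of those maxima — sample sd because
background sets are small. A filopodium is positive iff its linescan
maximum strictly exceeds the threshold. With a single background linescan
the statistics fall back to that linescan's samples. Backgrounds are pooled
per image rather than paired per filopodium; pairing is noisier and the
pooled reading is the natural one for thresholds built "per image".

A structural property of this 1-sd rule, quantified here on synthetic data:
negatives are exchangeable with background, and the threshold sits near the
86th percentile of the background-maximum distribution, so about 14% of
true negatives score positive. The estimated positive fraction is therefore
biased upward by roughly `(1 − p)·0.14`. At high prevalence (p ≈ 0.9, the
regime the score is used in) the bias is small; at low prevalence it
dominates the sampling error. The package reports the raw fraction, as the
rule defines it, and does not bias-correct.

KS comparisons use the standard two-sample statistic with the asymptotic
p-value. In a four-way comparison family, the familywise levels
0.05/0.01/0.001 are Bonferroni-divided by 4 into per-comparison tiers
0.0125/0.0025/0.00025; tier assignment is a pure function of p.

## Synthetic data generator

Filaments are polylines in µm starting on the base plane with strictly
increasing z: one vertex per z-step, lateral displacement a cumulative
Gaussian walk with per-step sd `curvature_scale` (0 gives straightness
exactly 1; larger values lower it continuously). Rendering paints, per
slice, a filled disk at the polyline position — the base radius
(0.4–0.6 µm) at slice 0, the shaft radius (0.2 µm) above — then blurs each
slice with a Gaussian PSF (σ = 1 px) and adds constant background (100
a.u.) plus zero-mean Gaussian noise (sd 20 a.u. against 400 a.u. peaks,
SNR 20). Ground truth (arc length, straightness, base area = πr²) is
computed from the polyline and radius before rasterization, so the truth
channel is exact. Base centres are rejection-sampled with a minimum
pairwise separation (default 3 µm). Default stacks are 18 × 256 × 256
voxels with 20 filaments of 3–15 µm.

The generator reproduces the features the pipeline depends on — base-rooted
bright filaments, disk-like bases, tunable curvature, PSF blur, additive
noise — and deliberately omits optical realism: no depth-dependent PSF,
photobleaching, Poisson shot noise (available as a conceptual extension,
off by default), autofluorescent debris, or crossing/merging structures.
Passing recovery tests therefore demonstrates correctness of the
measurement chain under its stated assumptions, not robustness to
real-microscopy artefacts such as touching structures or uneven
illumination.

Linescan datasets draw Gaussian background profiles (mean 100, sd 10, 50
samples); positives add a 100–500 a.u. peak at one sample; every filopodium
gets a paired pure-noise background linescan. Phenotype tables draw
region-level summaries (10–17 regions per condition by default, both actin
states, counts ~30/45 and lengths ~8/11 µm without/with added actin) with
cluster mean-shifts planted via `effect_sizes`.

## Numerical and degenerate-input conventions

- Thresholding sd: population (ddof = 0); scoring sd: sample (ddof = 1).
- Strict `>` in both thresholding and presence calls, so flat images and
  background-identical filopodia yield nothing.
- Empty masks, empty regions and zero-filament configs are valid and yield
  empty outputs; single-row feature matrices, infeasible perplexities,
  inverted DoG sigmas and non-positive calibrations raise errors.
- All stochastic stages take explicit seeds; CSV writers emit exact
  round-trip float formatting, and rerunning any stage on the same inputs
  reproduces output files byte-for-byte.

## Validation problem sizes

The shipped validation uses 10 stacks of 20 filaments for recovery, 1000
random instances for tracer-oracle agreement, 20 screen draws of 23
conditions for embedding separation, and n = 400 linescans per planted
fraction — sizes at which the checked properties are already stable while
the whole suite runs in well under a minute.
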