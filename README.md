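# flsquant

Quantification of **filopodia-like structures (FLS)** — actin bundles that
grow from a supported lipid bilayer into cell extract — from confocal
z-stacks, as used in antibody-perturbation screens of filopodia formation.
The package is for researchers running reconstitution screens who need
per-structure morphometrics, per-condition phenotype profiles, and
marker-presence scores, all reproducible from configuration and seed.

## What it computes

**Segmentation and tracing.** Each z-slice is band-pass filtered with a 2D
Difference of Gaussians, `DoG(I) = G_{σ₁}*I − G_{σ₂}*I` (σ₁ < σ₂), and
thresholded at `mean + k·sd` of the filtered slice. The resulting
8-connected components are linked from the base plane (slice 0) upward by a
deterministic greedy tracer: seeds are processed in descending base area,
and each trace claims the nearest unclaimed component (Euclidean, in µm)
within `max_link_um` in the next slices of its gap window.

**Morphometrics.** For a trace with node centroids `p₀…p_n` (anisotropic
scaling: µm/px laterally, µm/slice axially):

- path length `L = Σᵢ ‖pᵢ₊₁ − pᵢ‖`
- straightness `S = ‖p_n − p₀‖ / L ∈ (0, 1]`
- base area `A = (slice-0 component area in px) · (µm/px)²`

Regions are summarised by FLS count and the means of `L`, `S`, `A`.

**Phenotype embedding.** Each condition becomes a six-feature vector — the
median FLS count, median per-region mean length, and median per-region mean
base area, each with and without supplemental actin — standardised per
column and embedded in 2D by t-SNE with perplexity 2.49 and early
exaggeration 12.

**Linescan scoring.** A marker is present in a filopodium when the maximum
of its linescan strictly exceeds `mean + 1·sd` of the per-image background
linescan maxima. Distributions are compared with the two-sample
Kolmogorov–Smirnov test under four-way Bonferroni tiers
(`*` p < 0.0125, `**` p < 0.0025, `***` p < 0.00025).

A synthetic-data module generates stacks, linescans and phenotype tables
with exact ground truth, so every stage can be validated end to end.

## Worked example

```bash
python examples/01_quantify_synthetic_stack.py
```

```
stack: (18, 256, 256) voxels, 0.1 um/px, 1.0 um/slice

recovered FLS count:   20  (truth: 20)
mean path length (um): 9.14  (truth: 9.14)
mean straightness:     0.992  (truth: 0.992)
mean base area (um^2): 0.69  (truth: 0.81)
```

All 20 planted filaments are recovered as traces; the mean 3D path length
and straightness match the generator's polyline truth, while base area is
mildly underestimated (thresholding trims the dim rim of the base disk).
`examples/02_phenotype_embedding.py` and `examples/03_linescan_scoring.py`
walk through the screen-level embedding and the marker-presence score; the
`flsquant` CLI (`simulate`, `quantify`, `embed`, `score`, `all`) runs the
same stages on TIFF/CSV inputs and writes CSV outputs plus a JSON manifest
that makes each run bit-for-bit reproducible.

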