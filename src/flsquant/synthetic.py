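"""Synthetic FLS imagery, linescan datasets, and phenotype tables.

The generators emulate the statistical structure of a reconstituted-
filopodia screen so the full analysis pipeline can be exercised — and its
recovery of known ground truth measured — without any microscopy download.

A synthetic stack contains bright filaments rooted on the base plane
(slice 0), growing upward with a smooth lateral random walk (cumulative
Gaussian offsets per slice, scaled by ``curvature_scale``), rendered as a
filled base disk at slice 0 and a narrower shaft disk above, blurred per
slice with a Gaussian PSF and overlaid on constant background plus additive
Gaussian noise.  Ground-truth arc length, straightness and base area are
computed from the polyline and base radius before rasterization, so the
truth channel is exact.

Linescan datasets pair each filopodium profile with a background profile of
pure noise; true positives carry an added peak.  Phenotype tables plant
cluster structure (mean shifts on count / length / base area) across
conditions measured in both actin-supplementation states, mimicking
region-level screen summaries with 10-17 imaging regions per condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .scoring import Linescan
from .segmentation import ImageStack

__all__ = [
    "FilamentSpec",
    "SyntheticStackConfig",
    "GroundTruthRecord",
    "LinescanDatasetConfig",
    "generate_fls_stack",
    "generate_linescan_dataset",
    "generate_phenotype_conditions",
]


@dataclass(frozen=True)
class FilamentSpec:
    """Geometric ground truth for one synthetic filament.

    The polyline is an ordered chain of (x, y, z) points in µm with strictly
    increasing z starting at z = 0; the base is a disk of ``base_radius`` µm
    centred at ``base_center`` on the base plane.
    """

    base_center: tuple[float, float]
    base_radius: float
    polyline: tuple[tuple[float, float, float], ...]
    peak_intensity: float

    def __post_init__(self) -> None:
        if self.base_radius <= 0 or self.peak_intensity <= 0:
            raise ValueError("base_radius and peak_intensity must be > 0")
        if len(self.polyline) < 2:
            raise ValueError("polyline needs at least 2 points")
        zs = [p[2] for p in self.polyline]
        if zs[0] != 0:
            raise ValueError("polyline must start at z = 0")
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("polyline z values must be strictly increasing")

    @property
    def arc_length_um(self) -> float:
        return float(
            sum(math.dist(a, b) for a, b in zip(self.polyline, self.polyline[1:]))
        )

    @property
    def straightness_true(self) -> float:
        return float(math.dist(self.polyline[0], self.polyline[-1]) / self.arc_length_um)


@dataclass(frozen=True)
class GroundTruthRecord:
    """Truth-channel row for one generated filament."""

    filament_id: int
    arc_length_um: float
    straightness_true: float
    base_area_um2: float
    base_centroid_px: tuple[float, float]


@dataclass
class SyntheticStackConfig:
    """Study conditions for one synthetic z-stack.

    Defaults: 0.1 µm/px laterally and 1.0 µm z-spacing (a 100x objective and
    whole-structure confocal stacks), shafts of 0.2 µm radius on 0.4-0.6 µm
    base disks, and lengths spanning a few to ~15 µm.
    """

    image_shape: tuple[int, int, int] = (18, 256, 256)  # (n_slices, h, w)
    pixel_size_xy: float = 0.1
    z_step: float = 1.0
    n_filaments: int = 20
    length_range: tuple[float, float] = (3.0, 15.0)
    curvature_scale: float = 0.1
    psf_sigma_xy: float = 1.0
    background_level: float = 100.0
    noise_sd: float = 20.0
    peak_intensity: float = 400.0
    base_radius_range_um: tuple[float, float] = (0.4, 0.6)
    shaft_radius_um: float = 0.2
    min_separation_um: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_slices, h, w = self.image_shape
        if n_slices < 1 or h < 8 or w < 8:
            raise ValueError("image_shape too small")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("calibrations must be positive")
        if self.n_filaments < 0:
            raise ValueError("n_filaments must be >= 0")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("length_range must satisfy 0 < min <= max")
        if hi > n_slices * self.z_step:
            raise ValueError(
                "maximum length exceeds the axial extent of the stack "
                f"({hi} µm > {n_slices * self.z_step} µm)"
            )
        if self.curvature_scale < 0 or self.psf_sigma_xy < 0:
            raise ValueError("curvature_scale and psf_sigma_xy must be >= 0")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background_level and noise_sd must be >= 0")
        if self.peak_intensity <= 0 or self.shaft_radius_um <= 0:
            raise ValueError("peak_intensity and shaft_radius_um must be > 0")
        rlo, rhi = self.base_radius_range_um
        if not (0 < rlo <= rhi):
            raise ValueError("base_radius_range_um must satisfy 0 < min <= max")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be >= 0")


@dataclass
class LinescanDatasetConfig:
    """Study conditions for a synthetic marker-presence linescan dataset."""

    n_filopodia: int = 400
    positive_fraction: float = 0.7
    background_mean: float = 100.0
    background_sd: float = 10.0
    positive_delta: float = 100.0
    samples_per_linescan: int = 50
    n_images: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_filopodia < 0:
            raise ValueError("n_filopodia must be >= 0")
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.positive_delta < 0:
            raise ValueError("positive_delta must be >= 0")
        if self.samples_per_linescan < 2:
            raise ValueError("samples_per_linescan must be >= 2")
        if self.background_mean < 0 or self.background_sd < 0:
            raise ValueError("background parameters must be >= 0")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


# ---------------------------------------------------------------------------
# Stack generation
# ---------------------------------------------------------------------------


def _draw_base_centers(
    rng: np.random.Generator, cfg: SyntheticStackConfig
) -> list[tuple[float, float]]:
    """Rejection-sample base centres (µm) with pairwise separation >= minimum."""
    if cfg.n_filaments == 0:
        return []
    _, h, w = cfg.image_shape
    margin = max(cfg.base_radius_range_um[1], cfg.min_separation_um / 2) + 0.5
    x_hi = w * cfg.pixel_size_xy - margin
    y_hi = h * cfg.pixel_size_xy - margin
    if x_hi <= margin or y_hi <= margin:
        raise ValueError("field of view too small for the requested filaments")
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 * max(cfg.n_filaments, 1)
    while len(centers) < cfg.n_filaments:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not place filaments with the requested separation; "
                "reduce n_filaments or min_separation_um"
            )
        x = rng.uniform(margin, x_hi)
        y = rng.uniform(margin, y_hi)
        if all(
            math.hypot(x - cx, y - cy) >= cfg.min_separation_um
            for cx, cy in centers
        ):
            centers.append((x, y))
    return centers


def _build_filament(
    rng: np.random.Generator,
    cfg: SyntheticStackConfig,
    center: tuple[float, float],
) -> FilamentSpec:
    target_len = rng.uniform(*cfg.length_range)
    n_steps = max(1, int(round(target_len / cfg.z_step)))
    n_slices = cfg.image_shape[0]
    n_steps = min(n_steps, n_slices - 1) if n_slices > 1 else 1
    # Smooth lateral random walk: cumulative Gaussian offsets per z-step.
    dx = rng.normal(0.0, cfg.curvature_scale, size=n_steps)
    dy = rng.normal(0.0, cfg.curvature_scale, size=n_steps)
    xs = center[0] + np.concatenate([[0.0], np.cumsum(dx)])
    ys = center[1] + np.concatenate([[0.0], np.cumsum(dy)])
    zs = cfg.z_step * np.arange(n_steps + 1, dtype=float)
    polyline = tuple(
        (float(x), float(y), float(z)) for x, y, z in zip(xs, ys, zs)
    )
    return FilamentSpec(
        base_center=center,
        base_radius=float(rng.uniform(*cfg.base_radius_range_um)),
        polyline=polyline,
        peak_intensity=cfg.peak_intensity,
    )


def _paint_disk(
    image: np.ndarray, cx_px: float, cy_px: float, radius_px: float, value: float
) -> None:
    """Set pixels within radius of (cx, cy) to at least ``value`` (in place)."""
    h, w = image.shape
    r = int(math.ceil(radius_px)) + 1
    row_lo = max(0, int(math.floor(cy_px)) - r)
    row_hi = min(h, int(math.ceil(cy_px)) + r + 1)
    col_lo = max(0, int(math.floor(cx_px)) - r)
    col_hi = min(w, int(math.ceil(cx_px)) + r + 1)
    if row_lo >= row_hi or col_lo >= col_hi:
        return
    rows = np.arange(row_lo, row_hi)[:, None]
    cols = np.arange(col_lo, col_hi)[None, :]
    inside = (rows - cy_px) ** 2 + (cols - cx_px) ** 2 <= radius_px**2
    patch = image[row_lo:row_hi, col_lo:col_hi]
    patch[inside] = np.maximum(patch[inside], value)


def generate_fls_stack(
    config: SyntheticStackConfig,
) -> tuple[ImageStack, list[GroundTruthRecord]]:
    """Render a synthetic z-stack and its exact ground-truth table.

    Per slice, each filament paints a filled disk at its polyline position
    for that z (the base radius at slice 0, the narrower shaft radius
    above); each slice is then blurred with a Gaussian of ``psf_sigma_xy``
    pixels and offset by the background level plus zero-mean Gaussian noise.
    Identical configs (including seed) give bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_slices, h, w = cfg.image_shape

    centers = _draw_base_centers(rng, cfg)
    filaments = [_build_filament(rng, cfg, c) for c in centers]

    volume = np.zeros((n_slices, h, w), dtype=float)
    truth: list[GroundTruthRecord] = []
    for fid, fil in enumerate(filaments):
        for x_um, y_um, z_um in fil.polyline:
            z = int(round(z_um / cfg.z_step))
            if z >= n_slices:
                continue
            radius_um = fil.base_radius if z == 0 else cfg.shaft_radius_um
            _paint_disk(
                volume[z],
                x_um / cfg.pixel_size_xy,
                y_um / cfg.pixel_size_xy,
                radius_um / cfg.pixel_size_xy,
                fil.peak_intensity,
            )
        truth.append(
            GroundTruthRecord(
                filament_id=fid,
                arc_length_um=fil.arc_length_um,
                straightness_true=fil.straightness_true,
                base_area_um2=math.pi * fil.base_radius**2,
                base_centroid_px=(
                    fil.base_center[0] / cfg.pixel_size_xy,
                    fil.base_center[1] / cfg.pixel_size_xy,
                ),
            )
        )

    if cfg.psf_sigma_xy > 0:
        for z in range(n_slices):
            volume[z] = ndimage.gaussian_filter(
                volume[z], cfg.psf_sigma_xy, mode="reflect"
            )
    volume += cfg.background_level
    if cfg.noise_sd > 0:
        volume += rng.normal(0.0, cfg.noise_sd, size=volume.shape)
    np.clip(volume, 0.0, None, out=volume)

    stack = ImageStack(
        voxels=volume,
        pixel_size_xy=cfg.pixel_size_xy,
        z_step=cfg.z_step,
        region_id=f"synthetic_seed{cfg.seed}",
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Linescan generation
# ---------------------------------------------------------------------------


def generate_linescan_dataset(
    config: LinescanDatasetConfig,
) -> tuple[list[Linescan], dict[str, bool]]:
    """Paired filopodium/background linescans with known presence labels.

    Every filopodium linescan is Gaussian background noise; true positives
    additionally carry a peak of height ``positive_delta`` at a random
    sample.  Each filopodium gets a paired pure-noise background linescan in
    the same image.  Returns the linescans plus ``{filopodium_id: label}``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    labels_drawn = rng.random(cfg.n_filopodia) < cfg.positive_fraction

    scans: list[Linescan] = []
    labels: dict[str, bool] = {}
    for i in range(cfg.n_filopodia):
        image_id = f"img{i % cfg.n_images:03d}"
        fid = f"fil{i:04d}"
        base = rng.normal(
            cfg.background_mean, cfg.background_sd, size=cfg.samples_per_linescan
        )
        profile = base.copy()
        if labels_drawn[i]:
            peak_at = int(rng.integers(cfg.samples_per_linescan))
            profile[peak_at] += cfg.positive_delta
        bg = rng.normal(
            cfg.background_mean, cfg.background_sd, size=cfg.samples_per_linescan
        )
        scans.append(
            Linescan(
                intensities=tuple(float(v) for v in np.clip(profile, 0.0, None)),
                role="filopodium",
                image_id=image_id,
                filopodium_id=fid,
            )
        )
        scans.append(
            Linescan(
                intensities=tuple(float(v) for v in np.clip(bg, 0.0, None)),
                role="background",
                image_id=image_id,
                filopodium_id=None,
            )
        )
        labels[fid] = bool(labels_drawn[i])
    return scans, labels


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

# Region-level baselines: (fls_count, mean_length_um, mean_base_area_um2,
# mean_straightness) for each actin state.  Actin supplementation raises
# count and length, as in the screen's paired no-actin / added-actin design.
_BASELINES = {
    "none_added": (30.0, 8.0, 0.7, 0.92),
    "actin_added": (45.0, 11.0, 0.8, 0.92),
}


def generate_phenotype_conditions(
    n_conditions: int,
    n_regions_per_condition: int | None,
    cluster_assignments: list[int],
    effect_sizes: dict[int, tuple[float, float, float]],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Region-summary table for a synthetic screen with planted clusters.

    One row per (condition, actin state, region) with columns region_id,
    condition, actin_state, fls_count, mean_length_um, mean_base_area_um2,
    mean_straightness.  Condition 0 is the control ("C"); the others are
    labelled scFv01, scFv02, ...  ``cluster_assignments[i]`` maps condition
    i to a cluster whose ``effect_sizes`` entry shifts the baseline
    (count, length µm, base area µm²) means; cluster 0 conventionally has
    zero shift.  ``noise_sd`` scales region-to-region sampling noise.  When
    ``n_regions_per_condition`` is None, each condition draws 10-17 regions.
    """
    if len(cluster_assignments) != n_conditions:
        raise ValueError(
            f"cluster_assignments has {len(cluster_assignments)} entries "
            f"for {n_conditions} conditions"
        )
    for cl in set(cluster_assignments):
        if cl not in effect_sizes:
            raise ValueError(f"no effect_sizes entry for cluster {cl}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    names = ["C"] + [f"scFv{i:02d}" for i in range(1, n_conditions)]
    # Per-feature noise scales, multiplied by noise_sd.
    count_sd, length_sd, area_sd, straight_sd = 5.0, 1.0, 0.08, 0.03

    rows = []
    for ci, (name, cluster) in enumerate(zip(names, cluster_assignments)):
        d_count, d_length, d_area = effect_sizes[cluster]
        if n_regions_per_condition is None:
            n_regions = int(rng.integers(10, 18))
        else:
            n_regions = n_regions_per_condition
        for state in ("none_added", "actin_added"):
            b_count, b_length, b_area, b_straight = _BASELINES[state]
            for r in range(n_regions):
                count = b_count + d_count + rng.normal(0, count_sd * noise_sd)
                length = b_length + d_length + rng.normal(0, length_sd * noise_sd)
                area = b_area + d_area + rng.normal(0, area_sd * noise_sd)
                straight = b_straight + rng.normal(0, straight_sd * noise_sd)
                rows.append(
                    {
                        "region_id": f"{name}_{state}_r{r:02d}",
                        "condition": name,
                        "actin_state": state,
                        "fls_count": max(0, int(round(count))),
                        "mean_length_um": max(0.5, length),
                        "mean_base_area_um2": max(0.05, area),
                        "mean_straightness": float(np.clip(straight, 0.05, 1.0)),
                    }
                )
    return pd.DataFrame(rows)
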