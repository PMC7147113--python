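"""Per-trace morphometrics and per-region summaries.

Length is the cumulative 3D Euclidean distance through the node centroids
with anisotropic scaling (µm laterally via the pixel size, µm axially via
the z-step); straightness is the end-to-end distance divided by that path
length (1 for a perfectly straight structure); base area is the pixel area
of the slice-0 component converted to µm².  Gap slices contribute their
straight-line distance.  Region summaries follow the convention that each
data point is the mean over the FLS of one imaging region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .tracing import FlsTrace

__all__ = [
    "FlsMeasures",
    "RegionSummary",
    "path_length",
    "straightness",
    "base_area",
    "measure_trace",
    "summarize_region",
]


@dataclass(frozen=True)
class FlsMeasures:
    """Morphometrics of one traced FLS."""

    trace_id: int
    path_length_um: float
    straightness: float
    base_area_um2: float
    n_nodes: int


@dataclass(frozen=True)
class RegionSummary:
    """Aggregate phenotype of one imaging region.

    Means are ``None`` when the region holds no FLS (``fls_count == 0``).
    """

    region_id: str
    condition: str
    actin_state: str
    fls_count: int
    mean_length_um: float | None
    mean_base_area_um2: float | None
    mean_straightness: float | None


def _node_positions_um(
    trace: FlsTrace, pixel_size_xy: float, z_step: float
) -> list[tuple[float, float, float]]:
    if pixel_size_xy <= 0 or z_step <= 0:
        raise ValueError("calibrations must be positive")
    return [
        (
            n.centroid[0] * pixel_size_xy,
            n.centroid[1] * pixel_size_xy,
            n.slice_index * z_step,
        )
        for n in trace.nodes
    ]


def path_length(trace: FlsTrace, pixel_size_xy: float, z_step: float) -> float:
    """Cumulative 3D distance along the trace's centroid chain, in µm.

    A single-node trace has length 0.
    """
    pts = _node_positions_um(trace, pixel_size_xy, z_step)
    return float(
        sum(math.dist(a, b) for a, b in zip(pts, pts[1:]))
    )


def straightness(trace: FlsTrace, pixel_size_xy: float, z_step: float) -> float:
    """End-to-end 3D distance over path length; in (0, 1], 1 when straight."""
    if trace.n_nodes < 2:
        raise ValueError("straightness needs at least two nodes")
    pts = _node_positions_um(trace, pixel_size_xy, z_step)
    total = sum(math.dist(a, b) for a, b in zip(pts, pts[1:]))
    if total == 0:
        raise ValueError("degenerate trace with zero path length")
    return float(math.dist(pts[0], pts[-1]) / total)


def base_area(trace: FlsTrace, pixel_size_xy: float) -> float:
    """Area of the slice-0 component in µm² (pixel count × pixel area)."""
    if pixel_size_xy <= 0:
        raise ValueError("pixel_size_xy must be positive")
    return float(trace.base_component.area_px * pixel_size_xy**2)


def measure_trace(trace: FlsTrace, pixel_size_xy: float, z_step: float) -> FlsMeasures:
    """Bundle length, straightness and base area for one trace."""
    return FlsMeasures(
        trace_id=trace.trace_id,
        path_length_um=path_length(trace, pixel_size_xy, z_step),
        straightness=straightness(trace, pixel_size_xy, z_step),
        base_area_um2=base_area(trace, pixel_size_xy),
        n_nodes=trace.n_nodes,
    )


def summarize_region(
    measures: list[FlsMeasures],
    region_id: str,
    condition: str = "",
    actin_state: str = "none_added",
) -> RegionSummary:
    """Count and arithmetic means over the FLS of one imaging region."""
    n = len(measures)
    if n == 0:
        return RegionSummary(
            region_id=region_id,
            condition=condition,
            actin_state=actin_state,
            fls_count=0,
            mean_length_um=None,
            mean_base_area_um2=None,
            mean_straightness=None,
        )
    return RegionSummary(
        region_id=region_id,
        condition=condition,
        actin_state=actin_state,
        fls_count=n,
        mean_length_um=sum(m.path_length_um for m in measures) / n,
        mean_base_area_um2=sum(m.base_area_um2 for m in measures) / n,
        mean_straightness=sum(m.straightness for m in measures) / n,
    )
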