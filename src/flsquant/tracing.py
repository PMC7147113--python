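"""Greedy base-up linking of per-slice components into FLS traces.

An FLS is anchored at the base plane: every trace starts from a slice-0
component and is extended upward slice by slice.  The linker is trace-major
greedy — one trace is completed before the next is started — with seeds
processed in descending base area, on the rationale that large bases mark
the most confident structures.  All ties are broken by (y, x) centroid
order so the result is independent of input list ordering.

Linking rule, normative and frozen by :func:`trace_fls_reference`:

1. Seed one trace per slice-0 component, in descending ``area_px``
   (ties: ascending (y, x) centroid).
2. To extend a trace whose last node sits at slice ``s``, scan candidate
   slices ``s+1 .. s+1+gap_tolerance`` in order; at the first slice holding
   an unclaimed component whose lateral centroid distance (Euclidean, µm)
   is <= ``max_link_um``, claim the nearest such component (ties: (y, x)).
3. Terminate the trace when the whole gap window holds no candidate.
4. Discard traces with fewer than ``min_nodes`` nodes (their components stay
   claimed: a discarded short stub never re-enters another trace).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .segmentation import SliceComponent

__all__ = ["TraceConfig", "FlsTrace", "trace_fls", "trace_fls_reference"]


@dataclass
class TraceConfig:
    """Parameters of the greedy linker.

    max_link_um
        Maximum lateral centroid displacement per linking step, in µm
        (default 0.5 µm, of the order of one shaft diameter).
    gap_tolerance
        Number of consecutive slices a trace may skip (default 1, bridging
        single-slice segmentation dropouts).
    min_nodes
        Minimum nodes for a trace to count as an FLS (default 2: the
        structure must persist across at least two slices).
    """

    max_link_um: float = 0.5
    gap_tolerance: int = 1
    min_nodes: int = 2

    def __post_init__(self) -> None:
        if self.max_link_um <= 0:
            raise ValueError("max_link_um must be > 0")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be >= 0")
        if self.min_nodes < 1:
            raise ValueError("min_nodes must be >= 1")


@dataclass
class FlsTrace:
    """An ordered base-to-tip chain of slice components forming one FLS."""

    trace_id: int
    nodes: list[SliceComponent]

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("a trace needs at least one node")
        if self.nodes[0].slice_index != 0:
            raise ValueError("traces must start at the base slice (index 0)")
        slices = [n.slice_index for n in self.nodes]
        if any(b <= a for a, b in zip(slices, slices[1:])):
            raise ValueError("node slice indices must be strictly increasing")

    @property
    def base_component(self) -> SliceComponent:
        return self.nodes[0]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _seed_order_key(comp: SliceComponent) -> tuple[float, float, float]:
    return (-comp.area_px, comp.centroid[1], comp.centroid[0])


def trace_fls(
    per_slice_components: list[list[SliceComponent]],
    config: TraceConfig | None = None,
    pixel_size_xy: float = 1.0,
) -> list[FlsTrace]:
    """Link per-slice components into FLS traces with the greedy rule.

    ``per_slice_components`` is indexed by slice, slice 0 first (it may be
    empty).  Distances are evaluated in µm via ``pixel_size_xy``.  Every
    component is used at most once; the output is fully deterministic.
    """
    cfg = config or TraceConfig()
    if pixel_size_xy <= 0:
        raise ValueError("pixel_size_xy must be > 0")
    if not per_slice_components:
        raise ValueError("need component lists indexed by slice (slice 0 present)")

    n_slices = len(per_slice_components)
    claimed: set[int] = set()  # id() keys of claimed components
    seeds = sorted(per_slice_components[0], key=_seed_order_key)

    traces: list[FlsTrace] = []
    next_id = 0
    for seed in seeds:
        if id(seed) in claimed:
            continue
        claimed.add(id(seed))
        nodes = [seed]
        current = seed
        while True:
            nxt = _best_link(
                per_slice_components, current, claimed, cfg, pixel_size_xy, n_slices
            )
            if nxt is None:
                break
            claimed.add(id(nxt))
            nodes.append(nxt)
            current = nxt
        if len(nodes) >= cfg.min_nodes:
            traces.append(FlsTrace(trace_id=next_id, nodes=nodes))
            next_id += 1
    return traces


def _best_link(
    per_slice: list[list[SliceComponent]],
    current: SliceComponent,
    claimed: set[int],
    cfg: TraceConfig,
    pixel_size_xy: float,
    n_slices: int,
) -> SliceComponent | None:
    cx, cy = current.centroid
    lo = current.slice_index + 1
    hi = min(current.slice_index + 1 + cfg.gap_tolerance, n_slices - 1)
    for z in range(lo, hi + 1):
        best: SliceComponent | None = None
        best_key: tuple[float, float, float] | None = None
        for comp in per_slice[z]:
            if id(comp) in claimed:
                continue
            dx = (comp.centroid[0] - cx) * pixel_size_xy
            dy = (comp.centroid[1] - cy) * pixel_size_xy
            dist = math.hypot(dx, dy)
            if dist > cfg.max_link_um:
                continue
            key = (dist, comp.centroid[1], comp.centroid[0])
            if best_key is None or key < best_key:
                best, best_key = comp, key
        if best is not None:
            return best
    return None


# ---------------------------------------------------------------------------
# Literal reference implementation (test oracle)
# ---------------------------------------------------------------------------

_ORACLE_MAX_SLICES = 8
_ORACLE_MAX_PER_SLICE = 5


def trace_fls_reference(
    per_slice_components: list[list[SliceComponent]],
    config: TraceConfig | None = None,
    pixel_size_xy: float = 1.0,
) -> list[FlsTrace]:
    """Unoptimized literal transcription of the greedy linking rule.

    Written independently of :func:`trace_fls` as a reference for tests;
    guarded to small instances (<= 8 slices, <= 5 components per slice).
    """
    cfg = config or TraceConfig()
    if len(per_slice_components) > _ORACLE_MAX_SLICES or any(
        len(comps) > _ORACLE_MAX_PER_SLICE for comps in per_slice_components
    ):
        raise ValueError("reference tracer only accepts small instances")
    if pixel_size_xy <= 0:
        raise ValueError("pixel_size_xy must be > 0")
    if not per_slice_components:
        raise ValueError("need component lists indexed by slice")

    # Step 1: seeds in descending base area, (y, x) tie-break.
    seeds = list(per_slice_components[0])
    seeds.sort(key=lambda c: (c.centroid[1], c.centroid[0]))
    seeds.sort(key=lambda c: c.area_px, reverse=True)

    used: list[SliceComponent] = []
    all_traces: list[list[SliceComponent]] = []
    for seed in seeds:
        if any(seed is u for u in used):
            continue
        used.append(seed)
        chain = [seed]
        while True:
            last = chain[-1]
            # Step 2: scan each slice of the gap window in order.
            chosen = None
            for z in range(
                last.slice_index + 1,
                last.slice_index + 2 + cfg.gap_tolerance,
            ):
                if z >= len(per_slice_components):
                    break
                candidates = []
                for comp in per_slice_components[z]:
                    if any(comp is u for u in used):
                        continue
                    d = pixel_size_xy * math.sqrt(
                        (comp.centroid[0] - last.centroid[0]) ** 2
                        + (comp.centroid[1] - last.centroid[1]) ** 2
                    )
                    if d <= cfg.max_link_um:
                        candidates.append((d, comp.centroid[1], comp.centroid[0], comp))
                if candidates:
                    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
                    chosen = candidates[0][3]
                    break
            if chosen is None:
                break  # Step 3: window exhausted.
            used.append(chosen)
            chain.append(chosen)
        all_traces.append(chain)

    # Step 4: drop short stubs.
    kept = [c for c in all_traces if len(c) >= cfg.min_nodes]
    return [FlsTrace(trace_id=i, nodes=chain) for i, chain in enumerate(kept)]
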