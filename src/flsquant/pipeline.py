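"""End-to-end orchestration: quantify stacks, embed phenotypes, score linescans.

Each run writes its output CSVs plus a JSON manifest (config hash, seed,
input hashes, package version) sufficient to reproduce the run.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io as fio
from .config import PipelineConfig
from .embedding import build_feature_matrix, embed_2d, scale_features
from .morphometrics import measure_trace, summarize_region
from .scoring import background_threshold, fraction_positive, score_filopodia
from .segmentation import ImageStack, segment_stack
from .tracing import trace_fls

__all__ = ["quantify_stack", "run_quantify", "run_embed", "run_score"]

logger = logging.getLogger("flsquant")

METADATA_COLUMNS = ("stack_path", "region_id", "condition", "actin_state")


def quantify_stack(stack: ImageStack, config: PipelineConfig) -> pd.DataFrame:
    """Segment, trace and measure one stack; returns the per-FLS table."""
    per_slice = segment_stack(stack, config.segmentation)
    traces = trace_fls(per_slice, config.tracing, stack.pixel_size_xy)
    measures = [measure_trace(t, stack.pixel_size_xy, stack.z_step) for t in traces]
    logger.info(
        "region %s: %d components on base slice, %d traces",
        stack.region_id, len(per_slice[0]), len(traces),
    )
    rows = [
        {
            "region_id": stack.region_id,
            "condition": stack.condition,
            "actin_state": stack.actin_state,
            "trace_id": m.trace_id,
            "path_length_um": m.path_length_um,
            "straightness": m.straightness,
            "base_area_um2": m.base_area_um2,
            "n_nodes": m.n_nodes,
        }
        for m in measures
    ]
    return pd.DataFrame(rows, columns=list(fio.MEASUREMENT_COLUMNS))


def run_quantify(
    input_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    metadata_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every stack listed in the metadata file.

    ``metadata_csv`` (default ``<input_dir>/metadata.csv``) maps stack files
    to region/condition/actin-state labels.  Writes measurements.csv,
    region_summaries.csv and manifest.json under ``out_dir`` and returns the
    two tables.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig()
    meta_path = Path(metadata_csv) if metadata_csv else input_dir / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata file not found: {meta_path}")
    meta = pd.read_csv(meta_path)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")

    measurement_frames = []
    summaries = []
    input_hashes = {}
    for row in meta.itertuples(index=False):
        stack_path = input_dir / str(row.stack_path)
        if not stack_path.exists():
            raise FileNotFoundError(
                f"stack listed in metadata not found: {stack_path} "
                f"(region {row.region_id})"
            )
        stack = fio.read_stack(
            stack_path,
            pixel_size_xy=cfg.pixel_size_xy,
            z_step=cfg.z_step,
            region_id=str(row.region_id),
            condition=str(row.condition),
            actin_state=str(row.actin_state),
        )
        input_hashes[str(row.stack_path)] = fio.file_sha256(stack_path)
        table = quantify_stack(stack, cfg)
        measurement_frames.append(table)
        summaries.append(
            {
                "region_id": str(row.region_id),
                "condition": str(row.condition),
                "actin_state": str(row.actin_state),
                "fls_count": len(table),
                "mean_length_um": table["path_length_um"].mean()
                if len(table) else None,
                "mean_base_area_um2": table["base_area_um2"].mean()
                if len(table) else None,
                "mean_straightness": table["straightness"].mean()
                if len(table) else None,
            }
        )

    measurements = (
        pd.concat(measurement_frames, ignore_index=True)
        if measurement_frames
        else pd.DataFrame(columns=list(fio.MEASUREMENT_COLUMNS))
    )
    region_summaries = pd.DataFrame(
        summaries, columns=list(fio.REGION_SUMMARY_COLUMNS)
    )
    measurements.to_csv(out_dir / "measurements.csv", index=False)
    region_summaries.to_csv(out_dir / "region_summaries.csv", index=False)
    fio.write_manifest(
        out_dir / "manifest.json",
        stage="quantify",
        config=cfg.to_dict(),
        config_digest=cfg.digest(),
        input_hashes=input_hashes,
        n_stacks=len(meta),
        n_traces=int(len(measurements)),
    )
    return measurements, region_summaries


def run_embed(
    region_summary_csv: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Build, scale and embed the phenotype matrix from a region-summary CSV.

    Writes phenotype_matrix.csv, embedding.csv and manifest.json; returns
    the embedding table (condition, tsne_1, tsne_2).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig()
    summaries = pd.read_csv(region_summary_csv)
    matrix = build_feature_matrix(summaries)
    scaled = scale_features(matrix)
    result = embed_2d(
        scaled,
        perplexity=cfg.perplexity,
        early_exaggeration=cfg.early_exaggeration,
        seed=cfg.embed_seed,
    )
    matrix.to_csv(out_dir / "phenotype_matrix.csv")
    result.coordinates.to_csv(out_dir / "embedding.csv")
    fio.write_manifest(
        out_dir / "manifest.json",
        stage="embed",
        config=cfg.to_dict(),
        config_digest=cfg.digest(),
        input_hashes={str(region_summary_csv): fio.file_sha256(region_summary_csv)},
        seed=cfg.embed_seed,
        n_conditions=len(matrix),
    )
    return result.coordinates.reset_index()


def run_score(
    linescan_csv: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score marker presence from a linescan CSV.

    Per image: the background threshold, then presence calls per filopodium
    and per-image positive fractions.  Writes presence_scores.csv,
    fractions.csv and manifest.json.  An image with filopodium linescans but
    no background linescans is an error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig()
    scans = fio.read_linescan_csv(linescan_csv)
    if not scans:
        raise ValueError(f"no linescans found in {linescan_csv}")

    by_image: dict[str, dict[str, list]] = {}
    for scan in scans:
        by_image.setdefault(scan.image_id, {"filopodium": [], "background": []})[
            scan.role
        ].append(scan)

    score_rows = []
    scores_by_image = {}
    for image_id in sorted(by_image):
        groups = by_image[image_id]
        if groups["filopodium"] and not groups["background"]:
            raise ValueError(f"image {image_id!r} has no background linescans")
        if not groups["filopodium"]:
            continue
        threshold = background_threshold(
            groups["background"], sd_multiplier=cfg.sd_multiplier
        )
        scores = score_filopodia(groups["filopodium"], threshold)
        scores_by_image[image_id] = scores
        score_rows.extend(
            {
                "image_id": image_id,
                "filopodium_id": s.filopodium_id,
                "max_intensity": s.max_intensity,
                "threshold": s.threshold,
                "positive": s.positive,
                "margin": s.margin,
            }
            for s in scores
        )

    presence = pd.DataFrame(
        score_rows,
        columns=["image_id", "filopodium_id", "max_intensity", "threshold",
                 "positive", "margin"],
    )
    if scores_by_image:
        per_group, overall = fraction_positive(scores_by_image)
        frac_rows = [
            {"group": g, "fraction_positive": f} for g, f in sorted(per_group.items())
        ]
        frac_rows.append({"group": "__overall__", "fraction_positive": overall})
    else:
        frac_rows = []
    fractions = pd.DataFrame(frac_rows, columns=["group", "fraction_positive"])
    presence.to_csv(out_dir / "presence_scores.csv", index=False)
    fractions.to_csv(out_dir / "fractions.csv", index=False)
    fio.write_manifest(
        out_dir / "manifest.json",
        stage="score",
        config=cfg.to_dict(),
        config_digest=cfg.digest(),
        input_hashes={str(linescan_csv): fio.file_sha256(linescan_csv)},
        n_filopodia=int(len(presence)),
    )
    return presence, fractions
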