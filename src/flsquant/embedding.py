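"""Per-condition phenotype vectors and their 2D t-SNE embedding.

Each screening condition is summarised by six features — the median FLS
count, the median of the per-region mean path length, and the median of the
per-region mean base area, each taken separately for the no-added-actin and
added-actin states.  "Median average" is median-over-regions of
mean-over-FLS, in that order.  Features are standardised per column
(zero mean, unit population SD) and embedded with t-SNE at perplexity 2.49
and early exaggeration 12 — a deliberately low perplexity suited to a
few-dozen-condition screen, where each condition has only a couple of true
phenotypic neighbours.  Conditions are sorted by label before embedding so
results do not depend on input file order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

__all__ = [
    "FEATURE_COLUMNS",
    "EmbeddingResult",
    "build_feature_matrix",
    "scale_features",
    "embed_2d",
]

FEATURE_COLUMNS = (
    "median_count_none_added",
    "median_count_actin_added",
    "median_mean_length_none_added",
    "median_mean_length_actin_added",
    "median_mean_base_area_none_added",
    "median_mean_base_area_actin_added",
)

_STATE_FEATURES = {
    "fls_count": ("median_count_none_added", "median_count_actin_added"),
    "mean_length_um": (
        "median_mean_length_none_added",
        "median_mean_length_actin_added",
    ),
    "mean_base_area_um2": (
        "median_mean_base_area_none_added",
        "median_mean_base_area_actin_added",
    ),
}

DEFAULT_PERPLEXITY = 2.49
DEFAULT_EARLY_EXAGGERATION = 12.0


@dataclass
class EmbeddingResult:
    """2D t-SNE coordinates of condition phenotype vectors, with provenance."""

    coordinates: pd.DataFrame  # index: condition; columns: tsne_1, tsne_2
    perplexity: float
    early_exaggeration: float
    seed: int
    scaled_input: pd.DataFrame


def build_feature_matrix(region_summaries: pd.DataFrame) -> pd.DataFrame:
    """Six-feature phenotype matrix: one row per condition, sorted by label.

    ``region_summaries`` needs columns condition, actin_state, fls_count,
    mean_length_um, mean_base_area_um2 with one row per imaging region.
    Each feature is the median across that condition's regions of the
    per-region value.  A condition missing either actin state is an error.
    """
    required = {"condition", "actin_state", "fls_count", "mean_length_um",
                "mean_base_area_um2"}
    missing = required - set(region_summaries.columns)
    if missing:
        raise ValueError(f"region summaries missing columns: {sorted(missing)}")

    conditions = sorted(region_summaries["condition"].unique())
    for cond in conditions:
        states = set(
            region_summaries.loc[
                region_summaries["condition"] == cond, "actin_state"
            ]
        )
        if states != {"none_added", "actin_added"}:
            raise ValueError(
                f"condition {cond!r} lacks an actin state "
                f"(has {sorted(states)}, needs both)"
            )

    rows = {}
    for cond in conditions:
        feats = {}
        for source_col, (col_none, col_added) in _STATE_FEATURES.items():
            for state, col in (("none_added", col_none), ("actin_added", col_added)):
                sub = region_summaries[
                    (region_summaries["condition"] == cond)
                    & (region_summaries["actin_state"] == state)
                ]
                feats[col] = float(sub[source_col].median())
        rows[cond] = feats
    matrix = pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_COLUMNS)]
    matrix.index.name = "condition"
    return matrix


def scale_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardise each column to zero mean and unit population SD (ddof=0).

    A constant column cannot be scaled and maps to all zeros with a warning.
    """
    if len(matrix) < 2:
        raise ValueError("scaling needs at least 2 rows")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    scaled = np.zeros_like(values)
    for j, col in enumerate(matrix.columns):
        if sd[j] == 0:
            warnings.warn(
                f"constant feature column {col!r} mapped to zeros", stacklevel=2
            )
            continue
        scaled[:, j] = (values[:, j] - mean[j]) / sd[j]
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def embed_2d(
    scaled_matrix: pd.DataFrame,
    perplexity: float = DEFAULT_PERPLEXITY,
    early_exaggeration: float = DEFAULT_EARLY_EXAGGERATION,
    seed: int = 0,
) -> EmbeddingResult:
    """t-SNE embed scaled phenotype vectors into 2D, reproducibly.

    Random initialisation from ``seed``; identical input and seed give
    identical coordinates.  Requires at least 4 rows and
    ``perplexity < n_rows - 1``.
    """
    n = len(scaled_matrix)
    if n < 4:
        raise ValueError("embedding needs at least 4 conditions")
    if not perplexity < n - 1:
        raise ValueError(
            f"perplexity {perplexity} infeasible for {n} rows (need < {n - 1})"
        )
    ordered = scaled_matrix.sort_index()
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        early_exaggeration=early_exaggeration,
        init="random",
        random_state=seed,
    )
    coords = tsne.fit_transform(ordered.to_numpy(dtype=float))
    coordinates = pd.DataFrame(
        coords, index=ordered.index, columns=["tsne_1", "tsne_2"]
    )
    return EmbeddingResult(
        coordinates=coordinates,
        perplexity=perplexity,
        early_exaggeration=early_exaggeration,
        seed=seed,
        scaled_input=ordered.copy(),
    )
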