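"""Linescan marker-presence scoring and KS tier statistics.

A marker (e.g. SNX9) is called present in a filopodium when the maximal
intensity of a linescan drawn over it exceeds the background by more than
one standard deviation: the threshold for an image is the mean of the maxima
of its background linescans plus one sample SD (ddof=1) of those maxima.
With a single background linescan the SD is instead taken within that
linescan's samples.  The call is strict (>), so a filopodium identical to a
flat background is never positive.

Morphology distributions are compared with the two-sample
Kolmogorov-Smirnov test; in a four-way comparison the familywise levels
0.05 / 0.01 / 0.001 Bonferroni-divide by 4 into the per-comparison tiers
0.0125 (*), 0.0025 (**) and 0.00025 (***).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Linescan",
    "PresenceScore",
    "TierThresholds",
    "background_threshold",
    "score_filopodia",
    "fraction_positive",
    "ks_compare_with_tiers",
]

ROLES = ("filopodium", "background")


@dataclass(frozen=True)
class Linescan:
    """An ordered 1D intensity profile sampled along a segment of an image."""

    intensities: tuple[float, ...]
    role: str
    image_id: str
    filopodium_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if len(self.intensities) < 2:
            raise ValueError("a linescan needs at least 2 samples")
        if any(v < 0 for v in self.intensities):
            raise ValueError("intensities must be non-negative")

    @property
    def max_intensity(self) -> float:
        return float(max(self.intensities))


@dataclass(frozen=True)
class PresenceScore:
    """Presence call for one filopodium against its image's background threshold."""

    filopodium_id: str
    max_intensity: float
    threshold: float
    positive: bool

    def __post_init__(self) -> None:
        if self.positive != (self.margin > 0):
            raise ValueError("positive must equal (margin > 0)")

    @property
    def margin(self) -> float:
        return self.max_intensity - self.threshold


@dataclass(frozen=True)
class TierThresholds:
    """Per-comparison significance tiers of a Bonferroni-corrected family.

    Defaults encode a four-way comparison: familywise 0.05/0.01/0.001 become
    0.0125 (*), 0.0025 (**), 0.00025 (***).
    """

    n_comparisons: int = 4
    family_alphas: tuple[float, ...] = (0.05, 0.01, 0.001)
    labels: tuple[str, ...] = ("*", "**", "***")

    def __post_init__(self) -> None:
        if len(self.family_alphas) != len(self.labels):
            raise ValueError("one label per family alpha")
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")
        if list(self.family_alphas) != sorted(self.family_alphas, reverse=True):
            raise ValueError("family alphas must be strictly decreasing")

    @property
    def tiers(self) -> dict[str, float]:
        """Mapping label -> per-comparison threshold (family alpha / n)."""
        return {
            lab: a / self.n_comparisons
            for lab, a in zip(self.labels, self.family_alphas)
        }

    def assign(self, p: float) -> str:
        """Most stringent tier whose threshold exceeds p; else ``"n.s."``."""
        label = "n.s."
        for lab, thr in self.tiers.items():
            if p < thr:
                label = lab
        return label


def background_threshold(
    background_linescans: list[Linescan], sd_multiplier: float = 1.0
) -> float:
    """Presence threshold for one image from its background linescans.

    With >= 2 backgrounds: mean of the per-linescan maxima plus
    ``sd_multiplier`` sample SDs (ddof=1) of those maxima.  With a single
    background the statistics are taken over that linescan's samples instead.
    """
    scans = [s for s in background_linescans if s.role == "background"]
    if len(scans) != len(background_linescans):
        raise ValueError("all linescans must have role 'background'")
    if not scans:
        raise ValueError("an image needs at least one background linescan")
    if sd_multiplier < 0:
        raise ValueError("sd_multiplier must be >= 0")
    if len(scans) == 1:
        samples = np.asarray(scans[0].intensities, dtype=float)
        return float(samples.mean() + sd_multiplier * samples.std(ddof=1))
    maxima = np.array([s.max_intensity for s in scans], dtype=float)
    return float(maxima.mean() + sd_multiplier * maxima.std(ddof=1))


def score_filopodia(
    filopodium_linescans: list[Linescan], threshold: float
) -> list[PresenceScore]:
    """Call each filopodium positive iff its linescan maximum strictly exceeds
    the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = []
    for scan in filopodium_linescans:
        if scan.role != "filopodium":
            raise ValueError("all linescans must have role 'filopodium'")
        m = scan.max_intensity
        scores.append(
            PresenceScore(
                filopodium_id=scan.filopodium_id or "",
                max_intensity=m,
                threshold=float(threshold),
                positive=m > threshold,
            )
        )
    return scores


def fraction_positive(
    scores_by_group: dict[str, list[PresenceScore]],
) -> tuple[dict[str, float], float]:
    """Per-group positive fractions and the pooled overall fraction."""
    if not scores_by_group:
        raise ValueError("no score groups given")
    fractions: dict[str, float] = {}
    pos = tot = 0
    for group, scores in scores_by_group.items():
        if not scores:
            raise ValueError(f"group {group!r} has no scores")
        p = sum(s.positive for s in scores)
        fractions[group] = p / len(scores)
        pos += p
        tot += len(scores)
    return fractions, pos / tot


def ks_compare_with_tiers(
    sample_a,
    sample_b,
    thresholds: TierThresholds | None = None,
) -> tuple[float, float, str]:
    """Two-sample KS comparison with Bonferroni tier labelling.

    Returns ``(D, p, tier)`` where D is the maximum ECDF gap, p the
    asymptotic two-sided p-value, and tier the label from ``thresholds``
    (``"n.s."`` when not significant at the loosest tier).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    thr = thresholds or TierThresholds()
    res = stats.ks_2samp(a, b, method="asymp")
    d, p = float(res.statistic), float(res.pvalue)
    return d, p, thr.assign(p)
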