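"""Fluorescence quantification: expression-domain detection, mean
intensity, fold change, width conversion and group-comparison statistics
(one-way ANOVA followed by Tukey HSD)."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from autoreg.synthetic_data import DEFAULT_NUCLEUS_SPACING_UM

__all__ = [
    "DomainMask",
    "ComparisonReport",
    "detect_domain",
    "mean_domain_intensity",
    "fold_change",
    "width_um_to_nuclei",
    "anova_tukey",
    "group_summary",
]


@dataclass(frozen=True)
class DomainMask:
    """Row intervals (half-open, along the dorsoventral axis) flagged as
    expression domain."""

    intervals: tuple[tuple[int, int], ...]
    pixel_um: float
    n_rows: int

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.intervals:
            if not 0 <= start < end <= self.n_rows:
                raise ValueError(f"interval ({start}, {end}) outside image bounds")
            if start < prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = end

    @property
    def is_empty(self) -> bool:
        return not self.intervals

    @property
    def width_px(self) -> int:
        return sum(end - start for start, end in self.intervals)

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_um

    def row_indicator(self) -> np.ndarray:
        """Boolean row mask of length n_rows."""
        flags = np.zeros(self.n_rows, dtype=bool)
        for start, end in self.intervals:
            flags[start:end] = True
        return flags


def detect_domain(
    image: np.ndarray,
    threshold_fraction: float = 0.5,
    pixel_um: float = 1.0,
    smooth_px: int = 3,
) -> DomainMask:
    """Detect the ventral expression band of a striped embryo image.

    The image is smoothed with a box filter, averaged along the
    anteroposterior axis into a dorsoventral profile, and thresholded at
    ``background + threshold_fraction * (max - background)`` (background
    = profile minimum).  The largest connected run of above-threshold
    rows is returned; a flat image yields an empty mask, not an error.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.isfinite(image).all():
        raise ValueError("image must be finite-valued")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    smoothed = ndimage.uniform_filter(image, size=smooth_px, mode="nearest")
    profile = smoothed.mean(axis=1)
    background, peak = profile.min(), profile.max()
    span = peak - background
    if span <= 1e-9 * max(1.0, abs(peak)):
        return DomainMask((), pixel_um, image.shape[0])
    above = profile >= background + threshold_fraction * span
    labels, n_labels = ndimage.label(above)
    if n_labels == 0:
        return DomainMask((), pixel_um, image.shape[0])
    sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n_labels + 1))
    best = int(np.argmax(sizes)) + 1
    rows = np.flatnonzero(labels == best)
    return DomainMask(((int(rows[0]), int(rows[-1]) + 1),), pixel_um, image.shape[0])


def mean_domain_intensity(image: np.ndarray, mask: DomainMask) -> float:
    """Arithmetic mean of the pixels inside the domain mask."""
    image = np.asarray(image, dtype=float)
    if mask.is_empty:
        raise ValueError("cannot average over an empty domain mask")
    if mask.n_rows != image.shape[0]:
        raise ValueError("mask does not match image height")
    return float(image[mask.row_indicator(), :].mean())


def fold_change(group_mean: float, control_mean: float) -> float:
    """Group mean divided by the control mean."""
    if control_mean <= 0:
        raise ValueError(f"control mean must be > 0, got {control_mean}")
    return group_mean / control_mean


def width_um_to_nuclei(
    width_um: float, nucleus_spacing_um: float = DEFAULT_NUCLEUS_SPACING_UM
) -> float:
    """Convert a domain width in um to a nucleus count (one decimal)."""
    if nucleus_spacing_um <= 0:
        raise ValueError("nucleus spacing must be > 0")
    if width_um < 0:
        raise ValueError("width must be >= 0")
    return round(width_um / nucleus_spacing_um, 1)


@dataclass(frozen=True)
class ComparisonReport:
    """One-way ANOVA result plus Tukey-adjusted pairwise comparisons."""

    f_stat: float
    p_value: float
    table: pd.DataFrame  # group_a, group_b, diff, p_adj, significant
    alpha: float
    degenerate: bool = False

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.table[self.table["significant"]]
        return list(zip(sig["group_a"], sig["group_b"]))


def anova_tukey(
    groups: Sequence[np.ndarray],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> ComparisonReport:
    """One-way ANOVA followed by Tukey's HSD pairwise comparisons.

    Adjusted p-values come from the studentized-range distribution
    (scipy's Tukey HSD).  Identical zero-variance input is reported as
    degenerate with F = 0 and no significant pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels must match groups in length")

    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # all observations identical: F is 0/0
        rows = [
            {"group_a": a, "group_b": b, "diff": 0.0, "p_adj": 1.0, "significant": False}
            for a, b in combinations(labels, 2)
        ]
        return ComparisonReport(
            0.0, 1.0, pd.DataFrame(rows), alpha, degenerate=True
        )

    f_stat, p_value = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        p_adj = float(tukey.pvalue[i, j])
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "diff": float(groups[i].mean() - groups[j].mean()),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return ComparisonReport(float(f_stat), float(p_value), pd.DataFrame(rows), alpha)


def group_summary(
    df: pd.DataFrame, control_label: str, value_col: str = "mean_intensity"
) -> pd.DataFrame:
    """Per-genotype mean intensity and fold change relative to the control."""
    means = df.groupby("genotype")[value_col].agg(["mean", "std", "count"])
    if control_label not in means.index:
        raise ValueError(f"control genotype {control_label!r} not in table")
    control_mean = means.loc[control_label, "mean"]
    means["fold_change"] = [fold_change(m, control_mean) for m in means["mean"]]
    return means.reset_index()
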