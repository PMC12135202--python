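"""Dosage-ratio analysis: normalized 1-copy/2-copy levels, compensation
tests, and assembly of per-genotype model inference into a panel table.

All levels are normalized by the control 2-copy mean, so the control
record has ``m2 = 1`` exactly and the control repression threshold is 1
by construction.  The ratio is the ratio of group means (not the mean of
per-embryo ratios), with a percentile bootstrap CI over embryos.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from autoreg import feedback_model, quantify

__all__ = [
    "DosageRecord",
    "CompensationResult",
    "estimate_dosage_record",
    "compensation_test",
    "genotype_panel_analysis",
]

PANEL_COLUMNS = [
    "genotype",
    "m2",
    "m1",
    "rho",
    "ci_low",
    "ci_high",
    "n2",
    "n1",
    "category",
    "K_est",
    "K_is_bound",
    "bg_est",
    "bg_is_bound",
    "n_min",
]


@dataclass(frozen=True)
class DosageRecord:
    """Normalized 2-copy/1-copy levels and their ratio for one genotype."""

    genotype: str
    m2: float
    m1: float
    rho: float
    n2: int
    n1: int
    ci_low: float = math.nan
    ci_high: float = math.nan

    def __post_init__(self) -> None:
        if self.m2 <= 0 or self.m1 <= 0:
            raise ValueError("normalized levels must be > 0")
        if self.rho <= 0:
            raise ValueError("dosage ratio must be > 0")


def estimate_dosage_record(
    genotype: str,
    two_copy: np.ndarray,
    one_copy: np.ndarray,
    control_two_copy: np.ndarray,
    n_boot: int = 2000,
    seed: int | None = None,
) -> DosageRecord:
    """Normalized dosage record with a percentile bootstrap CI for the ratio.

    Group means are divided by the control 2-copy mean; rho = m1/m2.  The
    CI resamples embryos within the 1- and 2-copy groups independently
    (the normalization constant cancels in the ratio).
    """
    two_copy = np.asarray(two_copy, dtype=float)
    one_copy = np.asarray(one_copy, dtype=float)
    control_two_copy = np.asarray(control_two_copy, dtype=float)
    if min(two_copy.size, one_copy.size, control_two_copy.size) == 0:
        raise ValueError("all measurement groups must be non-empty")
    control_mean = control_two_copy.mean()
    if control_mean <= 0:
        raise ValueError("control 2-copy mean must be > 0")

    m2 = two_copy.mean() / control_mean
    m1 = one_copy.mean() / control_mean
    rho = m1 / m2

    ci_low = ci_high = math.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx2 = rng.integers(0, two_copy.size, size=(n_boot, two_copy.size))
        idx1 = rng.integers(0, one_copy.size, size=(n_boot, one_copy.size))
        boot_rho = one_copy[idx1].mean(axis=1) / two_copy[idx2].mean(axis=1)
        ci_low, ci_high = np.percentile(boot_rho, [2.5, 97.5])

    return DosageRecord(
        genotype=genotype,
        m2=m2,
        m1=m1,
        rho=rho,
        n2=two_copy.size,
        n1=one_copy.size,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


@dataclass(frozen=True)
class CompensationResult:
    """Outcome of the 1-vs-2-copy compensation test for one genotype."""

    decision: str  # "compensated" | "loss of compensation"
    p_adj: float
    significant: bool
    alpha: float


def compensation_test(
    two_copy: np.ndarray, one_copy: np.ndarray, alpha: float = 0.05
) -> CompensationResult:
    """Test whether 1- and 2-copy levels differ (ANOVA + Tukey HSD).

    Not significantly different means the gene dose is compensated.
    """
    report = quantify.anova_tukey(
        [np.asarray(two_copy, float), np.asarray(one_copy, float)],
        alpha=alpha,
        labels=["two_copy", "one_copy"],
    )
    p_adj = float(report.table["p_adj"].iloc[0])
    significant = bool(report.table["significant"].iloc[0])
    decision = "loss of compensation" if significant else "compensated"
    return CompensationResult(decision, p_adj, significant, alpha)


def genotype_panel_analysis(
    records: list[DosageRecord],
    cat1_threshold: float = 0.9,
    cat3_threshold: float = 0.6,
) -> pd.DataFrame:
    """Categorize each genotype and infer its step-limit parameters.

    Requires a normalized panel (some record with m2 == 1, the control).
    Adds the minimal admissible Hill coefficient for ratios in (0.5, 1);
    n_min is 0 at or below the no-feedback ratio 0.5 and infinite for
    full compensation (rho clipped to 1).
    """
    if not records:
        raise ValueError("empty panel")
    if not any(math.isclose(r.m2, 1.0, rel_tol=1e-6) for r in records):
        raise ValueError("no control record (m2 == 1) found; normalize the panel first")

    rows = []
    for rec in records:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # ratio clipping handled below
            category = feedback_model.categorize(
                rec.rho, cat1_threshold=cat1_threshold, cat3_threshold=cat3_threshold
            )
            result = feedback_model.infer_step_params(category, rec.m1, rec.m2)
        rho = min(rec.rho, 1.0)
        if rho <= 0.5:
            n_min = 0.0
        elif rho >= 1.0:
            n_min = math.inf
        else:
            n_min = feedback_model.min_hill_coefficient(rho)
        rows.append(
            {
                "genotype": rec.genotype,
                "m2": rec.m2,
                "m1": rec.m1,
                "rho": rec.rho,
                "ci_low": rec.ci_low,
                "ci_high": rec.ci_high,
                "n2": rec.n2,
                "n1": rec.n1,
                "category": category,
                "K_est": result.K_est,
                "K_is_bound": result.K_is_bound,
                "bg_est": result.bg_est,
                "bg_is_bound": result.bg_is_bound,
                "n_min": n_min,
            }
        )
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)
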