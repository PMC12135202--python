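"""Viability statistics: shifted-mean bootstrap, Bonferroni correction,
percent-viable summaries, Mendelian balancer-cross expectations and
phenotype frequency tables.

The two-sample test recenters both binary samples to their combined mean,
resamples each with replacement at the original sizes, and counts how often
the bootstrap mean difference is at least as extreme as the observed one.
Replicates are pooled before shifting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ViabilityDataset",
    "CrossSpec",
    "BootstrapResult",
    "shifted_mean_bootstrap",
    "bonferroni_alpha",
    "percent_viable",
    "expected_offspring",
    "phenotype_frequencies",
    "balancer_intercross",
]


@dataclass(frozen=True)
class ViabilityDataset:
    """Binary hatch outcomes for one genotype (1 = hatched)."""

    genotype: str
    outcomes: np.ndarray
    replicate_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        outcomes = np.asarray(self.outcomes)
        if outcomes.size == 0:
            raise ValueError("outcomes must be non-empty")
        if not np.isin(outcomes, (0, 1)).all():
            raise ValueError("outcomes must be binary (0/1)")
        object.__setattr__(self, "outcomes", outcomes.astype(np.int64))
        if self.replicate_ids is not None:
            rep = np.asarray(self.replicate_ids)
            if rep.shape != outcomes.shape:
                raise ValueError("replicate_ids must match outcomes in length")
            object.__setattr__(self, "replicate_ids", rep)


@dataclass(frozen=True)
class CrossSpec:
    """A genetic cross: offspring classes with Mendelian fractions,
    lethal classes, and optional per-class survival factors."""

    parents: tuple[str, str]
    offspring: dict[str, float]
    lethal: frozenset[str] = frozenset()
    survival: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.offspring.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"raw Mendelian fractions must sum to 1, got {total}")
        unknown = set(self.lethal) - set(self.offspring)
        if unknown:
            raise ValueError(f"lethal classes not among offspring: {unknown}")
        for label, s in self.survival.items():
            if label not in self.offspring:
                raise ValueError(f"survival factor for unknown class {label!r}")
            if not 0 <= s <= 1:
                raise ValueError(f"survival factor must be in [0, 1], got {s}")


def balancer_intercross(
    mutant: str = "mut",
    balancer: str = "CyO",
    homozygote_survival: float = 1.0,
) -> CrossSpec:
    """mut/Bal x mut/Bal with lethal balancer homozygotes.

    With full homozygote survival the expected surviving classes are
    1/3 mut/mut and 2/3 mut/Bal.
    """
    hom = f"{mutant}/{mutant}"
    het = f"{mutant}/{balancer}"
    bal = f"{balancer}/{balancer}"
    survival = {} if homozygote_survival == 1.0 else {hom: homozygote_survival}
    return CrossSpec(
        parents=(het, het),
        offspring={hom: 0.25, het: 0.5, bal: 0.25},
        lethal=frozenset({bal}),
        survival=survival,
    )


@dataclass(frozen=True)
class BootstrapResult:
    p_value: float
    observed_diff: float
    n_boot: int
    n_extreme: int


def shifted_mean_bootstrap(
    control: np.ndarray,
    mutant: np.ndarray,
    n_boot: int = 10_000_000,
    seed: int | None = None,
    tie: str = "ge",
    chunk_size: int = 200_000,
) -> BootstrapResult:
    """Two-sample shifted-mean bootstrap test for equal means.

    Both samples are shifted to the combined mean, then resampled with
    replacement at their original sizes ``n_boot`` times; the p-value is
    the fraction of bootstrap replicates whose absolute mean difference
    is at least (``tie="ge"``, default) or strictly greater than
    (``tie="gt"``) the observed absolute difference.

    Both samples constant and equal is degenerate and returns p = 1.
    """
    control = np.asarray(control, dtype=float)
    mutant = np.asarray(mutant, dtype=float)
    if control.size == 0 or mutant.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if tie not in ("ge", "gt"):
        raise ValueError("tie must be 'ge' or 'gt'")

    observed = abs(control.mean() - mutant.mean())
    combined = np.concatenate([control, mutant]).mean()
    shifted_c = control - control.mean() + combined
    shifted_m = mutant - mutant.mean() + combined

    if observed == 0 and np.ptp(shifted_c) == 0 and np.ptp(shifted_m) == 0:
        return BootstrapResult(1.0, 0.0, n_boot, n_boot)

    rng = np.random.default_rng(seed)
    nc, nm = control.size, mutant.size
    n_extreme = 0
    done = 0
    while done < n_boot:
        k = min(chunk_size, n_boot - done)
        boot_c = shifted_c[rng.integers(0, nc, size=(k, nc))].mean(axis=1)
        boot_m = shifted_m[rng.integers(0, nm, size=(k, nm))].mean(axis=1)
        diffs = np.abs(boot_c - boot_m)
        if tie == "ge":
            # tolerance so float round-off does not drop exact ties
            n_extreme += int(np.sum(diffs >= observed - 1e-12))
        else:
            n_extreme += int(np.sum(diffs > observed + 1e-12))
        done += k
    return BootstrapResult(n_extreme / n_boot, observed, n_boot, n_extreme)


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Bonferroni-corrected significance level alpha / n_comparisons."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if n_comparisons < 1 or int(n_comparisons) != n_comparisons:
        raise ValueError(f"n_comparisons must be a positive integer, got {n_comparisons}")
    return alpha / n_comparisons


def percent_viable(dataset: ViabilityDataset) -> tuple[float, float]:
    """Percent of hatched embryos, with the SD across replicates.

    The across-replicate SD is NaN when no replicate structure is given.
    """
    percent = 100.0 * dataset.outcomes.mean()
    if dataset.replicate_ids is None:
        return percent, float("nan")
    per_rep = (
        pd.Series(dataset.outcomes)
        .groupby(pd.Series(dataset.replicate_ids))
        .mean()
        .to_numpy()
    )
    sd = 100.0 * per_rep.std(ddof=1) if per_rep.size > 1 else float("nan")
    return percent, sd


def expected_offspring(cross: CrossSpec) -> dict[str, float]:
    """Surviving-class fractions of a cross.

    Removes lethal classes, applies per-class survival factors, and
    renormalizes so the surviving fractions sum to 1.
    """
    weights = {
        label: frac * cross.survival.get(label, 1.0)
        for label, frac in cross.offspring.items()
        if label not in cross.lethal
    }
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("no surviving offspring classes in cross")
    return {label: w / total for label, w in weights.items()}


def phenotype_frequencies(counts: dict[str, int]) -> pd.DataFrame:
    """Proportion table for phenotype severity classes.

    Returns a frame with count and proportion per class; proportions sum
    to 1 and round-trip back to counts via the recorded total.
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("total count is zero")
    return pd.DataFrame(
        {
            "phenotype": list(counts),
            "count": list(counts.values()),
            "proportion": [c / total for c in counts.values()],
            "total": total,
        }
    )
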