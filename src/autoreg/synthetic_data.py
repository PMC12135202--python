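"""Synthetic inputs for the dosage-compensation pipeline.

Generates per-embryo intensity tables whose true means are model steady
states, toy striped embryo images with a ventral expression band, Bernoulli
hatching outcomes and Mendelian cross offspring — all pure functions of
(parameters, seed), with ground-truth metadata emitted alongside the data
so downstream stages can be tested by parameter recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from autoreg.feedback_model import (
    ModelParams,
    steady_state_hill,
    steady_state_step,
)
from autoreg.viability_stats import CrossSpec, expected_offspring

__all__ = [
    "GenotypeScenario",
    "DEFAULT_NUCLEUS_SPACING_UM",
    "simulate_measurements",
    "simulate_embryo_image",
    "simulate_viability",
    "simulate_cross_offspring",
    "scenario_presets",
    "write_measurements",
    "read_measurements",
]

#: Default centre-to-centre nucleus spacing (um); 16 nuclei ~ 112 um.
DEFAULT_NUCLEUS_SPACING_UM = 7.0

#: Column schema of the per-embryo measurement table.
MEASUREMENT_COLUMNS = [
    "embryo_id",
    "genotype",
    "maternal_genotype",
    "copies",
    "mean_intensity",
    "width_um",
    "stage",
]


@dataclass(frozen=True)
class GenotypeScenario:
    """Ground-truth description of one genotype's 2-copy and 1-copy conditions."""

    label: str
    params_2copy: ModelParams
    params_1copy: ModelParams
    noise_cv: float = 0.12
    n_embryos: int = 50
    hatch_prob: float = 1.0
    maternal_genotype: str = "Df/+"
    domain_width_um: float = 126.0
    stage: str = "nc14"

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.hatch_prob <= 1:
            raise ValueError("hatch_prob must be in [0, 1]")
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        if self.params_2copy.c != 2 or self.params_1copy.c != 1:
            raise ValueError("params_2copy must have c=2 and params_1copy c=1")
        if self.params_2copy.with_copies(1) != self.params_1copy:
            raise ValueError("the two parameter sets may differ only in copy number")

    def steady_state(self, copies: int) -> float:
        p = self.params_2copy if copies == 2 else self.params_1copy
        solver = steady_state_step if p.step_limit else steady_state_hill
        return solver(p).m_ss

    def ground_truth(self) -> dict:
        return {
            "label": self.label,
            "params": self.params_2copy.to_dict(),
            "m2_true": self.steady_state(2),
            "m1_true": self.steady_state(1),
            "noise_cv": self.noise_cv,
            "n_embryos": self.n_embryos,
            "hatch_prob": self.hatch_prob,
        }


def simulate_measurements(
    scenario: GenotypeScenario, seed: int
) -> pd.DataFrame:
    """Per-embryo mean intensities for the 2- and 1-copy conditions.

    Embryo intensities are multiplicative lognormal around the model
    steady state with the scenario's coefficient of variation; the draw
    is mean-preserving, so the expected intensity equals the steady state
    and ``noise_cv=0`` reproduces it exactly.  Ground truth is attached
    as ``df.attrs["ground_truth"]``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for copies in (2, 1):
        m_true = scenario.steady_state(copies)
        if scenario.noise_cv > 0:
            sigma = math.sqrt(math.log(1.0 + scenario.noise_cv**2))
            draws = m_true * rng.lognormal(
                mean=-0.5 * sigma**2, sigma=sigma, size=scenario.n_embryos
            )
        else:
            draws = np.full(scenario.n_embryos, m_true)
        for i, intensity in enumerate(draws):
            rows.append(
                {
                    "embryo_id": f"{scenario.label}_c{copies}_{i:03d}",
                    "genotype": scenario.label,
                    "maternal_genotype": scenario.maternal_genotype,
                    "copies": copies,
                    "mean_intensity": float(intensity),
                    "width_um": scenario.domain_width_um,
                    "stage": scenario.stage,
                }
            )
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    df.attrs["ground_truth"] = scenario.ground_truth()
    return df


def simulate_embryo_image(
    length_um: float = 500.0,
    dv_um: float = 250.0,
    domain_width_um: float = 126.0,
    peak_intensity: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    pixel_um: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Toy 2-D intensity field with a centered ventral expression band.

    Rows run along the dorsoventral axis, columns along the
    anteroposterior axis.  Returns ``(image, ground_truth)`` where the
    metadata records the band's row extent and width in um.
    """
    if domain_width_um >= dv_um:
        raise ValueError("domain_width_um must be smaller than dv_um")
    if pixel_um <= 0:
        raise ValueError("pixel_um must be > 0")
    ny = int(round(dv_um / pixel_um))
    nx = int(round(length_um / pixel_um))
    y_um = (np.arange(ny) + 0.5) * pixel_um
    in_band = np.abs(y_um - dv_um / 2.0) <= domain_width_um / 2.0
    image = np.full((ny, nx), background, dtype=float)
    image[in_band, :] = peak_intensity
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    band_rows = np.flatnonzero(in_band)
    truth = {
        "domain_width_um": domain_width_um,
        "band_rows": (int(band_rows[0]), int(band_rows[-1]) + 1) if band_rows.size else None,
        "band_width_px": int(in_band.sum()),
        "peak_intensity": peak_intensity,
        "background": background,
        "noise_sd": noise_sd,
        "pixel_um": pixel_um,
    }
    return image, truth


def simulate_viability(hatch_prob: float, n: int, seed: int) -> np.ndarray:
    """i.i.d. Bernoulli hatch outcomes (1 = hatched)."""
    if not 0 <= hatch_prob <= 1:
        raise ValueError("hatch_prob must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return (rng.random(n) < hatch_prob).astype(np.int64)


def simulate_cross_offspring(cross: CrossSpec, n: int, seed: int) -> pd.DataFrame:
    """Multinomial offspring counts drawn from the cross's surviving fractions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    fractions = expected_offspring(cross)
    labels = list(fractions)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, [fractions[label] for label in labels])
    return pd.DataFrame(
        {
            "genotype": labels,
            "count": counts,
            "expected_fraction": [fractions[label] for label in labels],
        }
    )


def scenario_presets(
    noise_cv: float = 0.12, n_embryos: int = 50
) -> dict[str, GenotypeScenario]:
    """Ship-with defaults spanning the three dosage-ratio categories.

    ``control`` is deeply repressed (ratio ~1, category 1); ``cat2_mutant``
    has its 1-copy state unrepressed (category 2); ``cat3_mutant`` and the
    feedback-null ``no_feedback`` have both states unrepressed (ratio 0.5,
    category 3).  K and beta/gamma values are configuration defaults only.
    """

    def scenario(label, K, bg, hatch_prob):
        p2 = ModelParams(beta=bg, gamma=1.0, K=K, n=math.inf, c=2)
        return GenotypeScenario(
            label=label,
            params_2copy=p2,
            params_1copy=p2.with_copies(1),
            noise_cv=noise_cv,
            n_embryos=n_embryos,
            hatch_prob=hatch_prob,
        )

    return {
        "control": scenario("control", K=1.0, bg=1.2, hatch_prob=0.97),
        "no_feedback": scenario("no_feedback", K=math.inf, bg=0.71, hatch_prob=0.50),
        "cat2_mutant": scenario("cat2_mutant", K=1.0, bg=0.8, hatch_prob=0.90),
        "cat3_mutant": scenario("cat3_mutant", K=2.0, bg=0.7, hatch_prob=0.70),
    }


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table as CSV with a JSON ground-truth sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    truth = df.attrs.get("ground_truth")
    if truth is not None:
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        sidecar.write_text(json.dumps(truth, indent=2))


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV, reattaching its ground-truth sidecar if present."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    if sidecar.exists():
        df.attrs["ground_truth"] = json.loads(sidecar.read_text())
    return df
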