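"""Steady-state model of transcriptional negative autoregulation.

A gene product represses its own production with Hill kinetics,

    dm/dt = c * beta * K^n / (m^n + K^n) - gamma * m,

where ``m`` is the transcript level, ``c`` the gene copy number, ``beta``
the per-copy production rate, ``gamma`` the degradation rate, ``K`` the
repression threshold and ``n`` the Hill coefficient.  In the limit
``n -> inf`` the Hill term becomes a step (Heaviside) function and the
steady state has a closed form.  This module provides:

* forward solvers for the Hill and step steady states and a fixed-step
  ODE integrator used as a numerical cross-check;
* the closed-form inversion of a 1-copy / 2-copy dosage ratio into the
  repression threshold ``K`` and net production ``beta/gamma``;
* the minimal Hill coefficient for which that inversion is admissible;
* the three-way categorization of genotypes by dosage ratio, with
  step-limit parameter estimates or one-sided bounds per category;
* comparison utilities (no-feedback null, distance-effect scan,
  finite-n vs step-limit error).

Quantities are in normalized intensity units throughout: measured levels
are divided by the control 2-copy mean before inference, so the control
threshold is 1 by construction.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace

from scipy.optimize import brentq

__all__ = [
    "INFINITE_N",
    "ModelParams",
    "TimeCoursePoint",
    "SteadyState",
    "HillSolution",
    "CategoryResult",
    "HillStepError",
    "NoAdmissibleSolution",
    "hill_production",
    "integrate_ode",
    "steady_state_hill",
    "steady_state_step",
    "dosage_ratio_model",
    "solve_hill_threshold",
    "min_hill_coefficient",
    "solve_mutant_hill",
    "categorize",
    "infer_step_params",
    "no_feedback_steady_state",
    "distance_effect_predict",
    "hill_vs_step_error",
]

#: Sentinel for the step-function (infinite-cooperativity) limit.
INFINITE_N = math.inf


class NoAdmissibleSolution(ValueError):
    """Raised when a parameter-inference problem has no positive root."""


def _encode_n(n: float) -> object:
    return "inf" if math.isinf(n) else n


def _decode_n(n: object) -> float:
    if isinstance(n, str):
        if n != "inf":
            raise ValueError(f"unrecognized Hill coefficient encoding {n!r}")
        return INFINITE_N
    return float(n)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the autoregulation ODE.

    ``K = inf`` encodes absence of repression; ``n = INFINITE_N`` selects
    the step-function limit.
    """

    beta: float
    gamma: float
    K: float
    n: float
    c: int

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0 (use inf for no repression), got {self.K}")
        if self.n <= 0:
            raise ValueError(f"n must be > 0 or infinite, got {self.n}")
        if self.c not in (1, 2):
            raise ValueError(f"copy number must be 1 or 2, got {self.c}")

    @property
    def step_limit(self) -> bool:
        """True when the Hill coefficient is the infinite sentinel."""
        return math.isinf(self.n)

    @property
    def bg(self) -> float:
        """Net per-copy production beta/gamma."""
        return self.beta / self.gamma

    def with_copies(self, c: int) -> "ModelParams":
        return replace(self, c=c)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "gamma": self.gamma,
            "K": "inf" if math.isinf(self.K) else self.K,
            "n": _encode_n(self.n),
            "c": self.c,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        K = d["K"]
        return cls(
            beta=float(d["beta"]),
            gamma=float(d["gamma"]),
            K=math.inf if K == "inf" else float(K),
            n=_decode_n(d["n"]),
            c=int(d["c"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class TimeCoursePoint:
    t: float
    m: float


@dataclass(frozen=True)
class SteadyState:
    """Steady-state transcript level with its regime label."""

    m_ss: float
    regime: str  # "repressed" | "unrepressed" | "boundary"
    c: int


@dataclass(frozen=True)
class HillSolution:
    """Closed-form inversion of a dosage ratio under finite-n Hill kinetics.

    ``x`` is the auxiliary quantity ``(m2 / K)^n``.  ``valid`` is False when
    the admissibility condition ``x > 0`` fails (no exception is raised).
    """

    K: float
    beta_over_gamma: float
    x: float
    n: float
    valid: bool

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "beta_over_gamma": self.beta_over_gamma,
            "x": self.x,
            "n": _encode_n(self.n),
            "valid": self.valid,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "HillSolution":
        return cls(
            K=float(d["K"]),
            beta_over_gamma=float(d["beta_over_gamma"]),
            x=float(d["x"]),
            n=_decode_n(d["n"]),
            valid=bool(d["valid"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "HillSolution":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class CategoryResult:
    """Step-limit parameter estimates for one genotype.

    Depending on the category, ``K_est`` and ``bg_est`` are either point
    estimates or one-sided lower bounds; the ``*_is_bound`` flags say which.
    """

    category: int
    K_est: float
    bg_est: float
    K_is_bound: bool
    bg_is_bound: bool

    def __post_init__(self) -> None:
        if self.category not in (1, 2, 3):
            raise ValueError(f"category must be 1, 2 or 3, got {self.category}")

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "K_est": self.K_est,
            "bg_est": self.bg_est,
            "K_is_bound": self.K_is_bound,
            "bg_is_bound": self.bg_is_bound,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryResult":
        return cls(
            category=int(d["category"]),
            K_est=float(d["K_est"]),
            bg_est=float(d["bg_est"]),
            K_is_bound=bool(d["K_is_bound"]),
            bg_is_bound=bool(d["bg_is_bound"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "CategoryResult":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def hill_production(m: float, p: ModelParams) -> float:
    """Hill-repressed production rate c*beta*K^n / (m^n + K^n).

    Requires a finite Hill coefficient; raises on negative ``m``.
    """
    if m < 0:
        raise ValueError(f"transcript level must be >= 0, got {m}")
    if p.step_limit:
        raise ValueError("hill_production requires a finite Hill coefficient")
    if math.isinf(p.K):
        return p.c * p.beta
    # (m/K)^n form is overflow-safe for m >> K at large n
    return p.c * p.beta / (1.0 + (m / p.K) ** p.n)


def steady_state_hill(p: ModelParams) -> SteadyState:
    """Unique positive steady state of the Hill model.

    The production term is strictly decreasing and degradation strictly
    increasing in ``m``, so the root in ``(0, c*beta/gamma]`` is unique.
    """
    if p.step_limit:
        raise ValueError("use steady_state_step for the infinite-n limit")
    upper = p.c * p.beta / p.gamma
    if p.beta == 0:
        return SteadyState(0.0, "unrepressed", p.c)
    if math.isinf(p.K):
        return SteadyState(upper, "unrepressed", p.c)

    def residual(m: float) -> float:
        return hill_production(m, p) - p.gamma * m

    if residual(upper) >= 0:  # repression negligible at the unrepressed level
        return SteadyState(upper, "unrepressed", p.c)
    m_ss = brentq(residual, 0.0, upper, xtol=1e-14, rtol=1e-14)
    regime = "repressed" if upper > p.K else "unrepressed"
    return SteadyState(m_ss, regime, p.c)


def steady_state_step(p: ModelParams) -> SteadyState:
    """Steady state in the step-function (n -> inf) limit.

    If ``c*beta/gamma > K`` the level pins at the threshold ``K``
    (repressed); if ``c*beta/gamma < K`` it sits at the unrepressed level
    ``c*beta/gamma``.  At equality the convention theta(0) = 1 makes
    ``m = K`` the fixed point, labeled "boundary".
    """
    if not p.step_limit:
        raise ValueError("steady_state_step requires the infinite-n sentinel")
    unrepressed = p.c * p.beta / p.gamma
    if math.isinf(p.K) or unrepressed < p.K:
        return SteadyState(unrepressed, "unrepressed", p.c)
    if unrepressed > p.K:
        return SteadyState(p.K, "repressed", p.c)
    return SteadyState(p.K, "boundary", p.c)


def integrate_ode(
    p: ModelParams, m0: float, t_end: float, dt: float
) -> list[TimeCoursePoint]:
    """Fixed-step RK4 integration of the Hill ODE from ``m0``.

    A numerical cross-check of the analytic steady states: trajectories
    converge monotonically to `steady_state_hill` from either side.
    Raises if the trajectory goes negative (step-size instability).
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be > 0")
    if m0 < 0:
        raise ValueError("initial level must be >= 0")
    if p.step_limit:
        raise ValueError("integration requires a finite Hill coefficient")

    def rhs(m: float) -> float:
        return hill_production(m, p) - p.gamma * m

    points = [TimeCoursePoint(0.0, m0)]
    m, t = m0, 0.0
    n_steps = int(math.ceil(t_end / dt))
    for _ in range(n_steps):
        h = min(dt, t_end - t)
        k1 = rhs(m)
        k2 = rhs(max(m + 0.5 * h * k1, 0.0))
        k3 = rhs(max(m + 0.5 * h * k2, 0.0))
        k4 = rhs(max(m + h * k3, 0.0))
        m = m + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if m < 0:
            raise RuntimeError(
                f"trajectory became negative at t={t + h:.4g}; reduce dt"
            )
        t += h
        points.append(TimeCoursePoint(t, m))
    return points


def no_feedback_steady_state(beta: float, gamma: float, c: int) -> SteadyState:
    """Steady state without autoregulation: m = c*beta/gamma.

    The 1-copy to 2-copy ratio under this null is exactly 1/2 for any
    (beta, gamma).
    """
    if beta < 0 or gamma <= 0:
        raise ValueError("beta must be >= 0 and gamma > 0")
    if c not in (1, 2):
        raise ValueError(f"copy number must be 1 or 2, got {c}")
    return SteadyState(c * beta / gamma, "unrepressed", c)


def dosage_ratio_model(p: ModelParams) -> float:
    """Model-predicted ratio m(c=1) / m(c=2) at steady state.

    Always in [0.5, 1]; exactly 0.5 when repression is absent (K infinite).
    """
    solver = steady_state_step if p.step_limit else steady_state_hill
    m1 = solver(p.with_copies(1)).m_ss
    m2 = solver(p.with_copies(2)).m_ss
    if m2 == 0:
        return 1.0  # beta == 0 degenerate case: both steady states are 0
    return m1 / m2


# ---------------------------------------------------------------------------
# Inverse problem: dosage ratio -> (K, beta/gamma)
# ---------------------------------------------------------------------------


def solve_hill_threshold(rho: float, m2: float, n: float) -> HillSolution:
    """Closed-form inversion of the 1-vs-2-copy steady states at finite n.

    Writing ``x = (m2/K)^n``, the two steady-state equations

        2*(beta/gamma) = m2 * (1 + x)
        1*(beta/gamma) = rho*m2 * (1 + rho^n * x)

    combine to ``x = (2*rho - 1) / (1 - 2*rho^(n+1))``, whence
    ``K = m2 * x^(-1/n)`` and ``beta/gamma = rho*m2*(1 + rho^n * x)``.
    The solution exists only when the denominator is positive, i.e. when
    ``n > min_hill_coefficient(rho)``; otherwise ``valid`` is False.
    """
    if not 0.5 < rho < 1.0:
        raise ValueError(
            f"ratio must lie strictly in (0.5, 1) for a finite-n solution, got {rho}"
        )
    if m2 <= 0:
        raise ValueError(f"m2 must be > 0, got {m2}")
    if n <= 0 or math.isinf(n):
        raise ValueError(f"n must be positive and finite, got {n}")
    denom = 1.0 - 2.0 * rho ** (n + 1.0)
    if denom <= 0:
        return HillSolution(math.nan, math.nan, math.nan, n, valid=False)
    x = (2.0 * rho - 1.0) / denom
    K = m2 * x ** (-1.0 / n)
    bg = rho * m2 * (1.0 + rho**n * x)
    return HillSolution(K, bg, x, n, valid=True)


def min_hill_coefficient(rho: float) -> float:
    """Smallest Hill coefficient admitting a finite-n inversion at ratio rho.

    n_min = ln(1/2)/ln(rho) - 1; `solve_hill_threshold` is valid for all
    n > n_min and invalid below it.  Tends to 0 as rho -> 0.5+ and to
    infinity as rho -> 1-.
    """
    if not 0.5 < rho < 1.0:
        raise ValueError(f"ratio must lie strictly in (0.5, 1), got {rho}")
    return math.log(0.5) / math.log(rho) - 1.0


def solve_mutant_hill(
    control: HillSolution,
    mutant_m1: float,
    mutant_m2: float,
    n_max: float = 1e4,
) -> tuple[float, float]:
    """Solve for a mutant's (n, K) assuming it shares the control beta/gamma.

    Mutant levels are normalized by the control 2-copy mean.  With
    beta/gamma fixed at the control value, the inversion
    ``n -> beta/gamma(rho_mut, m2_mut, n)`` is monotone decreasing from
    +inf (at the admissibility bound) to ``m1_mut`` (as n -> inf), so a
    1-D root in n exists iff the control beta/gamma exceeds the mutant
    1-copy level.  Raises `NoAdmissibleSolution` otherwise.
    """
    if not control.valid:
        raise ValueError("control solution is not valid")
    if mutant_m1 <= 0 or mutant_m2 <= 0:
        raise ValueError("mutant levels must be > 0")
    rho = mutant_m1 / mutant_m2
    if rho <= 0.5 or rho >= 1.0:
        raise NoAdmissibleSolution(
            f"no admissible solution: mutant dosage ratio {rho:.4g} outside (0.5, 1)"
        )
    target = control.beta_over_gamma
    if target <= mutant_m1:
        raise NoAdmissibleSolution(
            "no admissible solution: shared beta/gamma "
            f"{target:.4g} does not exceed the mutant 1-copy level {mutant_m1:.4g}"
        )

    n_min = min_hill_coefficient(rho)

    def bg_gap(n: float) -> float:
        return solve_hill_threshold(rho, mutant_m2, n).beta_over_gamma - target

    lo = n_min * (1 + 1e-9) + 1e-12
    hi = max(2.0 * (n_min + 1.0), 10.0)
    while bg_gap(hi) > 0:
        hi *= 2.0
        if hi > n_max:
            raise NoAdmissibleSolution(
                f"no admissible solution: no root for n <= {n_max:g}"
            )
    n_mut = brentq(bg_gap, lo, hi, xtol=1e-12, rtol=1e-14)
    K_mut = solve_hill_threshold(rho, mutant_m2, n_mut).K
    return n_mut, K_mut


# ---------------------------------------------------------------------------
# Categorization and step-limit inference
# ---------------------------------------------------------------------------


def categorize(
    rho: float, cat1_threshold: float = 0.9, cat3_threshold: float = 0.6
) -> int:
    """Three-way classification of a dosage ratio.

    rho >= cat1_threshold -> 1 (both copies repressed, pinned at K);
    rho <= cat3_threshold -> 3 (neither repressed); otherwise 2.
    Ratios marginally above 1 (noise) are clipped to 1 with a warning.
    """
    if rho <= 0:
        raise ValueError(f"ratio must be > 0, got {rho}")
    if rho > 1.1:
        raise ValueError(f"ratio {rho} too far above 1 to be measurement noise")
    if not cat3_threshold < cat1_threshold:
        raise ValueError("cat3_threshold must be below cat1_threshold")
    if rho > 1.0:
        warnings.warn(
            f"dosage ratio {rho:.4g} > 1 clipped to 1.0", stacklevel=2
        )
        rho = 1.0
    if rho >= cat1_threshold:
        return 1
    if rho <= cat3_threshold:
        return 3
    return 2


def infer_step_params(
    category: int,
    m1: float,
    m2: float,
    cat3_tolerance: float = 0.25,
) -> CategoryResult:
    """Step-limit parameter estimates from normalized 1- and 2-copy levels.

    Category 1: both steady states at the threshold, so K = m2 (a point
    estimate) and beta/gamma is only bounded below by K.  Category 2: the
    2-copy state is at K and the 1-copy state unrepressed, so K = m2 and
    beta/gamma = m1, both points.  Category 3: neither state repressed, so
    beta/gamma = m1 and K is only bounded below by m2; geometry implies
    m2 = 2*m1, and a deviation beyond ``cat3_tolerance`` (relative) warns.
    """
    if m1 <= 0 or m2 <= 0:
        raise ValueError("levels must be > 0")
    if category == 1:
        return CategoryResult(1, K_est=m2, bg_est=m2, K_is_bound=False, bg_is_bound=True)
    if category == 2:
        return CategoryResult(2, K_est=m2, bg_est=m1, K_is_bound=False, bg_is_bound=False)
    if category == 3:
        expected_m2 = 2.0 * m1
        if abs(m2 - expected_m2) / expected_m2 > cat3_tolerance:
            warnings.warn(
                f"category-3 inconsistency: m2={m2:.4g} deviates from 2*m1="
                f"{expected_m2:.4g} by more than {cat3_tolerance:.0%}",
                stacklevel=2,
            )
        return CategoryResult(3, K_est=m2, bg_est=m1, K_is_bound=True, bg_is_bound=False)
    raise ValueError(f"category must be 1, 2 or 3, got {category}")


def distance_effect_predict(
    p: ModelParams, beta_scale: float, K_scale: float
) -> tuple[SteadyState, SteadyState, float]:
    """Step-model steady states after scaling beta and/or K.

    Scaling beta mimics a pure enhancer-distance effect (higher maximal
    production); scaling K mimics a change in repression strength.  While
    the 2-copy state is pinned at the threshold, increasing beta alone
    leaves it unchanged — only a change in K moves it.
    """
    if beta_scale <= 0 or K_scale <= 0:
        raise ValueError("scale factors must be > 0")
    if not p.step_limit:
        raise ValueError("distance-effect scan is defined for the step model")
    scaled = replace(p, beta=p.beta * beta_scale, K=p.K * K_scale)
    ss2 = steady_state_step(scaled.with_copies(2))
    ss1 = steady_state_step(scaled.with_copies(1))
    return ss2, ss1, ss1.m_ss / ss2.m_ss


@dataclass(frozen=True)
class HillStepError:
    """Relative disagreement between finite-n and step-limit inference."""

    n: float
    rho: float
    K_hill: float
    bg_hill: float
    K_step: float
    bg_step: float
    K_rel_error: float
    bg_rel_error: float
    valid: bool


def hill_vs_step_error(rho: float, m2: float, n_finite: float) -> HillStepError:
    """Compare finite-n closed-form inference against the step limit.

    Runs `solve_hill_threshold` at ``n_finite`` and `infer_step_params`
    on the same normalized (m1, m2); reports relative differences in K
    and beta/gamma.  Errors shrink to zero as n grows.  Invalidity of the
    finite-n solution propagates (no errors computed).
    """
    hill = solve_hill_threshold(rho, m2, n_finite)
    if not hill.valid:
        return HillStepError(
            n_finite, rho, math.nan, math.nan, math.nan, math.nan,
            math.nan, math.nan, valid=False,
        )
    m1 = rho * m2
    step = infer_step_params(categorize(rho), m1, m2)
    return HillStepError(
        n=n_finite,
        rho=rho,
        K_hill=hill.K,
        bg_hill=hill.beta_over_gamma,
        K_step=step.K_est,
        bg_step=step.bg_est,
        K_rel_error=abs(hill.K - step.K_est) / step.K_est,
        bg_rel_error=abs(hill.beta_over_gamma - step.bg_est) / step.bg_est,
        valid=True,
    )
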