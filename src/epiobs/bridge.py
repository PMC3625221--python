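"""The bridging special case: a symptom-based model with explicit
pre-symptomatic transmission.

The asymptomatic stage of the symptom-based model is decomposed into
pre-symptomatic individuals ``H_S`` (who will develop symptoms, transmitting
at rate ``beta_H``), asymptomatic non-infectious individuals ``H_A``, and
fully asymptomatic infectious individuals ``I`` (transmitting at relative
rate ``m``).  With ``R_a`` and ``R_pre`` the expected secondary cases of a
fully asymptomatic and a pre-symptomatic case, the basic reproduction number
is the symptom-probability-weighted average

    R0 = (1 - alpha) * R_a + alpha * (R_pre + R2).

Writing ``g`` for the share of pre-symptomatic transmission among all
asymptomatic transmission gives the bookkeeping identities

    alpha * R_pre = g * theta * R0,      (1 - alpha) * R_a = (1 - g) * theta * R0,

which close the parameter set from a published table (R_pre is rarely printed)
and yield the mapping ``alpha = g*R_a / ((1-g)*R_pre + g*R_a)``: the larger
the pre-symptomatic share g, the larger the symptom probability must be.
Setting ``g = 0`` (``beta_H = 0``) and matching rates recovers the SEIR-type
contagiousness-based model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .exceptions import DegenerateModelError, InconsistentParametersError
from .kernels import (
    AgeRate,
    default_age_max,
    expected_reproduction_integral,
    stage_occupancy,
    survival_from_hazards,
)
from .unobservable import (
    UnobservableKernels,
    r0_unobservable,
    unobservable_params_from_kernels,
)

__all__ = [
    "BridgeParams",
    "BridgeKernels",
    "r0_bridge",
    "alpha_from_g",
    "presymptomatic_share_from_components",
    "fully_asymptomatic_r_from_components",
    "g_sensitivity_curve",
    "GSweepPoint",
    "bridge_params_from_kernels",
    "bridge_r0_from_kernels",
    "check_consistency_conditions",
    "ConditionCheck",
    "ConsistencyReport",
]


@dataclass(frozen=True)
class BridgeParams:
    """Reduced-form parameters of the bridging model.

    ``g`` is the proportion of pre-symptomatic transmissions among all
    asymptomatic transmissions.
    """

    R_a: float
    R_pre: float
    R2: float
    alpha: float
    g: float

    def __post_init__(self) -> None:
        if min(self.R_a, self.R_pre, self.R2) < 0:
            raise ValueError("reproduction components must be nonnegative")
        if not 0.0 <= self.alpha <= 1.0 or not 0.0 <= self.g <= 1.0:
            raise ValueError("alpha and g must lie in [0, 1]")


@dataclass(frozen=True)
class BridgeKernels:
    """Mechanistic backing of the bridging model.

    Transition rates: ``eta(tau)/alpha`` from H_S to the symptomatic stage
    (the onset rate is scaled because only the fraction alpha ever reaches
    H_S), ``rho(tau)`` from H_A to the infectious asymptomatic stage I,
    ``zeta_A(tau)`` out of I, and ``gamma_S(sigma)`` out of the symptomatic
    stage.  Transmission: ``beta_H(tau)`` for H_S, ``m * beta(tau)`` for I,
    ``beta_S(sigma)`` for symptomatic cases.
    """

    beta: AgeRate
    beta_H: AgeRate
    beta_S: AgeRate
    eta: AgeRate
    rho: AgeRate
    zeta_A: AgeRate
    gamma_S: AgeRate
    alpha: float
    m: float = 1.0
    S0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            if self.alpha == 0.0:
                # alpha = 0 removes the symptomatic path entirely; the scaled
                # onset rate eta/alpha is then undefined.
                raise DegenerateModelError(
                    "bridge kernels need alpha > 0 (eta/alpha scaling)"
                )
            raise ValueError("alpha must lie in (0, 1]")


def r0_bridge(params: BridgeParams) -> float:
    """Basic reproduction number ``(1-alpha)*R_a + alpha*(R_pre + R2)``."""
    return (1.0 - params.alpha) * params.R_a + params.alpha * (
        params.R_pre + params.R2
    )


def alpha_from_g(g: float, R_a: float, R_pre: float) -> float:
    """Symptom probability implied by a pre-symptomatic share ``g``.

    ``alpha = g*R_a / ((1-g)*R_pre + g*R_a)``; monotone nondecreasing in g.
    """
    if not 0.0 <= g <= 1.0:
        raise ValueError("g must lie in [0, 1]")
    if R_a < 0 or R_pre < 0:
        raise ValueError("R_a and R_pre must be nonnegative")
    denom = (1.0 - g) * R_pre + g * R_a
    if denom <= 0.0:
        raise DegenerateModelError(
            "alpha(g) undefined: (1-g)*R_pre + g*R_a must be positive"
        )
    return g * R_a / denom


def presymptomatic_share_from_components(
    alpha: float, R_a: float, theta: float, R0: float, tol: float = 1e-6
) -> float:
    """Pre-symptomatic share ``g = 1 - (1-alpha)*R_a / (theta*R0)``.

    Inverts the bookkeeping identity ``(1-alpha)*R_a = (1-g)*theta*R0``;
    ``theta*R0`` is the total asymptomatic transmission.  Values outside
    [0, 1] beyond ``tol`` indicate an inconsistent parameter set.
    """
    total_asym = theta * R0
    if total_asym <= 0.0:
        raise DegenerateModelError("g undefined when theta * R0 = 0")
    g = 1.0 - (1.0 - alpha) * R_a / total_asym
    if g < -tol or g > 1.0 + tol:
        raise InconsistentParametersError(
            f"derived g = {g:.6g} lies outside [0, 1]: "
            "alpha, R_a, theta and R0 are mutually inconsistent"
        )
    return min(max(g, 0.0), 1.0)


def fully_asymptomatic_r_from_components(
    alpha: float, g: float, theta: float, R0: float
) -> float:
    """Fully asymptomatic reproduction number from the same closure.

    ``R_a = theta*R0*(1-g) / (1-alpha)``; requires alpha < 1 (with alpha = 1
    the fully asymptomatic class has zero weight and R_a is unidentifiable).
    """
    if alpha >= 1.0:
        raise DegenerateModelError(
            "R_a is unidentifiable from the closure when alpha = 1"
        )
    return theta * R0 * (1.0 - g) / (1.0 - alpha)


class GSweepPoint(NamedTuple):
    g: float
    alpha: float
    R0: float


def g_sensitivity_curve(
    params: BridgeParams, g_grid: Sequence[float]
) -> list[GSweepPoint]:
    """R0 as a function of the pre-symptomatic share g.

    Holds R_a, R_pre and R2 fixed; for each g the symptom probability is
    re-derived via :func:`alpha_from_g` and R0 re-evaluated.  The slope sign
    equals the sign of ``R_pre + R2 - R_a`` everywhere: diseases whose
    fully-asymptomatic transmission dominates (e.g. HIV) have R0 decreasing
    in g, the others increasing.
    """
    if len(g_grid) == 0:
        raise ValueError("g_grid must be nonempty")
    out = []
    for g in g_grid:
        alpha = alpha_from_g(g, params.R_a, params.R_pre)
        point = BridgeParams(
            R_a=params.R_a, R_pre=params.R_pre, R2=params.R2, alpha=alpha, g=g
        )
        out.append(GSweepPoint(g=float(g), alpha=alpha, R0=r0_bridge(point)))
    return out


def _occupancy_grid(kernels: BridgeKernels, grid_step: float, age_max: float | None):
    kk = kernels
    if age_max is None:
        age_max = default_age_max([kk.rho]) + default_age_max([kk.zeta_A])
    n = int(np.ceil(age_max / grid_step))
    ages = np.arange(n + 1) * grid_step
    rho = kk.rho(ages)
    surv_ha = np.exp(
        -np.concatenate(([0.0], np.cumsum(0.5 * (rho[1:] + rho[:-1]) * np.diff(ages))))
    )
    occ_i = stage_occupancy(rho * surv_ha, kk.zeta_A, ages)
    return ages, occ_i


def bridge_params_from_kernels(
    kernels: BridgeKernels,
    grid_step: float = 0.01,
    age_max: float | None = None,
) -> BridgeParams:
    """Reduced-form bridge parameters from age-dependent rates.

    R_pre integrates ``beta_H`` against survival in H_S (exit hazard
    ``eta/alpha``); R_a integrates ``m * beta`` against the probability of
    occupying the infectious asymptomatic stage I (entered from H_A at rate
    ``rho``, left at rate ``zeta_A``); R2 integrates ``beta_S`` against
    survival under ``gamma_S``.  g follows from the bookkeeping identity.
    """
    kk = kernels
    onset = kk.eta.scaled(1.0 / kk.alpha)
    surv_hs = survival_from_hazards(
        [onset], grid_step, age_max if age_max is not None else default_age_max([onset])
    )
    r_pre = expected_reproduction_integral(kk.beta_H, surv_hs)
    surv_s = survival_from_hazards(
        [kk.gamma_S],
        grid_step,
        age_max if age_max is not None else default_age_max([kk.gamma_S]),
    )
    r2 = expected_reproduction_integral(kk.beta_S, surv_s)
    ages, occ_i = _occupancy_grid(kk, grid_step, age_max)
    r_a = kk.m * float(np.trapezoid(kk.beta(ages) * occ_i, ages))
    total_asym = (1.0 - kk.alpha) * r_a + kk.alpha * r_pre
    g = kk.alpha * r_pre / total_asym if total_asym > 0.0 else 0.0
    return BridgeParams(R_a=r_a, R_pre=r_pre, R2=r2, alpha=kk.alpha, g=g)


def bridge_r0_from_kernels(
    kernels: BridgeKernels,
    grid_step: float = 0.01,
    age_max: float | None = None,
) -> float:
    """R0 of the bridging model computed from its kernels."""
    return r0_bridge(bridge_params_from_kernels(kernels, grid_step, age_max))


# ---------------------------------------------------------------------------
# consistency conditions linking the two model families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionCheck:
    passed: bool
    max_deviation: float
    detail: str


@dataclass(frozen=True)
class ConsistencyReport:
    """Result of checking the three conditions under which the symptom-based
    (bridge) model collapses onto the SEIR-type model."""

    condition_a: ConditionCheck
    condition_b: ConditionCheck
    condition_c: ConditionCheck

    @property
    def all_passed(self) -> bool:
        return (
            self.condition_a.passed
            and self.condition_b.passed
            and self.condition_c.passed
        )


def check_consistency_conditions(
    bridge_kernels: BridgeKernels,
    unobs_kernels: UnobservableKernels,
    grid_step: float = 0.01,
    tol: float = 1e-9,
) -> ConsistencyReport:
    """Check the conditions for the two model families to coincide.

    (a) identical symptom probabilities, ``alpha = k``;
    (b) the incubation period equals the latent period:
        ``epsilon(tau) = eta(tau)/alpha = rho(tau)`` pointwise, and no
        pre-symptomatic transmission, ``beta_H = 0``;
    (c) the recovery rates of both models are identical constants:
        ``kappa_S = gamma_S`` and ``kappa_A = zeta_A``.

    Each condition is reported with its maximal deviation on the evaluation
    grid; non-constant recovery rates make condition (c) a structural
    failure regardless of pointwise agreement.
    """
    bk, uk = bridge_kernels, unobs_kernels

    dev_a = abs(bk.alpha - uk.k)
    cond_a = ConditionCheck(
        passed=dev_a <= tol,
        max_deviation=dev_a,
        detail=f"alpha = {bk.alpha:.6g} vs k = {uk.k:.6g}",
    )

    horizon = default_age_max([uk.epsilon])
    ages = np.arange(int(np.ceil(horizon / grid_step)) + 1) * grid_step
    eps = uk.epsilon(ages)
    onset = bk.eta(ages) / bk.alpha
    rho = bk.rho(ages)
    beta_h = bk.beta_H(ages)
    dev_b = float(
        max(np.max(np.abs(eps - onset)), np.max(np.abs(eps - rho)), np.max(beta_h))
    )
    cond_b = ConditionCheck(
        passed=dev_b <= tol,
        max_deviation=dev_b,
        detail=(
            f"max|epsilon - eta/alpha| = {np.max(np.abs(eps - onset)):.3g}, "
            f"max|epsilon - rho| = {np.max(np.abs(eps - rho)):.3g}, "
            f"max beta_H = {np.max(beta_h):.3g}"
        ),
    )

    recovery = [uk.kappa_S, bk.gamma_S, uk.kappa_A, bk.zeta_A]
    if not all(r.is_constant for r in recovery):
        cond_c = ConditionCheck(
            passed=False,
            max_deviation=float("inf"),
            detail="recovery rates of both models must be identical constants "
            "(a non-constant rate is a structural failure)",
        )
    else:
        dev_s = abs(uk.kappa_S.params["rate"] - bk.gamma_S.params["rate"])
        dev_asym = abs(uk.kappa_A.params["rate"] - bk.zeta_A.params["rate"])
        dev_c = max(dev_s, dev_asym)
        cond_c = ConditionCheck(
            passed=dev_c <= tol,
            max_deviation=dev_c,
            detail=f"|kappa_S - gamma_S| = {dev_s:.3g}, |kappa_A - zeta_A| = {dev_asym:.3g}",
        )

    return ConsistencyReport(cond_a, cond_b, cond_c)


def unobservable_r0_from_kernels(
    kernels: UnobservableKernels,
    grid_step: float = 0.01,
    age_max: float | None = None,
) -> float:
    """Convenience: R0 of the SEIR-type model from its kernels."""
    return r0_unobservable(unobservable_params_from_kernels(kernels, grid_step, age_max))
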