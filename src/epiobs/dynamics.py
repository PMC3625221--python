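"""Linearized age-structured dynamics and growth-rate diagnostics.

During the invasion phase of an epidemic the susceptible pool is effectively
constant, so every model variant in this package reduces to a linear renewal
process.  This module advances the stage-structured cohort densities along
characteristics (infection-age and disease-age advance in lock-step with
calendar time, age grid = time grid) and records the incidence of new
infections and of new symptom onsets.  It doubles as the synthetic-data
generator: the deterministic series carry exactly the structure the models
assume, with an optional seeded negative-binomial observation-noise overlay
for realism.

The reproduction kernel ``psi(tau)`` — the expected rate of secondary
transmission at infection-age tau per infected individual — ties the
simulated series back to the analytics: its integral is R0 and its Laplace
transform gives the growth-rate (Euler-Lotka) relation
``int psi(tau) exp(-r*tau) dtau = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.optimize import brentq
from scipy.stats import linregress

from .bridge import BridgeKernels
from .exceptions import DivergenceError, StabilityError
from .kernels import stage_occupancy
from .observable import ObservableKernels, ObservableParams
from .unobservable import UnobservableKernels

__all__ = [
    "IncidenceSeries",
    "GrowthEstimate",
    "ReproductionKernel",
    "simulate_linear",
    "estimate_growth_rate",
    "reproduction_kernel",
    "euler_lotka_residual",
    "euler_lotka_root",
    "add_observation_noise",
    "constant_rate_kernels",
]

ModelKernels = Union[ObservableKernels, UnobservableKernels, BridgeKernels]


@dataclass(frozen=True)
class IncidenceSeries:
    """Per-step counts of new infections and new symptom onsets."""

    times: np.ndarray
    new_infections: np.ndarray
    new_onsets: np.ndarray
    seed_size: float
    step: float

    def __post_init__(self) -> None:
        for name in ("times", "new_infections", "new_onsets"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (
            self.times.shape == self.new_infections.shape == self.new_onsets.shape
        ):
            raise ValueError("series arrays must have equal length")
        if np.any(self.new_infections < 0) or np.any(self.new_onsets < 0):
            raise ValueError("incidence must be nonnegative")
        if self.seed_size <= 0 or self.step <= 0:
            raise ValueError("seed_size and step must be positive")

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    def cumulative_infections(self) -> float:
        return float(np.sum(self.new_infections))

    def to_csv(self, path) -> None:
        data = np.column_stack([self.times, self.new_infections, self.new_onsets])
        np.savetxt(
            path,
            data,
            delimiter=",",
            header="time,new_infections,new_onsets",
            comments="",
        )


@dataclass(frozen=True)
class GrowthEstimate:
    """Exponential growth rate fitted to log-incidence."""

    r: float
    window: tuple[float, float]
    fit_quality: float  # coefficient of determination

    def __post_init__(self) -> None:
        if not 0.0 <= self.fit_quality <= 1.0:
            raise ValueError("fit_quality must lie in [0, 1]")


@dataclass(frozen=True)
class ReproductionKernel:
    """``psi(tau)`` on a uniform age grid; ``int psi = R0``."""

    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.ages.shape != self.values.shape:
            raise ValueError("ages and values must have equal length")

    def total(self) -> float:
        """R0: the integral of the kernel."""
        return float(np.trapezoid(self.values, self.ages))


def _conv_trap(f: np.ndarray, g: np.ndarray, step: float) -> np.ndarray:
    """Trapezoid-rule convolution ``int_0^tau f(s) g(tau - s) ds`` on a grid."""
    n = f.size
    full = np.convolve(f, g)[:n]
    return step * (full - 0.5 * (f[0] * g[:n] + g[0] * f[:n]))


def _survival_grid(hazard_values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    increments = 0.5 * (hazard_values[1:] + hazard_values[:-1]) * np.diff(ages)
    return np.exp(-np.concatenate(([0.0], np.cumsum(increments))))


def reproduction_kernel(model: ModelKernels, ages: np.ndarray) -> ReproductionKernel:
    """Reproduction kernel ``psi(tau)`` of a model variant on an age grid."""
    ages = np.asarray(ages, dtype=float)
    step = float(ages[1] - ages[0])
    if isinstance(model, ObservableKernels):
        total = model.eta(ages) + model.gamma_A(ages)
        s_a = _survival_grid(total, ages)
        s_s = _survival_grid(model.gamma_S(ages), ages)
        onset_flux = model.eta(ages) * s_a
        psi = model.beta_A(ages) * s_a + _conv_trap(
            onset_flux, model.beta_S(ages) * s_s, step
        )
    elif isinstance(model, UnobservableKernels):
        eps = model.epsilon(ages)
        entry = eps * _survival_grid(eps, ages)
        occ_s = stage_occupancy(entry, model.kappa_S, ages)
        occ_a = stage_occupancy(entry, model.kappa_A, ages)
        psi = model.beta(ages) * (
            model.k * occ_s + (1.0 - model.k) * model.m * occ_a
        )
    elif isinstance(model, BridgeKernels):
        onset = model.eta(ages) / model.alpha
        s_h = _survival_grid(onset, ages)
        s_s = _survival_grid(model.gamma_S(ages), ages)
        rho = model.rho(ages)
        occ_i = stage_occupancy(rho * _survival_grid(rho, ages), model.zeta_A, ages)
        presym = model.beta_H(ages) * s_h + _conv_trap(
            onset * s_h, model.beta_S(ages) * s_s, step
        )
        psi = model.alpha * presym + (1.0 - model.alpha) * model.m * model.beta(
            ages
        ) * occ_i
    else:
        raise TypeError(f"unsupported model type: {type(model).__name__}")
    return ReproductionKernel(ages=ages, values=psi)


def _check_step(max_hazard: float, step: float) -> None:
    if max_hazard * step > 0.5:
        raise StabilityError(
            f"step {step:g} is too coarse for the fastest hazard "
            f"{max_hazard:g}/time unit; use step <= {0.5 / max_hazard:.4g}"
        )


def simulate_linear(
    model: ModelKernels,
    horizon: float,
    step: float = 0.01,
    seed_size: float = 1.0,
) -> IncidenceSeries:
    """Simulate the linearized dynamics of a model variant.

    A pulse of ``seed_size`` newly infected (age-0) individuals enters at
    t = 0; cohort densities are transported along characteristics with exact
    exponential within-step survival, the force of infection is computed by
    quadrature over the current age densities, and the susceptible pool is
    held at S0 (invasion-phase linearization).  Deterministic.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if horizon < 10 * step:
        raise ValueError("horizon must be at least 10 steps")
    n = int(round(horizon / step))
    times = np.arange(n + 1) * step
    if isinstance(model, ObservableKernels):
        return _simulate_observable(model, times, step, seed_size)
    if isinstance(model, UnobservableKernels):
        return _simulate_unobservable(model, times, step, seed_size)
    if isinstance(model, BridgeKernels):
        return _simulate_bridge(model, times, step, seed_size)
    raise TypeError(f"unsupported model type: {type(model).__name__}")


def _simulate_observable(
    k: ObservableKernels, times: np.ndarray, step: float, seed_size: float
) -> IncidenceSeries:
    n = times.size - 1
    ages = times
    b_a, b_s = k.beta_A(ages), k.beta_S(ages)
    eta, g_a, g_s = k.eta(ages), k.gamma_A(ages), k.gamma_S(ages)
    total = eta + g_a
    _check_step(max(total.max(), g_s.max()), step)
    keep_a, keep_s = np.exp(-total * step), np.exp(-g_s * step)
    onset_frac = np.divide(eta, total, out=np.zeros_like(eta), where=total > 0)
    j_a, j_s = np.zeros(n + 1), np.zeros(n + 1)
    new_inf, new_on = np.zeros(n + 1), np.zeros(n + 1)
    j_a[0] = seed_size
    new_inf[0] = seed_size
    # trapezoidal (Heun) birth term: the new age-0 cohort feeds back into
    # the force of infection at the end of the step, solved for linearly;
    # cohorts created within a step (births, onset transfers) occur at the
    # half-step on average and carry a half-step decay, which keeps the
    # scheme second order in step
    enter_a = float(np.exp(-total[0] * step / 2.0))
    enter_s = float(np.exp(-g_s[0] * step / 2.0))
    feedback = 0.5 * k.S0 * step * b_a[0] * enter_a
    for j in range(1, n + 1):
        lam_old = b_a @ j_a + b_s @ j_s
        onsets = float(onset_frac @ (j_a * (1.0 - keep_a)))
        j_a[1:] = j_a[:-1] * keep_a[:-1]
        j_a[0] = 0.0
        j_s[1:] = j_s[:-1] * keep_s[:-1]
        j_s[0] = onsets * enter_s
        lam_aged = b_a @ j_a + b_s @ j_s
        births = 0.5 * k.S0 * step * (lam_old + lam_aged) / (1.0 - feedback)
        j_a[0] = births * enter_a
        # the newborn mass removed by the half-step decay routes onward:
        # its onset share enters the symptomatic stage this step
        j_s[0] += births * (1.0 - enter_a) * onset_frac[0]
        new_inf[j], new_on[j] = births, onsets
    return IncidenceSeries(times, new_inf, new_on, seed_size, step)


def _simulate_unobservable(
    k: UnobservableKernels, times: np.ndarray, step: float, seed_size: float
) -> IncidenceSeries:
    n = times.size - 1
    ages = times
    beta = k.beta(ages)
    eps, k_a, k_s = k.epsilon(ages), k.kappa_A(ages), k.kappa_S(ages)
    _check_step(max(eps.max(), k_a.max(), k_s.max()), step)
    keep_e = np.exp(-eps * step)
    keep_a, keep_s = np.exp(-k_a * step), np.exp(-k_s * step)
    e, i_a, i_s = np.zeros(n + 1), np.zeros(n + 1), np.zeros(n + 1)
    new_inf, new_on = np.zeros(n + 1), np.zeros(n + 1)
    e[0] = seed_size
    new_inf[0] = seed_size
    # within-step entries carry a half-step decay (second-order scheme)
    enter_e = float(np.exp(-eps[0] * step / 2.0))
    half_s, half_a = np.exp(-k_s * step / 2.0), np.exp(-k_a * step / 2.0)
    for j in range(1, n + 1):
        lam_old = beta @ (i_s + k.m * i_a)
        leaving = e * (1.0 - keep_e)
        to_s, to_a = k.k * leaving, (1.0 - k.k) * leaving
        i_s_new = i_s * keep_s + to_s * half_s
        i_a_new = i_a * keep_a + to_a * half_a
        e_new = e * keep_e
        e[1:], i_a[1:], i_s[1:] = e_new[:-1], i_a_new[:-1], i_s_new[:-1]
        e[0] = i_a[0] = i_s[0] = 0.0
        lam_aged = beta @ (i_s + k.m * i_a)
        # newly infected enter the latent stage, which does not transmit,
        # so the trapezoidal birth term has no same-step feedback
        births = 0.5 * k.S0 * step * (lam_old + lam_aged)
        e[0] = births * enter_e
        # latency exits among the newborn cohort route to the infectious
        # stages within the same step
        i_s[0] += k.k * births * (1.0 - enter_e)
        i_a[0] += (1.0 - k.k) * births * (1.0 - enter_e)
        new_inf[j], new_on[j] = births, float(np.sum(to_s))
    return IncidenceSeries(times, new_inf, new_on, seed_size, step)


def _simulate_bridge(
    k: BridgeKernels, times: np.ndarray, step: float, seed_size: float
) -> IncidenceSeries:
    n = times.size - 1
    ages = times
    beta, b_h, b_s = k.beta(ages), k.beta_H(ages), k.beta_S(ages)
    onset = k.eta(ages) / k.alpha
    rho, zeta, g_s = k.rho(ages), k.zeta_A(ages), k.gamma_S(ages)
    _check_step(max(onset.max(), rho.max(), zeta.max(), g_s.max()), step)
    keep_h = np.exp(-onset * step)
    keep_ha, keep_i, keep_js = (
        np.exp(-rho * step),
        np.exp(-zeta * step),
        np.exp(-g_s * step),
    )
    h_s, h_a, i_inf, j_s = (np.zeros(n + 1) for _ in range(4))
    new_inf, new_on = np.zeros(n + 1), np.zeros(n + 1)
    h_s[0] = k.alpha * seed_size
    h_a[0] = (1.0 - k.alpha) * seed_size
    new_inf[0] = seed_size
    # within-step entries carry a half-step decay (second-order scheme)
    enter_hs = float(np.exp(-onset[0] * step / 2.0))
    enter_ha = float(np.exp(-rho[0] * step / 2.0))
    enter_js = float(np.exp(-g_s[0] * step / 2.0))
    half_i = np.exp(-zeta * step / 2.0)
    feedback = 0.5 * k.S0 * step * k.alpha * b_h[0] * enter_hs
    for j in range(1, n + 1):
        lam_old = b_h @ h_s + k.m * (beta @ i_inf) + b_s @ j_s
        onsets = float(np.sum(h_s * (1.0 - keep_h)))
        to_i = h_a * (1.0 - keep_ha)
        i_new = i_inf * keep_i + to_i * half_i
        h_s[1:], h_a[1:], i_inf[1:] = (
            (h_s * keep_h)[:-1],
            (h_a * keep_ha)[:-1],
            i_new[:-1],
        )
        j_s[1:] = (j_s * keep_js)[:-1]
        h_s[0] = h_a[0] = i_inf[0] = 0.0
        j_s[0] = onsets * enter_js
        lam_aged = b_h @ h_s + k.m * (beta @ i_inf) + b_s @ j_s
        births = 0.5 * k.S0 * step * (lam_old + lam_aged) / (1.0 - feedback)
        h_s[0], h_a[0] = k.alpha * births * enter_hs, (1.0 - k.alpha) * births * enter_ha
        # stage exits among the newborn cohort route onward within the step
        j_s[0] += k.alpha * births * (1.0 - enter_hs)
        i_inf[0] += (1.0 - k.alpha) * births * (1.0 - enter_ha)
        new_inf[j], new_on[j] = births, onsets
    return IncidenceSeries(times, new_inf, new_on, seed_size, step)


def estimate_growth_rate(
    series: IncidenceSeries, window: tuple[float, float] | None = None
) -> GrowthEstimate:
    """Exponential growth rate by least squares on log new infections.

    The default window is the last 40% of the horizon (skipping the seeding
    transient).  All values inside the window must be strictly positive.
    """
    if window is None:
        window = (0.6 * series.horizon, series.horizon)
    t0, t1 = window
    if not (0.0 <= t0 < t1 <= series.horizon + 1e-12):
        raise ValueError("window must lie within the simulated horizon")
    mask = (series.times >= t0) & (series.times <= t1)
    y = series.new_infections[mask]
    if y.size < 3:
        raise ValueError("window contains fewer than 3 points")
    if np.any(y <= 0):
        raise ValueError(
            "new infections are nonpositive inside the window; "
            "choose a later window past the transient"
        )
    fit = linregress(series.times[mask], np.log(y))
    r_squared = 1.0 if np.isnan(fit.rvalue) else float(min(fit.rvalue**2, 1.0))
    return GrowthEstimate(
        r=float(fit.slope), window=(float(t0), float(t1)), fit_quality=r_squared
    )


def euler_lotka_residual(kernel: ReproductionKernel, r: float) -> float:
    """``int psi(tau) exp(-r*tau) dtau - 1``; zero at the Malthusian rate.

    At r = 0 this is R0 - 1; as r grows it tends to -1.
    """
    value = float(np.trapezoid(kernel.values * np.exp(-r * kernel.ages), kernel.ages))
    if not math.isfinite(value):
        raise DivergenceError("Euler-Lotka integral diverged at this growth rate")
    return value - 1.0


def euler_lotka_root(
    kernel: ReproductionKernel, bracket: tuple[float, float] = (-1.0, 1.0)
) -> float:
    """Malthusian growth rate: the root of the Euler-Lotka residual.

    The residual is strictly decreasing in r, so the bracket is expanded
    geometrically until it straddles zero, then solved by Brent's method.
    """
    lo, hi = bracket
    for _ in range(80):
        if euler_lotka_residual(kernel, hi) < 0.0:
            break
        hi *= 2.0
    else:
        raise DivergenceError("could not bracket the Euler-Lotka root from above")
    for _ in range(80):
        if euler_lotka_residual(kernel, lo) > 0.0:
            break
        lo = lo * 2.0 if lo < 0 else -1.0
    else:
        raise DivergenceError("could not bracket the Euler-Lotka root from below")
    return float(brentq(lambda r: euler_lotka_residual(kernel, r), lo, hi, xtol=1e-12))


def add_observation_noise(
    series: IncidenceSeries, dispersion: float = 10.0, seed: int = 0
) -> IncidenceSeries:
    """Overlay negative-binomial observation noise on a deterministic series.

    Each per-step expectation mu is replaced by a draw with mean mu and
    variance ``mu + mu^2/dispersion``; the overlay is the package's only
    source of randomness and is fully governed by ``seed``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)

    def draw(mu: np.ndarray) -> np.ndarray:
        out = np.zeros_like(mu)
        pos = mu > 0
        p = dispersion / (dispersion + mu[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
        return out

    return IncidenceSeries(
        times=series.times,
        new_infections=draw(series.new_infections),
        new_onsets=draw(series.new_onsets),
        seed_size=series.seed_size,
        step=series.step,
    )


def constant_rate_kernels(
    params: ObservableParams,
    asym_rate: float = 1.0,
    sym_rate: float = 1.0,
) -> ObservableKernels:
    """Constant-hazard kernels matched to a reduced-form parameter set.

    Splits the asymptomatic exit rate ``asym_rate`` into onset
    (``alpha * asym_rate``) and recovery, and scales the transmission rates
    so the kernel integrals reproduce R1, alpha and R2 exactly:
    ``beta_A = R1 * asym_rate``, ``beta_S = R2 * sym_rate``.  The stage
    durations (1/asym_rate, 1/sym_rate) are a simulation convention, not an
    estimate.
    """
    if asym_rate <= 0 or sym_rate <= 0:
        raise ValueError("stage exit rates must be positive")
    from .kernels import AgeRate

    return ObservableKernels(
        beta_A=AgeRate.constant(params.R1 * asym_rate),
        beta_S=AgeRate.constant(params.R2 * sym_rate),
        eta=AgeRate.constant(params.alpha * asym_rate),
        gamma_A=AgeRate.constant((1.0 - params.alpha) * asym_rate),
        gamma_S=AgeRate.constant(sym_rate),
        S0=params.S0,
    )
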