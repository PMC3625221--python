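"""Age-dependent rate kernels and survival machinery.

Stage-structured transmission models are driven by rates that depend on the
time elapsed since an event: infection-age ``tau`` (since the infection event)
or disease-age ``sigma`` (since symptom onset).  This module provides a small
representation for such rates (:class:`AgeRate`), survival curves obtained by
integrating competing hazards, and the quadratures that turn a mechanistic
kernel set into reduced-form reproduction numbers (the expected number of
secondary cases contributed by one stage of infection).

All rates default to constants, i.e. exponentially distributed stage
durations, which makes every reduced-form quantity closed form.  Piecewise
constant and Erlang-stage hazards are available for sensitivity work.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import erlang as _erlang_dist

from .exceptions import DivergenceError

__all__ = [
    "AgeRate",
    "SurvivalCurve",
    "evaluate_rate",
    "survival_from_hazards",
    "expected_reproduction_integral",
    "default_age_max",
    "stage_occupancy",
]

logger = logging.getLogger(__name__)

#: Integrated hazard at which a stage is considered exhausted
#: (survival below 1e-10).
_TAIL_LOG = -math.log(1e-10)


@dataclass(frozen=True)
class AgeRate:
    """A nonnegative rate (per unit time) as a function of age.

    Parameters
    ----------
    form
        One of ``"constant"``, ``"piecewise"`` (piecewise-constant on
        half-open intervals) or ``"erlang"`` (the hazard of an Erlang-stage
        duration, i.e. a chain of ``shape`` exponential substages).
    params
        Form-specific parameters; see the factory classmethods.
    support
        Right end of the age support ``[0, support)``.  Evaluation beyond the
        support extrapolates with the final value (constant extrapolation).
    """

    form: str
    params: dict = field(default_factory=dict)
    support: float = math.inf

    def __post_init__(self) -> None:
        if self.form not in ("constant", "piecewise", "erlang"):
            raise ValueError(f"unknown AgeRate form: {self.form!r}")
        if self.support <= 0:
            raise ValueError("support must be positive")
        if self.form == "constant":
            if self.params["rate"] < 0:
                raise ValueError("rate must be nonnegative")
        elif self.form == "piecewise":
            breaks = np.asarray(self.params["breaks"], dtype=float)
            values = np.asarray(self.params["values"], dtype=float)
            if breaks.ndim != 1 or breaks.size != values.size:
                raise ValueError("breaks and values must be 1-d and equal length")
            if breaks[0] != 0.0 or np.any(np.diff(breaks) <= 0):
                raise ValueError("breaks must start at 0 and be strictly increasing")
            if np.any(values < 0):
                raise ValueError("piecewise values must be nonnegative")
        elif self.form == "erlang":
            if int(self.params["shape"]) < 1 or self.params["rate"] <= 0:
                raise ValueError("erlang form needs shape >= 1 and rate > 0")

    # -- factories ---------------------------------------------------------

    @classmethod
    def constant(cls, rate: float, support: float = math.inf) -> "AgeRate":
        """A rate that does not depend on age (exponential stage duration)."""
        return cls("constant", {"rate": float(rate)}, support)

    @classmethod
    def piecewise(
        cls,
        breaks: Sequence[float],
        values: Sequence[float],
        support: float = math.inf,
    ) -> "AgeRate":
        """Piecewise-constant rate on half-open intervals ``[b_i, b_{i+1})``.

        The last piece extends to the end of the support.
        """
        return cls(
            "piecewise",
            {"breaks": [float(b) for b in breaks], "values": [float(v) for v in values]},
            support,
        )

    @classmethod
    def erlang_stage(
        cls, shape: int, rate: float, support: float = math.inf
    ) -> "AgeRate":
        """Hazard of an Erlang(shape, rate) stage duration.

        Equivalent to ``shape`` sequential exponential substages each with the
        given rate; the hazard rises from 0 (for shape > 1) toward ``rate``.
        """
        return cls("erlang", {"shape": int(shape), "rate": float(rate)}, support)

    # -- evaluation --------------------------------------------------------

    def __call__(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be nonnegative")
        # constant extrapolation beyond the support: clamp to just below it
        if math.isfinite(self.support):
            age = np.minimum(age, np.nextafter(self.support, 0.0))
        if self.form == "constant":
            out = np.full_like(age, self.params["rate"])
        elif self.form == "piecewise":
            breaks = np.asarray(self.params["breaks"], dtype=float)
            values = np.asarray(self.params["values"], dtype=float)
            idx = np.searchsorted(breaks, age, side="right") - 1
            out = values[idx]
        else:  # erlang
            shape, rate = self.params["shape"], self.params["rate"]
            dist = _erlang_dist(shape, scale=1.0 / rate)
            sf = dist.sf(age)
            with np.errstate(divide="ignore", invalid="ignore"):
                haz = dist.pdf(age) / np.maximum(sf, 1e-300)
            # deep in the tail the hazard converges to the substage rate
            out = np.where(sf > 1e-12, haz, rate)
        return out if out.ndim else float(out)

    @property
    def is_constant(self) -> bool:
        return self.form == "constant"

    def scaled(self, factor: float) -> "AgeRate":
        """Return this rate multiplied by a nonnegative scalar."""
        if factor < 0:
            raise ValueError("scale factor must be nonnegative")
        if self.form == "constant":
            return AgeRate.constant(self.params["rate"] * factor, self.support)
        if self.form == "piecewise":
            return AgeRate.piecewise(
                self.params["breaks"],
                [v * factor for v in self.params["values"]],
                self.support,
            )
        raise NotImplementedError("scaling an erlang-stage hazard leaves the family")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        support = self.support if math.isfinite(self.support) else None
        return {"form": self.form, "params": dict(self.params), "support": support}

    @classmethod
    def from_dict(cls, obj: dict) -> "AgeRate":
        support = obj.get("support")
        return cls(obj["form"], dict(obj["params"]), math.inf if support is None else support)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "AgeRate":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class SurvivalCurve:
    """Probability of still being in a stage as a function of age.

    ``values[i] = exp(-integral of the total hazard up to ages[i])``;
    starts at 1 and is nonincreasing.
    """

    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if ages.shape != values.shape or ages.ndim != 1:
            raise ValueError("ages and values must be 1-d arrays of equal length")
        if np.any(np.diff(ages) < 0) or ages[0] != 0.0:
            raise ValueError("ages must be a nondecreasing grid starting at 0")
        if abs(values[0] - 1.0) > 1e-12:
            raise ValueError("survival must start at 1")
        if np.any(np.diff(values) > 1e-12) or np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
            raise ValueError("survival must be nonincreasing within [0, 1]")

    def __call__(self, age):
        return np.interp(age, self.ages, self.values)

    @property
    def step(self) -> float:
        return float(self.ages[1] - self.ages[0]) if self.ages.size > 1 else 0.0


def evaluate_rate(rate: AgeRate, age) -> float:
    """Evaluate an age-dependent rate; negative ages are a domain error."""
    return rate(age)


def _summed_hazard(hazards: Sequence[AgeRate], ages: np.ndarray) -> np.ndarray:
    total = np.zeros_like(ages)
    for h in hazards:
        total = total + h(ages)
    return total


def _midpoint_cumulative_hazard(
    hazards: Sequence[AgeRate], ages: np.ndarray
) -> np.ndarray:
    """Cumulative total hazard by the midpoint rule.

    Exact for piecewise-constant hazards whose breaks align with grid nodes
    (the midpoint samples the interior of each piece), second-order accurate
    otherwise.
    """
    mids = 0.5 * (ages[1:] + ages[:-1])
    total_mid = _summed_hazard(hazards, mids) if hazards else np.zeros_like(mids)
    return np.concatenate(([0.0], np.cumsum(total_mid * np.diff(ages))))


def default_age_max(
    hazards: Sequence[AgeRate], tail: float = 1e-10, cap: float = 1e6
) -> float:
    """Age at which the joint survival of the given hazards drops below ``tail``.

    Doubles a trial horizon until the integrated total hazard exceeds
    ``-log(tail)``; raises :class:`DivergenceError` if that never happens
    before ``cap`` (no absorbing hazard on the stage).
    """
    target = -math.log(tail)
    horizon = 16.0
    while horizon <= cap:
        ages = np.linspace(0.0, horizon, 4097)
        cum = cumulative_trapezoid(_summed_hazard(hazards, ages), ages, initial=0.0)
        if cum[-1] >= target:
            idx = int(np.searchsorted(cum, target))
            return float(ages[min(idx, ages.size - 1)])
        horizon *= 2.0
    raise DivergenceError(
        "integrated hazard never reaches the truncation target; "
        "the stage has no absorbing exit (infinite-mass kernel)"
    )


def survival_from_hazards(
    hazards: Sequence[AgeRate],
    grid_step: float = 0.01,
    age_max: float | None = None,
) -> SurvivalCurve:
    """Survival ``exp(-int_0^tau sum(hazards))`` on a uniform grid.

    An empty hazard list yields the all-ones curve (nothing removes the
    individual from the stage); this is documented behavior, not an error.
    ``age_max`` defaults to the point where survival falls below 1e-10
    (requires at least one absorbing hazard).
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if age_max is None:
        if not hazards:
            raise ValueError("age_max is required for an empty hazard list")
        age_max = default_age_max(hazards)
    if age_max < grid_step:
        raise ValueError("age_max must be at least grid_step")
    n = int(math.ceil(age_max / grid_step))
    ages = np.arange(n + 1) * grid_step
    return SurvivalCurve(ages, np.exp(-_midpoint_cumulative_hazard(hazards, ages)))


def expected_reproduction_integral(
    transmissibility: AgeRate,
    survival: SurvivalCurve,
    grid_step: float | None = None,
) -> float:
    """Expected secondary cases from one stage: ``int beta(tau) * S(tau) dtau``.

    Trapezoid rule on the survival grid.  If ``grid_step`` is given and
    differs from the survival grid, the survival curve is resampled by linear
    interpolation (logged, never silent).
    """
    ages, values = survival.ages, survival.values
    if grid_step is not None and not math.isclose(grid_step, survival.step):
        n = int(math.ceil(ages[-1] / grid_step))
        new_ages = np.arange(n + 1) * grid_step
        logger.info(
            "resampling survival grid from step %g to %g", survival.step, grid_step
        )
        values = np.interp(new_ages, ages, values)
        ages = new_ages
    if values[-1] > 1e-6:
        logger.warning(
            "survival is %.3g at truncation age %.3g; the reproduction "
            "integral may be truncated",
            values[-1],
            ages[-1],
        )
    beta = transmissibility(ages)
    return float(np.trapezoid(beta * values, ages))


def stage_occupancy(
    entry_flux: np.ndarray, exit_hazard: AgeRate | None, ages: np.ndarray
) -> np.ndarray:
    """Probability of occupying a downstream stage at each age.

    Given the density ``entry_flux(s)`` of entering the stage at age ``s``
    (per unit age, e.g. ``rate(s) * upstream_survival(s)``) and the hazard of
    leaving it, returns ``P(tau) = int_0^tau entry_flux(s) *
    exp(-int_s^tau exit_hazard) ds`` by a second-order exponential-decay
    recursion (stable for arbitrarily long grids, no overflowing
    exponentials).
    """
    ages = np.asarray(ages, dtype=float)
    f = np.asarray(entry_flux, dtype=float)
    if f.shape != ages.shape:
        raise ValueError("entry_flux must be evaluated on the same grid as ages")
    k = np.zeros_like(ages) if exit_hazard is None else exit_hazard(ages)
    out = np.zeros_like(ages)
    for i in range(ages.size - 1):
        dt = ages[i + 1] - ages[i]
        decay = math.exp(-0.5 * (k[i] + k[i + 1]) * dt)
        out[i + 1] = out[i] * decay + 0.5 * dt * (f[i] * decay + f[i + 1])
    return out
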