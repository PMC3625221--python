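"""Vaccination: next-generation matrices, effective reproduction numbers and
critical coverage.

A randomly mixing population is split into unvaccinated and vaccinated hosts.
The vaccine acts multiplicatively through three efficacies: VE_S reduces
susceptibility (remaining susceptibility ``q_S = 1 - VE_S``), VE_I reduces
infectiousness (``q_I = 1 - VE_I``), and VE_P prevents symptomatic illness
(``q_D = 1 - VE_P``).  The 2x2 next-generation matrix has rows indexed by the
infectee stratum (unvaccinated first) and columns by the infector stratum:

    K = [[(1-p) * A,      (1-p) * q_I * B],
         [p * q_S * A,    p * q_S * q_I * B]]

where A is the per-infector reproduction number of an unvaccinated case and B
that of a vaccinated case (the symptom-prevention effect q_D appears only in
B, i.e. only in the second column).  The two model families disagree on B:

* symptom-based model:      A = R1 + alpha*R2,        B = R1 + alpha*q_D*R2
  (preventing symptoms removes the symptomatic-stage transmission);
* SEIR-type model:          A = (1-k)*R3 + k*R4,      B = (1-k*q_D)*R3 + k*q_D*R4
  (preventing symptoms turns would-be symptomatic cases into asymptomatic
  *infectious* cases — the vaccine effect is forced onto the latency exit).

K has rank one (columns proportional to ((1-p), p*q_S)), so the effective
reproduction number — its dominant eigenvalue — equals the trace
``(1-p)*A + p*q_S*q_I*B``, and the critical coverage solves that for 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, NamedTuple, Sequence, Union

import numpy as np

from .observable import ObservableParams
from .unobservable import UnobservableParams

__all__ = [
    "VaccineEffects",
    "NextGenMatrix",
    "ngm_observable",
    "ngm_unobservable",
    "dominant_eigenvalue",
    "effective_r",
    "critical_coverage",
    "CriticalCoverage",
    "rv_comparison_sweep",
    "RvSweepPoint",
]

ModelParams = Union[ObservableParams, UnobservableParams]


@dataclass(frozen=True)
class VaccineEffects:
    """Coverage and the three vaccine efficacies.

    ``p`` may be ``None`` when the coverage is the unknown (critical-coverage
    solving).  The residual multipliers ``q_S = 1 - VE_S`` etc. are derived
    properties, so they can never drift out of sync with the efficacies.
    """

    ve_s: float
    ve_i: float
    ve_p: float
    p: float | None = None

    def __post_init__(self) -> None:
        for name in ("ve_s", "ve_i", "ve_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ValueError("coverage p must lie in [0, 1]")

    @property
    def q_s(self) -> float:
        return 1.0 - self.ve_s

    @property
    def q_i(self) -> float:
        return 1.0 - self.ve_i

    @property
    def q_d(self) -> float:
        return 1.0 - self.ve_p

    def with_coverage(self, p: float) -> "VaccineEffects":
        return replace(self, p=p)

    def with_ve_p(self, ve_p: float) -> "VaccineEffects":
        return replace(self, ve_p=ve_p)


@dataclass(frozen=True)
class NextGenMatrix:
    """2x2 stratified secondary-case matrix (row = infectee stratum,
    unvaccinated first; column = infector stratum)."""

    entries: np.ndarray
    model_tag: Literal["observable", "unobservable"]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        if entries.shape != (2, 2):
            raise ValueError("next-generation matrix must be 2x2")
        if np.any(entries < 0):
            raise ValueError("next-generation matrix entries must be nonnegative")


def _ab_observable(obs: ObservableParams, q_d: float) -> tuple[float, float]:
    a = obs.R1 + obs.alpha * obs.R2
    b = obs.R1 + obs.alpha * q_d * obs.R2
    return a, b


def _ab_unobservable(unobs: UnobservableParams, q_d: float) -> tuple[float, float]:
    a = (1.0 - unobs.k) * unobs.R3 + unobs.k * unobs.R4
    b = (1.0 - unobs.k * q_d) * unobs.R3 + unobs.k * q_d * unobs.R4
    return a, b


def _infector_terms(params: ModelParams, q_d: float) -> tuple[float, float, str]:
    if isinstance(params, ObservableParams):
        return (*_ab_observable(params, q_d), "observable")
    if isinstance(params, UnobservableParams):
        return (*_ab_unobservable(params, q_d), "unobservable")
    raise TypeError(f"unsupported parameter type: {type(params).__name__}")


def _build_ngm(a: float, b: float, v: VaccineEffects, tag: str) -> NextGenMatrix:
    if v.p is None:
        raise ValueError("vaccine effects must carry a coverage p to build the NGM")
    entries = np.array(
        [
            [(1.0 - v.p) * a, (1.0 - v.p) * v.q_i * b],
            [v.p * v.q_s * a, v.p * v.q_s * v.q_i * b],
        ]
    )
    return NextGenMatrix(entries=entries, model_tag=tag)  # type: ignore[arg-type]


def ngm_observable(obs: ObservableParams, v: VaccineEffects) -> NextGenMatrix:
    """Next-generation matrix of the symptom-based model under vaccination."""
    a, b = _ab_observable(obs, v.q_d)
    return _build_ngm(a, b, v, "observable")


def ngm_unobservable(unobs: UnobservableParams, v: VaccineEffects) -> NextGenMatrix:
    """Next-generation matrix of the SEIR-type model under vaccination.

    q_D shifts the symptomatic weight k to k*q_D: vaccinated cases whose
    symptoms are prevented remain infectious, merely reclassified as
    asymptomatic.
    """
    a, b = _ab_unobservable(unobs, v.q_d)
    return _build_ngm(a, b, v, "unobservable")


def dominant_eigenvalue(K: NextGenMatrix) -> float:
    """Largest eigenvalue modulus of the 2x2 matrix.

    The vaccination matrices here are rank one by construction, for which the
    dominant eigenvalue equals the trace; this identity is asserted
    internally whenever the columns are numerically proportional.
    """
    m = K.entries
    eig = float(np.max(np.abs(np.linalg.eigvals(m))))
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    scale = max(float(np.max(np.abs(m))), 1.0)
    if abs(det) <= 1e-10 * scale**2:  # rank one: spectrum is {trace, 0}
        trace = float(np.trace(m))
        assert abs(eig - trace) <= 1e-8 * max(trace, 1.0), (
            "rank-one NGM eigenvalue must equal its trace"
        )
    return eig


def effective_r(params: ModelParams, v: VaccineEffects) -> float:
    """Effective reproduction number under vaccination.

    Dominant eigenvalue of the model's next-generation matrix; equal in
    closed form to ``(1-p)*A + p*q_S*q_I*B``.
    """
    a, b, tag = _infector_terms(params, v.q_d)
    return dominant_eigenvalue(_build_ngm(a, b, v, tag))


class CriticalCoverage(NamedTuple):
    p_star: float
    status: Literal["interior", "always_subcritical", "uncontrollable"]


def critical_coverage(params: ModelParams, v: VaccineEffects) -> CriticalCoverage:
    """Smallest coverage p making the effective reproduction number 1.

    Solves ``(1-p)*A + p*q_S*q_I*B = 1`` in closed form:
    ``p* = (A - 1) / (A - q_S*q_I*B)``.  With a perfect vaccine
    (``q_S*q_I*B = 0``) this is the classical ``1 - 1/R0``.  Status is
    ``always_subcritical`` when A <= 1 (p* = 0) and ``uncontrollable`` when
    the fully vaccinated limit ``q_S*q_I*B`` is itself >= 1 (no coverage in
    [0, 1] reaches the threshold; p* reported as NaN).
    """
    a, b, _ = _infector_terms(params, v.q_d)
    residual = v.q_s * v.q_i * b
    if a <= 1.0:
        return CriticalCoverage(p_star=0.0, status="always_subcritical")
    if residual >= 1.0:
        return CriticalCoverage(p_star=float("nan"), status="uncontrollable")
    return CriticalCoverage(p_star=(a - 1.0) / (a - residual), status="interior")


class RvSweepPoint(NamedTuple):
    ve_p: float
    rv_obs: float
    rv_non: float


def rv_comparison_sweep(
    obs: ObservableParams,
    unobs: UnobservableParams,
    v: VaccineEffects,
    ve_p_grid: Sequence[float],
) -> list[RvSweepPoint]:
    """Effective reproduction numbers of both models across VE_P.

    Coverage and the other two efficacies are held at ``v``; only the
    symptom-prevention efficacy is swept.  At VE_P = 0 the two curves
    coincide whenever the parameter sets share a threshold (calibration).
    """
    out = []
    for ve_p in ve_p_grid:
        vv = v.with_ve_p(float(ve_p))
        out.append(
            RvSweepPoint(
                ve_p=float(ve_p),
                rv_obs=effective_r(obs, vv),
                rv_non=effective_r(unobs, vv),
            )
        )
    return out
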