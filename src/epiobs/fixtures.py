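"""Bundled disease parameter fixtures and cross-relation validation.

Four reduced-form parameter sets ship with the package — smallpox,
influenza, HIV and varicella — spanning the range from almost no
asymptomatic transmission (smallpox) to exclusively pre-onset transmission
(HIV).  Each fixture stores the printed reduced-form values (R1, R2, R_a,
alpha, theta, g, R0 and the three vaccine efficacies) together with
provenance notes.  The pre-symptomatic reproduction number R_pre is never
printed in such tables; it is derived at load time from the bookkeeping
identity ``alpha * R_pre = g * theta * R0`` and the derivation is logged.

Validation checks every closure identity linking the stored values at
tolerances that reflect the 2-decimal printed precision; a tightened
tolerance documents exactly which printed entries are rounding-affected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .bridge import BridgeParams
from .exceptions import FixtureValidationError
from .observable import ObservableParams, r0_observable
from .unobservable import UnobservableParams, calibrate_to_observable
from .vaccination import VaccineEffects

__all__ = [
    "DiseaseFixture",
    "RelationCheck",
    "ValidationReport",
    "BUNDLED_FIXTURES",
    "load_fixture",
    "save_fixture",
    "validate_cross_relations",
]

logger = logging.getLogger(__name__)

BUNDLED_FIXTURES = ("smallpox", "influenza", "hiv", "varicella")

# printed tables carry 2 decimals; two independently rounded entries can
# disagree by up to ~0.015, derived closures by ~0.02
TOL_R0 = 0.015
TOL_THETA = 0.01
TOL_CLOSURE = 0.02


@dataclass(frozen=True)
class DiseaseFixture:
    """One disease's reduced-form parameter set plus vaccine efficacies."""

    name: str
    observable: ObservableParams | None
    r_a: float = 0.0
    g: float = 0.0
    theta: float = 0.0
    r0_printed: float | None = None
    m_assumed: float = 0.5
    vaccine: VaccineEffects | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def r0(self) -> float:
        """Recomposed basic reproduction number ``R1 + alpha * R2``."""
        if self.observable is None:
            raise ValueError("fixture has no observable parameters")
        return r0_observable(self.observable)

    @property
    def r_pre(self) -> float:
        """Pre-symptomatic reproduction number from the decomposition closure.

        ``R_pre = g * theta * R0 / alpha`` (total asymptomatic transmission
        ``theta * R0`` times the pre-symptomatic share, per symptomatic
        infection).
        """
        obs = self.observable
        if obs is None or obs.alpha <= 0.0:
            raise ValueError("R_pre derivation requires alpha > 0")
        return self.g * self.theta * self.r0 / obs.alpha

    @property
    def bridge(self) -> BridgeParams:
        """Bridge-model parameter set with the derived R_pre."""
        obs = self.observable
        if obs is None:
            raise ValueError("fixture has no observable parameters")
        return BridgeParams(
            R_a=self.r_a, R_pre=self.r_pre, R2=obs.R2, alpha=obs.alpha, g=self.g
        )

    def calibrated_unobservable(self, m: float | None = None) -> UnobservableParams:
        """SEIR-type parameters sharing this fixture's epidemic threshold."""
        if self.observable is None:
            raise ValueError("fixture has no observable parameters")
        return calibrate_to_observable(
            self.observable, self.m_assumed if m is None else m
        )

    def to_dict(self) -> dict:
        obs = self.observable
        return {
            "name": self.name,
            "observable": None
            if obs is None
            else {"R1": obs.R1, "R2": obs.R2, "alpha": obs.alpha},
            "R_a": self.r_a,
            "g": self.g,
            "theta": self.theta,
            "R0_printed": self.r0_printed,
            "m_assumed": self.m_assumed,
            "vaccine": None
            if self.vaccine is None
            else {
                "VE_S": self.vaccine.ve_s,
                "VE_I": self.vaccine.ve_i,
                "VE_P": self.vaccine.ve_p,
            },
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "DiseaseFixture":
        obs = obj.get("observable")
        vac = obj.get("vaccine")
        return cls(
            name=obj["name"],
            observable=None
            if obs is None
            else ObservableParams(R1=obs["R1"], R2=obs["R2"], alpha=obs["alpha"]),
            r_a=float(obj.get("R_a", 0.0)),
            g=float(obj.get("g", 0.0)),
            theta=float(obj.get("theta", 0.0)),
            r0_printed=obj.get("R0_printed"),
            m_assumed=float(obj.get("m_assumed", 0.5)),
            vaccine=None
            if vac is None
            else VaccineEffects(ve_s=vac["VE_S"], ve_i=vac["VE_I"], ve_p=vac["VE_P"]),
            provenance=dict(obj.get("provenance", {})),
        )


@dataclass(frozen=True)
class RelationCheck:
    """One closure identity: computed vs stored value and its deviation."""

    relation: str
    computed: float
    stored: float
    deviation: float
    tolerance: float
    passed: bool


@dataclass(frozen=True)
class ValidationReport:
    fixture_name: str
    checks: tuple[RelationCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def failures(self) -> tuple[RelationCheck, ...]:
        return tuple(c for c in self.checks if not c.passed)

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["relation", "computed", "stored", "deviation", "tolerance", "passed"]
            )
            for c in self.checks:
                writer.writerow(
                    [c.relation, c.computed, c.stored, c.deviation, c.tolerance, c.passed]
                )


def validate_cross_relations(
    fixture: DiseaseFixture,
    tol_r0: float = TOL_R0,
    tol_theta: float = TOL_THETA,
    tol_closure: float = TOL_CLOSURE,
) -> ValidationReport:
    """Check the closure identities linking a fixture's stored values.

    Relations (all use the recomposed R0 = R1 + alpha*R2):

    * ``r0_recomposition``: recomposed R0 vs the printed R0;
    * ``theta_closure``: ``theta * R0`` vs R1;
    * ``g_closure``: stored g vs ``1 - (1-alpha) * R_a / (theta * R0)``;
    * ``r_a_closure``: ``(1-alpha) * R_a`` vs ``(1-g) * theta * R0``.

    Report-only: deviations are listed, nothing is raised.  A fixture
    without observable parameters yields an empty report.
    """
    if fixture.observable is None:
        return ValidationReport(fixture_name=fixture.name, checks=())
    obs = fixture.observable
    r0 = fixture.r0
    checks: list[RelationCheck] = []

    def add(relation: str, computed: float, stored: float, tol: float) -> None:
        dev = abs(computed - stored)
        checks.append(
            RelationCheck(
                relation=relation,
                computed=computed,
                stored=stored,
                deviation=dev,
                tolerance=tol,
                passed=dev <= tol,
            )
        )

    if fixture.r0_printed is not None:
        add("r0_recomposition", r0, float(fixture.r0_printed), tol_r0)
    add("theta_closure", fixture.theta * r0, obs.R1, tol_theta)
    total_asym = fixture.theta * r0
    if total_asym > 0:
        g_computed = 1.0 - (1.0 - obs.alpha) * fixture.r_a / total_asym
        add("g_closure", g_computed, fixture.g, tol_closure)
    add(
        "r_a_closure",
        (1.0 - obs.alpha) * fixture.r_a,
        (1.0 - fixture.g) * total_asym,
        tol_closure,
    )
    return ValidationReport(fixture_name=fixture.name, checks=tuple(checks))


def _read_bundled(name: str) -> dict:
    path = resources.files("epiobs.data").joinpath(f"{name}.json")
    return json.loads(path.read_text())


def load_fixture(name_or_path: str | Path, validate: bool = True) -> DiseaseFixture:
    """Load a bundled fixture by name or a user fixture from a JSON file.

    Validates the closure identities by default and raises
    :class:`~epiobs.exceptions.FixtureValidationError` listing every failed
    relation with its computed and stored values.  The derived R_pre is
    logged with its formula.
    """
    name = str(name_or_path)
    if name in BUNDLED_FIXTURES:
        obj = _read_bundled(name)
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise FileNotFoundError(
                f"unknown fixture {name!r}; bundled fixtures are "
                f"{', '.join(BUNDLED_FIXTURES)}"
            )
        obj = json.loads(path.read_text())
    fixture = DiseaseFixture.from_dict(obj)
    if validate:
        report = validate_cross_relations(fixture)
        if not report.passed:
            lines = [
                f"  {c.relation}: computed {c.computed:.6g} vs stored "
                f"{c.stored:.6g} (|dev| = {c.deviation:.3g} > tol {c.tolerance:g})"
                for c in report.failures
            ]
            raise FixtureValidationError(
                f"fixture {fixture.name!r} failed cross-relation validation:\n"
                + "\n".join(lines)
            )
    if fixture.observable is not None and fixture.observable.alpha > 0:
        logger.info(
            "fixture %s: derived R_pre = g*theta*R0/alpha = "
            "%.4g * %.4g * %.4g / %.4g = %.4g",
            fixture.name,
            fixture.g,
            fixture.theta,
            fixture.r0,
            fixture.observable.alpha,
            fixture.r_pre,
        )
    return fixture


def save_fixture(fixture: DiseaseFixture, path: str | Path) -> None:
    """Write a fixture to JSON (round-trips through :func:`load_fixture`)."""
    Path(path).write_text(json.dumps(fixture.to_dict(), indent=2) + "\n")
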