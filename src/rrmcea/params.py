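"""The parameter bundle: everything one model run consumes.

A :class:`ParameterSet` aggregates the model configuration, age tables,
intervention effects, disease history, costs, utilities, sensitivity
specifications, and the population-impact mix.  Scalars inside the
bundle are addressable by dotted paths (``costs.rrm``,
``utilities.stage_year1.STAGE2``, ``intervention.uptake``) for one-way
and probabilistic sensitivity analysis.

Every value carries a provenance tag (``paper`` | ``fixture`` |
``user``) recorded in ``provenance``.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .disease import (
    N_STAGES,
    STAGES,
    ContextParams,
    DiseaseHistoryParams,
    PathologyMix,
    ScreeningPerformance,
)
from .economics import CostTable, UtilityTable
from .errors import ConfigError, ValidationError
from .markov import ModelConfig
from .tables import AgeRateTable

SCHEMA_VERSION = 1


class Distribution(str, enum.Enum):
    GAMMA = "GAMMA"
    BETA = "BETA"
    LOGNORMAL = "LOGNORMAL"
    FIXED = "FIXED"


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain scalar: point value, deterministic range, PSA family."""

    name: str
    point: float
    low: float
    high: float
    distribution: Distribution
    dispersion: Optional[float] = None  # standard error; None -> default

    def __post_init__(self) -> None:
        if not self.low <= self.point <= self.high:
            raise ValidationError(
                f"{self.name}: require low <= point <= high "
                f"({self.low}, {self.point}, {self.high})"
            )
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValidationError(f"{self.name}: dispersion must be positive")


@dataclass(frozen=True)
class InterventionParams:
    """Effect sizes shared by both arms."""

    rrm_hazard_ratio: float = 0.09      # residual incidence after surgery
    rrm_hr_low: float = 0.02            # complement of 98% risk reduction
    rrm_hr_high: float = 0.38           # complement of 62% risk reduction
    hr_tamoxifen: float = 0.71
    hr_anastrozole: float = 0.51
    uptake: float = 0.163
    duration: int = 5
    carryover_years: int = 5

    def __post_init__(self) -> None:
        if not self.rrm_hr_low <= self.rrm_hazard_ratio <= self.rrm_hr_high:
            raise ValidationError("rrm hazard ratio outside its stated range")


@dataclass(frozen=True)
class PrevalenceMix:
    """High-risk subgroups of the female population for impact arithmetic.

    ``subgroups`` is a sequence of (prevalence, mean lifetime risk)
    pairs; ``population_lifetime_risk`` is the all-women lifetime risk
    and ``annual_cases`` the national annual case count.
    """

    subgroups: tuple
    population_lifetime_risk: float
    annual_cases: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "subgroups", tuple((float(p), float(r)) for p, r in self.subgroups)
        )
        if sum(p for p, _ in self.subgroups) > 1.0 + 1e-12:
            raise ValidationError("subgroup prevalences must sum to at most 1")
        for p, r in self.subgroups:
            if not (0.0 <= p <= 1.0 and 0.0 < r < 1.0):
                raise ValidationError("prevalences in [0,1], risks in (0,1)")
        if not 0.0 < self.population_lifetime_risk < 1.0:
            raise ValidationError("population lifetime risk must lie in (0,1)")
        if self.annual_cases < 0:
            raise ValidationError("annual_cases must be non-negative")


@dataclass
class ParameterSet:
    config: ModelConfig
    baseline_lifetime_risk: float
    incidence: AgeRateTable
    mortality: AgeRateTable
    intervention: InterventionParams
    disease: DiseaseHistoryParams
    costs: CostTable
    utilities: UtilityTable
    specs: tuple
    impact: PrevalenceMix
    wtp_low: float = 20_000.0
    wtp_high: float = 30_000.0
    discount_cost: float = 0.035
    discount_effect: float = 0.035
    provenance: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def __eq__(self, other):
        if not isinstance(other, ParameterSet):
            return NotImplemented
        for f in self.__dataclass_fields__:
            if getattr(self, f) != getattr(other, f):
                return False
        return True


# ---------------------------------------------------------------------------
# dotted-path resolution

_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


def _step(obj, seg: str):
    if isinstance(obj, np.ndarray):
        if seg in _STAGE_INDEX:
            return _STAGE_INDEX[seg]
        try:
            return int(seg)
        except ValueError as e:
            raise ConfigError(f"cannot index array with {seg!r}") from e
    return seg


def resolve(bundle: ParameterSet, path: str) -> float:
    """Read one scalar addressed by a dotted path."""
    obj = bundle
    for seg in path.split("."):
        if isinstance(obj, np.ndarray):
            obj = obj[_step(obj, seg)]
        elif isinstance(obj, dict):
            if seg not in obj:
                raise ConfigError(f"unresolvable path segment {seg!r} in {path!r}")
            obj = obj[seg]
        elif hasattr(obj, seg):
            obj = getattr(obj, seg)
        else:
            raise ConfigError(f"unresolvable path segment {seg!r} in {path!r}")
    if isinstance(obj, (int, float, np.floating, np.integer)):
        return float(obj)
    raise ConfigError(f"path {path!r} does not resolve to a scalar")


def assign(bundle: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a deep copy of the bundle with one scalar replaced."""
    new = bundle.copy()
    assign_inplace(new, path, value)
    return new


def assign_inplace(bundle: ParameterSet, path: str, value: float) -> None:
    """Replace one scalar inside an owned bundle without re-copying it.

    Invariant checks (``__post_init__``) re-run on every touched
    dataclass along the path.
    """
    segs = path.split(".")

    def set_on(obj, rest):
        seg = rest[0]
        if isinstance(obj, np.ndarray):
            idx = _step(obj, seg)
            if len(rest) == 1:
                obj[idx] = value
                return obj
            set_on(obj[idx], rest[1:])
            return obj
        if isinstance(obj, dict):
            if seg not in obj:
                raise ConfigError(f"unresolvable path segment {seg!r} in {path!r}")
            if len(rest) == 1:
                obj[seg] = value
            else:
                obj[seg] = set_on(obj[seg], rest[1:])
            return obj
        if not hasattr(obj, seg):
            raise ConfigError(f"unresolvable path segment {seg!r} in {path!r}")
        if len(rest) == 1:
            child = value
        else:
            child = set_on(getattr(obj, seg), rest[1:])
        if hasattr(obj, "__dataclass_fields__"):
            try:
                object.__setattr__(obj, seg, child)  # frozen-safe in-place
            except Exception as e:  # pragma: no cover
                raise ConfigError(f"cannot assign {path!r}") from e
            # re-run invariant checks where defined
            post = getattr(obj, "__post_init__", None)
            if post is not None:
                post()
            return obj
        setattr(obj, seg, child)
        return obj

    set_on(bundle, segs)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    def add(self, path: str, message: str) -> None:
        self.violations.append((path, message))

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_if_invalid(self) -> None:
        if not self.ok:
            lines = "; ".join(f"{p}: {m}" for p, m in self.violations)
            raise ValidationError(f"invalid parameter bundle: {lines}")

    def __str__(self) -> str:
        if self.ok:
            return "bundle valid: no violations"
        return "\n".join(f"{p}: {m}" for p, m in self.violations)


def validate(bundle: ParameterSet) -> ValidationReport:
    """Check every cross-module invariant; never raises on content.

    Type-level invariants (ranges, shapes, sums) are enforced at
    construction; this re-checks them plus the bundle-level rules that
    single types cannot see (table coverage, risk-window consistency).
    """
    rep = ValidationReport()
    cfg = bundle.config
    for name in ("incidence", "mortality"):
        tab: AgeRateTable = getattr(bundle, name)
        if not tab.covers(20, 80):
            rep.add(name, f"must cover ages [20, 80), covers [{tab.start}, {tab.end})")
        if np.any(tab.values < 0) or np.any(tab.values > 1):
            rep.add(name, "annual probabilities outside [0, 1]")
    if not bundle.utilities.norms.covers(cfg.start_age, cfg.horizon_age):
        rep.add("utilities.norms", "must cover the model age range")
    if not 0.0 < bundle.baseline_lifetime_risk < 1.0:
        rep.add("baseline_lifetime_risk", "must lie in (0, 1)")
    for ctx in ("screened", "general", "post_rrm"):
        cp: ContextParams = bundle.disease.context(ctx)
        s = float(cp.stage_distribution.probabilities.sum())
        if abs(s - 1.0) > 1e-12:
            rep.add(f"disease.{ctx}.stage_distribution", f"sums to {s:.15g}, not 1")
        if np.any(cp.bc_death + cp.distant_recurrence > 1.0 + 1e-12):
            rep.add(f"disease.{ctx}", "death + distant recurrence exceeds 1")
    if bundle.disease.survivor_cutoff != 20:
        rep.add("disease.survivor_cutoff", "fixed at 20 years")
    for name in ("rrm", "mammography", "mri"):
        if getattr(bundle.costs, name) < 0:
            rep.add(f"costs.{name}", "must be non-negative")
    for name in ("stage_first_year", "stage_subsequent", "stage_terminal"):
        if np.any(getattr(bundle.costs, name) < 0):
            rep.add(f"costs.{name}", "entries must be non-negative")
    iv = bundle.intervention
    if not 0.0 <= iv.uptake <= 1.0:
        rep.add("intervention.uptake", "must lie in [0, 1]")
    for name in ("rrm_hazard_ratio", "hr_tamoxifen", "hr_anastrozole"):
        v = getattr(iv, name)
        if not 0.0 <= v <= 1.0:
            rep.add(f"intervention.{name}", "must lie in [0, 1]")
    if bundle.wtp_low > bundle.wtp_high:
        rep.add("wtp_low", "must not exceed wtp_high")
    for name in ("discount_cost", "discount_effect"):
        if getattr(bundle, name) < 0:
            rep.add(name, "must be non-negative")
    for spec in bundle.specs:
        try:
            resolve(bundle, spec.name)
        except ConfigError:
            rep.add(f"specs.{spec.name}", "does not resolve to a scalar")
        if not spec.low <= spec.point <= spec.high:
            rep.add(f"specs.{spec.name}", "range must bracket the point value")
    prevs = sum(p for p, _ in bundle.impact.subgroups)
    if prevs > 1.0 + 1e-12:
        rep.add("impact.subgroups", "prevalences sum above 1")
    return rep
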