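"""Parameter-bundle serialization: one YAML config plus CSV side-tables.

A bundle directory contains ``params.yaml`` (scalars, nested groups,
sensitivity specs) and referenced CSV tables — the age-indexed rates as
two-column ``age,probability`` files and the per-context disease history
as long-format ``stage,year,...`` files — so the age tables stay
diffable.  Reading is strict: unknown keys are an error, missing table
files are reported with their path, and a write -> read round trip is
bit-identical.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .disease import (
    STAGES,
    ContextParams,
    DiseaseHistoryParams,
    PathologyMix,
    ScreeningPerformance,
    StageDistribution,
)
from .economics import CostTable, UtilityTable
from .errors import ConfigError
from .markov import ModelConfig
from .params import (
    SCHEMA_VERSION,
    Distribution,
    InterventionParams,
    ParameterSet,
    ParamSpec,
    PrevalenceMix,
)
from .tables import AgeRateTable

_CONTEXTS = ("screened", "general", "post_rrm")

_COST_SCALARS = (
    "rrm", "mammography", "mri", "false_positive_recall",
    "false_positive_biopsy", "prevention_annual_tamoxifen",
    "prevention_annual_anastrozole", "recurrence_annual",
    "local_recurrence_event",
)
_COST_STAGE = ("stage_first_year", "stage_subsequent", "stage_terminal")
_UTIL_SCALARS = (
    "healthy", "recurrence", "survivor", "disutility_rrm",
    "disutility_screen", "disutility_false_positive", "disutility_prevention",
)
_PERF_FIELDS = (
    "fp_recall_mammography", "fp_recall_mri",
    "biopsy_fraction_mammography", "biopsy_fraction_mri",
)


def _f(x) -> float:
    return float(x)


def _stage_map(vec) -> dict:
    return {s: _f(v) for s, v in zip(STAGES, vec)}


def _stage_vec(d: dict, where: str) -> np.ndarray:
    _expect_keys(d, STAGES, where)
    return np.array([d[s] for s in STAGES], dtype=float)


def _expect_keys(d: dict, allowed, where: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")


def bundle_to_dict(bundle: ParameterSet) -> dict:
    """Pure-Python dict form of a bundle (tables as value lists)."""
    d = {
        "schema_version": bundle.schema_version,
        "config": {
            "start_age": bundle.config.start_age,
            "horizon_age": bundle.config.horizon_age,
            "menopause_age": bundle.config.menopause_age,
        },
        "baseline_lifetime_risk": _f(bundle.baseline_lifetime_risk),
        "discount_cost": _f(bundle.discount_cost),
        "discount_effect": _f(bundle.discount_effect),
        "wtp_low": _f(bundle.wtp_low),
        "wtp_high": _f(bundle.wtp_high),
        "intervention": {
            k: (_f(v) if isinstance(v, float) else int(v))
            for k, v in (
                (f, getattr(bundle.intervention, f))
                for f in InterventionParams.__dataclass_fields__
            )
        },
        "tables": {
            "incidence": {"age": bundle.incidence.ages.tolist(),
                          "probability": [_f(v) for v in bundle.incidence.values]},
            "mortality": {"age": bundle.mortality.ages.tolist(),
                          "probability": [_f(v) for v in bundle.mortality.values]},
            "utility_norms": {
                "age": bundle.utilities.norms.ages.tolist(),
                "probability": [_f(v) for v in bundle.utilities.norms.values],
            },
        },
        "disease": {
            "recurrence_death": _f(bundle.disease.recurrence_death),
            "survivor_cutoff": bundle.disease.survivor_cutoff,
            "pathology_screened": {
                k: _f(v) for k, v in bundle.disease.pathology_screened.as_dict().items()
            },
            "pathology_general": {
                k: _f(v) for k, v in bundle.disease.pathology_general.as_dict().items()
            },
            "screening_performance": {
                k: _f(getattr(bundle.disease.screening_performance, k))
                for k in _PERF_FIELDS
            },
            "contexts": {
                ctx: {
                    "stage_distribution": _stage_map(
                        bundle.disease.context(ctx).stage_distribution.probabilities
                    ),
                    "bc_death": [[_f(v) for v in row]
                                 for row in bundle.disease.context(ctx).bc_death],
                    "distant_recurrence": [
                        [_f(v) for v in row]
                        for row in bundle.disease.context(ctx).distant_recurrence
                    ],
                    "local_recurrence": [
                        [_f(v) for v in row]
                        for row in bundle.disease.context(ctx).local_recurrence
                    ],
                }
                for ctx in _CONTEXTS
            },
        },
        "costs": {
            **{k: _f(getattr(bundle.costs, k)) for k in _COST_SCALARS},
            **{k: _stage_map(getattr(bundle.costs, k)) for k in _COST_STAGE},
        },
        "utilities": {
            **{k: _f(getattr(bundle.utilities, k)) for k in _UTIL_SCALARS},
            "stage_year1": _stage_map(bundle.utilities.stage_year1),
            "stage_subsequent": _stage_map(bundle.utilities.stage_subsequent),
        },
        "specs": [
            {
                "name": s.name,
                "point": _f(s.point),
                "low": _f(s.low),
                "high": _f(s.high),
                "distribution": s.distribution.value,
                "dispersion": None if s.dispersion is None else _f(s.dispersion),
            }
            for s in bundle.specs
        ],
        "impact": {
            "subgroups": [[_f(p), _f(r)] for p, r in bundle.impact.subgroups],
            "population_lifetime_risk": _f(bundle.impact.population_lifetime_risk),
            "annual_cases": _f(bundle.impact.annual_cases),
        },
        "provenance": dict(bundle.provenance),
    }
    return d


def bundle_from_dict(d: dict) -> ParameterSet:
    top_keys = (
        "schema_version", "config", "baseline_lifetime_risk", "discount_cost",
        "discount_effect", "wtp_low", "wtp_high", "intervention", "tables",
        "disease", "costs", "utilities", "specs", "impact", "provenance",
    )
    _expect_keys(d, top_keys, "params")
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {d.get('schema_version')!r}; "
            f"expected {SCHEMA_VERSION}"
        )
    cfg = d["config"]
    _expect_keys(cfg, ("start_age", "horizon_age", "menopause_age"), "config")
    iv = d["intervention"]
    _expect_keys(iv, tuple(InterventionParams.__dataclass_fields__), "intervention")

    def table(name: str) -> AgeRateTable:
        t = d["tables"][name]
        _expect_keys(t, ("age", "probability"), f"tables.{name}")
        return AgeRateTable(np.array(t["age"]), np.array(t["probability"]))

    dis = d["disease"]
    _expect_keys(
        dis,
        ("recurrence_death", "survivor_cutoff", "pathology_screened",
         "pathology_general", "screening_performance", "contexts"),
        "disease",
    )

    def context(name: str) -> ContextParams:
        c = dis["contexts"][name]
        _expect_keys(
            c,
            ("stage_distribution", "bc_death", "distant_recurrence",
             "local_recurrence"),
            f"disease.contexts.{name}",
        )
        return ContextParams(
            stage_distribution=StageDistribution(
                _stage_vec(c["stage_distribution"],
                           f"disease.contexts.{name}.stage_distribution")
            ),
            bc_death=np.array(c["bc_death"], dtype=float),
            distant_recurrence=np.array(c["distant_recurrence"], dtype=float),
            local_recurrence=np.array(c["local_recurrence"], dtype=float),
        )

    costs_d = d["costs"]
    _expect_keys(costs_d, _COST_SCALARS + _COST_STAGE, "costs")
    util_d = d["utilities"]
    _expect_keys(
        util_d, _UTIL_SCALARS + ("stage_year1", "stage_subsequent"), "utilities"
    )
    specs = tuple(
        ParamSpec(
            name=s["name"],
            point=s["point"],
            low=s["low"],
            high=s["high"],
            distribution=Distribution(s["distribution"]),
            dispersion=s.get("dispersion"),
        )
        for s in d["specs"]
    )
    imp = d["impact"]
    _expect_keys(
        imp, ("subgroups", "population_lifetime_risk", "annual_cases"), "impact"
    )
    return ParameterSet(
        config=ModelConfig(
            start_age=cfg["start_age"],
            horizon_age=cfg["horizon_age"],
            menopause_age=cfg["menopause_age"],
        ),
        baseline_lifetime_risk=d["baseline_lifetime_risk"],
        incidence=table("incidence"),
        mortality=table("mortality"),
        intervention=InterventionParams(**iv),
        disease=DiseaseHistoryParams(
            screened=context("screened"),
            general=context("general"),
            post_rrm=context("post_rrm"),
            pathology_screened=PathologyMix(**dis["pathology_screened"]),
            pathology_general=PathologyMix(**dis["pathology_general"]),
            screening_performance=ScreeningPerformance(
                **dis["screening_performance"]
            ),
            recurrence_death=dis["recurrence_death"],
            survivor_cutoff=dis["survivor_cutoff"],
        ),
        costs=CostTable(
            **{k: costs_d[k] for k in _COST_SCALARS},
            **{k: _stage_vec(costs_d[k], f"costs.{k}") for k in _COST_STAGE},
        ),
        utilities=UtilityTable(
            norms=table("utility_norms"),
            **{k: util_d[k] for k in _UTIL_SCALARS},
            stage_year1=_stage_vec(util_d["stage_year1"], "utilities.stage_year1"),
            stage_subsequent=_stage_vec(
                util_d["stage_subsequent"], "utilities.stage_subsequent"
            ),
        ),
        specs=specs,
        impact=PrevalenceMix(
            subgroups=tuple((p, r) for p, r in imp["subgroups"]),
            population_lifetime_risk=imp["population_lifetime_risk"],
            annual_cases=imp["annual_cases"],
        ),
        wtp_low=d["wtp_low"],
        wtp_high=d["wtp_high"],
        discount_cost=d["discount_cost"],
        discount_effect=d["discount_effect"],
        provenance=dict(d["provenance"]),
        schema_version=d["schema_version"],
    )


# ---------------------------------------------------------------------------
# directory layout: params.yaml + CSV side tables

_TABLE_FILES = {
    "incidence": "incidence.csv",
    "mortality": "mortality.csv",
    "utility_norms": "utility_norms.csv",
}


def write_params(bundle: ParameterSet, path) -> None:
    """Write a bundle directory: params.yaml plus CSV tables."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    d = bundle_to_dict(bundle)
    tables = d.pop("tables")
    for key, fname in _TABLE_FILES.items():
        pd.DataFrame(tables[key]).to_csv(root / fname, index=False, float_format="%.17g")
        d.setdefault("table_files", {})[key] = fname
    contexts = d["disease"].pop("contexts")
    d["disease"]["context_files"] = {}
    for ctx, c in contexts.items():
        rows = []
        for si, stage in enumerate(STAGES):
            for y in range(20):
                rows.append(
                    {
                        "stage": stage,
                        "year": y + 1,
                        "bc_death": c["bc_death"][si][y],
                        "distant_recurrence": c["distant_recurrence"][si][y],
                        "local_recurrence": c["local_recurrence"][si][y],
                    }
                )
        fname = f"disease_{ctx}.csv"
        pd.DataFrame(rows).to_csv(root / fname, index=False, float_format="%.17g")
        d["disease"]["context_files"][ctx] = {
            "file": fname,
            "stage_distribution": c["stage_distribution"],
        }
    with open(root / "params.yaml", "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_params(path) -> ParameterSet:
    """Read a bundle directory written by :func:`write_params`."""
    root = Path(path)
    cfg_path = root / "params.yaml"
    if not cfg_path.exists():
        raise ConfigError(f"missing config file: {cfg_path}")
    with open(cfg_path) as fh:
        try:
            d = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise ConfigError(f"{cfg_path}: {e}") from e
    if not isinstance(d, dict):
        raise ConfigError(f"{cfg_path}: expected a mapping at top level")
    table_files = d.pop("table_files", {})
    d["tables"] = {}
    for key, fname in table_files.items():
        fpath = root / fname
        if not fpath.exists():
            raise ConfigError(f"missing table file: {fpath}")
        df = pd.read_csv(fpath, float_precision="round_trip")
        d["tables"][key] = {
            "age": df["age"].tolist(),
            "probability": df["probability"].tolist(),
        }
    ctx_files = d.get("disease", {}).pop("context_files", {})
    d["disease"]["contexts"] = {}
    for ctx, meta in ctx_files.items():
        fpath = root / meta["file"]
        if not fpath.exists():
            raise ConfigError(f"missing disease table file: {fpath}")
        df = pd.read_csv(fpath, float_precision="round_trip")
        c = {"stage_distribution": meta["stage_distribution"]}
        for col in ("bc_death", "distant_recurrence", "local_recurrence"):
            c[col] = [
                df[df["stage"] == s].sort_values("year")[col].tolist()
                for s in STAGES
            ]
        d["disease"]["contexts"][ctx] = c
    return bundle_from_dict(d)


def bundle_hash(bundle: ParameterSet) -> str:
    """Stable content hash of a bundle (first 12 hex digits of SHA-256)."""
    canonical = yaml.safe_dump(bundle_to_dict(bundle), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
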