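"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis recomputes the ICER with a single parameter at its low
and high value, everything else at its point estimate; entries are
sorted by ICER spread for tornado plotting.  Probabilistic sensitivity
analysis redraws every uncertain parameter simultaneously — costs from
gamma, probabilities from beta, utilities from lognormal distributions
(truncated at 1) — re-runs the full model per draw, and reports the
probability that surgery is cost-effective across a willingness-to-pay
grid (the cost-effectiveness acceptability curve).

Default conventions where no confidence interval is available:
probabilities and utilities vary by +/-10%, costs by +/-30%, and the
standard error defaults to 10% of the mean.  All draws come from one
seeded ``numpy.random.Generator`` stream, so a run is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cea import evaluate_scenario, net_monetary_benefit
from .errors import ValidationError
from .params import (
    Distribution,
    ParameterSet,
    ParamSpec,
    assign,
    assign_inplace,
    resolve,
    validate,
)

log = logging.getLogger(__name__)

DEFAULT_SE_FRACTION = 0.10
MAX_REDRAW_RATE = 0.01


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_at_low: Optional[float]
    icer_at_high: Optional[float]
    spread: float


@dataclass(frozen=True)
class PSAResult:
    n_simulations: int
    seed: int
    cost_screen: np.ndarray
    qaly_screen: np.ndarray
    cost_rrm: np.ndarray
    qaly_rrm: np.ndarray
    wtp_grid: np.ndarray
    probability_cost_effective: np.ndarray
    n_redraws: int = 0

    @property
    def ceac(self):
        """Sequence of (wtp, probability RRM cost-effective)."""
        return list(zip(self.wtp_grid.tolist(),
                        self.probability_cost_effective.tolist()))


def default_specs_ranges(point: float, distribution: Distribution) -> tuple:
    """Default deterministic range: costs +/-30%, everything else +/-10%."""
    frac = 0.30 if distribution is Distribution.GAMMA else 0.10
    return point * (1 - frac), point * (1 + frac)


def _icer_value(bundle: ParameterSet, age: int, risk: float) -> Optional[float]:
    return evaluate_scenario(bundle, age, risk).comparison.icer


def owsa(
    bundle: ParameterSet,
    specs: Sequence[ParamSpec],
    age: int,
    lifetime_risk: float,
) -> list:
    """One-way sensitivity analysis; entries sorted by spread descending."""
    entries = []
    for spec in specs:
        resolve(bundle, spec.name)  # raises ConfigError on a bad path
        lo = _icer_value(assign(bundle, spec.name, spec.low), age, lifetime_risk)
        hi = _icer_value(assign(bundle, spec.name, spec.high), age, lifetime_risk)
        if lo is None or hi is None:
            spread = float("inf") if lo != hi else 0.0
        else:
            spread = abs(hi - lo)
        entries.append(TornadoEntry(spec.name, lo, hi, spread))
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


# ---------------------------------------------------------------------------
# parameter drawing


def _draw_one(spec: ParamSpec, rng: np.random.Generator) -> float:
    mean = spec.point
    if spec.distribution is Distribution.FIXED or mean == 0.0:
        return mean
    se = spec.dispersion if spec.dispersion is not None else DEFAULT_SE_FRACTION * abs(mean)
    if se == 0.0:
        return mean
    if spec.distribution is Distribution.GAMMA:
        shape = (mean / se) ** 2
        scale = se**2 / mean
        return float(rng.gamma(shape, scale))
    if spec.distribution is Distribution.BETA:
        if not 0.0 < mean < 1.0:
            raise ValidationError(f"{spec.name}: beta mean must lie in (0, 1)")
        cap = np.sqrt(mean * (1.0 - mean))
        if se >= cap:  # method of moments infeasible; shrink
            se = 0.99 * cap
        nu = mean * (1.0 - mean) / se**2 - 1.0
        return float(rng.beta(mean * nu, (1.0 - mean) * nu))
    if spec.distribution is Distribution.LOGNORMAL:
        sigma2 = np.log1p((se / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        draw = float(rng.lognormal(mu, np.sqrt(sigma2)))
        return min(draw, 1.0)  # utilities cannot exceed full health
    raise ValidationError(f"{spec.name}: unknown distribution")


def draw_parameters(
    bundle: ParameterSet,
    specs: Sequence[ParamSpec],
    rng: np.random.Generator,
) -> ParameterSet:
    """One joint redraw of every uncertain parameter."""
    drawn = bundle.copy()
    for spec in specs:
        assign_inplace(drawn, spec.name, _draw_one(spec, rng))
    return drawn


def psa(
    bundle: ParameterSet,
    specs: Sequence[ParamSpec],
    n: int,
    seed: int,
    age: int,
    lifetime_risk: float,
    wtp_grid: Optional[Sequence[float]] = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis for one (age, risk) scenario.

    Each of ``n`` simulations redraws all parameters, runs both arms,
    and records (cost, QALY) per arm.  A draw producing a bundle that
    fails validation is redrawn; more than 1% redraws is a hard error.
    """
    if n < 1:
        raise ValidationError("n must be at least 1")
    rng = np.random.default_rng(seed)
    grid = np.asarray(
        wtp_grid if wtp_grid is not None else np.arange(0.0, 50_001.0, 1_000.0),
        dtype=float,
    )
    cost_s = np.empty(n)
    qaly_s = np.empty(n)
    cost_r = np.empty(n)
    qaly_r = np.empty(n)
    redraws = 0
    for i in range(n):
        while True:
            drawn = draw_parameters(bundle, specs, rng)
            if validate(drawn).ok:
                break
            redraws += 1
            log.warning("invalid PSA draw redrawn (%d so far)", redraws)
            if redraws > MAX_REDRAW_RATE * max(n, 100):
                raise ValidationError("PSA redraw rate exceeded 1%")
        sc = evaluate_scenario(drawn, age, lifetime_risk)
        cost_s[i], qaly_s[i] = sc.screen.discounted_cost, sc.screen.discounted_qaly
        cost_r[i], qaly_r[i] = sc.rrm.discounted_cost, sc.rrm.discounted_qaly
    dc = cost_r - cost_s
    dq = qaly_r - qaly_s
    prob = np.array([(dq * w - dc > 0).mean() for w in grid])
    return PSAResult(
        n_simulations=n,
        seed=seed,
        cost_screen=cost_s,
        qaly_screen=qaly_s,
        cost_rrm=cost_r,
        qaly_rrm=qaly_r,
        wtp_grid=grid,
        probability_cost_effective=prob,
        n_redraws=redraws,
    )
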