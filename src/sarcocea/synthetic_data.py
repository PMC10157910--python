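"""Synthetic inputs for testing and validating the pipeline.

Nothing in this model requires a download: the reference configuration is
packaged, background mortality is synthesised (Gompertz), and three kinds
of validation input are generated here:

* :func:`make_toy_scenario` — configurations engineered so lifetime
  outcomes have closed forms (geometric series), computed independently of
  the cohort engine;
* :func:`random_scenario` — randomised but always-valid configurations for
  property tests (frontier oracle, serialisation round trips);
* :func:`microsim_oracle` — an individual-level Monte-Carlo simulation of
  the same transition rows and rewards, used as an independent check of the
  cohort-matrix engine.
"""

from __future__ import annotations

import importlib.resources
import shutil
from dataclasses import dataclass

import numpy as np

from .cohort_model import Arm, HealthState, _fall_effect, _state_quantities
from .mortality import LifeTable, gompertz_life_table
from .parameters import (
    DistributionSpec,
    ParameterSet,
    StrategySpec,
    UncertaintyDescriptor,
    load_model_config,
)

__all__ = [
    "ToyScenario",
    "reference_config_path",
    "load_reference_config",
    "make_table2_fixture",
    "default_life_table",
    "make_toy_scenario",
    "random_scenario",
    "microsim_oracle",
]

_FIXTURE_NAME = "table2.yaml"


def reference_config_path():
    """Path to the packaged reference configuration."""
    return importlib.resources.files("sarcocea") / "data" / _FIXTURE_NAME


def load_reference_config() -> tuple[ParameterSet, list[StrategySpec]]:
    """The packaged reference configuration (global parameters and the
    eight strategies)."""
    with importlib.resources.as_file(reference_config_path()) as path:
        return load_model_config(path)


def make_table2_fixture(path) -> None:
    """Write a copy of the packaged reference configuration to ``path``."""
    with importlib.resources.as_file(reference_config_path()) as src:
        shutil.copyfile(src, path)


def default_life_table() -> LifeTable:
    """The default synthetic background life table: Gompertz hazard anchored
    at the age-60 annual death probability 0.0095, slope 0.085/yr (hazard
    doubling time about 8 years), terminal age 110."""
    return gompertz_life_table(q_anchor=0.0095, anchor_age=60, slope=0.085,
                               max_age=110)


# ---------------------------------------------------------------------------
# closed-form toy scenarios


@dataclass(frozen=True)
class ToyScenario:
    """A configuration whose lifetime outcomes have closed forms.

    ``expected_cost`` / ``expected_qalys`` are the acceptance-weighted
    analytic outcomes of the single included strategy, computed from
    geometric-series formulas — never from the cohort engine.
    """

    kind: str
    params: ParameterSet
    strategy: StrategySpec
    life_table: LifeTable
    expected_cost: float
    expected_qalys: float


def _flat_table(start_age: int, q: float, n_ages: int) -> LifeTable:
    qx = np.full(n_ages, q)
    qx[-1] = 1.0
    return LifeTable(start_age=start_age, qx=qx)


def make_toy_scenario(kind: str) -> ToyScenario:
    """Closed-form scenario of one of three kinds.

    ``no-events``
        No falls, no background death for 20 years, then forced death:
        discounted QALYs are a plain annuity
        ``u * sum_{t=0..19} 1.05^-t``.
    ``constant-mortality``
        Flat annual death probability ``q`` with no discounting and no
        falls: QALYs are a truncated geometric series
        ``u * (1 - (1-q)^T) / q`` (about ``u / q`` for a long horizon).
    ``one-cycle``
        A single cycle with forced death at its end: outcomes are the
        first-cycle rewards of the starting state only.
    """
    if kind == "no-events":
        u, r, horizon = 0.785, 0.05, 20
        params = ParameterSet(
            discount_rate_costs=r,
            discount_rate_outcomes=r,
            p_fall=0.0,
            utility_sarcopenic=u,
        )
        strategy = StrategySpec(name="None", acceptance=0.0)
        table = _flat_table(60, 0.0, horizon)
        x = 1.0 / (1.0 + r)
        annuity = (1.0 - x**horizon) / (1.0 - x)
        return ToyScenario(kind, params, strategy, table, 0.0, u * annuity)
    if kind == "constant-mortality":
        u, q, horizon = 0.785, 0.05, 400
        params = ParameterSet(
            discount_rate_costs=0.0,
            discount_rate_outcomes=0.0,
            p_fall=0.0,
            hr_sarcopenia_mortality=1.0,
            utility_sarcopenic=u,
        )
        strategy = StrategySpec(name="None", acceptance=0.0)
        table = _flat_table(60, q, horizon)
        qalys = u * (1.0 - (1.0 - q) ** horizon) / q
        return ToyScenario(kind, params, strategy, table, 0.0, qalys)
    if kind == "one-cycle":
        params = ParameterSet()
        strategy = StrategySpec(name="D", annual_cost=129.276, acceptance=0.9)
        table = _flat_table(60, 1.0, 1)
        # everyone spends exactly one cycle in SARCOPENIC, then dies
        on_cost = strategy.annual_cost + params.cost_visits_labs
        cost = strategy.acceptance * on_cost
        return ToyScenario(kind, params, strategy, table, cost,
                           params.utility_sarcopenic)
    raise ValueError(f"unknown toy scenario kind {kind!r}")


# ---------------------------------------------------------------------------
# random scenarios


def random_scenario(
    rng: np.random.Generator, n_strategies: int | None = None
) -> tuple[ParameterSet, list[StrategySpec]]:
    """A randomised, always-valid model configuration.

    Probabilities are drawn in [0, 0.5], costs log-uniformly, hazard
    multipliers above 1; between 2 and 8 strategies with random effects and
    a no-intervention arm first.  Used for property tests (frontier oracle,
    round trips, engine/microsimulation agreement).
    """
    def logu(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    u = float(rng.uniform(0.4, 0.95))
    p_fall = float(rng.uniform(0.01, 0.5))
    cost_fracture = logu(100.0, 50_000.0)
    params = ParameterSet(
        discount_rate_costs=float(rng.uniform(0.0, 0.1)),
        discount_rate_outcomes=float(rng.uniform(0.0, 0.1)),
        q60_background=float(rng.uniform(0.001, 0.05)),
        hr_sarcopenia_mortality=float(rng.uniform(1.0, 3.0)),
        rr_fracture_mortality_y1=float(rng.uniform(1.0, 8.0)),
        p_fall=p_fall,
        p_fracture_given_fall=float(rng.uniform(0.01, 0.5)),
        utility_sarcopenic=u,
        disutility_fracture_y1=float(rng.uniform(0.0, 0.5 * u)),
        disutility_post_fracture=float(rng.uniform(0.0, 0.3 * u)),
        cost_fracture_y1=cost_fracture,
        cost_post_fracture=logu(10.0, 10_000.0),
        cost_visits_labs=logu(10.0, 1_000.0),
        wtp=logu(1_000.0, 100_000.0),
        distributions={
            # distribution means coincide with the base values, as in the
            # reference configuration
            "p_fall": DistributionSpec(
                "beta", p_fall, UncertaintyDescriptor("sd", 0.1 * p_fall)
            ),
            "cost_fracture_y1": DistributionSpec(
                "gamma",
                cost_fracture,
                UncertaintyDescriptor("sd", 0.2 * cost_fracture),
            ),
        },
    )
    if n_strategies is None:
        n_strategies = int(rng.integers(2, 9))
    strategies = [StrategySpec(name="None", acceptance=0.0)]
    for i in range(n_strategies - 1):
        strategies.append(
            StrategySpec(
                name=f"S{i + 1}",
                annual_cost=logu(10.0, 10_000.0),
                frr_mm=float(rng.uniform(0.0, 50.0)),
                frr_ms=float(rng.uniform(0.0, 50.0)),
                frr_mp=float(rng.uniform(0.0, 50.0)),
                acceptance=float(rng.uniform(0.5, 1.0)),
            )
        )
    return params, strategies


# ---------------------------------------------------------------------------
# individual-level microsimulation oracle


@dataclass(frozen=True)
class MicrosimResult:
    cost: float
    qalys: float
    cost_se: float
    qalys_se: float
    n_paths: int


def microsim_oracle(
    strategy: StrategySpec,
    arm: Arm,
    params: ParameterSet,
    life_table: LifeTable,
    n_paths: int,
    seed: int,
    start_age: int = 60,
) -> MicrosimResult:
    """Estimate one arm's outcomes by simulating individual trajectories.

    Uses the same per-cycle transition probabilities and rewards as the
    cohort engine but samples state paths instead of propagating occupancy
    fractions, so sampling error aside it must agree with the engine.
    Returns means with Monte-Carlo standard errors.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng(seed)
    qx = life_table.q_slice(start_age)
    n = len(qx)
    hr = params.hr_sarcopenia_mortality
    p_die = 1.0 - (1.0 - qx) ** hr
    p_die_fy = 1.0 - (1.0 - qx) ** (hr * params.rr_fracture_mortality_y1)
    p_fall_eff = params.p_fall * (1.0 - _fall_effect(strategy, arm))
    p_frac = (1.0 - p_die) * p_fall_eff * params.p_fracture_given_fall
    cost_vec, util_vec = _state_quantities(strategy, arm, params)
    disc_c = (1.0 + params.discount_rate_costs) ** -np.arange(n)
    disc_q = (1.0 + params.discount_rate_outcomes) ** -np.arange(n)

    state = np.full(n_paths, int(HealthState.SARCOPENIC), dtype=np.int8)
    cost_tot = np.zeros(n_paths)
    qaly_tot = np.zeros(n_paths)
    DEAD = int(HealthState.DEAD)
    for t in range(n):
        cost_tot += cost_vec[state] * disc_c[t]
        qaly_tot += util_vec[state] * disc_q[t]
        r = rng.random(n_paths)
        new = state.copy()
        sarc = state == int(HealthState.SARCOPENIC)
        post = state == int(HealthState.POST_FRACTURE)
        fy = state == int(HealthState.FRACTURE_YEAR)
        # death first, then fall/fracture among survivors
        for mask in (sarc, post):
            new[mask & (r < p_die[t])] = DEAD
            new[mask & (r >= p_die[t]) & (r < p_die[t] + p_frac[t])] = int(
                HealthState.FRACTURE_YEAR
            )
        new[fy & (r < p_die_fy[t])] = DEAD
        new[fy & (r >= p_die_fy[t])] = int(HealthState.POST_FRACTURE)
        state = new
        if np.all(state == DEAD):
            break
    return MicrosimResult(
        cost=float(cost_tot.mean()),
        qalys=float(qaly_tot.mean()),
        cost_se=float(cost_tot.std(ddof=1) / np.sqrt(n_paths)) if n_paths > 1 else 0.0,
        qalys_se=float(qaly_tot.std(ddof=1) / np.sqrt(n_paths)) if n_paths > 1 else 0.0,
        n_paths=n_paths,
    )
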