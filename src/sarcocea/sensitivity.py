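"""Deterministic and probabilistic sensitivity analysis and value of
information.

* :func:`tornado` — one-way deterministic sensitivity on the incremental
  net monetary benefit of the two top frontier strategies, each parameter
  swept across its reported 95% interval (or fitted 2.5/97.5 quantiles).
* :func:`run_psa` — Monte-Carlo probabilistic sensitivity analysis: joint
  parameter draws shared across strategies within an iteration, the full
  cohort model evaluated per draw and strategy.
* :func:`acceptability_at_wtp` / :func:`ceac` — probability each strategy
  attains the maximal net monetary benefit, at one threshold or across a
  grid (the cost-effectiveness acceptability curve).
* :func:`evpi` / :func:`evpi_curve` — per-person expected value of perfect
  information: the expected gain from choosing the per-draw optimum instead
  of committing to the strategy with the best expected net benefit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import efficiency_frontier, nmb
from .cohort_model import run_strategies, run_strategy
from .mortality import LifeTable
from .parameters import (
    DistributionSpec,
    ParameterSet,
    StrategySpec,
    sample_parameters,
)

__all__ = [
    "TornadoBar",
    "PSAResult",
    "CEACCurve",
    "EVPIResult",
    "tornado",
    "run_psa",
    "acceptability_at_wtp",
    "ceac",
    "evpi",
    "evpi_curve",
]


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity (tornado)


@dataclass(frozen=True)
class TornadoBar:
    parameter: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float

    @property
    def spread(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _default_pair(params, strategies, life_table, start_age) -> tuple[str, str]:
    """The two most effective frontier strategies at base case (the pair
    whose comparison drives the decision)."""
    outcomes = run_strategies(strategies, params, life_table, start_age)
    frontier = [r for r in efficiency_frontier(outcomes) if r.category == "undominated"]
    frontier.sort(key=lambda r: r.qalys)
    if len(frontier) >= 2:
        return frontier[-1].strategy, frontier[-2].strategy
    name = frontier[-1].strategy
    other = next(o.strategy for o in outcomes if o.strategy != name)
    return name, other


def _incremental_nmb(
    params: ParameterSet,
    strategy_map: dict[str, StrategySpec],
    pair: tuple[str, ...],
    life_table: LifeTable,
    wtp: float,
    start_age: int,
) -> float:
    a = run_strategy(strategy_map[pair[0]], params, life_table, start_age)
    value = nmb(a.discounted_cost, a.discounted_qalys, wtp)
    if len(pair) > 1:
        b = run_strategy(strategy_map[pair[1]], params, life_table, start_age)
        value -= nmb(b.discounted_cost, b.discounted_qalys, wtp)
    return value


def tornado(
    params: ParameterSet,
    strategies: list[StrategySpec],
    life_table: LifeTable,
    pair: tuple[str, ...] | str | None = None,
    wtp: float | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
    start_age: int = 60,
) -> list[TornadoBar]:
    """One-way sensitivity of a net-monetary-benefit outcome to every
    uncertain parameter.

    ``pair`` selects the outcome: a 2-tuple of strategy names gives the
    incremental NMB of the first over the second (the default is the two
    top frontier strategies — the comparison driving the decision); a
    single strategy name gives that strategy's absolute NMB.

    Each global parameter — and each uncertain field of the compared
    strategies — is set to the ends of its 95% interval with all others at
    base case, and the full model is re-run.  Bars are sorted by descending
    spread.  ``ranges`` overrides the swept interval per parameter name.
    """
    if wtp is None:
        wtp = params.wtp
    if pair is None:
        pair = _default_pair(params, strategies, life_table, start_age)
    elif isinstance(pair, str):
        pair = (pair,)
    strategy_map = {s.name: s for s in strategies}
    for name in pair:
        if name not in strategy_map:
            raise ValueError(f"unknown strategy {name!r} in comparator pair")
    ranges = dict(ranges or {})

    def interval(label: str, dist: DistributionSpec, base: float):
        lo, hi = ranges.get(label, dist.interval95())
        support_lo = dist.support_low if dist.family == "beta" else 0.0
        if dist.family in ("gamma", "lognormal"):
            support_lo = 0.0
        if lo < support_lo or (dist.family == "beta" and hi > dist.support_high):
            raise ValueError(f"{label}: range ({lo}, {hi}) outside support")
        return lo, hi

    bars: list[TornadoBar] = []
    # global parameters
    for name in ParameterSet._STOCHASTIC:
        dist = params.distributions.get(name)
        if dist is None or dist.is_fixed:
            continue
        lo, hi = interval(name, dist, getattr(params, name))
        out_lo = _incremental_nmb(
            params.with_values(**{name: lo}), strategy_map, pair, life_table, wtp,
            start_age,
        )
        out_hi = _incremental_nmb(
            params.with_values(**{name: hi}), strategy_map, pair, life_table, wtp,
            start_age,
        )
        bars.append(TornadoBar(name, lo, hi, out_lo, out_hi))
    # strategy-level parameters of the compared pair
    for sname in pair:
        strat = strategy_map[sname]
        for fname in StrategySpec._STOCHASTIC:
            dist = strat.distributions.get(fname)
            if dist is None or dist.is_fixed:
                continue
            label = f"{sname}:{fname}"
            lo, hi = interval(label, dist, getattr(strat, fname))
            outs = []
            for v in (lo, hi):
                varied = dict(strategy_map)
                varied[sname] = strat.with_values(**{fname: v})
                outs.append(
                    _incremental_nmb(params, varied, pair, life_table, wtp, start_age)
                )
            bars.append(TornadoBar(label, lo, hi, outs[0], outs[1]))
    bars.sort(key=lambda b: -b.spread)
    return bars


def tornado_table(bars: list[TornadoBar]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "parameter": b.parameter,
                "low": b.low,
                "high": b.high,
                "outcome_low": b.outcome_low,
                "outcome_high": b.outcome_high,
                "spread": b.spread,
            }
            for b in bars
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAResult:
    """Per-draw, per-strategy discounted outcomes from Monte-Carlo PSA."""

    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_iterations, n_strategies) $
    qalys: np.ndarray  # (n_iterations, n_strategies) QALYs
    seed: int
    n_iterations: int

    def nmb_matrix(self, wtp: float) -> np.ndarray:
        return self.qalys * wtp - self.costs

    def to_frame(self) -> pd.DataFrame:
        n, s = self.costs.shape
        return pd.DataFrame(
            {
                "draw": np.repeat(np.arange(n), s),
                "strategy": np.tile(np.array(self.strategies), n),
                "cost": self.costs.ravel(),
                "qalys": self.qalys.ravel(),
            }
        )


def run_psa(
    params: ParameterSet,
    strategies: list[StrategySpec],
    life_table: LifeTable,
    n_iterations: int = 1000,
    seed: int = 20230504,
    start_age: int = 60,
) -> PSAResult:
    """Monte-Carlo PSA: one joint parameter draw per iteration, shared by
    all strategies (common random numbers), full cohort model per strategy."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    names = tuple(s.name for s in strategies)
    costs = np.empty((n_iterations, len(strategies)))
    qalys = np.empty_like(costs)
    for i in range(n_iterations):
        draw = sample_parameters(params, strategies, rng, draw_index=i, seed=seed)
        outcomes = run_strategies(draw, draw, life_table, start_age)
        for j, out in enumerate(outcomes):
            costs[i, j] = out.discounted_cost
            qalys[i, j] = out.discounted_qalys
    return PSAResult(
        strategies=names,
        costs=costs,
        qalys=qalys,
        seed=seed,
        n_iterations=n_iterations,
    )


def acceptability_at_wtp(psa: PSAResult, wtp: float) -> dict[str, float]:
    """Fraction of draws in which each strategy attains the maximal net
    monetary benefit; exact ties share the draw equally."""
    nmbs = psa.nmb_matrix(wtp)
    best = nmbs.max(axis=1, keepdims=True)
    winners = nmbs == best
    weights = winners / winners.sum(axis=1, keepdims=True)
    probs = weights.mean(axis=0)
    return dict(zip(psa.strategies, probs.tolist()))


@dataclass(frozen=True)
class CEACCurve:
    wtp_grid: np.ndarray
    probabilities: pd.DataFrame  # index: wtp, columns: strategies

    def to_frame(self) -> pd.DataFrame:
        df = self.probabilities.copy()
        df.insert(0, "wtp", self.wtp_grid)
        return df


def ceac(psa: PSAResult, wtp_grid) -> CEACCurve:
    """Cost-effectiveness acceptability curve over an ascending WTP grid."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("wtp_grid must be a non-empty 1-D sequence")
    if np.any(np.diff(grid) < 0):
        raise ValueError("wtp_grid must be sorted ascending")
    records = [acceptability_at_wtp(psa, w) for w in grid]
    df = pd.DataFrame.from_records(records, columns=list(psa.strategies))
    return CEACCurve(wtp_grid=grid, probabilities=df)


def default_wtp_grid(wtp: float, factor: float = 3.0, steps: int = 60) -> np.ndarray:
    return np.linspace(0.0, factor * wtp, steps + 1)


# ---------------------------------------------------------------------------
# expected value of perfect information


@dataclass(frozen=True)
class EVPIResult:
    wtp: float
    evpi: float
    avg_incremental_cost_perfect_info: float
    avg_incremental_eff_perfect_info: float
    optimal_strategy: str


def evpi(psa: PSAResult, wtp: float) -> EVPIResult:
    """Per-person EVPI at threshold ``wtp``.

    ``EVPI = E[max_s NMB_s] - max_s E[NMB_s]``.  The incremental cost and
    effectiveness under perfect information are the mean differences between
    the per-draw NMB winner and the strategy with the best expected NMB.
    """
    nmbs = psa.nmb_matrix(wtp)
    per_draw_max = nmbs.max(axis=1)
    mean_nmb = nmbs.mean(axis=0)
    best = int(np.argmax(mean_nmb))
    value = float(per_draw_max.mean() - mean_nmb[best])
    winner = np.argmax(nmbs, axis=1)
    rows = np.arange(len(winner))
    inc_cost = float((psa.costs[rows, winner] - psa.costs[:, best]).mean())
    inc_eff = float((psa.qalys[rows, winner] - psa.qalys[:, best]).mean())
    return EVPIResult(
        wtp=wtp,
        evpi=value,
        avg_incremental_cost_perfect_info=inc_cost,
        avg_incremental_eff_perfect_info=inc_eff,
        optimal_strategy=psa.strategies[best],
    )


def evpi_curve(psa: PSAResult, wtp_grid) -> list[EVPIResult]:
    """EVPI evaluated across an ascending WTP grid."""
    grid = np.asarray(wtp_grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("wtp_grid must be sorted ascending")
    return [evpi(psa, w) for w in grid]


def evpi_table(results: list[EVPIResult]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "wtp": r.wtp,
                "evpi": r.evpi,
                "avg_incremental_cost_perfect_info":
                    r.avg_incremental_cost_perfect_info,
                "avg_incremental_eff_perfect_info":
                    r.avg_incremental_eff_perfect_info,
                "optimal_strategy": r.optimal_strategy,
            }
            for r in results
        ]
    )
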