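"""Model parameters: definitions, config I/O, distribution fitting, and sampling.

Every uncertain quantity in the model is described by a
:class:`DistributionSpec` — a distribution family (beta, gamma, log-normal,
or fixed) together with a mean and an uncertainty descriptor (a standard
deviation, a 95% confidence interval, or a plausible range).  Distributions
are fitted by moment matching:

* Beta on ``[low, high]``: closed-form inversion of the first two moments,
  ``alpha = m * (m (1 - m) / s^2 - 1)``, ``beta = alpha (1 - m) / m`` with
  ``m``, ``s`` rescaled to the unit interval.
* Gamma: ``shape = (mean / sd)^2``, ``scale = sd^2 / mean``.
* Log-normal from a 95% CI: ``mu = ln(point)``,
  ``sigma = (ln hi - ln lo) / (2 * 1.96)``.

A :class:`ParameterSet` carries the global model parameters (probabilities,
utilities, costs, discount rates, the willingness-to-pay threshold); a
:class:`StrategySpec` describes one management strategy (annual cost,
per-indicator fall-risk reductions, acceptance probability).  Joint random
draws for probabilistic sensitivity analysis are produced by
:func:`sample_parameters`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "ConfigError",
    "InfeasibleMomentsError",
    "UncertaintyDescriptor",
    "DistributionSpec",
    "ParameterSet",
    "StrategySpec",
    "ParameterDraw",
    "beta_from_moments",
    "gamma_from_moments",
    "lognormal_from_ci",
    "load_model_config",
    "save_model_config",
    "sample_parameters",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class ConfigError(ValueError):
    """Raised when a model configuration fails validation."""


class InfeasibleMomentsError(ValueError):
    """Requested mean/sd cannot be realised by the distribution family."""


# ---------------------------------------------------------------------------
# moment fitting


def beta_from_moments(
    mean: float, sd: float, low: float = 0.0, high: float = 1.0
) -> tuple[float, float]:
    """Shape parameters of a Beta on ``[low, high]`` with the given mean and sd.

    Raises :class:`InfeasibleMomentsError` when the variance exceeds what the
    bounded support allows (``s^2 >= (mean-low)(high-mean)`` after rescaling).
    """
    if not low < mean < high:
        raise InfeasibleMomentsError(
            f"beta mean {mean} outside open support ({low}, {high})"
        )
    if sd <= 0:
        raise InfeasibleMomentsError(f"beta sd must be positive, got {sd}")
    span = high - low
    m = (mean - low) / span
    s = sd / span
    if s * s >= m * (1.0 - m):
        raise InfeasibleMomentsError(
            f"variance {sd**2:g} infeasible for beta with mean {mean:g} "
            f"on [{low:g}, {high:g}]"
        )
    k = m * (1.0 - m) / (s * s) - 1.0
    return m * k, (1.0 - m) * k


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(shape, scale) of the Gamma with the given mean and sd."""
    if mean <= 0 or sd <= 0:
        raise InfeasibleMomentsError(
            f"gamma requires positive mean and sd, got ({mean}, {sd})"
        )
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def lognormal_from_ci(point: float, lo95: float, hi95: float) -> tuple[float, float]:
    """(log-mean, log-sd) of the log-normal whose median is ``point`` and whose
    2.5/97.5 percent quantiles are ``lo95``/``hi95``."""
    if lo95 <= 0 or hi95 <= 0 or point <= 0:
        raise InfeasibleMomentsError("lognormal requires positive point and bounds")
    if not lo95 <= point <= hi95:
        raise InfeasibleMomentsError(
            f"point {point} outside CI ({lo95}, {hi95})"
        )
    mu = math.log(point)
    sigma = (math.log(hi95) - math.log(lo95)) / (2.0 * _Z95)
    return mu, sigma


# ---------------------------------------------------------------------------
# distribution descriptors


@dataclass(frozen=True)
class UncertaintyDescriptor:
    """How a parameter's uncertainty was reported: an sd, a 95% CI, a range,
    or nothing (fixed)."""

    kind: str  # one of {"sd", "ci95", "range", "none"}
    value1: float = 0.0
    value2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("sd", "ci95", "range", "none"):
            raise ConfigError(f"unknown uncertainty kind {self.kind!r}")
        if self.kind == "sd" and self.value1 <= 0:
            raise ConfigError("sd must be positive")
        if self.kind in ("ci95", "range"):
            if self.value2 is None or not self.value1 < self.value2:
                raise ConfigError(
                    f"{self.kind} requires value1 < value2, got "
                    f"({self.value1}, {self.value2})"
                )


@dataclass(frozen=True)
class DistributionSpec:
    """A parameter's sampling distribution.

    ``family='fixed'`` (or an uncertainty of kind ``none``) means the
    parameter passes through probabilistic analysis unchanged.  Beta
    distributions may be rescaled to ``[support_low, support_high]`` —
    used for fall-risk-reduction percentages (support ``[0, 100]``) and
    for discount rates reported as a plausible range.
    """

    family: str  # one of {"beta", "gamma", "lognormal", "fixed"}
    mean: float
    uncertainty: UncertaintyDescriptor = UncertaintyDescriptor("none")
    support_low: float = 0.0
    support_high: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "lognormal", "fixed"):
            raise ConfigError(f"unknown distribution family {self.family!r}")
        if self.family in ("gamma", "lognormal") and self.mean <= 0:
            raise ConfigError(f"{self.family} mean must be positive")
        if self.family == "beta" and not (
            self.support_low < self.mean < self.support_high
        ):
            raise ConfigError(
                f"beta mean {self.mean} outside ({self.support_low}, "
                f"{self.support_high})"
            )

    @property
    def is_fixed(self) -> bool:
        return self.family == "fixed" or self.uncertainty.kind == "none"

    def sd(self) -> float:
        """Standard deviation implied by the uncertainty descriptor.

        CI and range descriptors are converted via half-width / 1.96.
        """
        u = self.uncertainty
        if u.kind == "none":
            return 0.0
        if u.kind == "sd":
            return u.value1
        return (u.value2 - u.value1) / (2.0 * _Z95)

    def frozen(self):
        """The fitted scipy frozen distribution (None when fixed)."""
        if self.is_fixed:
            return None
        if self.family == "beta":
            a, b = beta_from_moments(
                self.mean, self.sd(), self.support_low, self.support_high
            )
            span = self.support_high - self.support_low
            return stats.beta(a, b, loc=self.support_low, scale=span)
        if self.family == "gamma":
            shape, scale = gamma_from_moments(self.mean, self.sd())
            return stats.gamma(shape, scale=scale)
        # lognormal: fitted from the CI, not from an sd
        u = self.uncertainty
        if u.kind != "ci95":
            raise ConfigError("lognormal parameters require a ci95 uncertainty")
        mu, sigma = lognormal_from_ci(self.mean, u.value1, u.value2)
        if sigma == 0.0:
            return None
        return stats.lognorm(sigma, scale=math.exp(mu))

    def rvs(self, rng: np.random.Generator) -> float:
        dist = self.frozen()
        if dist is None:
            return self.mean
        return float(dist.rvs(random_state=rng))

    def ppf(self, q: float) -> float:
        dist = self.frozen()
        if dist is None:
            return self.mean
        return float(dist.ppf(q))

    def interval95(self) -> tuple[float, float]:
        """Low/high values for one-way sensitivity analysis: the printed CI or
        range when one was reported, otherwise the fitted 2.5/97.5 quantiles."""
        u = self.uncertainty
        if u.kind in ("ci95", "range"):
            return u.value1, u.value2
        if self.is_fixed:
            return self.mean, self.mean
        return self.ppf(0.025), self.ppf(0.975)


# ---------------------------------------------------------------------------
# parameter containers


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} = {value} outside [0, 1]")


@dataclass(frozen=True)
class ParameterSet:
    """Global model parameters (base-case values) plus the distributions
    attached to the uncertain ones.

    Monetary amounts are 2022 PPP dollars; probabilities and rates are
    annual; utilities are per-year quality weights on [0, 1].
    """

    discount_rate_costs: float = 0.05
    discount_rate_outcomes: float = 0.05
    q60_background: float = 0.0095
    hr_sarcopenia_mortality: float = 1.6
    rr_fracture_mortality_y1: float = 6.57
    p_fall: float = 0.155
    p_fracture_given_fall: float = 0.33
    utility_sarcopenic: float = 0.785
    disutility_fracture_y1: float = 0.25
    disutility_post_fracture: float = 0.17
    cost_fracture_y1: float = 12_588.214
    cost_post_fracture: float = 2_517.64
    cost_visits_labs: float = 400.409
    wtp: float = 25_249.13
    ppp_rial_per_dollar: float = 29_704.0
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)

    # parameters that may carry a distribution (wtp / PPP are decision-rule
    # constants, q60 anchors the life table and carries no descriptor)
    _STOCHASTIC = (
        "discount_rate_costs",
        "discount_rate_outcomes",
        "hr_sarcopenia_mortality",
        "rr_fracture_mortality_y1",
        "p_fall",
        "p_fracture_given_fall",
        "utility_sarcopenic",
        "disutility_fracture_y1",
        "disutility_post_fracture",
        "cost_fracture_y1",
        "cost_post_fracture",
        "cost_visits_labs",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "discount_rate_costs",
            "discount_rate_outcomes",
            "q60_background",
            "p_fall",
            "p_fracture_given_fall",
            "utility_sarcopenic",
        ):
            _check_prob(name, getattr(self, name))
        for name in ("hr_sarcopenia_mortality", "rr_fracture_mortality_y1"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "cost_fracture_y1",
            "cost_post_fracture",
            "cost_visits_labs",
            "wtp",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("disutility_fracture_y1", "disutility_post_fracture"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be non-negative")
        unknown = set(self.distributions) - set(self._STOCHASTIC)
        if unknown:
            raise ConfigError(f"distributions for unknown parameters: {unknown}")

    def with_values(self, **values: float) -> "ParameterSet":
        return replace(self, **values)


@dataclass(frozen=True)
class StrategySpec:
    """One management strategy.

    ``frr_mm`` / ``frr_ms`` / ``frr_mp`` are percent reductions in the
    annual fall probability attributed to improvement in muscle mass,
    muscle strength, and muscle performance; an indicator with no reported
    effect contributes zero.  ``acceptance`` is the probability that a
    patient accepts and adheres to the intervention (the decision-tree
    split); the no-intervention strategy has acceptance 0.
    """

    name: str
    annual_cost: float = 0.0
    frr_mm: float = 0.0
    frr_ms: float = 0.0
    frr_mp: float = 0.0
    acceptance: float = 0.9
    dosage_note: str = ""
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)

    _STOCHASTIC = ("annual_cost", "frr_mm", "frr_ms", "frr_mp")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.name:
            raise ConfigError("strategy name must be non-empty")
        if self.annual_cost < 0:
            raise ConfigError(f"{self.name}: annual_cost must be non-negative")
        _check_prob(f"{self.name}: acceptance", self.acceptance)
        for ind in ("frr_mm", "frr_ms", "frr_mp"):
            v = getattr(self, ind)
            if not 0.0 <= v <= 100.0:
                raise ConfigError(f"{self.name}: {ind} = {v} outside [0, 100]")
        unknown = set(self.distributions) - set(self._STOCHASTIC)
        if unknown:
            raise ConfigError(
                f"{self.name}: distributions for unknown fields: {unknown}"
            )

    def with_values(self, **values: float) -> "StrategySpec":
        return replace(self, **values)


@dataclass(frozen=True)
class ParameterDraw:
    """One joint realisation of all stochastic parameters.

    ``params`` and ``strategies`` are ordinary :class:`ParameterSet` /
    :class:`StrategySpec` objects whose uncertain fields have been replaced
    by sampled values, so the cohort engine consumes draws and base-case
    inputs identically.
    """

    params: ParameterSet
    strategies: tuple[StrategySpec, ...]
    draw_index: int = 0
    seed: int | None = None


def sample_parameters(
    params: ParameterSet,
    strategies: list[StrategySpec] | tuple[StrategySpec, ...],
    rng: np.random.Generator,
    draw_index: int = 0,
    seed: int | None = None,
) -> ParameterDraw:
    """Draw one joint parameter realisation.

    Parameters without a distribution pass through unchanged.  Sampling
    order is fixed (global parameters in declaration order, then strategies
    in list order, fields in declaration order) so a given generator state
    always yields the same draw.
    """
    values: dict[str, float] = {}
    for name in ParameterSet._STOCHASTIC:
        dist = params.distributions.get(name)
        if dist is not None and not dist.is_fixed:
            values[name] = dist.rvs(rng)
    drawn_params = params.with_values(**values) if values else params

    drawn_strategies = []
    for strat in strategies:
        svalues: dict[str, float] = {}
        for fname in StrategySpec._STOCHASTIC:
            dist = strat.distributions.get(fname)
            if dist is not None and not dist.is_fixed:
                svalues[fname] = dist.rvs(rng)
        drawn_strategies.append(strat.with_values(**svalues) if svalues else strat)

    return ParameterDraw(
        params=drawn_params,
        strategies=tuple(drawn_strategies),
        draw_index=draw_index,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# configuration I/O

_DIST_ENTRY_KEYS = {"value", "dist", "sd", "ci95", "range", "support"}
_PARAM_KEYS = set(ParameterSet._STOCHASTIC) | {
    "q60_background",
    "wtp",
    "ppp_rial_per_dollar",
}
_STRATEGY_KEYS = {
    "name",
    "annual_cost",
    "frr_mm",
    "frr_ms",
    "frr_mp",
    "acceptance",
    "dosage_note",
}


def _parse_entry(name: str, raw, default_support=(0.0, 1.0)):
    """Parse one parameter entry into (base value, DistributionSpec or None)."""
    if isinstance(raw, (int, float)):
        return float(raw), None
    if not isinstance(raw, dict):
        raise ConfigError(f"{name}: entry must be a number or a mapping")
    unknown = set(raw) - _DIST_ENTRY_KEYS
    if unknown:
        raise ConfigError(f"{name}: unknown keys {sorted(unknown)}")
    if "value" not in raw:
        raise ConfigError(f"{name}: missing 'value'")
    value = float(raw["value"])
    family = raw.get("dist", "fixed")
    if family == "fixed":
        return value, None

    low, high = default_support
    if "range" in raw:
        lo, hi = (float(x) for x in raw["range"])
        unc = UncertaintyDescriptor("range", lo, hi)
        if family == "beta":
            low, high = lo, hi
    elif "ci95" in raw:
        lo, hi = (float(x) for x in raw["ci95"])
        unc = UncertaintyDescriptor("ci95", lo, hi)
    elif "sd" in raw:
        unc = UncertaintyDescriptor("sd", float(raw["sd"]))
    else:
        raise ConfigError(f"{name}: distribution {family!r} needs sd, ci95 or range")
    if "support" in raw:
        low, high = (float(x) for x in raw["support"])
    try:
        spec = DistributionSpec(family, value, unc, low, high)
        spec.frozen()  # fail fast on infeasible moments
    except (ConfigError, InfeasibleMomentsError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc
    return value, spec


def _entry_to_raw(value: float, spec: DistributionSpec | None):
    if spec is None:
        return float(value)
    raw: dict = {"value": float(value), "dist": spec.family}
    u = spec.uncertainty
    if u.kind == "sd":
        raw["sd"] = u.value1
    elif u.kind in ("ci95", "range"):
        raw[u.kind] = [u.value1, u.value2]
    if spec.family == "beta" and (spec.support_low, spec.support_high) != (0.0, 1.0):
        if u.kind != "range" or (u.value1, u.value2) != (
            spec.support_low,
            spec.support_high,
        ):
            raw["support"] = [spec.support_low, spec.support_high]
    return raw


def load_model_config(path) -> tuple[ParameterSet, list[StrategySpec]]:
    """Load and validate a YAML model configuration.

    The document has two sections: ``parameters`` (global model parameters)
    and ``strategies`` (a list of strategy mappings).  Unknown keys are
    rejected; all container invariants are checked on construction.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_model_config(doc)


def parse_model_config(doc) -> tuple[ParameterSet, list[StrategySpec]]:
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(doc) - {"name", "description", "parameters", "strategies"}
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    raw_params = doc.get("parameters")
    raw_strategies = doc.get("strategies")
    if not isinstance(raw_params, dict):
        raise ConfigError("missing 'parameters' section")
    if not isinstance(raw_strategies, list) or not raw_strategies:
        raise ConfigError("missing or empty 'strategies' section")

    unknown = set(raw_params) - _PARAM_KEYS
    if unknown:
        raise ConfigError(f"unknown parameters {sorted(unknown)}")
    missing = _PARAM_KEYS - set(raw_params)
    if missing:
        raise ConfigError(f"missing parameters {sorted(missing)}")

    values: dict[str, float] = {}
    dists: dict[str, DistributionSpec] = {}
    for name, raw in raw_params.items():
        value, spec = _parse_entry(name, raw)
        values[name] = value
        if spec is not None:
            dists[name] = spec
    params = ParameterSet(distributions=dists, **values)

    strategies: list[StrategySpec] = []
    seen: set[str] = set()
    for raw in raw_strategies:
        if not isinstance(raw, dict) or "name" not in raw:
            raise ConfigError("each strategy must be a mapping with a 'name'")
        unknown = set(raw) - _STRATEGY_KEYS
        if unknown:
            raise ConfigError(f"{raw['name']}: unknown keys {sorted(unknown)}")
        name = str(raw["name"])
        if name in seen:
            raise ConfigError(f"duplicate strategy name {name!r}")
        seen.add(name)
        svalues: dict[str, float] = {}
        sdists: dict[str, DistributionSpec] = {}
        for fname in StrategySpec._STOCHASTIC:
            if fname in raw:
                support = (0.0, 100.0) if fname.startswith("frr_") else (0.0, 1.0)
                value, spec = _parse_entry(
                    f"{name}.{fname}", raw[fname], default_support=support
                )
                svalues[fname] = value
                if spec is not None:
                    sdists[fname] = spec
        strategies.append(
            StrategySpec(
                name=name,
                acceptance=float(raw.get("acceptance", 0.9)),
                dosage_note=str(raw.get("dosage_note", "")),
                distributions=sdists,
                **svalues,
            )
        )
    return params, strategies


def save_model_config(
    params: ParameterSet,
    strategies: list[StrategySpec] | tuple[StrategySpec, ...],
    path,
    name: str | None = None,
) -> None:
    """Write a configuration that :func:`load_model_config` reads back
    into identical objects."""
    raw_params: dict = {}
    for pname in sorted(_PARAM_KEYS):
        raw_params[pname] = _entry_to_raw(
            getattr(params, pname), params.distributions.get(pname)
        )
    raw_strategies = []
    for strat in strategies:
        raw: dict = {"name": strat.name, "acceptance": strat.acceptance}
        if strat.dosage_note:
            raw["dosage_note"] = strat.dosage_note
        for fname in StrategySpec._STOCHASTIC:
            value = getattr(strat, fname)
            spec = strat.distributions.get(fname)
            if value != 0.0 or spec is not None or fname == "annual_cost":
                raw[fname] = _entry_to_raw(value, spec)
        raw_strategies.append(raw)
    doc: dict = {"parameters": raw_params, "strategies": raw_strategies}
    if name:
        doc = {"name": name, **doc}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
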