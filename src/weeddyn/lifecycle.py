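"""Single-season demographic model of a generic annual weed.

One cycle runs seedbank -> seedlings -> mature plants -> fresh seed ->
seedbank, and returns the population growth rate lambda = seedbank at
t+1 / seedbank at t.  All densities are continuous (plants or seeds per
m^2); there is no demographic stochasticity.

Stage order: germination is removed from the bank first, exponential
decay is then applied to the residual bank over the season (dt = 1 yr).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Callable, Optional

import numpy as np
from scipy import optimize

from .errors import (
    CalibrationError,
    DomainError,
    InfeasibleError,
    ValidationError,
)
from .relationships import (
    CompetitionHeightModel,
    FecundityInterceptModel,
    ModelSet,
    SEED_WEIGHT_DOMAIN,
)

LN2 = math.log(2.0)


@dataclass
class VirtualWeed:
    """A point in trait space: maximum height (cm) and 1000-seed weight (mg)."""

    height: float
    seed_weight: float

    def __post_init__(self) -> None:
        if self.height <= 0 or self.seed_weight <= 0:
            raise DomainError("height and seed_weight must be > 0")


@dataclass
class Scenario:
    """Management scenario: herbicide kill rate and fertility level."""

    herbicide_mortality: float
    fertility: str  # "high" | "low"

    def __post_init__(self) -> None:
        if not 0.0 <= self.herbicide_mortality <= 1.0:
            raise DomainError("herbicide_mortality must be in [0, 1]")
        if self.fertility not in ("high", "low"):
            raise DomainError("fertility must be 'high' or 'low'")

    @property
    def name(self) -> str:
        herb = "high" if self.herbicide_mortality > 0.75 else "low"
        return f"{herb}-{self.fertility}"

    @classmethod
    def from_name(cls, name: str) -> "Scenario":
        try:
            return SCENARIOS[name]
        except KeyError:
            raise DomainError(
                f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}"
            ) from None


#: The four standard scenarios, "<herbicide>-<fertility>".
SCENARIOS: dict[str, Scenario] = {
    "low-low": Scenario(0.5, "low"),
    "low-high": Scenario(0.5, "high"),
    "high-low": Scenario(0.96, "low"),
    "high-high": Scenario(0.96, "high"),
}


@dataclass
class FertilityParams:
    """Parameters of the default low-fertility competition adjustment.

    The coefficient is a logistic in height relative to the crop, shifted
    by ln seed weight: short, small-seeded weeds suffer the largest
    relative loss of competitive ability at low fertility.
    """

    midpoint: float = 0.5        # relative height at which the logistic is centred
    steepness: float = 2.0       # per unit relative height
    seed_weight_slope: float = 0.1  # per unit ln(seed weight mg)


@dataclass
class SeedbankDecay:
    """Exponential seedbank decline: a * exp(-b * t)."""

    a: float  # seeds remaining after germination at time t
    b: float  # decay rate, yr^-1

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise DomainError("a and b must be >= 0")

    @property
    def half_life(self) -> float:
        return LN2 / self.b

    @classmethod
    def from_half_life(cls, a: float, half_life: float) -> "SeedbankDecay":
        if half_life <= 0:
            raise DomainError("half_life must be > 0")
        return cls(a=a, b=LN2 / half_life)

    def at(self, t: float) -> float:
        return self.a * math.exp(-self.b * t)


@dataclass
class LifecycleParams:
    """All scalar constants of the generic annual life cycle."""

    initial_seedbank: float = 1000.0     # seeds m^-2
    emergence_fraction: float = 0.071    # proportion of the bank emerging
    fresh_seed_loss: float = 0.79        # predation + fatal germination
    seedbank_half_life: float = 1.0      # years
    crop_height: float = 80.0            # cm
    allometric_slope: float = 1.0        # ln(seeds) vs ln(biomass)
    yield_loss_cap: float = 100.0        # asymptote of the one-parameter hyperbola, %
    biomass_coeff: Optional[float] = None  # g m^-2 per % yield loss; calibrated
    fertility: FertilityParams = field(default_factory=FertilityParams)
    #: optional replacements for the built-in sub-models (not serialised)
    fertility_fn: Optional[Callable[[float, float], float]] = None
    biomass_fn: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.initial_seedbank <= 0:
            raise DomainError("initial_seedbank must be > 0")
        for name in ("emergence_fraction", "fresh_seed_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {v}")
        if self.seedbank_half_life <= 0:
            raise DomainError("seedbank_half_life must be > 0")
        if self.crop_height <= 0:
            raise DomainError("crop_height must be > 0")
        if self.yield_loss_cap <= 5.0:
            raise InfeasibleError("yield_loss_cap must exceed 5%")
        if self.biomass_coeff is not None and self.biomass_coeff <= 0:
            raise DomainError("biomass_coeff must be > 0")
        if isinstance(self.fertility, dict):
            self.fertility = FertilityParams(**self.fertility)

    # -- serialisation ------------------------------------------------------
    _SCALARS = (
        "initial_seedbank", "emergence_fraction", "fresh_seed_loss",
        "seedbank_half_life", "crop_height", "allometric_slope",
        "yield_loss_cap", "biomass_coeff",
    )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self._SCALARS}
        d["fertility"] = asdict(self.fertility)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LifecycleParams":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "LifecycleParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def copy(self) -> "LifecycleParams":
        return replace(self, fertility=replace(self.fertility))


def load_default_params() -> LifecycleParams:
    """Packaged defaults (biomass_coeff unset: calibrate before running)."""
    with resources.files("weeddyn.data").joinpath("default_params.json").open(
        encoding="utf-8"
    ) as fh:
        return LifecycleParams.from_dict(json.load(fh))


@dataclass
class LifecycleResult:
    """Every intermediate flux of one annual cycle, plus lambda."""

    weed_height: float
    weed_seed_weight: float
    scenario: str
    emerged: float
    survivors: float
    d5: float
    i_param: float
    yield_loss_pct: float
    fertility_coefficient: float
    biomass_total: float
    biomass_per_plant: float
    seeds_produced: float
    seed_rain: float
    bank_carryover: float
    final_seedbank: float
    lam: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Stages


def emerge(params: LifecycleParams) -> float:
    """Seedlings m^-2 emerging from the initial bank."""
    return params.initial_seedbank * params.emergence_fraction


def survive_herbicide(seedlings: float, scenario: Scenario) -> float:
    """Seedlings surviving the herbicide filter (density kept continuous)."""
    if seedlings < 0:
        raise DomainError("seedlings must be >= 0")
    return seedlings * (1.0 - scenario.herbicide_mortality)


def yield_loss(
    survivors: float,
    weed: VirtualWeed,
    comp_model: CompetitionHeightModel,
    params: LifecycleParams,
    clamp: bool = True,
) -> tuple[float, float]:
    """Solve the one-parameter hyperbola for i and evaluate % yield loss.

    The asymptote m is fixed at ``params.yield_loss_cap``; i is back-solved
    from the height-predicted 5%-loss density, so YL(D5%) = 5 exactly.
    Returns (i, yield_loss_pct).
    """
    if survivors < 0:
        raise DomainError("survivors must be >= 0")
    cap = params.yield_loss_cap
    if cap <= 5.0:
        raise InfeasibleError("yield_loss_cap must exceed 5%")
    d5 = comp_model.predict_d5(weed.height, clamp=clamp)
    i = 5.0 / (d5 * (1.0 - 5.0 / cap))
    yl = i * survivors / (1.0 + i * survivors / cap)
    return i, yl


def default_fertility_fn(rel_height: float, ln_seed_weight: float,
                         fp: FertilityParams) -> float:
    """Logistic competitive-ability multiplier at low fertility, in (0, 1)."""
    z = fp.steepness * (rel_height - fp.midpoint) + fp.seed_weight_slope * ln_seed_weight
    return 1.0 / (1.0 + math.exp(-z))


def fertility_coefficient(
    weed: VirtualWeed, scenario: Scenario, params: LifecycleParams
) -> float:
    """Multiplier on % yield loss: 1 at high fertility, (0, 1] at low.

    At low fertility the default is a logistic in height relative to the
    crop, shifted by ln seed weight; a user-supplied function
    ``params.fertility_fn(rel_height, ln_seed_weight)`` may replace it and
    must return a value in (0, 1].
    """
    if scenario.fertility == "high":
        return 1.0
    rel_height = weed.height / params.crop_height
    ln_sw = math.log(weed.seed_weight)
    if params.fertility_fn is not None:
        coeff = float(params.fertility_fn(rel_height, ln_sw))
    else:
        coeff = default_fertility_fn(rel_height, ln_sw, params.fertility)
    if not 0.0 < coeff <= 1.0:
        raise ValidationError(
            f"fertility coefficient must lie in (0, 1], got {coeff}"
        )
    return coeff


def biomass_from_yield_loss(
    yield_loss_pct: float, survivors: float, params: LifecycleParams
) -> tuple[float, float]:
    """Mature weed biomass implied by the crop yield loss it caused.

    Default generic relationship: total biomass (g m^-2) is linear through
    the origin in % yield loss, with a calibrated coefficient.  A
    user-supplied ``params.biomass_fn(yield_loss_pct)`` may replace the
    linear form.  Returns (biomass_total, biomass_per_plant).
    """
    if yield_loss_pct < 0:
        raise DomainError("yield_loss_pct must be >= 0")
    if survivors <= 0.0:
        return 0.0, 0.0
    if params.biomass_fn is not None:
        total = float(params.biomass_fn(yield_loss_pct))
        if total < 0:
            raise ValidationError("biomass function returned a negative total")
    else:
        if params.biomass_coeff is None:
            raise CalibrationError(
                "biomass_coeff is unset: run calibrate_biomass_coeff first "
                "or set it explicitly"
            )
        total = params.biomass_coeff * yield_loss_pct
    return total, total / survivors


def fecundity(
    biomass_per_plant: float,
    survivors: float,
    weed: VirtualWeed,
    fec_model: FecundityInterceptModel,
    params: LifecycleParams,
    clamp: bool = True,
) -> float:
    """Fresh seed production (seeds m^-2) from the allometric relationship.

    seeds per plant = exp(intercept(seed weight)) * biomass^slope with the
    slope fixed at ``params.allometric_slope`` (default 1, i.e. seeds per
    gram is size-invariant).
    """
    if biomass_per_plant < 0:
        raise DomainError("biomass_per_plant must be >= 0")
    if survivors <= 0 or biomass_per_plant == 0.0:
        return 0.0
    intercept = fec_model.predict(weed.seed_weight, clamp=clamp)
    per_plant = math.exp(intercept) * biomass_per_plant ** params.allometric_slope
    return survivors * per_plant


def seedbank_carryover(
    params: LifecycleParams, emerged: float, dt: float = 1.0
) -> float:
    """Seeds m^-2 surviving in the bank after germination and decay.

    Germinated seed is subtracted first; the residual bank then decays
    exponentially with the configured half-life over ``dt`` years.
    """
    if dt < 0:
        raise DomainError("dt must be >= 0")
    if emerged > params.initial_seedbank:
        raise DomainError("emerged seedlings exceed the initial seedbank")
    residual = params.initial_seedbank - emerged
    decay = SeedbankDecay.from_half_life(residual, params.seedbank_half_life)
    return decay.at(dt)


def run_lifecycle(
    weed: VirtualWeed,
    scenario: Scenario,
    params: LifecycleParams,
    models: ModelSet,
    clamp: bool = True,
    dt: float = 1.0,
) -> LifecycleResult:
    """Chain all stages of one growing season and return lambda."""
    emerged = emerge(params)
    survivors = survive_herbicide(emerged, scenario)
    i, yl_raw = yield_loss(survivors, weed, models.competition, params, clamp=clamp)
    fert = fertility_coefficient(weed, scenario, params)
    yl = yl_raw * fert
    biomass_total, biomass_per_plant = biomass_from_yield_loss(yl, survivors, params)
    seeds = fecundity(
        biomass_per_plant, survivors, weed, models.fecundity, params, clamp=clamp
    )
    seed_rain = seeds * (1.0 - params.fresh_seed_loss)
    carryover = seedbank_carryover(params, emerged, dt=dt)
    final = carryover + seed_rain
    return LifecycleResult(
        weed_height=weed.height,
        weed_seed_weight=weed.seed_weight,
        scenario=scenario.name,
        emerged=emerged,
        survivors=survivors,
        d5=models.competition.predict_d5(weed.height, clamp=clamp),
        i_param=i,
        yield_loss_pct=yl,
        fertility_coefficient=fert,
        biomass_total=biomass_total,
        biomass_per_plant=biomass_per_plant,
        seeds_produced=seeds,
        seed_rain=seed_rain,
        bank_carryover=carryover,
        final_seedbank=final,
        lam=final / params.initial_seedbank,
    )


# ---------------------------------------------------------------------------
# Calibration


def _default_calibration_seed_weights() -> np.ndarray:
    lo, hi = SEED_WEIGHT_DOMAIN
    return np.round(np.arange(1, int(round(hi / lo)) + 1) * lo, 2)


def calibrate_biomass_coeff(
    params: LifecycleParams,
    models: ModelSet,
    scenario: Scenario = SCENARIOS["high-high"],
    tolerance: float = 1e-6,
    calibration_height: float = 10.0,
    seed_weights: Optional[np.ndarray] = None,
) -> float:
    """Set the biomass coefficient so the shortest plant is just viable.

    Finds the smallest biomass_coeff for which the maximum over seed weight
    of lambda(height = ``calibration_height``) under the given (by default
    maximum-stress) scenario equals 1, i.e. the 10 cm plant can maintain a
    viable population only by optimising seed size.  Root found by
    bracketed bisection (Brent) on the coefficient; the inner maximisation
    scans the sweep grid of seed weights.  Mutates ``params.biomass_coeff``
    and returns the coefficient.
    """
    sw = (
        np.asarray(seed_weights, dtype=float)
        if seed_weights is not None
        else _default_calibration_seed_weights()
    )

    def max_lambda(coeff: float) -> float:
        trial = params.copy()
        trial.biomass_coeff = coeff
        best = -math.inf
        for w in sw:
            res = run_lifecycle(VirtualWeed(calibration_height, float(w)),
                                scenario, trial, models)
            if res.lam > best:
                best = res.lam
        return best

    f = lambda c: max_lambda(c) - 1.0

    lo, hi = 1e-9, 1.0
    flo = f(lo)
    if flo > 0:
        raise CalibrationError(
            f"max lambda already exceeds 1 at biomass_coeff={lo:g} "
            f"(f={flo:g}); no bracketing interval below"
        )
    fhi = f(hi)
    n_expand = 0
    while fhi < 0:
        hi *= 10.0
        fhi = f(hi)
        n_expand += 1
        if n_expand > 12:
            raise CalibrationError(
                f"could not bracket the calibration root: f({hi:g})={fhi:g} "
                "still negative — seed production may be identically zero "
                "(check emergence fraction and herbicide mortality)"
            )
    coeff = float(optimize.brentq(f, lo, hi, xtol=tolerance, rtol=1e-12))
    params.biomass_coeff = coeff
    return coeff
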