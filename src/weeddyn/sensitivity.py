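"""One-at-a-time sensitivity analysis of the growth rate lambda.

Each registered scalar is perturbed multiplicatively (default x1.05), the
life cycle is re-run for a stated baseline weed and scenario, and the
percent change in lambda reported.  Perturbations act on deep copies, so
caller state is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import DomainError
from .lifecycle import LifecycleParams, Scenario, VirtualWeed, run_lifecycle
from .relationships import ModelSet


def _copy_all(params: LifecycleParams, models: ModelSet, scenario: Scenario):
    return (
        params.copy(),
        ModelSet.from_dict(models.to_dict()),
        replace(scenario),
    )


def _setter(target: str, attr: str, proportion: bool = False):
    def apply(params, models, scenario, fraction):
        obj = {
            "params": params,
            "fecundity": models.fecundity,
            "emergence_depth": models.emergence_depth,
            "competition": models.competition,
            "scenario": scenario,
        }[target]
        value = getattr(obj, attr) * (1.0 + fraction)
        if proportion:  # perturbed proportions stay in [0, 1]
            value = min(max(value, 0.0), 1.0)
        setattr(obj, attr, value)
    return apply


#: Registered scalar parameters, name -> in-place multiplier.
PARAMETERS = {
    "fecundity_intercept_c0": _setter("fecundity", "c0"),
    "emergence_fraction": _setter("params", "emergence_fraction", proportion=True),
    "fresh_seed_loss": _setter("params", "fresh_seed_loss", proportion=True),
    "seedbank_half_life": _setter("params", "seedbank_half_life"),
    "d5_intercept": _setter("competition", "intercept"),
    "d5_slope_magnitude": _setter("competition", "slope_magnitude"),
    "biomass_coeff": _setter("params", "biomass_coeff"),
    "herbicide_mortality": _setter("scenario", "herbicide_mortality", proportion=True),
    "crop_height": _setter("params", "crop_height"),
}


@dataclass
class PerturbResult:
    parameter: str
    fraction: float
    lambda_baseline: float
    lambda_perturbed: float

    @property
    def percent_change(self) -> float:
        return 100.0 * (self.lambda_perturbed - self.lambda_baseline) / self.lambda_baseline


def perturb(
    param_name: str,
    fraction: float,
    baseline_weed: VirtualWeed,
    scenario: Scenario,
    params: LifecycleParams,
    models: ModelSet,
) -> PerturbResult:
    """Percent change in lambda when one scalar is multiplied by (1+fraction)."""
    if param_name not in PARAMETERS:
        raise DomainError(
            f"unknown parameter {param_name!r}; registered: {sorted(PARAMETERS)}"
        )
    base = run_lifecycle(baseline_weed, scenario, params, models).lam
    p, m, s = _copy_all(params, models, scenario)
    PARAMETERS[param_name](p, m, s, fraction)
    pert = run_lifecycle(baseline_weed, s, p, m).lam
    return PerturbResult(
        parameter=param_name, fraction=fraction,
        lambda_baseline=base, lambda_perturbed=pert,
    )


@dataclass
class SensitivityReport:
    baseline_weed: VirtualWeed
    scenario: str
    fraction: float
    baseline_lambda: float
    rows: list[PerturbResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [
                {
                    "parameter": r.parameter,
                    "lambda_baseline": r.lambda_baseline,
                    "lambda_perturbed": r.lambda_perturbed,
                    "pct_change": r.percent_change,
                }
                for r in self.rows
            ]
        )
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, encoding="utf-8")


def full_report(
    baseline_weed: VirtualWeed,
    scenario: Scenario,
    params: LifecycleParams,
    models: ModelSet,
    fraction: float = 0.05,
) -> SensitivityReport:
    """Perturb every registered parameter; rows ranked by |percent change|."""
    base = run_lifecycle(baseline_weed, scenario, params, models).lam
    rows = [
        perturb(name, fraction, baseline_weed, scenario, params, models)
        for name in PARAMETERS
    ]
    rows.sort(key=lambda r: abs(r.percent_change), reverse=True)
    return SensitivityReport(
        baseline_weed=baseline_weed,
        scenario=scenario.name,
        fraction=fraction,
        baseline_lambda=base,
        rows=rows,
    )
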