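"""Empirical trait -> demographic-parameter regressions.

Three relationships drive the generic life-cycle model:

* fecundity intercept (ln seeds produced by 1 g shoot biomass) as a
  quadratic in ln seed weight (mg);
* maximum emergence depth (cm) linear in ln seed weight;
* ln of the weed density causing 5% crop yield loss (D5%) linear in
  maximum height (cm).

Default coefficients are the published fits; :func:`fit_fecundity_model`
and :func:`fit_loglinear_model` re-estimate the same functional forms
from arbitrary species-level tables.

Sign convention: the published competition fit prints a positive slope,
which would make taller weeds *less* competitive.  The default here uses
the printed magnitude with a negative sign so D5% decreases with height
(taller weed = fewer plants needed for a 5% loss); the sign is a model
field so the printed orientation can be restored.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError

#: Trait domains over which the regressions were established; predictions
#: outside are clamped (with a warning) unless clamp=False is requested.
SEED_WEIGHT_DOMAIN: tuple[float, float] = (0.01, 20.0)   # mg
HEIGHT_DOMAIN: tuple[float, float] = (10.0, 200.0)       # cm


def _clamp(value: float, lo: float, hi: float, what: str, clamp: bool) -> float:
    if value < lo or value > hi:
        if clamp:
            clamped = min(max(value, lo), hi)
            warnings.warn(
                f"{what}={value:g} outside fitted domain [{lo:g}, {hi:g}]; "
                f"clamped to {clamped:g}",
                stacklevel=3,
            )
            return clamped
    return value


@dataclass
class FecundityInterceptModel:
    """ln(seeds per g biomass) = c2*x^2 + c1*x + c0, x = ln(seed weight mg)."""

    c2: float = -0.14
    c1: float = -0.70
    c0: float = 5.85

    def predict(self, seed_weight: float, clamp: bool = True) -> float:
        if seed_weight <= 0:
            raise DomainError(f"seed_weight must be > 0 mg, got {seed_weight}")
        sw = _clamp(seed_weight, *SEED_WEIGHT_DOMAIN, what="seed_weight", clamp=clamp)
        x = math.log(sw)
        return self.c2 * x * x + self.c1 * x + self.c0


@dataclass
class EmergenceDepthModel:
    """Maximum emergence depth (cm) = slope*ln(seed weight mg) + intercept.

    The optimum emergence depth showed no significant trait relationship
    and is treated as a constant elsewhere; only the maximum is modelled.
    Predicted depths are floored at zero.
    """

    slope: float = 1.36
    intercept: float = 7.53

    def predict(self, seed_weight: float, clamp: bool = True) -> float:
        if seed_weight <= 0:
            raise DomainError(f"seed_weight must be > 0 mg, got {seed_weight}")
        sw = _clamp(seed_weight, *SEED_WEIGHT_DOMAIN, what="seed_weight", clamp=clamp)
        return max(0.0, self.slope * math.log(sw) + self.intercept)


@dataclass
class CompetitionHeightModel:
    """ln(D5% plants m^-2) = intercept + sign*slope_magnitude*height(cm)."""

    slope_magnitude: float = 0.020
    intercept: float = 4.51
    sign: int = -1

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise DomainError("sign must be -1 or +1")
        if self.slope_magnitude < 0:
            raise DomainError("slope_magnitude must be >= 0")

    @property
    def signed_slope(self) -> float:
        return self.sign * self.slope_magnitude

    def predict_d5(self, height: float, clamp: bool = True) -> float:
        if height <= 0 and clamp:
            raise DomainError(f"height must be > 0 cm, got {height}")
        h = _clamp(height, *HEIGHT_DOMAIN, what="height", clamp=clamp)
        return math.exp(self.intercept + self.signed_slope * h)


# Module-level conveniences mirroring the model methods -----------------------

def predict_fecundity_intercept(
    seed_weight: float, model: Optional[FecundityInterceptModel] = None,
    clamp: bool = True,
) -> float:
    return (model or FecundityInterceptModel()).predict(seed_weight, clamp=clamp)


def predict_max_emergence_depth(
    seed_weight: float, model: Optional[EmergenceDepthModel] = None,
    clamp: bool = True,
) -> float:
    return (model or EmergenceDepthModel()).predict(seed_weight, clamp=clamp)


def predict_d5(
    height: float, model: Optional[CompetitionHeightModel] = None,
    clamp: bool = True,
) -> float:
    return (model or CompetitionHeightModel()).predict_d5(height, clamp=clamp)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class RegressionFit:
    """Ordinary least-squares fit with enough metadata for inference.

    ``coefficients`` are ordered highest degree first (quadratic:
    (c2, c1, c0); line: (slope, intercept)).
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    residual_variance: float
    r2: float
    n: int

    @property
    def df_resid(self) -> int:
        return self.n - len(self.coefficients)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """(k, 2) array of coefficient confidence intervals."""
        se = np.sqrt(np.diag(self.covariance))
        tval = stats.t.ppf(0.5 + level / 2.0, self.df_resid)
        return np.column_stack(
            [self.coefficients - tval * se, self.coefficients + tval * se]
        )


def _ols(design: np.ndarray, y: np.ndarray) -> RegressionFit:
    n, p = design.shape
    if n < p + 1:
        raise InsufficientDataError(f"need at least {p + 1} points, got {n}")
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p:
        raise DomainError("degenerate design matrix (collinear or constant predictor)")
    resid = y - design @ beta
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    sigma2 = ssr / (n - p)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    return RegressionFit(
        coefficients=beta, covariance=cov, residual_variance=sigma2, r2=r2, n=n
    )


@dataclass
class FecundityFit:
    quadratic: RegressionFit
    linear: RegressionFit
    #: the form with the lower residual variance
    preferred: str = "quadratic"


def fit_fecundity_model(
    seed_weights: Sequence[float], intercepts: Sequence[float]
) -> FecundityFit:
    """Fit ln-seed-weight quadratic (and a straight line for comparison).

    ``seed_weights`` in mg; ``intercepts`` are species-level allometric
    intercepts (ln seeds per g).  Requires >= 4 species.
    """
    sw = np.asarray(seed_weights, dtype=float)
    y = np.asarray(intercepts, dtype=float)
    if sw.shape != y.shape or sw.ndim != 1:
        raise DomainError("seed_weights and intercepts must be equal-length 1-D")
    if len(sw) < 4:
        raise InsufficientDataError(f"quadratic fit needs >= 4 species, got {len(sw)}")
    if np.any(sw <= 0):
        raise DomainError("seed weights must be > 0 mg")
    x = np.log(sw)
    quad = _ols(np.column_stack([x * x, x, np.ones_like(x)]), y)
    lin = _ols(np.column_stack([x, np.ones_like(x)]), y)
    preferred = (
        "quadratic" if quad.residual_variance <= lin.residual_variance else "linear"
    )
    return FecundityFit(quadratic=quad, linear=lin, preferred=preferred)


def fit_loglinear_model(
    x: Sequence[float], y: Sequence[float], log_y: bool = False
) -> RegressionFit:
    """OLS straight line y = slope*x + intercept, optionally on ln(y)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D")
    if len(xv) < 3:
        raise InsufficientDataError(f"line fit needs >= 3 points, got {len(xv)}")
    if np.ptp(xv) == 0.0:
        raise DomainError("x has zero variance")
    if log_y:
        if np.any(yv <= 0):
            raise DomainError("log_y requires strictly positive y")
        yv = np.log(yv)
    return _ols(np.column_stack([xv, np.ones_like(xv)]), yv)


# ---------------------------------------------------------------------------
# Serialisation


@dataclass
class ModelSet:
    """The three trait regressions bundled for the life-cycle model."""

    fecundity: FecundityInterceptModel = field(default_factory=FecundityInterceptModel)
    emergence_depth: EmergenceDepthModel = field(default_factory=EmergenceDepthModel)
    competition: CompetitionHeightModel = field(default_factory=CompetitionHeightModel)

    def to_dict(self) -> dict:
        return {
            "fecundity": asdict(self.fecundity),
            "emergence_depth": asdict(self.emergence_depth),
            "competition": asdict(self.competition),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSet":
        return cls(
            fecundity=FecundityInterceptModel(**d["fecundity"]),
            emergence_depth=EmergenceDepthModel(**d["emergence_depth"]),
            competition=CompetitionHeightModel(**d["competition"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ModelSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def load_default_models() -> ModelSet:
    """The packaged default coefficients."""
    with resources.files("weeddyn.data").joinpath("default_models.json").open(
        encoding="utf-8"
    ) as fh:
        return ModelSet.from_dict(json.load(fh))
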