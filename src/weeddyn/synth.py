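"""Generators for every input the pipeline needs, plus the published-range fixture.

``generate_wtdb`` emits a virtual trait database whose species obey the
default trait regressions plus configurable noise, so parameter-recovery
and correlation analyses can be exercised without any external data.
``generate_species_pools`` draws "common-like" and "declining-like"
species pools by rejection sampling against the model's own calibrated
fitness surface, so pool guarantees stay valid if the model is
re-calibrated.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .lifecycle import (
    LifecycleParams,
    SCENARIOS,
    Scenario,
    VirtualWeed,
    run_lifecycle,
)
from .relationships import ModelSet, SEED_WEIGHT_DOMAIN, HEIGHT_DOMAIN
from .landscape import SpeciesRecord
from .wtdb import ENDPOINT_TAG, TraitRecord, UNITS, d5_from_comphyp


@dataclass
class GeneratorConfig:
    """Sampling plan for a virtual trait database.

    Seed weights are log-uniform and heights uniform over the fitted trait
    domains.  Emergence fraction and seedbank half-life are right-skewed
    (log-normal parameterised by its median) with medians matching the
    database-wide values used by the life-cycle model (7.1% and 1 year).
    """

    n_species: int = 19
    seed_weight_range: tuple[float, float] = SEED_WEIGHT_DOMAIN
    height_range: tuple[float, float] = HEIGHT_DOMAIN
    noise_fecundity: float = 0.3      # sd on the allometric intercept
    noise_depth: float = 0.2          # sd (cm) on max emergence depth
    noise_ln_d5: float = 0.3          # sd on ln(D5%)
    emergence_median: float = 0.071   # median emergence fraction
    emergence_sigma: float = 0.8      # ln-scale spread (right skew)
    half_life_median: float = 1.0     # years
    half_life_sigma: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        for nm in ("noise_fecundity", "noise_depth", "noise_ln_d5",
                   "emergence_sigma", "half_life_sigma"):
            if getattr(self, nm) < 0:
                raise ValidationError(f"{nm} must be >= 0")


def skewed_median_draw(rng: np.random.Generator, median: float, sigma: float,
                       size: Optional[int] = None):
    """Right-skewed positive draws with the requested median (log-normal)."""
    return np.exp(rng.normal(math.log(median), sigma, size=size))


def generate_wtdb(
    config: GeneratorConfig, models: Optional[ModelSet] = None
) -> list[TraitRecord]:
    """A schema-valid virtual trait database built around the default models.

    Per species: SEEDWEIGHT and COMPHEIGHT draws; an allometric intercept
    (FECUNDITY_2) from the seed-weight quadratic plus Gaussian noise with a
    unit slope (FECUNDITY_1); maximum emergence depth (EMDEPTH_2) from the
    seed-weight line plus additive noise and a near-constant optimum
    (EMDEPTH_1);
    hyperbola parameters (COMPHYP_1/2) back-derived from the noisy
    height->D5% line; and skewed EMTOT_1 / SEEDPER_1 draws.  Fully
    reproducible from ``config.rng_seed``.
    """
    models = models or ModelSet()
    rng = np.random.default_rng(config.rng_seed)
    lo_sw, hi_sw = config.seed_weight_range
    lo_h, hi_h = config.height_range
    records: list[TraitRecord] = []

    def add(species: str, code: str, value) -> None:
        records.append(
            TraitRecord(
                species=species, field_code=code, value=value,
                units=UNITS.get(code, ""), source_quality="unpublished",
                notes="synthetic",
            )
        )

    for k in range(config.n_species):
        species = f"species_{k + 1:03d}"
        sw = float(np.exp(rng.uniform(math.log(lo_sw), math.log(hi_sw))))
        height = float(rng.uniform(lo_h, hi_h))
        add(species, "SEEDWEIGHT", sw)
        add(species, "COMPHEIGHT", height)

        intercept = models.fecundity.predict(sw) + rng.normal(0.0, config.noise_fecundity)
        add(species, "FECUNDITY_1", 1.0)
        add(species, "FECUNDITY_2", intercept)

        depth = models.emergence_depth.predict(sw) + rng.normal(
            0.0, config.noise_depth
        )
        add(species, "EMDEPTH_2", max(depth, 1e-3))
        add(species, "EMDEPTH_1", float(rng.uniform(0.5, 3.0)))  # optimum: trait-free

        d5 = models.competition.predict_d5(height) * math.exp(
            rng.normal(0.0, config.noise_ln_d5)
        )
        m = float(rng.uniform(40.0, 100.0))
        i = 5.0 / (d5 * (1.0 - 5.0 / m))
        add(species, "COMPHYP_1", i)
        add(species, "COMPHYP_2", m)

        add(species, "EMTOT_1",
            float(min(100.0, 100.0 * skewed_median_draw(
                rng, config.emergence_median, config.emergence_sigma))))
        add(species, "SEEDPER_1",
            float(skewed_median_draw(rng, config.half_life_median,
                                     config.half_life_sigma)))
    return records


# ---------------------------------------------------------------------------
# Species pools


def generate_species_pools(
    n_common: int,
    n_declining: int,
    seed: int,
    params: LifecycleParams,
    models: ModelSet,
    scenario: Scenario = SCENARIOS["high-high"],
    threshold: float = 1.0,
    declining_min_lambda: float = 0.7,
    max_tries_per_species: int = 20000,
) -> list[SpeciesRecord]:
    """Two trait-space pools defined against the model's own fitness surface.

    "common-like" species are rejection-sampled from the region where
    lambda >= threshold under ``scenario`` (high herbicide + high fertility
    by default); "declining-like" species from the complement, restricted
    to lambda >= ``declining_min_lambda`` so the pool represents declining
    but extant populations rather than the carryover-only floor where no
    real weed flora would persist.  Sampling is height-uniform and
    seed-weight log-uniform over the sweep domain.
    """
    if n_common < 1 or n_declining < 1:
        raise ValidationError("pool sizes must be >= 1")
    if params.biomass_coeff is None:
        raise ValidationError("params must be calibrated before pool generation")
    rng = np.random.default_rng(seed)
    lo_sw, hi_sw = SEED_WEIGHT_DOMAIN
    lo_h, hi_h = HEIGHT_DOMAIN

    def draw_one(accept, label: str) -> VirtualWeed:
        for _ in range(max_tries_per_species):
            h = float(rng.uniform(lo_h, hi_h))
            sw = float(np.exp(rng.uniform(math.log(lo_sw), math.log(hi_sw))))
            lam = run_lifecycle(VirtualWeed(h, sw), scenario, params, models).lam
            if accept(lam):
                return VirtualWeed(h, sw)
        raise ValidationError(
            f"could not sample a {label} species in {max_tries_per_species} tries; "
            "the target lambda region may be empty at the current calibration"
        )

    pools: list[SpeciesRecord] = []
    for j in range(n_common):
        w = draw_one(lambda lam: lam >= threshold, "common-like")
        pools.append(SpeciesRecord(
            name=f"common_{j + 1:03d}", height=w.height,
            seed_weight=w.seed_weight, status="common"))
    for j in range(n_declining):
        w = draw_one(
            lambda lam: declining_min_lambda <= lam < threshold, "declining-like"
        )
        pools.append(SpeciesRecord(
            name=f"declining_{j + 1:03d}", height=w.height,
            seed_weight=w.seed_weight, status="rare_declining"))
    return pools


def species_to_csv(pools, path) -> None:
    pd.DataFrame(
        [
            {
                "name": s.name,
                "height_cm": s.height,
                "seed_weight_mg": s.seed_weight,
                "status": s.status,
            }
            for s in pools
        ]
    ).to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Published-range fixture

_FIXTURE_NAME = "published_trait_ranges.csv"
#: sha256 of the packaged fixture; guards against silent corruption.
_FIXTURE_SHA256 = "fc49c17b4453546ec9d163ca72e4310312d8ebe9dd27f550833f34eb647212c3"

#: field -> printed-summary column labels, for reference/debugging
FIXTURE_FIELDS = (
    "COMPHEIGHT", "COMPHYP_1", "FECUNDITY_2", "GERMBASE",
    "EMDEPTH_2", "EMTOT_1", "SEEDPER_1", "SEEDWEIGHT",
)


def load_published_ranges() -> list[TraitRecord]:
    """Endpoint-tagged records transcribed from the published 19-species summary.

    Only the printed minimum/maximum of each field (with the number of
    underlying entries, n) are available, so each row of the fixture
    expands to one record (min == max, single entry) or two endpoint
    records.  Summaries over these records label themselves
    ``endpoint-only`` and must never be confused with full-database means.
    """
    res = resources.files("weeddyn.data").joinpath(_FIXTURE_NAME)
    raw = res.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FormatError(
            f"packaged fixture {_FIXTURE_NAME} checksum mismatch "
            f"(got {digest}); the installation is corrupt"
        )
    with res.open(encoding="utf-8") as fh:
        frame = pd.read_csv(fh)
    records: list[TraitRecord] = []
    for _, row in frame.iterrows():
        n = int(row["n"])
        vmin, vmax = float(row["min"]), float(row["max"])
        endpoints = [vmin] if vmin == vmax else [vmin, vmax]
        for which, v in zip(("min", "max"), endpoints):
            records.append(
                TraitRecord(
                    species=row["species"],
                    field_code=row["field_code"],
                    value=v,
                    units=UNITS.get(row["field_code"], ""),
                    source_quality="report",
                    notes=f"{ENDPOINT_TAG} ({which} of {n} entries)",
                )
            )
    return records
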