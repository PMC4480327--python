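"""Independent straight-line re-implementation of the annual cycle.

Deliberately written from the formulas alone — no imports from the
package under test — so it can serve as an oracle for run_lifecycle.
"""

import math


def oracle_lambda(
    height,
    seed_weight,
    herbicide_mortality,
    fertility,               # "high" | "low"
    *,
    initial_seedbank=1000.0,
    emergence_fraction=0.071,
    fresh_seed_loss=0.79,
    seedbank_half_life=1.0,
    crop_height=80.0,
    allometric_slope=1.0,
    yield_loss_cap=100.0,
    biomass_coeff=1.0,
    fert_midpoint=0.5,
    fert_steepness=2.0,
    fert_sw_slope=0.1,
    c2=-0.14,
    c1=-0.70,
    c0=5.85,
    d5_intercept=4.51,
    d5_slope=-0.020,
    dt=1.0,
):
    x = math.log(seed_weight)
    emerged = initial_seedbank * emergence_fraction
    survivors = emerged * (1.0 - herbicide_mortality)

    d5 = math.exp(d5_intercept + d5_slope * height)
    i = 5.0 / (d5 * (1.0 - 5.0 / yield_loss_cap))
    yl = i * survivors / (1.0 + i * survivors / yield_loss_cap)

    if fertility == "low":
        z = fert_steepness * (height / crop_height - fert_midpoint) + fert_sw_slope * x
        yl *= 1.0 / (1.0 + math.exp(-z))

    biomass_total = biomass_coeff * yl
    if survivors > 0 and biomass_total > 0:
        per_plant = biomass_total / survivors
        a = c2 * x * x + c1 * x + c0
        seeds = survivors * math.exp(a) * per_plant ** allometric_slope
    else:
        seeds = 0.0

    seed_rain = seeds * (1.0 - fresh_seed_loss)
    carryover = (initial_seedbank - emerged) * math.exp(
        -math.log(2.0) * dt / seedbank_half_life
    )
    return (carryover + seed_rain) / initial_seedbank
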