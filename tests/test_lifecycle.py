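import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from weeddyn.errors import (
    CalibrationError,
    DomainError,
    InfeasibleError,
    ValidationError,
)
from weeddyn.lifecycle import (
    LifecycleParams,
    SCENARIOS,
    Scenario,
    SeedbankDecay,
    VirtualWeed,
    biomass_from_yield_loss,
    calibrate_biomass_coeff,
    emerge,
    fecundity,
    fertility_coefficient,
    run_lifecycle,
    seedbank_carryover,
    survive_herbicide,
    yield_loss,
)

from _oracle import oracle_lambda


class TestTypes:
    def test_virtual_weed_positive(self):
        with pytest.raises(DomainError):
            VirtualWeed(0.0, 1.0)
        with pytest.raises(DomainError):
            VirtualWeed(10.0, -1.0)

    def test_scenario_validation(self):
        with pytest.raises(DomainError):
            Scenario(1.5, "high")
        with pytest.raises(DomainError):
            Scenario(0.5, "medium")

    def test_scenario_names(self):
        assert SCENARIOS["high-high"].herbicide_mortality == 0.96
        assert SCENARIOS["low-low"].herbicide_mortality == 0.5
        for name, sc in SCENARIOS.items():
            assert sc.name == name
            assert Scenario.from_name(name) == sc
        with pytest.raises(DomainError):
            Scenario.from_name("medium-high")

    def test_seedbank_decay_half_life_identity(self):
        d = SeedbankDecay.from_half_life(929.0, 2.5)
        assert d.half_life * d.b == pytest.approx(math.log(2.0), abs=1e-12)

    def test_params_validation(self):
        with pytest.raises(DomainError):
            LifecycleParams(initial_seedbank=0.0)
        with pytest.raises(DomainError):
            LifecycleParams(emergence_fraction=1.2)
        with pytest.raises(DomainError):
            LifecycleParams(seedbank_half_life=0.0)
        with pytest.raises(InfeasibleError):
            LifecycleParams(yield_loss_cap=4.0)

    def test_params_json_round_trip(self, tmp_path, params):
        params.biomass_coeff = 3.25
        p = tmp_path / "params.json"
        params.to_json(p)
        assert LifecycleParams.from_json(p) == params


class TestEmergence:
    def test_defaults_give_71(self, params):
        assert emerge(params) == pytest.approx(71.0)

    def test_zero_fraction(self, params):
        params.emergence_fraction = 0.0
        assert emerge(params) == 0.0

    def test_arithmetic(self):
        p = LifecycleParams(initial_seedbank=500.0, emergence_fraction=0.2)
        assert emerge(p) == pytest.approx(100.0)


class TestHerbicide:
    def test_high_mortality(self):
        assert survive_herbicide(71.0, Scenario(0.96, "high")) == pytest.approx(2.84)

    def test_low_mortality(self):
        assert survive_herbicide(71.0, Scenario(0.5, "high")) == pytest.approx(35.5)

    def test_zero_mortality_identity(self):
        assert survive_herbicide(71.0, Scenario(0.0, "high")) == 71.0

    def test_continuous_density(self):
        out = survive_herbicide(71.0, Scenario(0.96, "high"))
        assert out != round(out)

    def test_negative_seedlings(self):
        with pytest.raises(DomainError):
            survive_herbicide(-1.0, Scenario(0.5, "high"))


class TestYieldLoss:
    def test_exactly_five_at_d5(self, models, params):
        for h in (10.0, 80.0, 150.0, 200.0):
            d5 = models.competition.predict_d5(h)
            _, yl = yield_loss(d5, VirtualWeed(h, 1.0), models.competition, params)
            assert yl == pytest.approx(5.0, abs=1e-9)

    def test_zero_density(self, models, params):
        _, yl = yield_loss(0.0, VirtualWeed(100, 1.0), models.competition, params)
        assert yl == 0.0

    def test_hand_worked_example(self, models, params):
        i, yl = yield_loss(35.5, VirtualWeed(100, 1.0), models.competition, params)
        d5 = math.exp(4.51 - 2.0)
        i_expected = 5.0 / (d5 * (1.0 - 0.05))
        assert i == pytest.approx(i_expected, rel=1e-12)
        assert i == pytest.approx(0.4279, abs=5e-4)
        assert yl == pytest.approx(i_expected * 35.5 / (1 + i_expected * 35.5 / 100),
                                   rel=1e-12)
        assert yl == pytest.approx(13.2, abs=0.1)

    def test_cap_bounds_loss(self, models, params):
        _, yl = yield_loss(1e9, VirtualWeed(200, 1.0), models.competition, params)
        assert 0.0 < yl < params.yield_loss_cap

    def test_infeasible_cap(self, models, params):
        params.yield_loss_cap = 100.0
        object.__setattr__(params, "yield_loss_cap", 4.0)  # bypass ctor check
        with pytest.raises(InfeasibleError):
            yield_loss(10.0, VirtualWeed(100, 1.0), models.competition, params)


class TestFertility:
    def test_high_is_identity(self, params):
        for w in (VirtualWeed(10, 0.01), VirtualWeed(200, 20.0)):
            assert fertility_coefficient(w, Scenario(0.5, "high"), params) == 1.0

    def test_low_bounded_and_monotone_in_height(self, params):
        low = Scenario(0.5, "low")
        for sw in (0.01, 1.0, 20.0):
            coeffs = [
                fertility_coefficient(VirtualWeed(h, sw), low, params)
                for h in np.linspace(10, 200, 60)
            ]
            assert all(0.0 < c <= 1.0 for c in coeffs)
            assert np.all(np.diff(coeffs) >= 0)

    def test_user_function_out_of_bounds(self, params):
        params.fertility_fn = lambda rel_h, ln_sw: 1.2
        with pytest.raises(ValidationError):
            fertility_coefficient(VirtualWeed(100, 1.0), Scenario(0.5, "low"), params)

    def test_user_function_used(self, params):
        params.fertility_fn = lambda rel_h, ln_sw: 0.42
        got = fertility_coefficient(VirtualWeed(100, 1.0), Scenario(0.5, "low"), params)
        assert got == 0.42


class TestBiomass:
    def test_zero_yield_loss(self, params):
        params.biomass_coeff = 2.0
        assert biomass_from_yield_loss(0.0, 10.0, params) == (0.0, 0.0)

    def test_linear_example(self, params):
        params.biomass_coeff = 2.0
        total, per = biomass_from_yield_loss(13.22, 35.5, params)
        assert total == pytest.approx(26.44)
        assert per == pytest.approx(26.44 / 35.5)

    def test_doubling_coefficient(self, params):
        params.biomass_coeff = 2.0
        t1, p1 = biomass_from_yield_loss(7.0, 10.0, params)
        params.biomass_coeff = 4.0
        t2, p2 = biomass_from_yield_loss(7.0, 10.0, params)
        assert (t2, p2) == (2 * t1, 2 * p1)

    def test_zero_survivors(self, params):
        params.biomass_coeff = 2.0
        assert biomass_from_yield_loss(5.0, 0.0, params) == (0.0, 0.0)

    def test_uncalibrated_errors(self, params):
        assert params.biomass_coeff is None
        with pytest.raises(CalibrationError):
            biomass_from_yield_loss(5.0, 10.0, params)

    def test_pluggable_biomass_fn(self, params):
        params.biomass_fn = lambda yl: 3.0 * yl ** 0.5
        total, _ = biomass_from_yield_loss(4.0, 2.0, params)
        assert total == pytest.approx(6.0)


class TestFecundity:
    def test_one_gram_one_mg(self, models, params):
        params.biomass_coeff = 2.0
        seeds = fecundity(1.0, 1.0, VirtualWeed(100, 1.0), models.fecundity, params)
        assert seeds == pytest.approx(math.exp(5.85), rel=1e-12)
        assert seeds == pytest.approx(347.2, abs=0.1)

    def test_zero_biomass(self, models, params):
        assert fecundity(0.0, 10.0, VirtualWeed(100, 1.0), models.fecundity, params) == 0.0

    @given(
        total=st.floats(0.1, 500.0),
        n1=st.floats(0.5, 200.0),
        n2=st.floats(0.5, 200.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_density_invariance_with_unit_slope(self, total, n1, n2):
        models = __import__("weeddyn").load_default_models()
        params = LifecycleParams(biomass_coeff=2.0)
        w = VirtualWeed(100, 1.3)
        s1 = fecundity(total / n1, n1, w, models.fecundity, params)
        s2 = fecundity(total / n2, n2, w, models.fecundity, params)
        assert s1 == pytest.approx(s2, rel=1e-9)
        assert s1 == pytest.approx(
            math.exp(models.fecundity.predict(1.3)) * total, rel=1e-9
        )


class TestCarryover:
    def test_default_half_life_one_year(self, params):
        assert seedbank_carryover(params, 71.0, dt=1.0) == pytest.approx(464.5, rel=1e-12)

    def test_no_decay_limit(self, params):
        params.seedbank_half_life = 1e12
        assert seedbank_carryover(params, 71.0, dt=1.0) == pytest.approx(929.0, rel=1e-9)

    def test_dt_zero_identity(self, params):
        assert seedbank_carryover(params, 71.0, dt=0.0) == pytest.approx(929.0)

    def test_emerged_exceeds_bank(self, params):
        with pytest.raises(DomainError):
            seedbank_carryover(params, 1001.0)

    @given(hl=st.floats(0.1, 50.0), dt=st.floats(0.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_residual_bank(self, hl, dt):
        p = LifecycleParams(seedbank_half_life=hl)
        out = seedbank_carryover(p, 71.0, dt=dt)
        assert 0.0 < out <= 929.0


class TestRunLifecycle:
    def test_total_kill_fitness_floor(self, calibrated_params, models):
        res = run_lifecycle(VirtualWeed(100, 1.0), Scenario(1.0, "high"),
                            calibrated_params, models)
        assert res.seeds_produced == 0.0
        assert res.lam == pytest.approx(0.4645, abs=1e-9)

    def test_worked_example_matches_oracle(self, params, models):
        params.biomass_coeff = 2.0
        res = run_lifecycle(VirtualWeed(100, 1.0), Scenario(0.5, "high"),
                            params, models)
        assert res.lam == pytest.approx(
            oracle_lambda(100, 1.0, 0.5, "high", biomass_coeff=2.0), abs=1e-12
        )
        # chained published-rounding arithmetic gives ~2.39
        assert res.lam == pytest.approx(2.39, abs=0.01)

    def test_seedbank_conservation_exact(self, calibrated_params, models):
        res = run_lifecycle(VirtualWeed(57.0, 0.37), SCENARIOS["low-low"],
                            calibrated_params, models)
        assert res.final_seedbank == res.bank_carryover + res.seed_rain
        assert res.lam == res.final_seedbank / calibrated_params.initial_seedbank

    def test_lambda_floor(self, calibrated_params, models):
        floor = (1 - calibrated_params.emergence_fraction) * 0.5
        for h in (10, 60, 200):
            for sw in (0.01, 1.0, 20.0):
                for sc in SCENARIOS.values():
                    res = run_lifecycle(VirtualWeed(h, sw), sc,
                                        calibrated_params, models)
                    assert res.lam >= floor

    def test_monotone_in_mortality(self, calibrated_params, models):
        lams = [
            run_lifecycle(VirtualWeed(120, 0.5), Scenario(m, "high"),
                          calibrated_params, models).lam
            for m in np.linspace(0.0, 1.0, 21)
        ]
        assert np.all(np.diff(lams) <= 0)

    def test_all_fluxes_nonnegative(self, calibrated_params, models, rng):
        for _ in range(20):
            res = run_lifecycle(
                VirtualWeed(rng.uniform(10, 200),
                            float(np.exp(rng.uniform(np.log(0.01), np.log(20))))),
                SCENARIOS["high-low"], calibrated_params, models,
            )
            for f in ("emerged", "survivors", "d5", "i_param", "yield_loss_pct",
                      "biomass_total", "biomass_per_plant", "seeds_produced",
                      "seed_rain", "bank_carryover", "final_seedbank", "lam"):
                assert getattr(res, f) >= 0.0

    def test_result_serialises_flat(self, calibrated_params, models):
        d = run_lifecycle(VirtualWeed(100, 1.0), SCENARIOS["high-high"],
                          calibrated_params, models).to_dict()
        assert all(isinstance(v, (int, float, str)) for v in d.values())


class TestCalibration:
    def test_postcondition(self, models, calibrated_params):
        sw = np.round(np.arange(1, 2001) * 0.01, 2)
        lams = [
            run_lifecycle(VirtualWeed(10.0, float(s)), SCENARIOS["high-high"],
                          calibrated_params, models).lam
            for s in sw
        ]
        assert max(lams) == pytest.approx(1.0, abs=1e-3)

    def test_coeff_increases_with_fresh_seed_loss(self, models):
        coeffs = []
        for loss in (0.5, 0.79, 0.9):
            p = LifecycleParams(fresh_seed_loss=loss)
            coeffs.append(calibrate_biomass_coeff(p, models))
        assert coeffs[0] < coeffs[1] < coeffs[2]

    def test_converges_with_printed_stress_parameters(self, models):
        p = LifecycleParams(fresh_seed_loss=0.79)
        coeff = calibrate_biomass_coeff(p, models,
                                        scenario=Scenario(0.96, "high"))
        assert coeff > 0
        assert p.biomass_coeff == coeff

    def test_failure_diagnostics_when_no_seed_production(self, models):
        p = LifecycleParams(emergence_fraction=0.0)
        with pytest.raises(CalibrationError):
            calibrate_biomass_coeff(p, models)
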