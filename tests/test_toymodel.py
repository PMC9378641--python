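"""Toy land carbon model: forcing generation, steady state, dynamics,
factorial scenarios and ensemble sampling."""

import numpy as np
import pytest

from landcarbon.containers import PoolFlags
from landcarbon.toymodel import (
    DEFAULT_PARAM_RANGES,
    RECYCLE_PERIOD,
    ForcingSet,
    PoolState,
    ToyModelParams,
    analytic_steady_state,
    generate_ensemble,
    generate_forcing,
    run_quartet,
    run_scenario,
    sample_params,
    step_toy_model,
)


class TestGenerateForcing:
    def test_same_seed_gives_identical_series(self):
        a = generate_forcing(range(1901, 1961), seed=7)
        b = generate_forcing(range(1901, 1961), seed=7)
        assert np.array_equal(a.t_anom, b.t_anom)
        assert np.array_equal(a.co2, b.co2)
        assert np.array_equal(a.f_ag, b.f_ag)

    def test_different_seed_changes_noise(self):
        a = generate_forcing(range(1901, 1961), seed=1)
        b = generate_forcing(range(1901, 1961), seed=2)
        assert not np.array_equal(a.t_anom, b.t_anom)

    def test_recycled_climate_repeats_first_twenty_years(self):
        f = generate_forcing(range(1901, 1961), seed=3)
        recycled = f.recycled_t_anom()
        np.testing.assert_array_equal(
            recycled[RECYCLE_PERIOD : 2 * RECYCLE_PERIOD], recycled[:RECYCLE_PERIOD]
        )
        np.testing.assert_array_equal(recycled[:RECYCLE_PERIOD], f.t_anom[:RECYCLE_PERIOD])

    def test_co2_rises_monotonically_from_reference(self):
        f = generate_forcing(range(1901, 2021), seed=0)
        assert f.co2[0] == pytest.approx(280.0)
        assert np.all(np.diff(f.co2) >= 0)

    def test_lulcc_spike_is_local(self):
        f = generate_forcing(
            range(1901, 2021),
            lulcc_spec={
                "anchors": {1901: 0.20, 2020: 0.20},
                "spike": (1960, 0.05),
            },
            seed=0,
        )
        i = np.flatnonzero(f.years == 1960)[0]
        assert f.f_ag[i] == pytest.approx(0.25)
        assert f.f_ag[i - 1] == pytest.approx(0.20)
        assert f.f_ag[i + 1] == pytest.approx(0.20)

    def test_non_consecutive_years_rejected(self):
        with pytest.raises(ValueError):
            generate_forcing(list(range(1901, 1931)) + list(range(1932, 1962)))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            generate_forcing(range(1901, 1961), climate_spec={"sigma": -0.1})


class TestSteadyState:
    def test_vegetation_is_input_times_turnover(self):
        params = ToyModelParams(npp0=10.0, tau_v_nat=20.0,
                                flags=PoolFlags(has_litter=False))
        state = analytic_steady_state(params, f_ag=0.0)
        assert state.cv == pytest.approx(200.0)

    def test_single_pool_soil(self):
        params = ToyModelParams(npp0=10.0, tau_s0=25.0,
                                flags=PoolFlags(has_litter=False))
        state = analytic_steady_state(params, f_ag=0.0)
        assert state.cs == pytest.approx(250.0)

    def test_litter_variant_solves_two_pool_balance(self):
        # oracle: at equilibrium litter input = npp0, litter loss = Clit/tau_lit,
        # soil input = eps * Clit/tau_lit, soil loss = Cs/tau_s0; solving the
        # two linear balance equations by hand gives Clit = npp0*tau_lit = 30
        # and Cs = eps*npp0*tau_s0 = 125.
        params = ToyModelParams(npp0=10.0, eps_lit=0.5, tau_lit=3.0, tau_s0=25.0)
        state = analytic_steady_state(params, f_ag=0.0)
        assert state.clit == pytest.approx(30.0)
        assert state.cs == pytest.approx(125.0)

    def test_stepping_from_steady_state_changes_nothing(self, default_params):
        state = analytic_steady_state(default_params, f_ag=0.15)
        new, fx = step_toy_model(state, default_params, 280.0, 0.0, 0.15)
        assert new.cv == pytest.approx(state.cv, rel=1e-13)
        assert new.clit == pytest.approx(state.clit, rel=1e-13)
        assert new.cs == pytest.approx(state.cs, rel=1e-13)
        assert fx["nbp"] == pytest.approx(0.0, abs=1e-10)

    def test_zero_turnover_rejected(self):
        with pytest.raises(ValueError):
            ToyModelParams(tau_v_nat=0.0)


class TestStepToyModel:
    def test_mass_balance_is_exact(self, default_params):
        state = PoolState(cv=300.0, clit=150.0, cs=900.0)
        new, fx = step_toy_model(state, default_params, 380.0, 0.7, 0.25, 0.01)
        d_total = (new.cv - state.cv) + (new.clit - state.clit) + (new.cs - state.cs)
        assert d_total == pytest.approx(fx["nbp"], abs=1e-10)

    def test_clearing_flux_partition(self):
        # E_lu is taken from the standing (start-of-year) biomass: half is
        # emitted directly, half enters the soil system with litterfall.
        params = ToyModelParams(lambda_lu=1.0, p_atm=0.5,
                                flags=PoolFlags(has_litter=False))
        state = PoolState(cv=200.0, clit=0.0, cs=500.0)
        _, fx = step_toy_model(state, params, 280.0, 0.0, 0.16, d_f_ag=0.01)
        assert fx["e_lu"] == pytest.approx(2.0)
        veg_out = fx["f_vs"] - 0.5 * fx["e_lu"]
        assert fx["f_vs"] - veg_out == pytest.approx(1.0)  # soil gains 1 via f_vs
        assert fx["nbp"] == pytest.approx(fx["npp"] - fx["rh"] - 1.0)

    def test_negative_pool_aborts_with_diagnostic(self):
        params = ToyModelParams(lambda_lu=500.0, flags=PoolFlags(has_litter=False))
        state = PoolState(cv=1.0, clit=0.0, cs=10.0)
        with pytest.raises(RuntimeError, match="negative"):
            step_toy_model(state, params, 280.0, 0.0, 0.5, d_f_ag=0.4)

    def test_diagnosed_turnover_matches_prescription(self, single_pool_params):
        # with backward-Euler decay the reported stock over the reported
        # outflux recovers tau exactly, even far from equilibrium
        state = PoolState(cv=100.0, clit=0.0, cs=400.0)
        new, fx = step_toy_model(state, single_pool_params, 350.0, 0.0, 0.0)
        tau_v_eff = single_pool_params.tau_v_eff(0.0)
        d_cv = new.cv - state.cv
        assert new.cv / (fx["npp"] - d_cv) == pytest.approx(tau_v_eff, rel=1e-12)
        assert new.cs / fx["rh"] == pytest.approx(single_pool_params.tau_s0, rel=1e-12)


class TestRunScenario:
    def test_s0_pools_constant_under_quiet_forcing(self, quiet_forcing, default_params):
        run = run_scenario(default_params, quiet_forcing, "S0", window=(1902, 2020))
        for var in ("cveg", "csoil", "clitter"):
            values = run.series(var).values
            drift = np.max(np.abs(values - values[0])) / values[0]
            assert drift < 1e-12

    def test_s1_fertilization_grows_vegetation(self, quiet_quartet):
        cveg = quiet_quartet["S1"].series("cveg").values
        assert cveg[-1] > cveg[0]

    def test_factorial_nesting_with_flat_axes(self, flat_forcing, default_params):
        # when every forcing axis is flat, all scenarios collapse onto S0
        q = run_quartet(default_params, flat_forcing, "flat", window=(1902, 2020))
        for label in ("S1", "S2", "S3"):
            for var in ("cveg", "csoil", "nbp"):
                np.testing.assert_allclose(
                    q[label].series(var).values,
                    q["S0"].series(var).values,
                    rtol=1e-12, atol=1e-12,
                )

    def test_s3_equals_s2_when_lulcc_flat(self, default_params):
        years = np.arange(1901, 2021)
        forcing = generate_forcing(
            years, lulcc_spec={"anchors": {1901: 0.15, 2020: 0.15}}, seed=5
        )
        q = run_quartet(default_params, forcing, "noLU")
        for var in ("cveg", "csoil", "nbp"):
            np.testing.assert_allclose(
                q["S3"].series(var).values, q["S2"].series(var).values,
                rtol=1e-12, atol=1e-12,
            )

    def test_window_outside_forcing_span_rejected(self, forcing, default_params):
        with pytest.raises(ValueError):
            run_scenario(default_params, forcing, "S3", window=(1850, 2020))

    def test_mass_conservation_every_year(self, default_quartet):
        for label in ("S0", "S1", "S2", "S3"):
            run = default_quartet[label]
            total = (
                run.series("cveg").values
                + run.series("csoil").values
                + run.series("clitter").values
            )
            nbp = run.series("nbp").values[1:]
            np.testing.assert_allclose(np.diff(total), nbp, rtol=1e-10, atol=1e-10)

    def test_regional_split_sums_to_global(self, forcing, default_params):
        run = run_scenario(
            default_params, forcing, "S3",
            region_weights={"north": 0.4, "south": 0.6},
        )
        for var in ("cveg", "csoil", "npp", "nbp"):
            np.testing.assert_allclose(
                run.series(var, "north").values + run.series(var, "south").values,
                run.series(var, "global").values,
                rtol=1e-12,
            )

    def test_steady_state_closure_160_years(self, default_params):
        # long noise-free control: pools preserved to 1e-9 relative
        forcing = generate_forcing(
            range(1901, 2081), climate_spec={"sigma": 0.0}, seed=0
        )
        run = run_scenario(default_params, forcing, "S0", window=(1902, 2080))
        for var in ("cveg", "csoil", "clitter"):
            values = run.series(var).values
            assert np.max(np.abs(values / values[0] - 1.0)) < 1e-9


class TestFalsePriming:
    def test_rising_inputs_lower_aggregate_soil_turnover(self, quiet_forcing):
        # pool-level rates constant (q10=1, no warming response), but rising
        # CO2 shifts soil-system mass toward the fast litter pool, lowering
        # the diagnosed aggregate turnover (Clit+Cs)/Rh
        params = ToyModelParams(gamma=0.0, q10=1.0, tau_lit=3.0, tau_s0=30.0)
        run = run_scenario(params, quiet_forcing, "S1")
        cs = run.series("csoil").values + run.series("clitter").values
        rh = run.series("rh").values
        tau = cs / rh
        assert tau[-1] < tau[1]


class TestGenerateEnsemble:
    def test_reproducible_and_in_range(self, forcing):
        a = generate_ensemble(6, forcing=forcing, seed=11)
        b = generate_ensemble(6, forcing=forcing, seed=11)
        assert len(a) == 6
        for qa, qb in zip(a, b):
            np.testing.assert_array_equal(
                qa["S3"].series("cveg").values, qb["S3"].series("cveg").values
            )

    def test_sampled_params_within_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = sample_params(rng)
            for name, (lo, hi) in DEFAULT_PARAM_RANGES.items():
                assert lo <= getattr(p, name) <= hi

    def test_degenerate_ranges_give_zero_spread(self, forcing):
        ranges = {k: (np.mean(v), np.mean(v)) for k, v in DEFAULT_PARAM_RANGES.items()}
        flags = {"has_litter": 1.0, "has_cwd": 0.0, "litter_in_soil": 0.0}
        ensemble = generate_ensemble(
            3, forcing=forcing, parameter_ranges=ranges,
            flag_probabilities=flags, seed=2,
        )
        finals = [q["S3"].series("cveg").values[-1] for q in ensemble]
        assert finals[0] == finals[1] == finals[2]
        assert np.std(finals) <= 1e-12 * abs(finals[0])

    def test_empty_range_rejected(self, forcing):
        with pytest.raises(ValueError):
            generate_ensemble(
                3, forcing=forcing, parameter_ranges={"beta": (0.7, 0.3)}, seed=0
            )

    def test_too_few_models_rejected(self, forcing):
        with pytest.raises(ValueError):
            generate_ensemble(1, forcing=forcing, seed=0)
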