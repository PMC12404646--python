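import numpy as np
import pandas as pd
import pytest

from endodiff.experiments import (
    DerivedOutputs,
    PlatingMap,
    ScenarioModifier,
    derived_outputs,
    design_sampling_period,
    durbin_watson,
    fit_plating_map,
    normalized_residuals,
    nrmse,
    plating_scan,
    rocki_scenario,
)
from endodiff.model_core import ModelSpec
from endodiff.simulate import Trajectory, integrate


class TestPlatingMap:
    def test_two_levels_interpolate_group_means(self):
        pairs = [(100.0, 50.0, 6.0), (100.0, 54.0, 8.0),
                 (300.0, 140.0, 20.0), (300.0, 150.0, 24.0)]
        m = fit_plating_map(pairs)
        assert m.beta1 * 100 + m.beta01 == pytest.approx(52.0)
        assert m.beta1 * 300 + m.beta01 == pytest.approx(145.0)
        assert m.beta2 * 100 + m.beta02 == pytest.approx(7.0)
        assert m.beta2 * 300 + m.beta02 == pytest.approx(22.0)

    def test_noisy_recovery_within_ols_error(self):
        rng = np.random.default_rng(0)
        beta1, beta01 = 0.45, 10.0
        n_p = rng.uniform(500, 3000, size=120)
        ns0 = beta1 * n_p + beta01 + rng.normal(0, 20.0, size=n_p.size)
        m = fit_plating_map(np.column_stack([n_p, ns0, 0.1 * ns0]))
        # standard OLS slope error ~ sigma / (sd(x) sqrt(n)) ~ 0.0026
        assert m.beta1 == pytest.approx(beta1, abs=0.01)
        assert m.beta01 == pytest.approx(beta01, abs=25.0)

    def test_collinear_points_fit_exactly(self):
        n_p = np.array([100.0, 200.0, 400.0])
        m = fit_plating_map(np.column_stack([n_p, 0.5 * n_p + 3, 0.04 * n_p]))
        pred = m.beta1 * n_p + m.beta01
        assert np.allclose(pred, 0.5 * n_p + 3, atol=1e-8)

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            fit_plating_map([(100.0, 50.0, 5.0), (100.0, 52.0, 6.0)])

    def test_negative_mapped_state_clipped_and_flagged(self):
        m = PlatingMap(beta1=0.5, beta01=-100.0, beta2=0.05, beta02=0.0)
        state = m.day0_state(10.0)
        assert state["ns"] == 0.0 and state["_clipped"]


class TestDerivedOutputs:
    def _traj(self, times, nd, ns=None, spec=None):
        spec = spec or ModelSpec.from_code("M1-gompertz-combined")
        ns = np.full_like(nd, 100.0) if ns is None else ns
        means = np.column_stack([ns, nd, np.zeros_like(nd)])
        return Trajectory(times=np.asarray(times, float), means=means,
                          spec=spec, theta={})

    def test_decreasing_de_peaks_at_start(self):
        t = np.linspace(0, 5, 501)
        out = derived_outputs(self._traj(t, 100 * np.exp(-t), ), n_p=50.0)
        assert out.tmax == 0.0
        assert out.ndmax == pytest.approx(100.0)
        assert out.yield_per_input_cell == pytest.approx(2.0)

    def test_pure_de_culture_has_ratio_one(self):
        t = np.linspace(0, 2, 201)
        nd = 50 + 10 * t
        out = derived_outputs(self._traj(t, nd, ns=np.zeros_like(nd)), n_p=10.0)
        assert out.de_ratio == 1.0

    def test_earliest_argmax_tie_break(self):
        t = np.linspace(0, 1, 101)
        nd = np.ones_like(t)
        out = derived_outputs(self._traj(t, nd), n_p=1.0)
        assert out.tmax == 0.0

    def test_undefined_ratio_rejected(self):
        t = np.linspace(0, 1, 11)
        z = np.zeros_like(t)
        with pytest.raises(ValueError, match="undefined"):
            derived_outputs(self._traj(t, z, ns=z), n_p=1.0)

    def test_peak_time_window_at_reference_parameters(self, ref_spec,
                                                      ref_theta):
        # DE peaks between 1.5 and 3 days for day-0 states with at most
        # 25% DE and total density within the range the study's plating
        # levels reach (below the carrying capacity; above it the
        # saturating growth laws stall differentiation and delay the peak)
        times = np.arange(0.0, 5.0001, 0.01)
        for total in (100.0, 300.0, 600.0):
            for frac in (0.0, 0.1, 0.25):
                ic = [total * (1 - frac), total * frac, 0.0]
                traj = integrate(ref_spec, ref_theta, ic, times)
                out = derived_outputs(traj, n_p=total)
                assert 1.5 <= out.tmax <= 3.0, (total, frac, out.tmax)


class TestPlatingScan:
    def test_monotone_outputs_under_positive_slope_map(self, ref_spec,
                                                       ref_theta, ref_xi):
        pmap = PlatingMap(beta1=0.225, beta01=0.0, beta2=0.025, beta02=0.0)
        grid = np.linspace(200_000, 1_200_000, 6)
        table = plating_scan(ref_spec, ref_theta, ref_xi, pmap, grid)
        assert (np.diff(table["ndmax"]) >= -1e-9).all()
        assert (np.diff(table["yield_per_input_cell"]) <= 1e-9).all()
        assert {"nd_day2", "nd_day3", "nd_day4"} <= set(table.columns)
        assert (table["nd_day2_sd"] > 0).all()

    def test_inert_system_yields_nothing(self, ref_xi):
        spec = ModelSpec.from_code("M1-exponential-additive")
        theta = {"beta_s": 0.0, "p_sd": 1.0, "delta_s": 0.0,
                 "beta_d": 0.0, "delta_d": 0.0}
        pmap = PlatingMap(beta1=1.0, beta01=0.0, beta2=0.0, beta02=0.0)
        table = plating_scan(spec, theta, {"a": 1.0}, pmap, [100_000.0])
        assert table["ndmax"].iloc[0] == 0.0
        assert table["yield_per_input_cell"].iloc[0] == 0.0

    def test_empty_grid_rejected(self, ref_spec, ref_theta, ref_xi):
        pmap = PlatingMap(0.5, 0.0, 0.05, 0.0)
        with pytest.raises(ValueError, match="empty"):
            plating_scan(ref_spec, ref_theta, ref_xi, pmap, [])


class TestRockiScenario:
    IC = {"ns": 533.0, "nd": 59.0, "nq": 0.0}

    def test_identity_modifier_reproduces_baseline(self, ref_spec, ref_theta,
                                                   ref_xi):
        base = integrate(ref_spec, ref_theta, self.IC,
                         np.arange(0.0, 5.001, 0.01), xi=ref_xi)
        same = rocki_scenario(ref_spec, ref_theta, ref_xi, self.IC,
                              ScenarioModifier(1.0, 1.0, 1.0))
        common = np.intersect1d(base.times, same.times)
        ib = np.searchsorted(base.times, common)
        is_ = np.searchsorted(same.times, common)
        rel = np.abs(base.means[ib] - same.means[is_]) / (1.0 + np.abs(base.means[ib]))
        assert rel.max() < 1e-7  # restart at tau only adds solver noise

    def test_halved_death_rates_raise_de_peak(self, ref_spec, ref_theta,
                                              ref_xi):
        base = rocki_scenario(ref_spec, ref_theta, ref_xi, self.IC,
                              ScenarioModifier(1.0, 1.0, 0.0))
        day1 = rocki_scenario(ref_spec, ref_theta, ref_xi, self.IC,
                              ScenarioModifier(0.5, 0.5, 1.0))
        full = rocki_scenario(ref_spec, ref_theta, ref_xi, self.IC,
                              ScenarioModifier(0.5, 0.5, 5.0))
        nd_b = derived_outputs(base, 100.0).ndmax
        nd_1 = derived_outputs(day1, 100.0).ndmax
        nd_f = derived_outputs(full, 100.0).ndmax
        assert nd_1 > nd_b
        assert nd_f >= nd_1

    def test_reduced_death_dominates_pointwise_without_crowding(self):
        # exponential growth gives a cooperative (quasimonotone) system, so
        # lowering death rates raises every live state pointwise.  Under
        # logistic/Gompertz crowding this is NOT a theorem: the larger early
        # populations feed back into lower per-capita growth and the
        # trajectories can cross later.
        spec = ModelSpec.from_code("M1-exponential-additive")
        rng = np.random.default_rng(8)
        for _ in range(10):
            theta = {"beta_s": rng.uniform(0.1, 1), "p_sd": rng.uniform(0.2, 0.9),
                     "delta_s": rng.uniform(0.1, 1), "beta_d": rng.uniform(0, 0.5),
                     "delta_d": rng.uniform(0.1, 1)}
            ic = {"ns": rng.uniform(100, 800), "nd": rng.uniform(0, 100),
                  "nq": 0.0}
            m = ScenarioModifier(rng.uniform(0, 1), rng.uniform(0, 1), 2.0)
            base = rocki_scenario(spec, theta, None, ic,
                                  ScenarioModifier(1.0, 1.0, 0.0),
                                  grid_step=0.05)
            mod = rocki_scenario(spec, theta, None, ic, m, grid_step=0.05)
            common = np.intersect1d(base.times, mod.times)
            ib = np.searchsorted(base.times, common)
            im = np.searchsorted(mod.times, common)
            live = slice(0, 2)
            assert np.all(mod.means[im, live] >= base.means[ib, live] - 1e-6)

    def test_invalid_modifiers_rejected(self, ref_spec, ref_theta, ref_xi):
        with pytest.raises(ValueError):
            ScenarioModifier(-0.5, 1.0, 1.0)
        with pytest.raises(ValueError, match="horizon"):
            rocki_scenario(ref_spec, ref_theta, ref_xi, self.IC,
                           ScenarioModifier(0.5, 0.5, 9.0), horizon=5.0)

    def test_bit_identical_reruns(self, ref_spec, ref_theta, ref_xi):
        a = rocki_scenario(ref_spec, ref_theta, ref_xi, self.IC,
                           ScenarioModifier(0.5, 0.5, 1.0))
        b = rocki_scenario(ref_spec, ref_theta, ref_xi, self.IC,
                           ScenarioModifier(0.5, 0.5, 1.0))
        assert np.array_equal(a.means, b.means)


class TestValidationMetrics:
    def _traj_and_data(self, offset=0.0):
        spec = ModelSpec.from_code("M1-gompertz-combined")
        t = np.arange(0.0, 4.0)
        means = np.column_stack([100 - 10 * t, 20 + 5 * t, 3 * t])
        traj = Trajectory(times=t, means=means, spec=spec, theta={})
        rows = [("r0", tt, s, means[i, j] + offset)
                for i, tt in enumerate(t) for j, s in enumerate(spec.states)]
        data = pd.DataFrame(rows, columns=["replicate_id", "time_d", "state",
                                           "value"])
        return traj, data

    def test_nrmse_zero_for_perfect_predictions(self):
        traj, data = self._traj_and_data()
        assert nrmse(traj, data) == 0.0

    def test_nrmse_constant_offset_closed_form(self):
        traj, data = self._traj_and_data(offset=7.0)
        rng = data["value"].max() - data["value"].min()
        assert nrmse(traj, data) == pytest.approx(7.0 / rng)

    def test_nrmse_matches_brute_force(self):
        rng_gen = np.random.default_rng(4)
        traj, data = self._traj_and_data()
        data = data.copy()
        data["value"] += rng_gen.normal(0, 5, size=len(data))
        data["value"] = data["value"].clip(lower=0)
        got = nrmse(traj, data)
        sq, vals = [], []
        for _, row in data.iterrows():
            i = list(traj.times).index(row["time_d"])
            j = traj.states.index(row["state"])
            sq.append((row["value"] - traj.means[i, j]) ** 2)
            vals.append(row["value"])
        expected = np.sqrt(np.mean(sq)) / (max(vals) - min(vals))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_nrmse_zero_range_rejected(self):
        traj, data = self._traj_and_data()
        data["value"] = 5.0
        with pytest.raises(ValueError, match="range"):
            nrmse(traj, data)

    def test_durbin_watson_closed_forms(self):
        assert durbin_watson([1.0, -1.0, 1.0, -1.0]) == pytest.approx(3.0)
        assert durbin_watson([2.0, 2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_durbin_watson_white_noise_near_two(self):
        e = np.random.default_rng(12).standard_normal(10_000)
        assert durbin_watson(e) == pytest.approx(2.0, abs=0.05)

    def test_durbin_watson_guards(self):
        with pytest.raises(ValueError):
            durbin_watson([1.0, 2.0])
        with pytest.raises(ValueError, match="zero"):
            durbin_watson([0.0, 0.0, 0.0])

    def test_normalized_residuals_ordering_and_scale(self, ref_spec, ref_theta,
                                                     ref_xi, study):
        data, truth = study
        resid = normalized_residuals(ref_spec, ref_theta, ref_xi, data,
                                     truth["day0_states"])
        n_expected = len(data[data["time_d"] > 0])
        assert resid.size == n_expected
        # generating parameters: residuals roughly standard normal
        assert abs(np.std(resid) - 1.0) < 0.35


class TestDesignSamplingPeriod:
    def test_noise_free_recovery_below_tolerance(self, ref_spec, ref_theta):
        n0 = {"rA": {"ns": 533.0, "nd": 59.0, "nq": 0.0},
              "rB": {"ns": 355.0, "nd": 39.0, "nq": 0.0}}
        table = design_sampling_period(
            ref_spec, ref_theta, n0, periods_h=(24,), eps_level=0.0,
            seed=0, n_starts=16, budget=8000,
        )
        assert table["converged"].all()
        assert (table["error"] < 1e-3).all()

    def test_single_time_point_period_flagged(self, ref_spec, ref_theta):
        n0 = {"rA": {"ns": 533.0, "nd": 59.0, "nq": 0.0}}
        table = design_sampling_period(
            ref_spec, ref_theta, n0, periods_h=(120,), eps_level=0.1,
            seed=0, n_starts=2, budget=200,
        )
        assert not table["converged"].iloc[0]
        assert np.isnan(table["error"].iloc[0])
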