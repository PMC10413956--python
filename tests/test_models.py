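"""Mixed-effects step-length model and observer-effect trend."""

import numpy as np
import pytest

from foragepath.data import Dataset
from foragepath.models import (
    StepRecord,
    build_step_records,
    fit_step_length_lmm,
    observer_effect_trend,
)

from conftest import make_observation


def simulate_records(rng, n_individuals=30, n_per=10, beta_svl=0.0,
                     sigma_ind=0.0, sigma_res=0.5, intercept=2.0):
    """Records from a known random-intercept model (positive responses)."""
    records = []
    for i in range(n_individuals):
        svl = float(rng.normal(100.0, 10.0))
        sex = "M" if rng.random() < 0.5 else "F"
        b = float(rng.normal(0.0, sigma_ind))
        for j in range(n_per):
            temp = float(rng.normal(24.0, 2.0))
            wind = float(rng.normal(2.0, 0.5))
            y = intercept + beta_svl * svl + b + float(rng.normal(0.0, sigma_res))
            records.append(StepRecord(
                lizard_id=f"liz{i:03d}", step_length=y, t=j % 31,
                sex=sex, svl_mm=svl, air_temp_c=temp, wind_speed_ms=wind))
    return records


class TestBuildStepRecords:
    def test_one_record_per_moving_interval(self):
        coords = [(0, 0), (1, 0), (1, 0), (2, 0), (3, 0)]
        obs = make_observation(coords, temp=[20.0] * 5, wind=[1.0] * 5)
        ds = Dataset(observations=[obs])
        recs = build_step_records(ds, "visual")
        assert len(recs) == 3  # 4 intervals, 1 pause
        assert [r.t for r in recs] == [1, 3, 4]

    def test_absent_covariate_drops_record(self):
        coords = [(0, 0), (1, 0), (2, 0)]
        obs = make_observation(coords, temp=[20.0, 20.0, None], wind=[1.0] * 3)
        ds = Dataset(observations=[obs])
        recs = build_step_records(ds, "visual")
        assert len(recs) == 1  # the step landing on the missing-temp minute drops

    def test_count_matches_filter_oracle(self, rng):
        from conftest import random_walk_observation
        observations = []
        for k in range(10):
            o = random_walk_observation(rng, obs_id=f"o{k}")
            for fx in o.fixes:
                fx.air_temp_c, fx.wind_speed_ms = 22.0, 1.0
            observations.append(o)
        ds = Dataset(observations=observations)
        recs = build_step_records(ds, "visual")
        oracle = sum(
            1
            for o in observations
            for a, b in zip(o.fixes[:-1], o.fixes[1:])
            if (a.x, a.y) != (b.x, b.y)
        )
        assert len(recs) == oracle

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            build_step_records(Dataset(), "visual")


class TestMixedModel:
    def test_zero_variance_ratio_reproduces_ols(self, rng):
        records = simulate_records(rng, sigma_ind=0.4)
        res = fit_step_length_lmm(records, var_ratio=0.0)
        X = np.column_stack([
            np.ones(len(records)),
            [1.0 if r.sex == "M" else 0.0 for r in records],
            [r.svl_mm for r in records],
            [r.air_temp_c for r in records],
            [r.wind_speed_ms for r in records],
        ])
        y = np.array([r.step_length for r in records])
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        est = [res.fixed_effects[k].estimate
               for k in ("intercept", "sex[M]", "svl_mm", "air_temp_c", "wind_speed_ms")]
        assert np.allclose(est, beta_ols, rtol=1e-6, atol=1e-8)

    def test_matches_statsmodels_reml(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        records = simulate_records(rng, n_individuals=25, n_per=8,
                                   beta_svl=0.02, sigma_ind=0.4)
        res = fit_step_length_lmm(records)
        y = np.array([r.step_length for r in records])
        X = np.column_stack([
            np.ones(len(records)),
            [1.0 if r.sex == "M" else 0.0 for r in records],
            [r.svl_mm for r in records],
            [r.air_temp_c for r in records],
            [r.wind_speed_ms for r in records],
        ])
        groups = [r.lizard_id for r in records]
        fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        est = [res.fixed_effects[k].estimate
               for k in ("intercept", "sex[M]", "svl_mm", "air_temp_c", "wind_speed_ms")]
        assert np.allclose(est, fit.fe_params, rtol=1e-4, atol=1e-6)
        assert res.variance_residual == pytest.approx(fit.scale, rel=1e-3)
        assert res.variance_individual == pytest.approx(
            float(np.asarray(fit.cov_re)[0, 0]), rel=1e-2, abs=1e-4)

    def test_objective_trace_non_increasing(self, rng):
        records = simulate_records(rng, sigma_ind=0.3)
        res = fit_step_length_lmm(records)
        trace = res.objective_trace
        assert all(a >= b - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_invariant_to_record_order_and_relabeling(self, rng):
        records = simulate_records(rng, n_individuals=15, n_per=6, sigma_ind=0.3)
        res0 = fit_step_length_lmm(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        relabeled = [
            StepRecord(lizard_id="ID_" + r.lizard_id[::-1], step_length=r.step_length,
                       t=r.t, sex=r.sex, svl_mm=r.svl_mm, air_temp_c=r.air_temp_c,
                       wind_speed_ms=r.wind_speed_ms)
            for r in shuffled
        ]
        res1 = fit_step_length_lmm(relabeled)
        for k in res0.fixed_effects:
            assert res1.fixed_effects[k].estimate == pytest.approx(
                res0.fixed_effects[k].estimate, rel=1e-9, abs=1e-12)
        assert res1.var_ratio == pytest.approx(res0.var_ratio, rel=1e-5, abs=1e-9)

    def test_single_individual_rejected(self, rng):
        records = simulate_records(rng, n_individuals=1, n_per=20)
        with pytest.raises(ValueError):
            fit_step_length_lmm(records)

    def test_null_data_flags_singular_fit_mostly(self):
        # no true individual variance: the variance ratio should collapse
        # (design large enough that the REML boundary estimate dominates)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            records = simulate_records(rng, n_individuals=30, n_per=20)
            res = fit_step_length_lmm(records)
            if res.variance_individual < 0.05 * res.variance_residual:
                hits += 1
        assert hits >= 18

    def test_svl_slope_recovery_quick(self):
        # 20-seed version of the full recovery check in the acceptance suite
        ok_est = ok_p = 0
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            records = simulate_records(rng, n_individuals=50, n_per=20,
                                       beta_svl=0.05, sigma_ind=0.3)
            res = fit_step_length_lmm(records)
            fe = res.fixed_effects["svl_mm"]
            if abs(fe.estimate - 0.05) <= 0.25 * 0.05:
                ok_est += 1
            if fe.p < 0.05:
                ok_p += 1
        assert ok_est >= 18 and ok_p == 20

    def test_log_transform_response(self, rng):
        records = simulate_records(rng, intercept=1.0, sigma_ind=0.2)
        res = fit_step_length_lmm(
            [r for r in records if r.step_length > 0], response_transform="log")
        assert res.response_transform == "log"


class TestObserverEffect:
    def _trend_dataset(self, slope=0.0, n_obs=5, rng=None):
        observations = []
        for k in range(n_obs):
            coords = [(0.0, float(k) * 100.0)]
            for t in range(1, 31):
                # step length at destination minute t is slope * t + 1
                noise = 0.0 if rng is None else float(rng.normal(0, 0.01))
                coords.append((coords[-1][0] + slope * t + 1.0 + noise,
                               coords[-1][1]))
            observations.append(make_observation(
                coords, obs_id=f"o{k}", lizard_id=f"l{k}"))
        return Dataset(observations=observations)

    def test_exact_linear_trend_detected(self):
        ds = self._trend_dataset(slope=0.1)
        res = observer_effect_trend(ds, "visual", "step_length")
        assert res.p < 1e-6
        assert res.slope == pytest.approx(0.1, rel=1e-9)

    def test_zero_variance_response_degenerates(self):
        ds = self._trend_dataset(slope=0.0)
        res = observer_effect_trend(ds, "visual", "step_length")
        assert res.F == 0.0 and res.p == 1.0

    def test_residual_df_is_n_minus_2(self, rng):
        from conftest import random_walk_observation
        observations = [random_walk_observation(rng, obs_id=f"o{k}")
                        for k in range(6)]
        ds = Dataset(observations=observations)
        res = observer_effect_trend(ds, "visual", "step_length")
        n_moving = sum(
            1
            for o in observations
            for a, b in zip(o.fixes[:-1], o.fixes[1:])
            if (a.x, a.y) != (b.x, b.y)
        )
        assert res.df == (1, n_moving - 2) and res.n == n_moving

    def test_turn_angle_response_runs(self, rng):
        from conftest import random_walk_observation
        ds = Dataset(observations=[random_walk_observation(rng, obs_id=f"o{k}")
                                   for k in range(6)])
        res = observer_effect_trend(ds, "visual", "turn_angle_abs")
        assert res.df[0] == 1 and 0.0 <= res.p <= 1.0

    def test_null_slope_coverage(self):
        # response independent of time: p < 0.05 should be rare
        rejections = 0
        for seed in range(40):
            rng = np.random.default_rng(500 + seed)
            ds = self._trend_dataset(slope=0.0, rng=rng)
            if observer_effect_trend(ds, "visual", "step_length").p < 0.05:
                rejections += 1
        assert rejections <= 6
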