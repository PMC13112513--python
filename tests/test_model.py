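import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats

from ecsbmr import (
    FitError,
    FitOptions,
    ModelParams,
    SyntheticConfig,
    bmd_at_bmr,
    fit_combined,
    fit_single,
    generate_database,
    log_likelihood,
    model_mean,
    profile_ci,
)

from conftest import make_dataset

PARAMS = ModelParams(a=10.0, b=50.0, c=5.0, d=1.0)

params_strategy = st.builds(
    ModelParams,
    a=st.floats(0.1, 100),
    b=st.floats(1.0, 500),
    c=st.floats(1.2, 200),
    d=st.floats(0.3, 6.0),
)


class TestModelMean:
    def test_background_at_zero(self):
        assert model_mean(PARAMS, 0.0) == pytest.approx(10.0, abs=0)

    def test_asymptote_is_a_times_c(self):
        assert model_mean(PARAMS, 1e9) == pytest.approx(50.0, rel=1e-12)

    def test_hand_evaluated_point(self):
        # 10 * (5 - 4*exp(-1))
        assert model_mean(PARAMS, 50.0) == pytest.approx(35.28482235, rel=1e-9)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            model_mean(PARAMS, -1.0)

    @given(params=params_strategy)
    def test_nondecreasing_in_dose(self, params):
        grid = np.linspace(0, 10 * params.b, 200)
        means = model_mean(params, grid)
        assert np.all(np.diff(means) >= -1e-9 * means[:-1])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(a=1, b=1, c=0.9, d=1)
        with pytest.raises(ValueError):
            ModelParams(a=-1, b=1, c=2, d=1)


class TestLogLikelihood:
    def test_zero_residual_convention(self):
        # responses exactly on the curve, var=1: each obs contributes -ln(2*pi)/2
        doses = {0.0: None, 20.0: None, 80.0: None}
        groups = {d: [model_mean(PARAMS, d)] * 2 for d in doses}
        ds = make_dataset(groups)
        assert log_likelihood(PARAMS, ds, var=1.0) == pytest.approx(
            -6 * 0.5 * math.log(2 * math.pi), rel=1e-12
        )

    def test_additivity_of_identical_observations(self):
        single = make_dataset({0.0: [9.0], 50.0: [30.0]})
        double = make_dataset({0.0: [9.0, 9.0], 50.0: [30.0, 30.0]})
        assert log_likelihood(PARAMS, double, 0.3) == pytest.approx(
            2 * log_likelihood(PARAMS, single, 0.3), rel=1e-12
        )

    def test_matches_per_point_normal_density(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            doses = np.sort(rng.uniform(1, 100, 3))
            groups = {0.0: rng.lognormal(1, 0.3, 3)}
            for d in doses:
                groups[float(d)] = rng.lognormal(1.5, 0.3, 2)
            ds = make_dataset(groups)
            var = rng.uniform(0.05, 1.0)
            dose, resp = ds.observations()
            expected = sum(
                stats.norm.logpdf(
                    math.log(y), math.log(model_mean(PARAMS, x)), math.sqrt(var)
                )
                for x, y in zip(dose, resp)
            )
            assert log_likelihood(PARAMS, ds, var) == pytest.approx(expected, rel=1e-10)

    def test_rejects_nonpositive_var(self):
        ds = make_dataset({0.0: [1.0], 10.0: [2.0]})
        with pytest.raises(ValueError):
            log_likelihood(PARAMS, ds, 0.0)


def _noise_free_dataset(params, doses=(0.0, 10.0, 25.0, 60.0, 150.0), n=4):
    return make_dataset({d: [model_mean(params, d)] * n for d in doses})


class TestFitting:
    def test_noise_free_recovery(self):
        truth = ModelParams(a=2.0, b=40.0, c=8.0, d=1.3)
        fit = fit_single(_noise_free_dataset(truth), FitOptions(profile_c=False))
        a, b = fit.per_dataset["ds1"]
        assert a == pytest.approx(truth.a, rel=1e-4)
        assert b == pytest.approx(truth.b, rel=1e-4)
        assert fit.c == pytest.approx(truth.c, rel=1e-4)
        assert fit.d == pytest.approx(truth.d, rel=1e-4)
        assert fit.var_mle < 1e-10

    def test_concentrated_var_identity(self, small_synth_db):
        fit = fit_combined(small_synth_db.datasets, FitOptions(n_starts=3, profile_c=False))
        sse = 0.0
        for ds in small_synth_db:
            p = fit.params_for(ds.dataset_id)
            dose, resp = ds.observations()
            sse += np.sum((np.log(resp) - np.log(model_mean(p, dose))) ** 2)
        assert fit.var_mle == pytest.approx(sse / fit.n_obs, rel=1e-10)

    def test_scale_equivariance(self, small_synth_db):
        from ecsbmr import Dataset, DoseGroup

        opts = FitOptions(n_starts=2, profile_c=False)
        base = fit_combined(small_synth_db.datasets, opts)
        k = 7.3
        scaled = [
            Dataset(
                dataset_id=ds.dataset_id,
                technology=ds.technology,
                chemical=ds.chemical,
                covariates=ds.covariates,
                groups=[DoseGroup(g.dose, k * g.responses) for g in ds.groups],
            )
            for ds in small_synth_db
        ]
        fit = fit_combined(scaled, opts)
        # the objective is exactly invariant; 1e-3 absorbs optimizer
        # termination noise on the reparameterized surface
        assert fit.c == pytest.approx(base.c, rel=1e-3)
        assert fit.d == pytest.approx(base.d, rel=1e-3)
        assert fit.var_mle == pytest.approx(base.var_mle, rel=1e-6)
        for ds_id, (a, b) in base.per_dataset.items():
            a2, b2 = fit.per_dataset[ds_id]
            assert a2 == pytest.approx(k * a, rel=1e-3)
            assert b2 == pytest.approx(b, rel=1e-2)

    def test_dose_unit_equivariance(self, small_synth_db):
        from ecsbmr import Dataset, DoseGroup

        opts = FitOptions(n_starts=2, profile_c=False)
        base = fit_combined(small_synth_db.datasets, opts)
        k = 3.0
        scaled = [
            Dataset(
                dataset_id=ds.dataset_id,
                technology=ds.technology,
                chemical=ds.chemical,
                covariates=ds.covariates,
                groups=[DoseGroup(k * g.dose, g.responses) for g in ds.groups],
            )
            for ds in small_synth_db
        ]
        fit = fit_combined(scaled, opts)
        assert fit.c == pytest.approx(base.c, rel=1e-6)
        for ds_id, (_, b) in base.per_dataset.items():
            assert fit.per_dataset[ds_id][1] == pytest.approx(k * b, rel=1e-6)

    def test_combined_single_equals_fit_single(self, small_synth_db):
        ds = small_synth_db.datasets[0]
        opts = FitOptions(n_starts=3, profile_c=False)
        single = fit_single(ds, opts)
        combined = fit_combined([ds], opts)
        assert combined.loglik == pytest.approx(single.loglik, abs=1e-6)
        assert combined.c == pytest.approx(single.c, rel=1e-6)

    def test_replication_symmetry(self, small_synth_db):
        from ecsbmr import Dataset

        ds = small_synth_db.datasets[1]
        copy = Dataset(
            dataset_id="copy",
            technology=ds.technology,
            chemical=ds.chemical,
            covariates=dict(ds.covariates),
            groups=ds.groups,
        )
        opts = FitOptions(n_starts=3, profile_c=False)
        one = fit_single(ds, opts)
        two = fit_combined([ds, copy], opts)
        assert two.c == pytest.approx(one.c, rel=1e-4)
        assert two.d == pytest.approx(one.d, rel=1e-4)
        assert two.var_mle == pytest.approx(one.var_mle, rel=1e-6)
        a1, b1 = two.per_dataset[ds.dataset_id]
        a2, b2 = two.per_dataset["copy"]
        assert a1 == pytest.approx(a2, rel=1e-6)
        assert b1 == pytest.approx(b2, rel=1e-6)

    def test_flat_data_drives_c_to_boundary(self):
        rng = np.random.default_rng(4)
        groups = {d: rng.lognormal(0.5, 0.2, 5) for d in (0.0, 10.0, 40.0, 160.0)}
        fit = fit_single(make_dataset(groups), FitOptions(n_starts=4, profile_c=False))
        assert fit.c < 1.5

    def test_two_dose_levels_fixes_d(self):
        ds = make_dataset({0.0: [1.0, 1.1, 0.9], 50.0: [3.0, 3.3, 2.8]})
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = fit_single(ds, FitOptions(profile_c=False))
        assert fit.d_fixed
        assert fit.d == 1.0

    def test_determinism_under_fixed_seed(self, small_synth_db):
        opts = FitOptions(n_starts=4, seed=11, profile_c=False)
        f1 = fit_combined(small_synth_db.datasets, opts)
        f2 = fit_combined(small_synth_db.datasets, opts)
        assert f1.c == f2.c and f1.var == f2.var and f1.loglik == f2.loglik


class TestProfileCI:
    def test_var_ci_contains_estimate(self, small_synth_db):
        fit = fit_combined(small_synth_db.datasets, FitOptions(n_starts=2, profile_c=False))
        lo, hi = fit.ci90_var
        assert lo < fit.var < hi

    def test_degenerate_level_zero(self, small_synth_db):
        fit = fit_combined(small_synth_db.datasets, FitOptions(n_starts=2, profile_c=False))
        lo, hi = profile_ci(fit, small_synth_db.datasets, "var", level=0.0)
        assert lo == hi == fit.var

    def test_var_profile_matches_wald_width(self):
        # well-identified case: profile and Wald intervals nearly agree
        cfg = SyntheticConfig(n_datasets=20, var_true=0.06, covariate_design={}, seed=8)
        db = generate_database(cfg)
        fit = fit_combined(db.datasets, FitOptions(n_starts=2, profile_c=False))
        lo, hi = fit.ci90_var
        nu = fit.n_obs - fit.n_params
        z = stats.norm.ppf(0.95)
        wald_width = 2 * z * math.sqrt(2.0 / nu) * fit.var
        assert (hi - lo) == pytest.approx(wald_width, rel=0.10)

    def test_no_plateau_c_unbounded_above(self):
        cfg = SyntheticConfig(
            n_datasets=3, var_true=0.057, shared_c=3490.0, shared_d=1.0,
            b_rel_range=(20.0, 40.0), covariate_design={}, seed=3,
        )
        db = generate_database(cfg)
        fit = fit_combined(db.datasets, FitOptions(n_starts=4))
        assert math.isinf(fit.ci90_c[1])
        assert fit.ci90_c[0] > 1.0

    def test_plateau_c_bounded(self, small_synth_db):
        fit = fit_combined(small_synth_db.datasets, FitOptions(n_starts=2))
        lo, hi = fit.ci90_c
        assert lo < fit.c < hi
        assert math.isfinite(hi)

    def test_requires_converged_fit(self, small_synth_db):
        fit = fit_combined(small_synth_db.datasets, FitOptions(n_starts=2, profile_c=False))
        fit.converged = False
        with pytest.raises(FitError):
            profile_ci(fit, small_synth_db.datasets, "var")


class TestBMD:
    def test_closed_form_hand_value(self):
        res = bmd_at_bmr(PARAMS, 0.5)
        assert res.bmd == pytest.approx(-50 * math.log(0.875), rel=1e-12)

    def test_closed_form_agrees_with_bisection(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = ModelParams(
                a=rng.uniform(0.2, 50),
                b=rng.uniform(1, 300),
                c=rng.uniform(1.3, 100),
                d=rng.uniform(0.3, 5),
            )
            bmr = rng.uniform(0.01, 0.9) * (p.c - 1)
            bmd = bmd_at_bmr(p, bmr).bmd
            target = p.a * (1 + bmr)
            root = optimize.brentq(
                lambda x: model_mean(p, x) - target, 0, 1e6 * p.b, rtol=1e-14
            )
            assert bmd == pytest.approx(root, rel=1e-8)

    def test_bmd_invariant_to_background(self):
        p2 = ModelParams(a=123.0, b=PARAMS.b, c=PARAMS.c, d=PARAMS.d)
        assert bmd_at_bmr(p2, 0.5).bmd == bmd_at_bmr(PARAMS, 0.5).bmd

    def test_small_bmr_limit(self):
        assert bmd_at_bmr(PARAMS, 1e-9).bmd < 1e-6 * PARAMS.b

    def test_bmr_beyond_max_effect_rejected(self):
        with pytest.raises(ValueError, match="attainable"):
            bmd_at_bmr(PARAMS, 4.0)

    def test_profile_interval_brackets_estimate(self, small_synth_db):
        ds = small_synth_db.datasets[2]
        fit = fit_single(ds, FitOptions(n_starts=3, profile_c=False))
        res = bmd_at_bmr(fit, 0.277, data=ds, dataset_id=ds.dataset_id)
        assert 0 < res.bmdl <= res.bmd <= res.bmdu


class TestSharedDToggle:
    def test_per_dataset_d_fit_runs(self, small_synth_db):
        datasets = small_synth_db.datasets[:4]
        fit = fit_combined(datasets, FitOptions(share_d=False, profile_c=False))
        assert fit.d is None
        assert set(fit.per_dataset_d) == {ds.dataset_id for ds in datasets}
        assert all(0.25 <= d <= 8.0 for d in fit.per_dataset_d.values())
        assert fit.var > 0
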