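"""CWRES, bootstrap, NPDE, VPC and external-validation behaviour."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neopkpd import (
    CohortSpec,
    PopModel,
    bootstrap,
    cwres,
    external_validate,
    final_model,
    generate_cohort,
    generate_dataset,
    npde,
    prediction_error_summary,
    vpc,
)


class TestCWRES:
    def test_calibrated_under_true_model(self, sparse_study, model):
        """Data simulated from the model: CWRES near mean 0, variance 1."""
        table = cwres(sparse_study, model)
        vals = table["cwres"].dropna()
        assert abs(vals.mean()) < 0.15
        assert 0.7 <= vals.var() <= 1.3

    def test_residual_scale_equivariance(self, model):
        """Doubling sigma in a sigma-dominated model halves each CWRES."""
        quiet = PopModel(1.63, 0.503, 0.209, 2.14,
                         omega=np.diag([1e-12, 1e-12]), sigma_prop=0.288)
        loud = PopModel(1.63, 0.503, 0.209, 2.14,
                        omega=np.diag([1e-12, 1e-12]), sigma_prop=0.576)
        cohort = generate_cohort(CohortSpec(n_subjects=15, seed=81))
        ds = generate_dataset(cohort, quiet, seed=82)
        c1 = cwres(ds, quiet)["cwres"]
        c2 = cwres(ds, loud)["cwres"]
        np.testing.assert_allclose(c2, c1 / 2.0, rtol=1e-6)

    def test_zero_at_conditional_mean(self, model):
        """An observation equal to its conditional mean has CWRES 0 when
        random effects are pinned (eta_hat = 0, IPRED = PRED)."""
        pinned = PopModel(1.63, 0.503, 0.209, 2.14,
                          omega=np.diag([1e-12, 1e-12]), sigma_prop=0.288)
        cohort = generate_cohort(CohortSpec(n_subjects=4, seed=83))
        noise_free = PopModel(1.63, 0.503, 0.209, 2.14,
                              omega=np.zeros((2, 2)), sigma_prop=0.0)
        ds = generate_dataset(cohort, noise_free, seed=84)
        table = cwres(ds, pinned)
        np.testing.assert_allclose(table["cwres"], 0.0, atol=1e-6)


class TestBootstrap:
    def test_degenerate_resampling_returns_point_estimate(self, model, monkeypatch):
        """Every resample identical to the original: medians collapse onto
        the point estimates."""
        cohort = generate_cohort(CohortSpec(n_subjects=25, seed=91))
        ds = generate_dataset(cohort, model, seed=92)

        class IdentityRng:
            def integers(self, lo, hi, size):
                return np.arange(size)

        monkeypatch.setattr(
            "neopkpd.diagnostics.np.random.default_rng", lambda s: IdentityRng()
        )
        res = bootstrap(ds, n_resamples=3, seed=0, init=model)
        np.testing.assert_allclose(
            res.summary["median"], res.summary["estimate"], rtol=1e-3
        )

    def test_percentiles_ordered(self, model):
        cohort = generate_cohort(CohortSpec(n_subjects=25, seed=93))
        ds = generate_dataset(cohort, model, seed=94)
        res = bootstrap(ds, n_resamples=8, seed=5, init=model, maxfev=600)
        assert (res.summary["p5"] <= res.summary["median"]).all()
        assert (res.summary["median"] <= res.summary["p95"]).all()
        assert res.n_converged <= 8


class TestNPDE:
    def test_degenerate_simulation_gives_zero(self, model):
        """sigma = omega = 0 and the exact model: every simulated value
        ties the observation, the mid-rank sits at 1/2, NPDE = 0."""
        exact = PopModel(1.63, 0.503, 0.209, 2.14,
                         omega=np.zeros((2, 2)), sigma_prop=0.0)
        cohort = generate_cohort(CohortSpec(n_subjects=6, seed=95))
        ds = generate_dataset(cohort, exact, seed=96)
        res = npde(ds, exact, n_sim=50, seed=97)
        np.testing.assert_allclose(res.npde, 0.0, atol=1e-9)

    def test_calibrated_under_true_model(self, sparse_study, model):
        res = npde(sparse_study, model, n_sim=500, seed=98)
        assert abs(res.mean) < 0.3
        assert 0.6 <= res.variance <= 1.4
        assert res.ks_pvalue > 0.01

    def test_doubled_clearance_shifts_npde(self, sparse_study, model):
        """A model with doubled typical CL underpredicts concentrations;
        observations rank high among simulations, so NPDE mean > 0."""
        wrong = PopModel(1.63, 2 * 0.503, 0.209, 2.14,
                         omega=model.omega, sigma_prop=model.sigma_prop)
        res = npde(sparse_study, wrong, n_sim=300, seed=99)
        assert res.mean > 0.5
        assert res.ks_pvalue < 0.01


class TestVPC:
    def test_self_consistency_coverage(self, sparse_study, model):
        res = vpc(sparse_study, model, n_sim=300, bins=4, seed=101)
        assert res.coverage["p50"] >= 0.75

    def test_single_replicate_degenerates_to_point_ci(self, sparse_study, model):
        res = vpc(sparse_study, model, n_sim=1, bins=3, seed=102)
        for p in ("5", "50", "95"):
            np.testing.assert_allclose(
                res.table[f"sim_p{p}_lo"], res.table[f"sim_p{p}_hi"]
            )


class TestPredictionError:
    def test_perfect_predictions(self):
        res = prediction_error_summary(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]), ["a", "a", "b"]
        )
        assert res.mpe_percent == 0.0
        assert res.mape_percent == 0.0
        assert res.pct_subjects_within_20 == 100.0

    def test_signed_errors_cancel_absolute_do_not(self):
        obs = np.array([10.0, 10.0])
        ipred = np.array([12.0, 8.0])  # +20% and -20%
        res = prediction_error_summary(ipred, obs, ["a", "b"])
        assert res.mpe_percent == pytest.approx(0.0, abs=1e-12)
        assert res.mape_percent == pytest.approx(20.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        errors=st.lists(st.floats(-0.9, 3.0), min_size=1, max_size=20),
    )
    def test_mape_dominates_absolute_mpe(self, errors):
        obs = np.full(len(errors), 10.0)
        ipred = obs * (1.0 + np.array(errors))
        res = prediction_error_summary(ipred, obs, [f"s{i}" for i in range(len(errors))])
        assert res.mape_percent >= abs(res.mpe_percent) - 1e-9
        assert res.pct_subjects_within_20 <= res.pct_subjects_within_30

    def test_external_cohort_mape_near_residual_scale(self, model):
        """Scoring a preterm-shifted external cohort against its generating
        model gives MAPE on the order of the residual error (~25-35%)."""
        spec = CohortSpec(n_subjects=16, seed=111)
        cohort = generate_cohort(spec)
        ds = generate_dataset(cohort, model, seed=112)
        res = external_validate(model, ds)
        assert 10.0 <= res.mape_percent <= 45.0
        assert res.pct_subjects_within_20 <= res.pct_subjects_within_30
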