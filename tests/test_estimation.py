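"""FOCE-I objective, fitting, empirical Bayes, and covariate selection."""
import numpy as np
import pytest

from neopkpd import (
    CohortSpec,
    PopModel,
    SamplingScheme,
    StudyDataset,
    empirical_bayes,
    final_model,
    fit,
    foce_objective,
    generate_cohort,
    generate_dataset,
    stepwise_covariates,
)
from neopkpd.estimation import StructuralSpec, _Workspace

from oracles import agh_minus2ll_single_eta


@pytest.fixture(scope="module")
def medium_study(model):
    """40 subjects x 6 samples: informative but quick to fit."""
    cohort = generate_cohort(CohortSpec(n_subjects=40, seed=31))
    return generate_dataset(cohort, model, SamplingScheme.rich(6), seed=32)


class TestObjective:
    def test_subject_order_invariance(self, sparse_study, model):
        ofv = foce_objective(sparse_study, model)
        rev = StudyDataset(subjects=list(reversed(sparse_study.subjects)))
        assert foce_objective(rev, model) == pytest.approx(ofv, abs=1e-9)

    def test_matches_quadrature_oracle_single_eta(self):
        """FOCE-I tracks the adaptive Gauss-Hermite marginal -2LL."""
        m = PopModel(1.63, 0.503, 0.209, 2.14,
                     omega=np.diag([0.508**2, 1e-12]), sigma_prop=0.12)
        cohort = generate_cohort(CohortSpec(n_subjects=3, seed=9))
        ds = generate_dataset(cohort, m, SamplingScheme.rich(6), seed=10)
        assert foce_objective(ds, m) == pytest.approx(
            agh_minus2ll_single_eta(ds, m), abs=0.5
        )

    def test_vanishing_iiv_reduces_to_pooled_objective(self, sparse_study):
        """omega -> 0: the FOCE-I objective approaches naive pooled
        proportional-error extended least squares at eta = 0."""
        m = PopModel(1.63, 0.503, 0.209, 2.14,
                     omega=np.diag([1e-12, 1e-12]), sigma_prop=0.288)
        ws = _Workspace(sparse_study, StructuralSpec.final())
        cl, v = ws.typical(
            {"theta_v": 1.63, "theta_cl": 0.503, "beta_pna_cl": 0.209,
             "beta_ga_cl": 2.14}
        )
        f = ws.predict(cl, v)[0]
        w = (0.288 * f) ** 2
        pooled = float(np.sum((ws.y - f) ** 2 / w + np.log(2 * np.pi * w)))
        assert foce_objective(sparse_study, m) == pytest.approx(pooled, rel=1e-6)


class TestFit:
    def test_noise_free_data_identify_thetas_exactly(self):
        """sigma = 0, omega = 0: fixed effects recovered to <= 0.1%."""
        truth = PopModel(1.63, 0.503, 0.209, 2.14,
                         omega=np.zeros((2, 2)), sigma_prop=0.0)
        cohort = generate_cohort(CohortSpec(n_subjects=12, seed=41))
        ds = generate_dataset(cohort, truth, SamplingScheme.rich(8), seed=42)
        init = {"theta_v": 1.3, "theta_cl": 0.65, "beta_pna_cl": 0.1,
                "beta_ga_cl": 1.5, "omega_cl_sd": 0.1, "omega_v_sd": 0.1,
                "sigma_prop": 0.05}
        fr = fit(ds, init=init, compute_se=False, maxfev=6000)
        assert fr.estimates["theta_cl"] == pytest.approx(0.503, rel=1e-3)
        assert fr.estimates["theta_v"] == pytest.approx(1.63, rel=1e-3)

    def test_recovery_on_rich_design(self, rich_study):
        fr = fit(rich_study, compute_se=False)
        assert fr.converged
        assert fr.estimates["theta_cl"] == pytest.approx(0.503, rel=0.15)
        assert fr.estimates["omega_cl_sd"] == pytest.approx(0.508, rel=0.30)

    def test_optimum_stable_under_perturbed_init(self, medium_study, model):
        """Refit from inits perturbed +/-50%: same optimum within 1 OFV unit."""
        f0 = fit(medium_study, init=model, compute_se=False)
        shaky = {
            "theta_v": 1.63 * 1.5, "theta_cl": 0.503 * 0.5,
            "beta_pna_cl": 0.1, "beta_ga_cl": 3.0,
            "omega_cl_sd": 0.25, "omega_v_sd": 0.26, "sigma_prop": 0.43,
        }
        f1 = fit(medium_study, init=shaky, compute_se=False, maxfev=6000)
        assert f1.ofv == pytest.approx(f0.ofv, abs=1.0)

    def test_standard_errors_reported(self, medium_study, model):
        fr = fit(medium_study, init=model)
        for name in ("theta_cl", "theta_v", "sigma_prop"):
            assert np.isfinite(fr.se[name])
            assert fr.rse_percent[name] >= 0

    def test_bql_rows_excluded(self, sparse_study):
        fr = fit(sparse_study, init=final_model(), compute_se=False, maxfev=10)
        assert fr.n_bql_excluded == (
            sparse_study.n_observations - sparse_study.n_quantifiable
        )


class TestEmpiricalBayes:
    def test_subject_without_observations_sits_at_prior_mode(self, model):
        cohort = generate_cohort(CohortSpec(n_subjects=3, seed=2))
        ds = generate_dataset(cohort, model, seed=3)
        ds.subjects[1].observations = []
        ebe = empirical_bayes(ds, model)
        assert ebe.etas[ds.subjects[1].id] == (0.0, 0.0)

    def test_noise_free_subject_recovers_true_eta(self):
        truth = final_model()
        quiet = PopModel(1.63, 0.503, 0.209, 2.14,
                         omega=truth.omega, sigma_prop=1e-4)
        cohort = generate_cohort(CohortSpec(n_subjects=8, seed=51))
        ds = generate_dataset(cohort, quiet, SamplingScheme.rich(8), seed=52)
        ebe = empirical_bayes(ds, quiet)
        for sid, true_eta in ds.truth.etas.items():
            assert ebe.etas[sid][0] == pytest.approx(true_eta[0], abs=1e-3)
            assert ebe.etas[sid][1] == pytest.approx(true_eta[1], abs=1e-3)

    def test_shrinkage_grows_as_observations_vanish(self, model):
        """One observation per subject shrinks eta_hat toward zero
        relative to six observations (same subjects, same true etas)."""
        cohort = generate_cohort(CohortSpec(n_subjects=40, seed=61))
        rich = generate_dataset(cohort, model, SamplingScheme.rich(6), seed=62)
        poor = generate_dataset(cohort, model, SamplingScheme.rich(1), seed=62)
        e_rich = empirical_bayes(rich, model)
        e_poor = empirical_bayes(poor, model)
        m_rich = np.mean([abs(e[0]) for e in e_rich.etas.values()])
        m_poor = np.mean([abs(e[0]) for e in e_poor.etas.values()])
        assert m_poor < m_rich

    def test_weight_normalized_volume_near_typical(self, sparse_study, model):
        ebe = empirical_bayes(sparse_study, model)
        med = np.median(list(ebe.v_per_kg.values()))
        # typical value is theta1/2.68 = 0.608 L/kg
        assert med == pytest.approx(0.61, abs=0.08)


class TestStepwise:
    def test_redundant_candidate_not_added(self):
        """When the data carry no effects beyond allometric weight, adding
        CW again as an estimated effect yields a negligible OFV drop."""
        truth = PopModel(1.63, 0.503, 0.0, 0.0,
                         omega=final_model().omega, sigma_prop=0.288)
        cohort = generate_cohort(CohortSpec(n_subjects=40, seed=71))
        ds = generate_dataset(cohort, truth, SamplingScheme.rich(6), seed=72)
        res = stepwise_covariates(
            ds, candidates=("cw_g",), parameters=("cl",), init=truth
        )
        assert res.retained == []
        (step,) = [s for s in res.steps if s.phase == "forward"]
        assert step.delta_ofv < 3.84
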