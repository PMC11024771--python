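"""Estimator behaviour: heritability algebra, recovery, intervals, ladder."""

import numpy as np
import pandas as pd
import pytest

from famh2.estimation import (LiabilityThresholdModel, fit_model,
                              h2_from_scales, heritability,
                              heritability_difference, model_ladder)
from famh2.model import ParamVector
from famh2.registry import apply_cohort_filters
from famh2.simulate import GeneratorConfig, simulate_registry

# Small, information-rich configuration for fast estimation tests: common
# outcome and moderate heritability so that desk-size cohorts identify the
# scales, with slightly smaller sibships to keep group probabilities cheap.
# The rare-outcome study conditions are exercised in the acceptance tests
# at larger sizes.
FAST = dict(prev_male=0.25, prev_female=0.18, cohort_prevalences=None,
            twin_rate=0.0,
            parent_sibship_dist={1: 0.3, 2: 0.5, 3: 0.2},
            children_per_mother_dist={1: 0.3, 2: 0.5, 3: 0.2})


def _cohort(n_couples, seed, sigma_A, sigma_C=(0.0, 0.0), **kw):
    cfg = GeneratorConfig(n_couples=n_couples, seed=seed, sigma_A=sigma_A,
                          sigma_C=sigma_C, **{**FAST, **kw})
    coh, _ = apply_cohort_filters(simulate_registry(cfg))
    return coh


def _fast_fit(coh, model="M1", **kw):
    kw.setdefault("n_qmc", 128)
    kw.setdefault("n_randomizations", 1)
    kw.setdefault("max_iter", 50)
    est = LiabilityThresholdModel(model=model, **kw)
    return est.fit(coh)


class TestHeritabilityAlgebra:
    def test_table_value(self):
        # sigma_A^2 = 6.8125 with no shared environment -> h2 = 0.872
        assert h2_from_scales(6.8125, 0.0) == pytest.approx(0.872, abs=5e-4)

    def test_zero_additive_is_zero(self):
        pv = ParamVector(beta=np.zeros(1), log_sigma_A=np.log([1e-12]),
                         log_sigma_C=np.log([2.0]))
        h2, _ = heritability(pv)
        assert h2 == pytest.approx(0.0, abs=1e-12)

    def test_shared_environment_decreases_h2(self):
        vals = [h2_from_scales(4.0, c) for c in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_difference_antisymmetry(self):
        pv = ParamVector(beta=np.zeros(1), log_sigma_A=np.log([2.0, 1.0]),
                         log_sigma_C=np.log([0.1, 0.2]))
        swapped = ParamVector(beta=np.zeros(1), log_sigma_A=np.log([1.0, 2.0]),
                              log_sigma_C=np.log([0.2, 0.1]))
        d1, _ = heritability_difference(pv)
        d2, _ = heritability_difference(swapped)
        assert d1 == pytest.approx(-d2, abs=1e-12)

    def test_difference_requires_sex_specific(self):
        pv = ParamVector(beta=np.zeros(1), log_sigma_A=np.log([1.0]),
                         log_sigma_C=np.log([0.1]))
        with pytest.raises(ValueError):
            heritability_difference(pv)

    def test_identical_scales_zero_difference(self):
        pv = ParamVector(beta=np.zeros(1), log_sigma_A=np.log([1.5, 1.5]),
                         log_sigma_C=np.log([0.3, 0.3]))
        d, _ = heritability_difference(pv)
        assert d == pytest.approx(0.0, abs=1e-12)


class TestFitting:
    def test_null_recovery(self):
        """Data with no familial component gives h2 and sigma_C near 0."""
        coh = _cohort(1500, seed=21, sigma_A=(0.0, 0.0))
        est = _fast_fit(coh, model="M2", compute_vcov=False)
        assert est.heritability_["male"]["estimate"] < 0.20
        assert est.heritability_["female"]["estimate"] < 0.20
        sc = np.exp(est.params_.log_sigma_C)
        assert np.all(sc ** 2 < 0.15)

    def test_moderate_recovery_overall(self):
        """Shared-scale fit recovers a moderate heritability."""
        sa = 1.2  # h2 ~ 0.59
        coh = _cohort(2000, seed=22, sigma_A=(sa, sa))
        est = _fast_fit(coh, compute_vcov=True)
        h = est.heritability_["overall"]
        truth = sa ** 2 / (1 + sa ** 2)
        assert h["estimate"] == pytest.approx(truth, abs=0.15)
        assert h["ci_low"] < h["estimate"] < h["ci_high"]
        assert est.vcov_.shape == (4, 4)
        assert np.allclose(est.vcov_, est.vcov_.T, atol=1e-8)
        assert np.all(np.linalg.eigvalsh(est.vcov_) > -1e-10)

    def test_shared_env_share_tracks_truth(self):
        """The fitted shared-environment share is small on data generated
        without one and clearly larger when one is present (at desk size
        the non-negativity boundary keeps the null estimate above zero)."""
        def share(sigma_c, seed):
            coh = _cohort(2500, seed=seed, sigma_A=(1.2, 1.2),
                          sigma_C=(sigma_c, sigma_c))
            est = _fast_fit(coh, compute_vcov=False)
            sa2 = float(np.exp(2 * est.params_.log_sigma_A[0]))
            sc2 = float(np.exp(2 * est.params_.log_sigma_C[0]))
            return sc2 / (1 + sa2 + sc2)

        null_share = share(0.0, seed=31)
        env_share = share(1.0, seed=31)
        assert null_share < 0.25
        assert env_share > null_share + 0.05

    def test_reparameterization_invariance(self):
        coh = _cohort(1200, seed=23, sigma_A=(1.0, 1.0))
        h2a = _fast_fit(coh, scale_parameterization="log_sigma",
                        compute_vcov=False).heritability_["overall"]["estimate"]
        h2b = _fast_fit(coh, scale_parameterization="log_sigma2",
                        compute_vcov=False).heritability_["overall"]["estimate"]
        assert h2a == pytest.approx(h2b, abs=5e-3)

    def test_consistency_rmse_shrinks_with_size(self):
        """Estimator error contracts as the cohort grows (fixed seeds)."""
        sa = 1.2
        truth = sa ** 2 / (1 + sa ** 2)
        rmse = {}
        for n in (500, 2500):
            errs = []
            for seed in (41, 42, 43):
                coh = _cohort(n, seed=seed, sigma_A=(sa, sa))
                est = _fast_fit(coh, compute_vcov=False)
                errs.append(est.heritability_["overall"]["estimate"] - truth)
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[2500] < rmse[500]

    def test_sklearn_params_roundtrip(self):
        est = LiabilityThresholdModel(model="M4", n_qmc=512)
        params = est.get_params()
        assert params["model"] == "M4"
        est2 = LiabilityThresholdModel(**params)
        assert est2.get_params() == params

    def test_predict_proba_matches_prevalence(self):
        coh = _cohort(2000, seed=24, sigma_A=(1.0, 1.0))
        est = _fast_fit(coh, compute_vcov=False)
        p = est.predict_proba(coh)[:, 1]
        assert p.mean() == pytest.approx(coh.diagnosis.mean(), abs=0.02)


class TestIntervals:
    def test_ci_coverage_near_nominal(self):
        """Male-heritability CI covers the truth at close to the nominal
        rate over repeated small simulations (fixed seeds)."""
        sa = 1.0
        truth = sa ** 2 / (1 + sa ** 2)
        covered = trials = 0
        for seed in range(50):
            coh = _cohort(350, seed=900 + seed, sigma_A=(sa, sa))
            est = _fast_fit(coh, model="M2", n_qmc=128, max_iter=40, compute_vcov=True)
            ci = est.heritability_["male"]
            if np.isnan(ci["ci_low"]):
                continue
            trials += 1
            covered += int(ci["ci_low"] <= truth <= ci["ci_high"])
        assert trials >= 45
        # binomial 99% band around 0.95 at n=50
        assert covered / trials >= 0.84


class TestLadder:
    def test_ladder_bookkeeping(self):
        coh = _cohort(900, seed=25, sigma_A=(1.0, 1.0))
        tab = model_ladder(coh, models=("M1", "M2"), n_qmc=256,
                           n_randomizations=1, compute_vcov=False, max_iter=60)
        assert len(tab) == 2
        k1, k2 = tab.n_parameters
        assert k2 - k1 == 2  # sex-specific scales add two parameters
        assert np.allclose(tab.aic, 2 * tab.n_parameters + tab.minus2_loglik)
        # nested: sex-specific fit cannot be worse than shared (tolerance
        # for the optimizer's termination)
        assert tab.minus2_loglik[1] <= tab.minus2_loglik[0] + 0.5
        assert not np.isnan(tab.delta_aic[1])

    def test_aic_delta_omitted_across_subsets(self):
        cfg = GeneratorConfig(n_couples=700, seed=26, sigma_A=(1.0, 1.0),
                              gestational_missing_rate=0.1, **FAST)
        coh, _ = apply_cohort_filters(simulate_registry(cfg))
        tab = model_ladder(coh, models=("M5", "M9"), n_qmc=128,
                           n_randomizations=1, compute_vcov=False, max_iter=12)
        assert np.isnan(tab.delta_aic[1])  # M9 drops missing-gestation rows
        assert tab.n_individuals[1] < tab.n_individuals[0]
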