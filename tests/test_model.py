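"""Design construction, liability covariance, and the pseudolikelihood."""

import numpy as np
import pytest
from scipy.special import ndtr

from famh2.model import (ModelSpec, ParamVector, design_matrix, design_row,
                         group_covariance, prepare, pseudo_loglik,
                         pseudo_loglik_prepared, term_columns)
from famh2.mvn import QMCConfig
from famh2.registry import build_groups
from famh2.simulate import GeneratorConfig, simulate_registry
from famh2.registry import apply_cohort_filters

from conftest import make_child, make_registry
from test_mvn import quad_rectangle


class TestModelSpec:
    def test_ladder_structure(self):
        for i in range(1, 11):
            spec = ModelSpec.from_id(f"M{i}")
            assert spec.sex_specific_scales == (i % 2 == 0)
        assert ModelSpec.from_id("M1").fixed_terms == ("intercept", "sex")
        assert "gestational_age_cat" in ModelSpec.from_id("M10").fixed_terms
        assert ModelSpec.from_id("M7").categorization_scheme == "alternative"

    def test_unknown_id(self):
        with pytest.raises(ValueError):
            ModelSpec.from_id("M11")


class TestDesign:
    def test_m1_male_row(self):
        x = design_row(make_child("a", sex="male"), ModelSpec.from_id("M1"))
        assert np.array_equal(x, [1.0, 1.0])

    def test_female_interactions_zero(self):
        spec = ModelSpec.from_id("M3")
        x = design_row(make_child("a", sex="female", birth_year=1996), spec)
        cols = term_columns(spec)
        inter = [i for i, c in enumerate(cols) if c.startswith("sex_male:")]
        assert all(x[i] == 0.0 for i in inter)
        assert x[cols.index("birth_year_4")] == 1.0   # 1995-1998 bin

    def test_paternal_age_29_middle_bin(self):
        spec = ModelSpec.from_id("M5")
        cols = term_columns(spec)
        x = design_row(make_child("a", paternal_age=29), spec)
        assert x[cols.index("paternal_age_1")] == 1.0  # 29-32 band
        x28 = design_row(make_child("a", paternal_age=28), spec)
        assert x28[cols.index("paternal_age_1")] == 0.0

    def test_alternative_scheme_bins(self):
        spec = ModelSpec.from_id("M7")
        cols = term_columns(spec)
        x = design_row(make_child("a", paternal_age=36, maternal_age=33), spec)
        assert x[cols.index("paternal_age_1")] == 1.0  # 35-42 band
        assert x[cols.index("maternal_age_1")] == 1.0  # 32-37 band

    def test_missing_gestational_age_dropped_only_when_used(self):
        df = make_registry([make_child("a"), make_child("b", gest=np.nan)])
        _, keep5 = design_matrix(df, ModelSpec.from_id("M5"))
        _, keep9 = design_matrix(df, ModelSpec.from_id("M9"))
        assert keep5.all()
        assert list(keep9) == [True, False]


class TestGroupCovariance:
    def test_single_female(self):
        pv = ParamVector(beta=np.zeros(1), log_sigma_A=np.log([1e-9, 2.0]),
                         log_sigma_C=np.log([1e-9, 1e-9]))
        cov = group_covariance(np.array([[1.0]]), np.array([[1.0]]),
                               np.array([False]), pv)
        assert cov == pytest.approx(np.array([[5.0]]), abs=1e-6)

    def test_brother_pair(self):
        pv = ParamVector(beta=np.zeros(1), log_sigma_A=np.log([1.0]),
                         log_sigma_C=np.log([1.0]))
        cov = group_covariance(np.array([[1, 0.5], [0.5, 1]]),
                               np.array([[1, 1], [1, 1]]),
                               np.array([True, True]), pv)
        assert np.allclose(np.diag(cov), 3.0)
        assert cov[0, 1] == pytest.approx(1.5)

    def test_mixed_sex_cousin_pair(self):
        pv = ParamVector(beta=np.zeros(1), log_sigma_A=np.log([2.0, 1.0]),
                         log_sigma_C=np.log([1e-9, 1e-9]))
        cov = group_covariance(np.array([[1, 0.125], [0.125, 1]]),
                               np.array([[1, 0], [0, 1]]),
                               np.array([True, False]), pv)
        assert cov[0, 1] == pytest.approx(0.25, abs=1e-9)
        assert cov[0, 0] == pytest.approx(5.0, abs=1e-6)
        assert cov[1, 1] == pytest.approx(2.0, abs=1e-6)

    def test_nonfinite_params_rejected(self):
        pv = ParamVector(beta=np.zeros(1), log_sigma_A=np.array([np.inf]),
                         log_sigma_C=np.log([1.0]))
        with pytest.raises(ValueError):
            group_covariance(np.eye(2), np.eye(2), np.array([True, True]), pv)


def _tiny_cohort(n_couples=120, seed=5, prev=0.25):
    # small sibships keep the brute-force quadrature oracle tractable
    cfg = GeneratorConfig(n_couples=n_couples, seed=seed, twin_rate=0.0,
                          cohort_prevalences=None, prev_male=prev,
                          prev_female=prev, sigma_A=(1.2, 1.2), sigma_C=(0.4, 0.4),
                          parent_sibship_dist={1: 0.5, 2: 0.5},
                          children_per_mother_dist={1: 0.5, 2: 0.5})
    df = simulate_registry(cfg)
    coh, _ = apply_cohort_filters(df)
    return coh


class TestPseudoLoglik:
    def test_independence_limit_equals_probit(self):
        coh = _tiny_cohort()
        pv = ParamVector(beta=np.array([-0.6, 0.2]),
                         log_sigma_A=np.log([1e-9, 1e-9]),
                         log_sigma_C=np.log([1e-9, 1e-9]))
        ll = pseudo_loglik(coh, ModelSpec.from_id("M2"), pv)
        male = (coh.sex == "male").to_numpy()
        y = coh.diagnosis.to_numpy()
        p = ndtr(-0.6 + 0.2 * male)
        mult = np.zeros(len(coh))
        for g in build_groups(coh):
            mult[g.indices] += 1
        want = float(np.sum(mult * (y * np.log(p) + (1 - y) * np.log(1 - p))))
        assert ll == pytest.approx(want, rel=1e-10)

    def test_additivity_under_duplication(self):
        coh = _tiny_cohort(n_couples=60)
        spec = ModelSpec.from_id("M1")
        pv = ParamVector(beta=np.array([-0.5, 0.1]), log_sigma_A=np.log([1.0]),
                         log_sigma_C=np.log([0.5]))
        qmc = QMCConfig(n_samples=512, n_randomizations=2, seed=3)
        data = prepare(coh, spec, qmc=qmc)
        single = pseudo_loglik_prepared(data, pv)
        dup = coh.copy()
        dup2 = coh.copy()
        # relabel every id so the duplicate forms disjoint groups
        for c in ("child_id", "mother_id", "father_id", "maternal_grandmother_id",
                  "maternal_grandfather_id", "paternal_grandmother_id",
                  "paternal_grandfather_id"):
            dup2[c] = dup2[c] + "_copy"
        both = prepare(
            __import__("pandas").concat([dup, dup2], ignore_index=True), spec, qmc=qmc)
        assert pseudo_loglik_prepared(both, pv) == pytest.approx(2 * single, rel=1e-9)

    def test_matches_bruteforce_quadrature_on_small_fixture(self):
        coh = _tiny_cohort(n_couples=12, seed=9)
        assert 5 <= len(coh) <= 30
        spec = ModelSpec.from_id("M2")
        pv = ParamVector(beta=np.array([-0.7, 0.3]),
                         log_sigma_A=np.log([1.1, 0.8]),
                         log_sigma_C=np.log([0.5, 0.4]))
        qmc = QMCConfig(n_samples=8192, n_randomizations=8, seed=11)
        ll = pseudo_loglik(coh, spec, pv, qmc=qmc)
        X, _ = design_matrix(coh, spec)
        male = (coh.sex == "male").to_numpy()
        y = coh.diagnosis.to_numpy()
        want = 0.0
        for g in build_groups(coh):
            idx = g.indices
            cov = group_covariance(g.R_A, g.R_C, male[idx], pv)
            means = X[idx] @ pv.beta
            want += np.log(quad_rectangle(y[idx], means, cov,
                                          n_nodes=30 if len(idx) > 3 else 60))
        assert ll == pytest.approx(want, rel=5e-4)

    def test_pattern_deduplication_is_exact(self):
        """The de-duplicated evaluation equals a direct per-group sum."""
        coh = _tiny_cohort(n_couples=80, seed=13)
        spec = ModelSpec.from_id("M2")
        pv = ParamVector(beta=np.array([-0.7, 0.3]),
                         log_sigma_A=np.log([1.1, 0.8]),
                         log_sigma_C=np.log([0.3, 0.6]))
        qmc = QMCConfig(n_samples=4096, n_randomizations=8, seed=2)
        ll = pseudo_loglik(coh, spec, pv, qmc=qmc)
        from famh2.mvn import group_probability
        X, _ = design_matrix(coh, spec)
        male = (coh.sex == "male").to_numpy()
        y = coh.diagnosis.to_numpy()
        direct = 0.0
        for g in build_groups(coh):
            idx = g.indices
            cov = group_covariance(g.R_A, g.R_C, male[idx], pv)
            p, _, _ = group_probability(y[idx], X[idx] @ pv.beta, cov, qmc)
            direct += np.log(p)
        assert ll == pytest.approx(direct, rel=2e-3)
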