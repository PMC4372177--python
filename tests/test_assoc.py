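"""Kinship-aware mixed-model association: likelihood, tests, scan."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from kinewas.assoc import (
    KinshipCovariance, SignificanceConfig, bonferroni_threshold,
    direction_summary, fit_probe, run_ewas,
)
from kinewas.assoc import test_age as age_test  # alias: avoid pytest collection
from kinewas.cellcomp import covariate_columns, estimate_cell_proportions
from kinewas.pedigree import kinship_matrix
from kinewas.simulate import SimulationConfig, simulate_pedigree


def _dense_loglik(y, X, two_phi, sigma2_g, sigma2_e, beta):
    """Brute-force multivariate-normal log density (independent oracle)."""
    mean = X @ beta
    cov = sigma2_g * two_phi + sigma2_e * np.eye(len(y))
    return stats.multivariate_normal.logpdf(y, mean=mean, cov=cov)


@pytest.fixture(scope="module")
def family_K():
    ped = simulate_pedigree(SimulationConfig(n_families=2, generations=3, seed=21))
    return kinship_matrix(ped)


class TestFitProbe:
    def test_ols_equivalence_when_unrelated(self):
        rng = np.random.default_rng(30)
        n = 80
        age = rng.uniform(6, 85, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = 1.0 + 0.02 * age + 0.1 * sex + rng.normal(0, 0.3, n)
        X = pd.DataFrame({"age": age, "sex": sex})
        model = fit_probe(y, X, KinshipCovariance(np.eye(n)))  # 2*Phi = I
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert model.coef("age")[0] == pytest.approx(ols.params["age"], abs=1e-6)
        assert model.coef("sex")[0] == pytest.approx(ols.params["sex"], abs=1e-6)

    def test_noiseless_linear_trait_exact(self, family_K):
        n = len(family_K.sample_ids)
        rng = np.random.default_rng(31)
        age = rng.uniform(6, 85, n)
        X = pd.DataFrame({"age": age, "sex": rng.integers(0, 2, n).astype(float)})
        model = fit_probe(0.03 * age, X, family_K)
        assert model.coef("age")[0] == pytest.approx(0.03, abs=1e-8)
        assert model.fit.sigma2_g + model.fit.sigma2_e == pytest.approx(0.0, abs=1e-10)

    def test_rotated_likelihood_equals_dense(self, family_K):
        # eigen-rotated profiled likelihood vs brute-force MVN density, n <= 50
        rng = np.random.default_rng(32)
        n = min(50, len(family_K.sample_ids))
        two_phi = family_K.two_phi[:n, :n]
        age = rng.uniform(6, 85, n)
        X = pd.DataFrame({"age": age})
        y = 0.02 * age + rng.multivariate_normal(
            np.zeros(n), 0.05 * two_phi + 0.04 * np.eye(n))
        model = fit_probe(y, X, KinshipCovariance(two_phi))
        f = model.fit
        design = np.column_stack([np.ones(n), age])
        dense = _dense_loglik(y, design, two_phi, f.sigma2_g, f.sigma2_e, f.beta)
        assert f.loglik == pytest.approx(dense, abs=1e-8)

    def test_h2_recovery(self):
        # 200 replicate probes simulated at h2 = 0.5 on a ~300-sample pedigree;
        # the ML estimate's mean should land within 0.05 of the truth
        rng = np.random.default_rng(33)
        ped = simulate_pedigree(SimulationConfig(n_families=12, generations=4,
                                                 seed=22))
        family_K = kinship_matrix(ped)
        n = len(family_K.sample_ids)
        lam, U = np.linalg.eigh(family_K.two_phi)
        L = U * np.sqrt(np.clip(lam, 0, None))
        age = rng.uniform(6, 85, n)
        X = pd.DataFrame({"age": age})
        s2 = 0.09
        h2_hat = []
        for _ in range(200):
            g = np.sqrt(0.5 * s2) * (L @ rng.normal(size=n))
            y = g + rng.normal(0, np.sqrt(0.5 * s2), n)
            h2_hat.append(fit_probe(y, X, family_K).fit.h2)
        assert np.mean(h2_hat) == pytest.approx(0.5, abs=0.05)

    def test_sample_misalignment_rejected(self, family_K):
        X = pd.DataFrame({"age": [1.0, 2.0]})
        with pytest.raises(ValueError, match="aligned"):
            fit_probe(np.zeros(2), X, family_K)


class TestTestAge:
    def test_constant_age_gives_p_one(self):
        rng = np.random.default_rng(34)
        n = 40
        X = pd.DataFrame({"age": np.full(n, 50.0), "sex": rng.integers(0, 2, n)})
        with pytest.warns(UserWarning, match="constant"):
            model = fit_probe(rng.normal(size=n), X, KinshipCovariance(np.eye(n)))
        res = age_test(model)
        assert res.p_age == 1.0
        assert np.isnan(res.beta_age)

    def test_lrt_statistic_nonnegative_and_wald_agrees(self):
        rng = np.random.default_rng(35)
        n = 120
        age = rng.uniform(6, 85, n)
        X = pd.DataFrame({"age": age, "sex": rng.integers(0, 2, n).astype(float)})
        y = 0.01 * age + rng.normal(0, 0.5, n)
        model = fit_probe(y, X, KinshipCovariance(np.eye(n)))
        lrt = age_test(model, test="lrt")
        wald = age_test(model, test="wald")
        assert 0 < lrt.p_age <= 1
        # the two tests are asymptotically equivalent
        assert np.log10(lrt.p_age) == pytest.approx(np.log10(wald.p_age), abs=1.0)

    def test_p_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(36)
        n = 100
        age = rng.uniform(6, 85, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = 0.02 * age + 0.2 * sex + rng.normal(0, 0.4, n)
        K = KinshipCovariance(np.eye(n))
        p1 = age_test(fit_probe(y, pd.DataFrame({"age": age, "sex": sex}), K)).p_age
        p2 = age_test(fit_probe(
            y, pd.DataFrame({"age": age, "sex": 100.0 * sex + 3.0}), K)).p_age
        assert p1 == pytest.approx(p2, rel=1e-6)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,n,expected", [
        (0.05, 1, 0.05),
        (0.05, 10, 0.005),
    ])
    def test_simple_cases(self, alpha, n, expected):
        assert bonferroni_threshold(SignificanceConfig(alpha, n)) == pytest.approx(expected)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SignificanceConfig(alpha=1.5)
        with pytest.raises(ValueError):
            SignificanceConfig(n_tests=0)


class TestRunEwas:
    def test_planted_probes_found(self, small_cohort):
        co = small_cohort
        props = estimate_cell_proportions(co.cell_signal_beta, co.cell_reference)
        res = run_ewas(co.m_matrix, co.phenotypes, co.kinship,
                       cell_covariates=covariate_columns(props),
                       annotation=co.annotation)
        planted = co.truth.index[co.truth["is_age_probe"]]
        found = res.loc[planted, "significant"]
        assert found.mean() >= 0.9  # slopes 0.02-0.04 are well-powered here
        false_pos = res.loc[res.index.difference(planted), "significant"].sum()
        assert false_pos <= 1

    def test_fitted_slope_invariant_to_dropped_celltype(self, small_cohort):
        # reparameterization: which of the six proportions is dropped is moot
        co = small_cohort
        probe = co.truth.index[co.truth["is_age_probe"]][0]
        m = co.m_matrix.loc[[probe]]
        out = {}
        for drop in ("granulocytes", "NK"):
            cells = covariate_columns(co.cell_proportions, drop=drop)
            res = run_ewas(m, co.phenotypes, co.kinship, cell_covariates=cells)
            out[drop] = res.loc[probe, "beta_age"]
        assert out["granulocytes"] == pytest.approx(out["NK"], abs=1e-6)

    def test_direction_summary_counts(self):
        df = pd.DataFrame({
            "beta_age": [0.1, 0.2, -0.3, 0.4, -0.5],
            "significant": [True, True, True, False, True],
        }, index=[f"p{i}" for i in range(5)])
        s = direction_summary(df)
        assert s == {"n_significant": 4, "n_positive": 2, "n_negative": 2,
                     "ratio_pos_neg": 1.0}
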