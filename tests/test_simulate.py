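"""Synthetic cohort generator: structure, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest

from kinewas.assoc import KinshipCovariance, fit_probe
from kinewas.pedigree import kinship, kinship_matrix
from kinewas.preprocess import beta_to_m
from kinewas.simulate import (
    SimulationConfig, simulate_cohort, simulate_methylation, simulate_pedigree,
    simulate_probe_map, write_cohort,
)


class TestSimulatePedigree:
    def test_two_generation_family_is_quartet(self):
        cfg = SimulationConfig(n_families=1, generations=2,
                               offspring_per_mating=(2, 2), seed=1)
        ped = simulate_pedigree(cfg)
        assert len(ped) == 4
        sibs = [m.id for m in ped if not m.is_founder]
        assert 2 * kinship(ped, *sibs) == 0.5

    def test_four_generations_contain_first_cousins(self):
        ped = simulate_pedigree(SimulationConfig(n_families=1, generations=4, seed=2))
        ids = ped.ids
        K = kinship_matrix(ped, ids)
        vals = set(np.round(K.two_phi[np.triu_indices(len(ids), 1)], 10))
        assert 0.125 in vals  # at least one first-cousin (or equivalent) pair

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=3)
        assert simulate_pedigree(cfg) == simulate_pedigree(cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="generations"):
            SimulationConfig(generations=1)
        with pytest.raises(ValueError, match="heritability"):
            SimulationConfig(heritability_h2=1.0)
        with pytest.raises(ValueError, match="n_age_probes"):
            SimulationConfig(n_probes=10, n_age_probes=20, n_clustered_regions=0)


class TestProbeMap:
    def test_planted_regions_dense_background_sparse(self):
        cfg = SimulationConfig(n_probes=200, n_clustered_regions=2,
                               cluster_probe_spacing=1000, seed=4)
        ann = simulate_probe_map(cfg)
        clustered = ann[ann["cluster_region"] != ""]
        assert clustered.shape[0] == 24  # 2 regions x 12 probes
        for _, region in clustered.groupby("cluster_region"):
            gaps = np.diff(np.sort(region["position"]))
            assert (gaps < 10_000).all()
        background = ann[ann["cluster_region"] == ""]
        for _, chrom in background.groupby("chromosome"):
            gaps = np.diff(np.sort(chrom["position"]))
            assert (gaps > 10_000).all()

    def test_wide_spacing_breaks_clusters(self):
        cfg = SimulationConfig(n_probes=60, n_clustered_regions=1,
                               cluster_probe_spacing=10_001, seed=4)
        ann = simulate_probe_map(cfg)
        region = ann[ann["cluster_region"] == "region1"]
        assert (np.diff(np.sort(region["position"])) > 10_000).all()

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=5)
        pd.testing.assert_frame_equal(simulate_probe_map(cfg), simulate_probe_map(cfg))

    def test_positions_positive_autosomal(self):
        ann = simulate_probe_map(SimulationConfig(seed=6))
        assert (ann["position"] >= 1).all()
        assert set(ann["chromosome"]) <= {str(c) for c in range(1, 23)}


class TestSimulateMethylation:
    def test_noiseless_limit_ols_recovers_slope_exactly(self):
        cfg = SimulationConfig(
            n_families=1, generations=3, n_probes=40, n_age_probes=10,
            n_clustered_regions=0, n_mets_probes=0, heritability_h2=0.0,
            residual_sd=0.0, sex_effect_sd=0.0, cell_effect_sd=0.0, seed=7,
        )
        co = simulate_cohort(cfg)
        age = co.phenotypes["age"].to_numpy()
        probe = co.truth.index[co.truth["is_age_probe"]][0]
        slope = np.polyfit(age, co.m_matrix.loc[probe].to_numpy(), 1)[0]
        assert slope == pytest.approx(co.truth.loc[probe, "true_slope"], abs=1e-10)

    def test_truth_table_covers_every_probe(self, small_cohort):
        assert small_cohort.truth.index.equals(small_cohort.m_matrix.index)
        planted = small_cohort.truth["is_age_probe"].sum()
        assert planted >= small_cohort.config.n_age_probes

    def test_beta_m_mutual_inverses_on_output(self, small_cohort):
        b = small_cohort.beta_matrix.to_numpy()
        assert ((b > 0) & (b < 1)).all()
        np.testing.assert_allclose(beta_to_m(b), small_cohort.m_matrix.to_numpy(),
                                   atol=1e-9)

    def test_null_type_one_error_calibrated(self):
        # no planted effects: LMM p < 0.05 for ~5% of 2,000 null probes
        cfg = SimulationConfig(
            n_families=6, generations=3, n_probes=2000, n_age_probes=0,
            n_clustered_regions=0, n_mets_probes=0, sex_effect_sd=0.0,
            cell_effect_sd=0.0, seed=8,
        )
        co = simulate_cohort(cfg)
        from kinewas.assoc import run_ewas
        res = run_ewas(co.m_matrix, co.phenotypes, co.kinship)
        rate = (res["p_age"] < 0.05).mean()
        assert 0.035 <= rate <= 0.065

    def test_slope_recovery_unbiased(self):
        # 200 replicate probes share b = 0.03; the mean estimate should sit
        # within 2 Monte-Carlo standard errors of the truth
        cfg = SimulationConfig(
            n_families=8, generations=3, n_probes=200, n_age_probes=200,
            age_effect_range=(0.03, 0.03), positive_fraction=1.0,
            n_clustered_regions=0, n_mets_probes=0, residual_sd=0.3, seed=9,
        )
        co = simulate_cohort(cfg)
        from kinewas.assoc import run_ewas
        res = run_ewas(co.m_matrix, co.phenotypes, co.kinship)
        est = res["beta_age"].to_numpy()
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.03) < 2 * mc_se

    def test_polygenic_covariance_structure(self):
        # empirical covariance of null probes ~ s2 * (h2 * 2Phi + (1-h2) I)
        cfg = SimulationConfig(
            n_families=1, generations=3, offspring_per_mating=(2, 2),
            n_probes=4000, n_age_probes=0, n_clustered_regions=0,
            n_mets_probes=0, heritability_h2=0.6, residual_sd=0.5,
            sex_effect_sd=0.0, cell_effect_sd=0.0, seed=10,
        )
        ped = simulate_pedigree(cfg)
        co = simulate_methylation(ped, cfg)
        M = co.m_matrix.to_numpy()
        n = len(ped)
        # remove the per-probe baseline: row-center, which applies the
        # centering projector P to the sample-by-sample covariance as well
        resid = M - M.mean(axis=1, keepdims=True)
        emp = resid.T @ resid / M.shape[0]
        s2 = cfg.residual_sd ** 2
        sigma = s2 * (cfg.heritability_h2 * co.kinship.two_phi
                      + (1 - cfg.heritability_h2) * np.eye(n))
        P = np.eye(n) - np.full((n, n), 1.0 / n)
        theory = P @ sigma @ P
        # Monte-Carlo tolerance over 4,000 probes
        assert np.abs(emp - theory).max() < 0.05

    def test_mets_probes_have_group_slopes(self, small_cohort):
        t = small_cohort.truth
        mets_probes = t[t["is_mets_probe"]]
        assert mets_probes.shape[0] == small_cohort.config.n_mets_probes
        np.testing.assert_allclose(
            mets_probes["slope_mets"],
            small_cohort.config.mets_slope_multiplier * mets_probes["slope_no_mets"])

    def test_mets_only_for_adults(self, small_cohort):
        ph = small_cohort.phenotypes
        assert ph.loc[ph["age"] < 18, "mets"].isna().all()
        assert ph.loc[ph["age"] >= 18, "mets"].notna().all()

    def test_same_seed_identical_cohort(self):
        cfg = SimulationConfig(n_families=1, generations=3, n_probes=50,
                               n_age_probes=5, n_clustered_regions=1, seed=12)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.m_matrix, b.m_matrix)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_write_cohort_roundtrip(self, small_cohort, tmp_path):
        paths = write_cohort(small_cohort, tmp_path)
        from kinewas.pedigree import read_pedigree
        from kinewas.preprocess import read_annotation, read_matrix
        assert read_pedigree(paths["pedigree"]) == small_cohort.pedigree
        beta = read_matrix(paths["beta"])
        np.testing.assert_allclose(beta.to_numpy(),
                                   small_cohort.beta_matrix.to_numpy(), atol=1e-9)
        ann = read_annotation(paths["annotation"])
        assert ann.index.equals(small_cohort.annotation.index)
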