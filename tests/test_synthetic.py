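import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from nanoprune.core_data import aggregate_series, check_validity
from nanoprune.dose_response import fit_log_endpoint
from nanoprune.synthetic import (
    SyntheticConfig,
    generate_bioassay,
    generate_block_matrix,
    generate_descriptors,
    planted_b_table,
)


@pytest.fixture(scope="module")
def default_study():
    cfg = SyntheticConfig(seed=42)
    matrix, truth = generate_descriptors(cfg)
    return cfg, matrix, truth


class TestGenerateDescriptors:
    def test_default_study_shape(self, default_study):
        _, matrix, _ = default_study
        assert matrix.data.shape == (40, 68)

    def test_deterministic_per_seed(self):
        cfg = SyntheticConfig(seed=7)
        m1, _ = generate_descriptors(cfg)
        m2, _ = generate_descriptors(SyntheticConfig(seed=7))
        assert m1.data.equals(m2.data)
        m3, _ = generate_descriptors(SyntheticConfig(seed=8))
        assert not m1.data.equals(m3.data)

    def test_independent_columns_constant_within_material(self, default_study):
        _, matrix, _ = default_study
        for col in matrix.concentration_independent_columns():
            per_mat = matrix.data[col].groupby(level="material").nunique()
            assert (per_mat == 1).all()

    def test_dependent_columns_vary_with_concentration(self, default_study):
        _, matrix, _ = default_study
        for col in ("concentration", "hydrodynamic_size", "zeta_potential"):
            per_mat = matrix.data[col].groupby(level="material").nunique()
            assert (per_mat > 1).all()

    def test_within_cluster_rho_exceeds_floor(self, default_study):
        cfg, matrix, truth = default_study
        per_mat = matrix.data[list(truth.cluster_labels)].groupby(level="material").first()
        rho, _ = spearmanr(per_mat.to_numpy())
        cols = list(per_mat.columns)
        labels = np.array([truth.cluster_labels[c] for c in cols])
        for k in np.unique(labels):
            idx = np.where(labels == k)[0]
            if len(idx) < 2:
                continue
            sub = np.abs(rho[np.ix_(idx, idx)])
            assert sub[np.triu_indices_from(sub, k=1)].min() >= cfg.within_cluster_abs_rho - 0.1

    def test_exact_monotone_transforms_at_unit_rho(self):
        cfg = SyntheticConfig(seed=3, within_cluster_abs_rho=1.0)
        matrix, truth = generate_descriptors(cfg)
        per_mat = matrix.data[list(truth.cluster_labels)].groupby(level="material").first()
        rho, _ = spearmanr(per_mat.to_numpy())
        labels = np.array([truth.cluster_labels[c] for c in per_mat.columns])
        for k in np.unique(labels):
            idx = np.where(labels == k)[0]
            if len(idx) < 2:
                continue
            sub = np.abs(rho[np.ix_(idx, idx)])
            assert np.allclose(sub, 1.0)

    def test_active_descriptors_in_distinct_clusters(self, default_study):
        _, _, truth = default_study
        clusters = [truth.cluster_labels[a] for a in truth.active_descriptors]
        assert len(set(clusters)) == len(clusters)

    def test_inconsistent_cluster_sizes_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_clusters=3, cluster_sizes=(5, 5))


class TestGenerateBioassay:
    def test_plugin_count_noiseless(self):
        # y = -2 ln(e^2) + 20 = 16 exactly
        cfg = SyntheticConfig(
            n_materials=2, concentrations=(math.e**2,), n_clusters=2,
            cluster_sizes=(1, 1), true_descriptors={}, b_center=2.0,
            b0_range=(20.0, 20.0), noise_sd=0.0, seed=0,
        )
        _, truth = generate_descriptors(cfg)
        recs = generate_bioassay(cfg, truth)
        counts = {
            r.count for r in recs
            if r.concentration > 0 and r.endpoint == "reproduction"
        }
        assert counts == {16}

    def test_zero_slope_gives_flat_counts(self):
        cfg = SyntheticConfig(
            true_descriptors={}, b_center=0.0, noise_sd=0.0,
            b0_range=(300.0, 300.0), seed=1,
        )
        _, truth = generate_descriptors(cfg)
        recs = generate_bioassay(cfg, truth)
        nonzero = [r.count for r in recs if r.concentration > 0 and r.endpoint == "reproduction"]
        assert set(nonzero) == {300}

    def test_noiseless_log_fit_recovers_planted_parameters(self):
        cfg = SyntheticConfig(noise_sd=0.0, round_counts=False, seed=5)
        _, truth = generate_descriptors(cfg)
        recs = generate_bioassay(cfg, truth)
        series = [s for s in aggregate_series(recs)
                  if s.endpoint == "reproduction" and s.day == 49]
        assert len(series) == cfg.n_materials
        for s in series:
            fit = fit_log_endpoint(s)
            assert abs(fit.b - truth.b[s.material]) < 1e-8
            assert abs(fit.b0 - truth.b0[s.material]) < 1e-8

    def test_seed_reproducibility(self):
        cfg = SyntheticConfig(seed=9)
        _, truth = generate_descriptors(cfg)
        r1 = generate_bioassay(cfg, truth)
        r2 = generate_bioassay(cfg, truth)
        assert r1 == r2
        cfg2 = SyntheticConfig(seed=10)
        _, truth2 = generate_descriptors(cfg2)
        r3 = generate_bioassay(cfg2, truth2)
        assert [x.count for x in r1] != [x.count for x in r3]

    def test_controls_satisfy_oecd_validity(self):
        cfg = SyntheticConfig(seed=2)
        _, truth = generate_descriptors(cfg)
        recs = generate_bioassay(cfg, truth)
        for mat in truth.b:
            ctl = [r for r in recs if r.material == mat and r.concentration == 0]
            assert check_validity(ctl).valid

    def test_counts_are_non_negative_integers(self):
        cfg = SyntheticConfig(noise_sd=0.5, seed=13)  # heavy noise exercises the floor
        _, truth = generate_descriptors(cfg)
        recs = generate_bioassay(cfg, truth)
        assert all(isinstance(r.count, int) and r.count >= 0 for r in recs)


class TestBlockMatrix:
    def test_planted_separation(self):
        m, truth = generate_block_matrix(seed=1)
        names = list(truth)
        rho, _ = spearmanr(m.data[names].to_numpy())
        labels = np.array([truth[n] for n in names])
        same = labels[:, None] == labels[None, :]
        triu = np.triu(np.ones_like(same, dtype=bool), k=1)
        assert np.abs(rho[same & triu]).min() >= 0.9
        assert np.abs(rho[~same & triu]).max() <= 0.45

    def test_shape_and_determinism(self):
        m1, _ = generate_block_matrix(seed=4)
        m2, _ = generate_block_matrix(seed=4)
        assert m1.data.shape == (40, 68)
        assert m1.data.equals(m2.data)


class TestPlantedBTable:
    def test_noiseless_matches_truth(self):
        cfg = SyntheticConfig(seed=0)
        _, truth = generate_descriptors(cfg)
        b = planted_b_table(truth)
        assert b.to_dict() == truth.b

    def test_noise_scales_with_spread(self):
        cfg = SyntheticConfig(seed=0)
        _, truth = generate_descriptors(cfg)
        b0 = planted_b_table(truth)
        b1 = planted_b_table(truth, noise_sd=0.05, seed=1)
        rel = np.abs(b1 - b0).mean() / b0.std()
        assert 0 < rel < 0.2
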