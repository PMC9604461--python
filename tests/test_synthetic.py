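import math

import numpy as np
import pandas as pd
import pytest

from diaphos.errors import ConfigError
from diaphos.normalization import protein_normalize, total_normalize
from diaphos.synthetic import (
    SimulationConfig,
    generate_dataset,
    generate_kinase_substrate_map,
    generate_ppi,
)


class TestConfigValidation:
    def test_bad_dimensions_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_proteins=0)
        with pytest.raises(ConfigError):
            SimulationConfig(de_fraction=1.5)
        with pytest.raises(ConfigError):
            SimulationConfig(n_stages=1)


class TestGenerateDataset:
    def test_shapes_and_invariants(self):
        config = SimulationConfig(seed=2, n_proteins=50, n_kinases=2, regulon_size=5)
        data = generate_dataset(config)
        assert data.protein.values.shape == (50, 9)
        assert (data.protein.values.to_numpy() > 0).all()
        assert (data.phospho.values.to_numpy() > 0).all()
        protein_ids = set(data.protein.feature_ids)
        assert all(s.protein_id in protein_ids for s in data.sites)
        assert len({s.site_id for s in data.sites}) == len(data.sites)
        # every generated feature appears exactly once in the ground truth
        assert set(data.truth.protein_templates) == protein_ids
        assert set(data.truth.site_effects) == set(data.phospho.feature_ids)

    def test_seed_determinism(self):
        config = SimulationConfig(seed=42, n_proteins=40, n_kinases=2, regulon_size=4)
        d1 = generate_dataset(config)
        d2 = generate_dataset(config)
        pd.testing.assert_frame_equal(d1.protein.values, d2.protein.values)
        pd.testing.assert_frame_equal(d1.phospho.values, d2.phospho.values)
        assert d1.sites == d2.sites
        assert d1.truth.kinase_truth == d2.truth.kinase_truth

    def test_no_effect_no_noise_is_flat(self):
        config = SimulationConfig(
            seed=1, n_proteins=30, de_fraction=0.0, replicate_sd=0.0, n_kinases=0
        )
        data = generate_dataset(config)
        for matrix in (data.protein.values, data.phospho.values):
            arr = matrix.to_numpy()
            by_stage = arr.reshape(arr.shape[0], 3, 3)
            # replicates identical within stage, stage means all equal
            assert np.allclose(by_stage, by_stage[:, :, :1])
            assert np.allclose(by_stage.mean(axis=2), by_stage.mean(axis=2)[:, :1])

    def test_zero_noise_matches_ground_truth_exactly(self):
        config = SimulationConfig(seed=6, n_proteins=30, replicate_sd=0.0, n_kinases=0)
        data = generate_dataset(config)
        log2 = np.log2(data.protein.values.to_numpy())
        truth = np.array([data.truth.protein_stage_means[p] for p in data.protein.feature_ids])
        assert np.allclose(log2.reshape(-1, 3, 3)[:, :, 0], truth)

    def test_de_fraction_recovered_by_counting(self):
        config = SimulationConfig(seed=9, n_proteins=1000, de_fraction=0.3, n_kinases=0)
        data = generate_dataset(config)
        n_de = sum(t != "flat" for t in data.truth.protein_templates.values())
        sigma = math.sqrt(1000 * 0.3 * 0.7)
        assert abs(n_de - 300) <= 3 * sigma

    def test_windows_are_valid(self):
        config = SimulationConfig(seed=4, n_proteins=80, n_kinases=2, regulon_size=5)
        data = generate_dataset(config)
        for site in data.sites:
            assert len(site.window) == 13
            assert site.window[6] == site.residue

    def test_regulon_windows_carry_planted_motif(self):
        config = SimulationConfig(seed=4, n_proteins=80, n_kinases=3, regulon_size=6)
        data = generate_dataset(config)
        windows = {s.site_id: s.window for s in data.sites}
        for info in data.truth.kinase_truth.values():
            for sid in info["substrates"]:
                w = windows[sid]
                assert w[6] == "S"
                for offset, residue in config.motif_spec:
                    assert w[offset + 6] == residue


class TestKinaseRegulons:
    def test_gmt_construction(self):
        config = SimulationConfig(seed=3, n_proteins=60, n_kinases=2, regulon_size=5)
        data = generate_dataset(config)
        gmt = generate_kinase_substrate_map(config, data.sites, data.truth)
        assert len(gmt) == 2
        assert all(len(gmt[k]) == 5 for k in gmt)
        site_ids = {s.site_id for s in data.sites}
        assert all(gmt[k] <= site_ids for k in gmt)

    def test_planted_shift_recovered_from_matrix(self):
        """With zero noise, the protein-normalized log2 contrast of each
        substrate site equals the planted kinase shift exactly."""
        config = SimulationConfig(
            seed=8, n_proteins=120, n_kinases=3, regulon_size=8, replicate_sd=0.0,
            kinase_shift=1.0,
        )
        data = generate_dataset(config)
        adj, _ = protein_normalize(data.phospho, data.protein, data.sites)
        log2 = np.log2(adj.values)
        for info in data.truth.kinase_truth.values():
            a = info["stage_index"] - 1
            b = info["stage_index"]
            stage_a = data.truth.stages[a]
            stage_b = data.truth.stages[b]
            for sid in info["substrates"]:
                va = log2.loc[sid, adj.samples_for_stage(stage_a)].mean()
                vb = log2.loc[sid, adj.samples_for_stage(stage_b)].mean()
                assert vb - va == pytest.approx(info["sign"] * 1.0, abs=1e-9)

    def test_negative_kinase_substrates_mostly_down(self):
        config = SimulationConfig(
            seed=11, n_proteins=200, n_kinases=2, regulon_size=10,
            kinase_signs=(-1,), kinase_stages=(1,), replicate_sd=0.25,
        )
        data = generate_dataset(config)
        adj, _ = protein_normalize(data.phospho, data.protein, data.sites)
        log2 = np.log2(adj.values)
        d_cols = adj.samples_for_stage("D")
        pd_cols = adj.samples_for_stage("PD")
        for info in data.truth.kinase_truth.values():
            ratios = [
                log2.loc[s, pd_cols].mean() - log2.loc[s, d_cols].mean()
                for s in info["substrates"]
            ]
            assert sum(r < 0 for r in ratios) > len(ratios) / 2

    def test_regulons_exceeding_sites_rejected(self):
        config = SimulationConfig(seed=1, n_proteins=10, n_kinases=50, regulon_size=10)
        with pytest.raises(ConfigError, match="regulon"):
            generate_dataset(config)


class TestGeneratePpi:
    def test_single_module_edge_count(self):
        config = SimulationConfig(
            seed=1, ppi_module_sizes=(5,), background_edge_prob=0.0
        )
        edges, modules = generate_ppi(config, [f"F{i}" for i in range(20)])
        assert len(edges) == 10  # C(5,2)
        assert len(modules[0]) == 5
        assert (edges["confidence"] >= 0.7).all()

    def test_two_module_edge_count(self):
        config = SimulationConfig(
            seed=1, ppi_module_sizes=(4, 6), background_edge_prob=0.0
        )
        edges, _ = generate_ppi(config, [f"F{i}" for i in range(30)])
        assert len(edges) == 6 + 15

    def test_background_edge_count_binomial(self):
        config = SimulationConfig(
            seed=5, ppi_module_sizes=(), background_edge_prob=0.01
        )
        n = 500
        edges, _ = generate_ppi(config, [f"F{i}" for i in range(n)])
        n_pairs = n * (n - 1) // 2
        expected = 0.01 * n_pairs
        sigma = math.sqrt(n_pairs * 0.01 * 0.99)
        assert abs(len(edges) - expected) <= 3 * sigma
        assert (edges["confidence"] >= 0.15).all() and (edges["confidence"] <= 0.95).all()

    def test_no_self_loops_or_duplicates(self):
        config = SimulationConfig(seed=2, ppi_module_sizes=(4,), background_edge_prob=0.05)
        edges, _ = generate_ppi(config, [f"F{i}" for i in range(40)])
        assert (edges["node_a"] != edges["node_b"]).all()
        keys = {tuple(sorted(p)) for p in zip(edges["node_a"], edges["node_b"])}
        assert len(keys) == len(edges)

    def test_overlapping_explicit_modules_rejected(self):
        config = SimulationConfig(seed=1)
        with pytest.raises(ConfigError, match="overlap"):
            generate_ppi(config, ["A", "B", "C"], module_members=[["A", "B"], ["B", "C"]])

    def test_module_sizes_exceeding_features_rejected(self):
        config = SimulationConfig(seed=1, ppi_module_sizes=(10,))
        with pytest.raises(ConfigError):
            generate_ppi(config, ["A", "B"])
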