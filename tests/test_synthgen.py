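"""Generator correctness: LD-block structure, architecture statistics,
summary-statistic distribution, weight-model constraints, flat-file
round trips."""

import numpy as np
import pandas as pd
import pytest

from ddgen import synthgen
from ddgen.synthgen import (
    ConfigurationError,
    simulate_causal_pair,
    simulate_effects,
    simulate_ld_blocks,
    simulate_null_pair,
    simulate_sumstats,
    simulate_weight_models,
)


class TestLdBlocks:
    def test_ar1_closed_form(self):
        (blk,) = simulate_ld_blocks(sizes=[3], ld_param=0.5, seed=1)
        assert blk.R[0, 2] == pytest.approx(0.25, abs=1e-12)
        assert blk.R[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_zero_decay_gives_identity(self):
        (blk,) = simulate_ld_blocks(sizes=[5], ld_param=0.0, seed=1)
        assert np.array_equal(blk.R, np.eye(5))

    def test_random_psd_invariants(self):
        (blk,) = simulate_ld_blocks(
            sizes=[20], ld_model="random_psd", seed=7
        )
        assert np.linalg.eigvalsh(blk.R).min() >= -1e-8
        assert np.allclose(np.diag(blk.R), 1.0, atol=1e-10)

    def test_invariants_over_random_configs(self):
        """Symmetry, unit diagonal and PSD over 100 random block configs."""
        rng = np.random.default_rng(99)
        for i in range(100):
            size = int(rng.integers(1, 15))
            model = "ar1" if i % 2 else "random_psd"
            rho = float(rng.uniform(0, 0.99))
            (blk,) = simulate_ld_blocks(
                sizes=[size], ld_model=model, ld_param=rho, seed=1000 + i
            )
            blk.validate()  # raises on violation

    def test_blocks_ordered_and_nonoverlapping(self):
        blocks = simulate_ld_blocks(sizes=8, n_blocks=5, seed=3)
        for a, b in zip(blocks, blocks[1:]):
            assert a.end < b.start

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_ld_blocks(sizes=[0], seed=1)

    def test_seed_mandatory(self):
        with pytest.raises(ConfigurationError):
            simulate_ld_blocks(sizes=[3])


class TestEffects:
    def test_zero_h2_gives_zero_effects(self, small_blocks):
        truth = simulate_effects(small_blocks, h2=(0.0, 0.3), rg=0.0, seed=5)
        assert np.all(truth.beta[:, 0] == 0)

    def test_perfect_correlation_identical_vectors(self, small_blocks):
        truth = simulate_effects(small_blocks, h2=(0.4, 0.4), rg=1.0, seed=5)
        np.testing.assert_allclose(truth.beta[:, 0], truth.beta[:, 1], atol=1e-12)

    def test_effect_pair_correlation_converges(self):
        """At M = 10,000 the empirical effect correlation is within 0.03
        of the requested rg."""
        blocks = simulate_ld_blocks(sizes=100, n_blocks=100, seed=11)
        truth = simulate_effects(blocks, h2=(0.5, 0.25), rg=-0.2, seed=12)
        corr = np.corrcoef(truth.beta[:, 0], truth.beta[:, 1])[0, 1]
        assert corr == pytest.approx(-0.2, abs=0.03)

    def test_exact_scaling_hits_h2(self, small_blocks):
        truth = simulate_effects(small_blocks, h2=(0.37, 0.11), rg=0.2, seed=5)
        assert truth.genetic_variance(small_blocks, 0) == pytest.approx(0.37, abs=1e-6)
        assert truth.genetic_variance(small_blocks, 1) == pytest.approx(0.11, abs=1e-6)

    def test_oligogenic_confines_causals(self, small_blocks):
        truth = simulate_effects(
            small_blocks, h2=(0.5, 0.0), rg=0.0, architecture="oligogenic",
            n_causal_blocks=3, seed=6,
        )
        causal_blocks = set(truth.block_ids[truth.causal[:, 0]])
        assert len(causal_blocks) == 3

    def test_invalid_rg_rejected(self, small_blocks):
        with pytest.raises(ConfigurationError):
            simulate_effects(small_blocks, h2=(0.5, 0.5), rg=1.5, seed=5)

    def test_null_pair_has_zero_local_covariance(self, small_blocks):
        truth = simulate_null_pair(small_blocks, h2=(0.4, 0.4), seed=13)
        offset = 0
        for blk in small_blocks:
            b1 = truth.beta[offset : offset + blk.n_snps, 0]
            b2 = truth.beta[offset : offset + blk.n_snps, 1]
            assert abs(b1 @ blk.R @ b2) < 1e-12
            offset += blk.n_snps

    def test_causal_pair_trait2_inherits_trait1(self, small_blocks):
        truth = simulate_causal_pair(
            small_blocks, h2_1=0.2, h2_2_own=0.0, causal_scale=0.5,
            blocks_1=[0, 1], blocks_2=[], n_causal_per_block=2, seed=21,
            shared_only=True,
        )
        np.testing.assert_allclose(
            truth.beta[:, 1], 0.5 * truth.beta[:, 0], atol=1e-12
        )


class TestSumstats:
    def test_null_distribution(self):
        """With beta = 0 the Z-scores are standard normal marginally:
        mean near 0, unit variance, ~5% beyond 1.96 over >= 10,000 SNPs."""
        blocks = simulate_ld_blocks(sizes=50, n_blocks=240, ld_param=(0.1, 0.9), seed=31)
        truth = simulate_effects(blocks, h2=(0.0, 0.0), rg=0.0, seed=32)
        table = simulate_sumstats(truth, blocks, n=10_000, seed=33, trait=0)
        z = table["Z"].to_numpy()
        assert len(z) >= 10_000
        assert abs(z.mean()) <= 3 / np.sqrt(len(z)) * 1.5
        assert 0.9 <= z.var() <= 1.1
        assert 0.04 <= np.mean(np.abs(z) > 1.96) <= 0.06

    def test_deterministic_for_fixed_seed(self, small_blocks):
        truth = simulate_effects(small_blocks, h2=(0.3, 0.0), rg=0.0, seed=41)
        a = simulate_sumstats(truth, small_blocks, n=5000, seed=42, trait=0)
        b = simulate_sumstats(truth, small_blocks, n=5000, seed=42, trait=0)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_z_matches_closed_form(self):
        """Monte-Carlo mean of Z at each SNP equals sqrt(n) V beta."""
        blocks = simulate_ld_blocks(sizes=[6], ld_param=0.5, seed=51)
        truth = simulate_effects(blocks, h2=(0.02, 0.0), rg=0.0, seed=52)
        n = 1000
        reps = np.array(
            [
                simulate_sumstats(truth, blocks, n=n, seed=530 + r, trait=0)["Z"]
                for r in range(200)
            ]
        )
        expected = np.sqrt(n) * blocks[0].R @ truth.beta[:, 0]
        mc_se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert np.all(np.abs(reps.mean(axis=0) - expected) <= 3 * mc_se + 1e-9)

    def test_snp_mismatch_rejected(self, small_blocks):
        truth = simulate_effects(small_blocks, h2=(0.3, 0.0), rg=0.0, seed=61)
        with pytest.raises(ConfigurationError):
            simulate_sumstats(truth, small_blocks[:-1], n=1000, seed=62)


class TestWeightModels:
    def test_cis_h2_within_requested_range(self, small_blocks):
        models = simulate_weight_models(
            small_blocks, n_genes=50, cis_h2_range=(0.01, 0.68), seed=71
        )
        assert all(0.01 <= m.cis_h2 <= 0.68 for m in models)

    def test_single_snp_model_single_weight(self):
        blocks = simulate_ld_blocks(sizes=[1], seed=72)
        models = simulate_weight_models(blocks, n_genes=1, sparsity=1.0, seed=73)
        assert np.count_nonzero(models[0].weights) == 1

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            synthgen.WeightModel(
                gene_id="g", panel_id="p", chrom="1", tss=1, tes=2,
                snp_ids=["rs1"], weights=np.zeros(1), cis_h2=0.1,
            )

    def test_hopeless_sparsity_errors(self, small_blocks):
        with pytest.raises(ConfigurationError):
            simulate_weight_models(small_blocks, n_genes=1, sparsity=0.0, seed=74)


class TestFlatFiles:
    def test_ld_manifest_round_trip(self, tmp_path, small_blocks):
        manifest = synthgen.write_ld_manifest(small_blocks, tmp_path / "ld")
        blocks2, alleles = synthgen.read_ld_manifest(manifest)
        assert [b.block_id for b in blocks2] == [b.block_id for b in small_blocks]
        for a, b in zip(small_blocks, blocks2):
            np.testing.assert_allclose(a.R, b.R, atol=1e-9)
            assert a.snp_ids == b.snp_ids
        assert alleles[small_blocks[0].snp_ids[0]] == ("A", "G")

    def test_truth_serialization(self, tmp_path, small_blocks):
        truth = simulate_effects(small_blocks, h2=(0.3, 0.1), rg=0.4, seed=81)
        synthgen.write_truth(truth, tmp_path / "truth.tsv")
        df = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert len(df) == len(truth.snp_ids)
        np.testing.assert_allclose(df["BETA_T1"], truth.beta[:, 0], atol=1e-12)
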