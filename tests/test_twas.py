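"""TWAS statistic, permutation test, conditional GWAS, novelty rule and
tissue chi-square summary."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_sumstats
from ddgen.synthgen import LDBlock, WeightModel
from ddgen.twas import (
    DegenerateModelError,
    classify_novelty,
    conditional_gwas,
    permutation_test,
    tissue_chi2_summary,
    twas_association,
    twas_scan,
    TwasAssociation,
)


def make_block(R, bp_start=1000, prefix="rs"):
    R = np.asarray(R, dtype=float)
    m = R.shape[0]
    return LDBlock(
        block_id="blk",
        chrom="1",
        start=bp_start,
        end=bp_start + 100 * (m - 1),
        snp_ids=[f"{prefix}{i + 1}" for i in range(m)],
        R=R,
        bp=bp_start + 100 * np.arange(m),
    )


def make_model(weights, block, cis_h2=0.2, gene="geneX", panel="panelA"):
    return WeightModel(
        gene_id=gene,
        panel_id=panel,
        chrom=block.chrom,
        tss=block.start,
        tes=block.start + 10,
        snp_ids=list(block.snp_ids),
        weights=np.asarray(weights, dtype=float),
        cis_h2=cis_h2,
    )


def table_for(block, z):
    return make_sumstats(
        [
            {"SNP": s, "BP": int(b), "Z": float(zz)}
            for s, b, zz in zip(block.snp_ids, block.bp, z)
        ]
    )


class TestAssociation:
    def test_single_snp_identity(self):
        block = make_block([[1.0]])
        model = make_model([1.0], block)
        assoc = twas_association(model, table_for(block, [2.5]), block)
        assert assoc.z_twas == pytest.approx(2.5, abs=1e-12)

    def test_two_snp_identity_ld(self):
        block = make_block(np.eye(2))
        model = make_model([1.0, 1.0], block)
        assoc = twas_association(model, table_for(block, [3.0, 4.0]), block)
        assert assoc.z_twas == pytest.approx(7 / np.sqrt(2), abs=1e-10)

    def test_scale_invariance_and_antisymmetry(self):
        """z_twas is invariant under positive weight rescaling and flips
        sign under negation, over 1,000 random instances."""
        rng = np.random.default_rng(5)
        for _ in range(1000):
            m = int(rng.integers(1, 11))
            A = rng.standard_normal((m, m + 2))
            R = A @ A.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
            block = make_block(R)
            w = rng.standard_normal(m)
            if not np.any(w != 0):
                continue
            z = rng.standard_normal(m)
            table = table_for(block, z)
            base = twas_association(make_model(w, block), table, block).z_twas
            # brute-force evaluation of the defining formula
            brute = (w @ z) / np.sqrt(w @ R @ w)
            assert base == pytest.approx(brute, abs=1e-10)
            c = float(rng.uniform(0.1, 10))
            scaled = twas_association(make_model(c * w, block), table, block).z_twas
            flipped = twas_association(make_model(-w, block), table, block).z_twas
            assert scaled == pytest.approx(base, abs=1e-10)
            assert flipped == pytest.approx(-base, abs=1e-10)

    def test_degenerate_model_raises(self):
        block = make_block([[1.0, 1.0], [1.0, 1.0]])
        model = make_model([1.0, -1.0], block)
        with pytest.raises(DegenerateModelError, match="geneX"):
            twas_association(model, table_for(block, [1.0, 1.0]), block)

    def test_null_statistic_standard_normal(self):
        """Under the null (weights orthogonal to causal effects -- here no
        effects at all), z_twas over 5,000 simulated loci is ~N(0, 1)."""
        rng = np.random.default_rng(17)
        zs = []
        for _ in range(100):
            m = 8
            A = rng.standard_normal((m, m + 3))
            R = A @ A.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
            L = np.linalg.cholesky(R + 1e-10 * np.eye(m))
            block = make_block(R)
            w = rng.standard_normal(m)
            model = make_model(w, block)
            for _ in range(50):
                z = L @ rng.standard_normal(m)
                zs.append(
                    twas_association(model, table_for(block, z), block).z_twas
                )
        zs = np.asarray(zs)
        assert len(zs) == 5000
        assert abs(zs.mean()) <= 0.05
        assert 0.9 <= zs.var() <= 1.1


class TestScan:
    def test_boundary_significance_inclusive(self):
        block = make_block(np.eye(1))
        from scipy import stats

        alpha, m = 0.05, 1
        z_at_threshold = stats.norm.isf(alpha / m / 2)
        model = make_model([1.0], block)
        assocs, meta = twas_scan(
            [model], table_for(block, [z_at_threshold]), [block], alpha=alpha
        )
        assert meta["m_tested"] == 1
        assert assocs[0].significant

    def test_degenerate_models_logged_and_skipped(self):
        block = make_block([[1.0, 1.0], [1.0, 1.0]])
        good = make_model([1.0, 0.0], block, gene="good")
        bad = make_model([1.0, -1.0], block, gene="bad")
        table = table_for(block, [1.0, 1.0])
        assocs, meta = twas_scan([good, bad], table, [block])
        assert [a.gene_id for a in assocs] == ["good"]
        assert meta["m_tested"] == 1
        assert meta["skipped"][0][0] == "bad"


class TestPermutation:
    def test_single_snp_model_p_one(self):
        block = make_block([[1.0]])
        model = make_model([1.0], block)
        p = permutation_test(model, table_for(block, [5.0]), block, B=99, seed=1)
        assert p == 1.0

    def test_zero_statistic_p_one(self):
        block = make_block(np.eye(2))
        model = make_model([1.0, 1.0], block)
        p = permutation_test(model, table_for(block, [2.0, -2.0]), block, B=99, seed=1)
        assert p == 1.0

    def test_lower_bound(self):
        rng = np.random.default_rng(3)
        block = make_block(np.eye(5))
        model = make_model(rng.standard_normal(5), block)
        table = table_for(block, rng.standard_normal(5) + 4)
        B = 49
        p = permutation_test(model, table, block, B=B, seed=2)
        assert 1 / (B + 1) <= p <= 1.0


class TestConditional:
    def test_self_conditioning_zero(self):
        block = make_block(np.eye(3))
        model = make_model([0.0, 1.0, 0.0], block)
        out = conditional_gwas(model, table_for(block, [1.0, 4.0, 2.0]), block)
        assert out.loc[1, "Z_COND"] == 0.0

    def test_uncorrelated_snp_unchanged(self):
        block = make_block(np.eye(3))
        model = make_model([0.0, 1.0, 0.0], block)
        out = conditional_gwas(model, table_for(block, [1.0, 4.0, 2.0]), block)
        assert out.loc[0, "Z_COND"] == pytest.approx(1.0, abs=1e-12)

    def test_formula_value(self):
        # r = 0.5, z_j = 4, z_twas = 4 -> (4 - 2) / sqrt(0.75)
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        block = make_block(R)
        model = make_model([0.0, 1.0], block)
        out = conditional_gwas(model, table_for(block, [4.0, 4.0]), block)
        assert out.loc[0, "R"] == pytest.approx(0.5, abs=1e-12)
        assert out.loc[0, "Z_COND"] == pytest.approx(2 / np.sqrt(0.75), abs=1e-6)

    def test_shrinks_aligned_top_correlated_snp(self):
        """At the SNP most correlated with the predicted expression score,
        conditioning shrinks the association whenever the observed score
        and the model-implied component agree in sign."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = 6
            A = rng.standard_normal((m, m + 2))
            R = A @ A.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
            block = make_block(R)
            model = make_model(rng.standard_normal(m), block)
            z = rng.standard_normal(m) + 2
            out = conditional_gwas(model, table_for(block, z), block)
            z_twas = (model.weights @ z) / np.sqrt(
                model.weights @ R @ model.weights
            )
            j = int(np.argmax(np.abs(out["R"])))
            r = out.loc[j, "R"]
            zj = out.loc[j, "Z"]
            if r**2 >= 1 - 1e-10:
                continue
            # aligned and not over-explained: the model-adjusted numerator
            # shrinks (the 1/sqrt(1-r^2) rescaling can still exceed |z|
            # when the model over-explains the SNP, so that case is excluded)
            if np.sign(zj) == np.sign(r * z_twas) and abs(r * z_twas) <= 2 * abs(zj):
                numerator = out.loc[j, "Z_COND"] * np.sqrt(1 - r**2)
                assert abs(numerator) <= abs(zj) + 1e-9


class TestNovelty:
    def _assoc(self, tss):
        return TwasAssociation(
            gene_id="g", panel_id="p", chrom="1", tss=tss, tes=tss + 10,
            cis_h2=0.1, z_twas=5.0, p_twas=1e-7, best_gwas_snp=None,
            best_gwas_z=None, best_gwas_p=None,
        )

    def test_near_known_region_not_novel(self):
        table = make_sumstats([{"BP": 10_000_000, "P": 0.5}])
        known = [("1", 10_000_000, 10_100_000)]
        flags = classify_novelty(self._assoc(10_500_000), known, table)
        assert flags[500_000] is False  # 0.4 Mb away

    def test_far_and_subthreshold_is_novel(self):
        tss = 11_000_000
        table = make_sumstats([{"BP": tss, "P": 1e-6}])
        known = [("1", 10_000_000, 10_400_000)]
        flags = classify_novelty(self._assoc(tss), known, table)
        assert flags[500_000] is True
        assert flags[1_000_000] is False  # 0.6 Mb < 1 Mb window

    def test_local_gws_signal_never_novel(self):
        tss = 50_000_000
        table = make_sumstats([{"BP": tss, "P": 1e-9}])
        flags = classify_novelty(self._assoc(tss), [], table)
        assert not any(flags.values())


class TestTissueChi2:
    def _sig(self, z, panel):
        a = self._base(z, panel)
        a.significant = True
        return a

    @staticmethod
    def _base(z, panel):
        return TwasAssociation(
            gene_id="g", panel_id=panel, chrom="1", tss=1, tes=2, cis_h2=0.1,
            z_twas=z, p_twas=0.5, best_gwas_snp=None, best_gwas_z=None,
            best_gwas_p=None,
        )

    def test_mean_square_and_sign_invariance(self):
        out = tissue_chi2_summary([self._sig(2.0, "a"), self._sig(-2.0, "a")])
        assert out.loc[0, "mean_chi2"] == pytest.approx(4.0)

    def test_hand_arithmetic(self):
        out = tissue_chi2_summary(
            [self._sig(z, "a") for z in (1.0, 2.0, 3.0)]
        )
        assert out.loc[0, "mean_chi2"] == pytest.approx(14 / 3)

    def test_empty_input_empty_table(self):
        out = tissue_chi2_summary([self._base(2.0, "a")])  # not significant
        assert len(out) == 0
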