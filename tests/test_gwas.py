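"""Weighted single-step GWAS engine: back-solving, nonlinearA weights,
normalization, the iteration loop and window decomposition."""

import warnings

import numpy as np
import pandas as pd
import pytest

from wssgwas import (
    MarkerMap,
    RelationshipMatrix,
    SNPWeights,
    SnpEffectSet,
    VarianceComponents,
    backsolve_snp_effects,
    build_A,
    build_A_inverse,
    build_design,
    build_G,
    extract_A22,
    nonlinearA_weights,
    normalize_weights,
    run_wssgwas,
    top_windows,
    window_variance,
)
from wssgwas.genotypes import allele_frequencies, apply_qc, center_gene_content, impute_missing
from wssgwas.gwas import window_table_for_result
from wssgwas.relmat import scaling_denominator


class TestBacksolve:
    def test_zero_gebv_zero_effects(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(4, 4))
        G = RelationshipMatrix(Z @ Z.T + np.eye(4), ids=list("abcd"))
        u = backsolve_snp_effects(Z, SNPWeights.identity(4), G, np.zeros(4), lam=0.5)
        assert np.all(u.u_hat == 0)

    def test_square_invertible_identity(self):
        rng = np.random.default_rng(1)
        n = m = 6
        Z = rng.normal(size=(n, m))
        freqs = rng.uniform(0.2, 0.4, m)
        lam = 1.0 / scaling_denominator(freqs)
        G = build_G(Z, None, freqs, sample_ids=[str(i) for i in range(n)])
        gebv = rng.normal(size=n)
        u = backsolve_snp_effects(Z, SNPWeights.identity(m), G, gebv, lam)
        assert np.abs(Z @ u.u_hat - gebv).max() < 1e-8

    def test_matches_independent_dense_expression(self):
        rng = np.random.default_rng(2)
        n, m = 8, 12
        Z = rng.normal(size=(n, m))
        d = SNPWeights(rng.uniform(0.5, 2.0, m))
        freqs = rng.uniform(0.1, 0.5, m)
        lam = 1.0 / scaling_denominator(freqs)
        A22 = np.eye(n) + 0.1
        G_w = RelationshipMatrix(
            0.95 * build_G(Z, d, freqs).values + 0.05 * A22, ids=[str(i) for i in range(n)]
        )
        gebv = rng.normal(size=n)
        u = backsolve_snp_effects(Z, d, G_w, gebv, lam)
        expected = lam * np.diag(d.d) @ Z.T @ np.linalg.inv(G_w.values) @ gebv
        assert np.abs(u.u_hat - expected).max() < 1e-10

    def test_singular_G_raises(self):
        Z = np.ones((3, 2))
        G = RelationshipMatrix(np.ones((3, 3)), ids=list("abc"))
        with pytest.raises(np.linalg.LinAlgError):
            backsolve_snp_effects(Z, SNPWeights.identity(2), G, np.ones(3), 1.0)


class TestNonlinearAWeights:
    def test_exact_ratio_arithmetic(self):
        # fixed unit sd: ratio r maps to ct^(min(r, cap+2) - 2)
        u = np.array([0.0, 1.0, 2.0, 3.0, 50.0])
        w = nonlinearA_weights(u, ct=1.125, cap=5.0, sd=1.0)
        assert np.allclose(w.d, 1.125 ** np.array([-2.0, -1.0, 0.0, 1.0, 5.0]))

    def test_zero_effect_weight(self):
        w = nonlinearA_weights(np.array([0.0, 2.0, -2.0]), sd=1.0)
        assert w.d[0] == pytest.approx(1.125**-2)
        assert w.d[0] == pytest.approx(0.7901234567901234)

    def test_cap_value(self):
        w = nonlinearA_weights(np.array([50.0, 1.0]), sd=1.0)
        assert w.d[0] == pytest.approx(1.125**5)
        assert w.d[0] == pytest.approx(1.802032470703125)

    def test_internal_sd_is_std_of_effects(self):
        u = np.array([-2.0, 2.0])  # sd = 2, ratios = 1 -> ct^-1
        assert np.allclose(nonlinearA_weights(u).d, 1.125**-1)

    def test_monotone_below_cap(self):
        rng = np.random.default_rng(4)
        u = rng.normal(size=500)
        w = nonlinearA_weights(u).d
        order = np.argsort(np.abs(u))
        assert np.all(np.diff(w[order]) >= -1e-15)

    def test_degenerate_sd_warns_equal_weights(self):
        with pytest.warns(RuntimeWarning):
            w = nonlinearA_weights(np.zeros(5))
        assert np.all(w.d == 1.0)


class TestNormalizeWeights:
    def test_already_normalized_unchanged(self):
        d = SNPWeights(np.array([1.5, 0.5, 1.0]))
        out = normalize_weights(d, SNPWeights(np.ones(3)))
        assert np.allclose(out.d, d.d)

    def test_scalar_multiple_cancels(self):
        prev = SNPWeights(np.array([0.7, 1.3, 1.0]))
        out = normalize_weights(SNPWeights(2 * prev.d), prev)
        assert np.allclose(out.d, prev.d)

    def test_hand_example(self):
        prev = SNPWeights(np.ones(4))
        new = SNPWeights(np.array([2.0, 1.0, 1.0, 0.5]))
        out = normalize_weights(new, prev)
        assert np.allclose(out.d, [16 / 9, 8 / 9, 8 / 9, 4 / 9])
        assert out.d.sum() == pytest.approx(4.0)


@pytest.fixture(scope="module")
def pipeline_run(small_dataset):
    sim = small_dataset
    gq, _ = apply_qc(sim.genotypes)
    gq = impute_missing(gq, 5)
    design = build_design(sim.phenotypes, sim.ped)
    A = build_A(sim.ped)
    return sim, gq, run_wssgwas(
        design,
        sim.ped,
        gq,
        sim.config.vc,
        n_iter=3,
        a_inv=build_A_inverse(sim.ped),
        A22=extract_A22(A, list(gq.sample_ids)),
    )


class TestRunWssgwas:
    def test_first_iteration_is_unweighted(self, pipeline_run):
        _, _, res = pipeline_run
        assert np.all(res.iterations[0].weights.d == 1.0)

    def test_weight_trace_conserved(self, pipeline_run):
        _, gq, res = pipeline_run
        for it in res.iterations:
            assert it.weights.d.sum() == pytest.approx(gq.n_snps, abs=1e-8)

    def test_direct_and_maternal_effects_returned_each_iteration(self, pipeline_run):
        _, _, res = pipeline_run
        assert len(res.iterations) == 3
        for it in res.iterations:
            assert set(it.snp_effects) == {"direct", "maternal"}
            assert it.snp_effects["direct"].iteration == it.iteration

    def test_alpha_one_backsolve_identity_per_iteration(self):
        """Unblended full-rank G: Z u reproduces genotyped GEBVs exactly."""
        from conftest import random_pedigree

        rng = np.random.default_rng(11)
        ped = random_pedigree(60, seed=11, p_founder=0.3)
        import pandas as pd

        rows = []
        for i in range(len(ped)):
            d = ped.dam[i]
            if d < 0:
                continue
            rows.append(
                {"animal": ped.ids[i], "dam": ped.ids[d], "trait": float(rng.normal(4, 2))}
            )
        phenos = pd.DataFrame(rows)
        design = build_design(phenos, ped, fixed_effects=())
        # genotype the first 12 animals at 40 SNPs (m > n so G has full rank)
        g_ids = ped.ids[:12]
        m = 40
        p = rng.uniform(0.3, 0.5, m)
        counts = rng.binomial(2, p, size=(12, m)).astype(float)
        from tests_helpers import make_genotype_matrix

        g = make_genotype_matrix(counts, g_ids)
        vc = VarianceComponents(2.0, 1.0, 0.5, 4.0)
        # centering at the base-population frequencies keeps G full rank
        res = run_wssgwas(design, ped, g, vc, n_iter=3, alpha=1.0, beta=0.0, freqs=p)
        for it in res.iterations:
            gebv = it.solutions.a_hat.loc[g_ids].to_numpy()
            zu = res.Z @ it.snp_effects["direct"].u_hat
            assert np.abs(zu - gebv).max() < 1e-6

    def test_missing_genotypes_rejected(self, small_dataset):
        sim = small_dataset
        design = build_design(sim.phenotypes, sim.ped)
        with pytest.raises(ValueError, match="impute"):
            run_wssgwas(design, sim.ped, sim.genotypes, sim.config.vc)


def make_map(chroms, positions):
    return MarkerMap(
        pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(chroms))],
                "chromosome": chroms,
                "position_bp": positions,
                "allele_a": "A",
                "allele_b": "B",
            }
        )
    )


class TestWindowVariance:
    def test_zero_effects_zero_percent(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(10, 5))
        mm = make_map([1] * 5, [1, 2, 999_999, 1_000_000, 1_000_001])
        wt = window_variance(SnpEffectSet(np.zeros(5), "direct", 1), Z, mm, denom_variance=2.0)
        assert np.all(wt.table["pct_variance"] == 0)

    def test_window_edges(self):
        # bp 1_000_000 belongs to window 1, bp 1_000_001 starts window 2
        Z = np.zeros((3, 2))
        mm = make_map([1, 1], [1_000_000, 1_000_001])
        wt = window_variance(SnpEffectSet(np.zeros(2), "direct", 1), Z, mm, denom_variance=1.0)
        assert list(wt.table["window_start_bp"]) == [1, 1_000_001]
        assert list(wt.table["window_end_bp"]) == [1_000_000, 2_000_000]

    def test_single_snp_window_value(self):
        rng = np.random.default_rng(7)
        zcol = rng.normal(size=20)
        Z = zcol[:, None]
        c = 0.37
        wt = window_variance(SnpEffectSet(np.array([c]), "direct", 1), Z, make_map([1], [5000]), 2.0)
        expected = 100 * c**2 * np.var(zcol, ddof=1) / 2.0
        assert wt.table["pct_variance"][0] == pytest.approx(expected)

    def test_every_snp_in_exactly_one_window(self, pipeline_run):
        _, gq, res = pipeline_run
        wt = window_table_for_result(res, "direct")
        assert wt.table["n_snps"].sum() == gq.n_snps
        # windows non-overlapping within chromosome
        for _, grp in wt.table.groupby("chromosome"):
            starts = grp["window_start_bp"].to_numpy()
            ends = grp["window_end_bp"].to_numpy()
            assert np.all(starts[1:] > ends[:-1])

    def test_whole_genome_single_window_matches_dense(self):
        rng = np.random.default_rng(8)
        n, m = 15, 6
        Z = rng.normal(size=(n, m))
        u = rng.normal(size=m)
        mm = make_map([1] * m, np.arange(100, 100 + m))
        wt = window_variance(SnpEffectSet(u, "direct", 1), Z, mm, denom_variance=2.0)
        assert len(wt) == 1
        assert wt.table["pct_variance"][0] == pytest.approx(
            100 * np.var(Z @ u, ddof=1) / 2.0, abs=1e-8
        )

    def test_empty_rejected(self):
        mm = make_map([], [])
        with pytest.raises(ValueError):
            window_variance(SnpEffectSet(np.array([]), "direct", 1), np.zeros((3, 0)), mm, 1.0)


class TestTopWindows:
    def make_table(self, pcts):
        rows = [
            {
                "chromosome": 1 + i % 3,
                "window_start_bp": 1 + (i // 3) * 1_000_000,
                "window_end_bp": (i // 3 + 1) * 1_000_000,
                "first_snp_bp": 1,
                "last_snp_bp": 2,
                "n_snps": 1,
                "pct_variance": p,
            }
            for i, p in enumerate(pcts)
        ]
        from wssgwas import WindowTable

        return WindowTable(pd.DataFrame(rows))

    def test_k1_is_max(self):
        wt = self.make_table([0.1, 0.9, 0.3])
        assert top_windows(wt, 1).table["pct_variance"].tolist() == [0.9]

    def test_ties_in_genome_order(self):
        wt = self.make_table([0.5] * 6)
        out = top_windows(wt, 3).table
        assert out["chromosome"].tolist() == [1, 1, 2]

    def test_k10_of_30_known_values(self):
        rng = np.random.default_rng(9)
        pcts = rng.permutation(np.linspace(0.01, 0.30, 30))
        wt = self.make_table(list(pcts))
        out = top_windows(wt, 10).table["pct_variance"].to_numpy()
        assert np.allclose(np.sort(out)[::-1], np.sort(pcts)[::-1][:10])

    def test_k_exceeding_warns_returns_all(self):
        wt = self.make_table([0.1, 0.2])
        with pytest.warns(RuntimeWarning):
            out = top_windows(wt, 10)
        assert len(out) == 2

    def test_permuting_snp_order_permutes_effects(self):
        """No positional dependence: weights follow the SNP, not its index."""
        rng = np.random.default_rng(10)
        u = rng.normal(size=30)
        w = nonlinearA_weights(u).d
        perm = rng.permutation(30)
        w_perm = nonlinearA_weights(u[perm]).d
        assert np.allclose(w_perm, w[perm])
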