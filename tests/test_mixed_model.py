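"""Maternal-effects MME: design assembly, solving, and REML components."""

import warnings

import numpy as np
import pandas as pd
import pytest

from wssgwas import (
    VarianceComponents,
    adjust_weaning_weight,
    build_A,
    build_A_inverse,
    build_design,
    estimate_varcomps_reml,
    extract_A22,
    solve_mme,
    sort_pedigree,
    Pedigree,
)
from wssgwas.relmat import single_step_h_inverse
from wssgwas.simulate import SimConfig, simulate_dataset


class TestAdjustWeaningWeight:
    def test_printed_formula(self):
        assert adjust_weaning_weight(22, 4, 100) == pytest.approx(16.2)

    def test_identity_at_90_days(self):
        for g in (0.1, 0.2, 0.35):
            assert adjust_weaning_weight(4 + g * 90, 4, 90) == pytest.approx(g * 90)

    def test_zero_gain(self):
        assert adjust_weaning_weight(4, 4, 50) == 0.0

    def test_vectorized(self):
        out = adjust_weaning_weight(np.array([22.0, 22.0]), np.array([4.0, 4.0]), np.array([100.0, 90.0]))
        assert np.allclose(out, [16.2, 18.0])

    def test_nonpositive_age(self):
        with pytest.raises(ValueError):
            adjust_weaning_weight(22, 4, 0)


def tiny_phenos(ped, rng, n_extra_effects=True):
    rows = []
    for i in range(len(ped)):
        d = ped.dam[i]
        if d < 0:
            continue
        rows.append(
            {
                "animal": ped.ids[i],
                "dam": ped.ids[d],
                "sex": rng.choice(["m", "f"]),
                "birth_type": rng.choice(["single", "twin"]),
                "herd": rng.choice(["h1", "h2"]),
                "birth_year": rng.choice(["y1", "y2"]),
                "dam_age": rng.choice(["2", "3"]),
                "trait": float(rng.normal(4, 2)),
            }
        )
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_intercept_only(self, trio):
        ph = pd.DataFrame({"animal": ["O"], "dam": ["D"], "trait": [5.0]})
        d = build_design(ph, trio, fixed_effects=(), trait="trait")
        assert d.X.shape == (1, 1) and d.X[0, 0] == 1.0

    def test_incidence_selects_animal_and_dam(self, trio):
        ph = pd.DataFrame({"animal": ["O"], "dam": ["D"], "trait": [5.0]})
        d = build_design(ph, trio, fixed_effects=())
        o, dd = trio.index_of("O"), trio.index_of("D")
        assert d.Zd[0, o] == 1 and d.Zd.sum() == 1
        assert d.S[0, dd] == 1 and d.S.sum() == 1
        assert d.W.shape[1] == 1 and d.W[0, 0] == 1

    def test_dummy_column_count(self, trio):
        ph = pd.DataFrame(
            {
                "animal": ["O", "O2", "O3"],
                "dam": ["D", "D", "D"],
                "e1": ["a", "b", "a"],
                "e2": ["x", "y", "z"],
                "trait": [1.0, 2.0, 3.0],
            }
        )
        ped = sort_pedigree(
            Pedigree.from_records(
                [("S", None, None), ("D", None, None), ("O", "S", "D"), ("O2", "S", "D"), ("O3", "S", "D")]
            )
        )
        d = build_design(ph, ped, fixed_effects=("e1", "e2"))
        assert d.X.shape[1] == 1 + 1 + 2  # intercept + (2-1) + (3-1)

    def test_unknown_dam_rejected(self, trio):
        ph = pd.DataFrame({"animal": ["O"], "dam": ["0"], "trait": [5.0]})
        with pytest.raises(ValueError, match="dam"):
            build_design(ph, trio, fixed_effects=())


def dense_gls_solutions(design, K, vc):
    """Independent oracle: explicit V = Zd K s2a Zd' + S K s2m S' + W s2p W' + I s2e."""
    y, X = design.y, design.X
    Zd, W, S = design.Zd.toarray(), design.W.toarray(), design.S.toarray()
    V = (
        vc.sigma2_a * Zd @ K @ Zd.T
        + vc.sigma2_m * S @ K @ S.T
        + vc.sigma2_p * W @ W.T
        + vc.sigma2_e * np.eye(len(y))
    )
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    Py = Vi @ (y - X @ b)
    return b, vc.sigma2_a * K @ Zd.T @ Py, vc.sigma2_m * K @ S.T @ Py, vc.sigma2_p * W.T @ Py


@pytest.fixture(scope="module")
def ped_and_phenos():
    from conftest import random_pedigree

    ped = random_pedigree(40, seed=21, p_founder=0.3)
    rng = np.random.default_rng(22)
    return ped, tiny_phenos(ped, rng)


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(n_founders=80, n_generations=3, offspring_per_mating=4, n_snps=60, seed=31)
    return simulate_dataset(cfg)


class TestSolveMME:
    def test_matches_dense_gls_oracle(self, ped_and_phenos):
        ped, ph = ped_and_phenos
        design = build_design(ph, ped)
        K = build_A(ped).values
        vc = VarianceComponents(2.0, 1.0, 0.5, 4.0)
        sol = solve_mme(design, build_A_inverse(ped), vc)
        b, a, m, p = dense_gls_solutions(design, K, vc)
        assert np.abs(sol.fixed_solutions.to_numpy() - b).max() < 1e-6
        assert np.abs(sol.a_hat.to_numpy() - a).max() < 1e-6
        assert np.abs(sol.m_hat.to_numpy() - m).max() < 1e-6
        assert np.abs(sol.p_hat.to_numpy() - p).max() < 1e-6

    def test_residual_orthogonal_to_fixed_effects(self, ped_and_phenos):
        ped, ph = ped_and_phenos
        design = build_design(ph, ped)
        vc = VarianceComponents(2.0, 1.0, 0.5, 4.0)
        sol = solve_mme(design, build_A_inverse(ped), vc)
        resid = (
            design.y
            - design.X @ sol.fixed_solutions.to_numpy()
            - design.Zd @ sol.a_hat.to_numpy()
            - design.W @ sol.p_hat.to_numpy()
            - design.S @ sol.m_hat.to_numpy()
        )
        assert np.abs(design.X.T @ resid).max() < 1e-6

    def test_infinite_shrinkage_zeroes_gebvs(self, ped_and_phenos):
        ped, ph = ped_and_phenos
        design = build_design(ph, ped)
        vc = VarianceComponents(1e-8 * 4.0, 1.0, 0.5, 4.0)  # lambda_a = 4e8
        sol = solve_mme(design, build_A_inverse(ped), vc)
        assert np.abs(sol.a_hat.to_numpy()).max() < 1e-4

    def test_single_step_equals_pedigree_blup_when_G_is_A22(self, ped_and_phenos):
        ped, ph = ped_and_phenos
        design = build_design(ph, ped)
        A = build_A(ped)
        a_inv = build_A_inverse(ped)
        g_ids = [ped.ids[i] for i in range(0, len(ped), 3)]
        A22 = extract_A22(A, g_ids)
        H_inv, _ = single_step_h_inverse(a_inv, A22, A22, g_ids, alpha=1.0, beta=0.0)
        vc = VarianceComponents(2.0, 1.0, 0.5, 4.0)
        s_a = solve_mme(design, a_inv, vc)
        s_h = solve_mme(design, H_inv, vc)
        assert np.abs(s_a.a_hat.to_numpy() - s_h.a_hat.to_numpy()).max() < 1e-8
        assert np.abs(s_a.m_hat.to_numpy() - s_h.m_hat.to_numpy()).max() < 1e-8


class TestREML:
    def test_em_loglik_nondecreasing(self, sim):
        design = build_design(sim.phenotypes, sim.ped)
        a_inv = build_A_inverse(sim.ped, sparse_out=True)
        vy = float(np.var(design.y))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, info = estimate_varcomps_reml(
                design,
                a_inv,
                VarianceComponents(0.3 * vy, 0.15 * vy, 0.1 * vy, 0.45 * vy),
                max_iter=25,
                tol=1e-10,
                return_info=True,
            )
        assert np.all(np.diff(info.loglik) > -1e-7)

    def test_scale_equivariance(self, sim):
        design = build_design(sim.phenotypes, sim.ped)
        a_inv = build_A_inverse(sim.ped, sparse_out=True)
        init = VarianceComponents(1.0, 1.0, 1.0, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vc1 = estimate_varcomps_reml(design, a_inv, init, max_iter=10, tol=1e-12)
        design2 = build_design(sim.phenotypes.assign(trait=3.0 * sim.phenotypes["trait"]), sim.ped)
        init2 = VarianceComponents(9.0, 9.0, 9.0, 9.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vc2 = estimate_varcomps_reml(design2, a_inv, init2, max_iter=10, tol=1e-12)
        assert np.allclose(vc2.as_array(), 9.0 * vc1.as_array(), rtol=1e-6)

    def test_em_and_ai_reach_same_stationary_point(self, sim):
        design = build_design(sim.phenotypes, sim.ped)
        a_inv = build_A_inverse(sim.ped, sparse_out=True)
        vy = float(np.var(design.y))
        init = VarianceComponents(0.3 * vy, 0.15 * vy, 0.1 * vy, 0.45 * vy)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vc_ai, info_ai = estimate_varcomps_reml(
                design, a_inv, init, max_iter=100, tol=1e-8, method="ai", return_info=True
            )
            # one EM sweep from the AI solution barely moves: shared fixed point
            vc_em = estimate_varcomps_reml(
                design, a_inv, vc_ai, max_iter=1, tol=0.0, method="em"
            )
        rel = np.abs(vc_em.as_array() - vc_ai.as_array()) / vc_ai.as_array()
        assert rel.max() < 0.02

    def test_nonpositive_init_rejected(self, sim):
        design = build_design(sim.phenotypes, sim.ped)
        a_inv = build_A_inverse(sim.ped, sparse_out=True)
        with pytest.raises(ValueError):
            estimate_varcomps_reml(design, a_inv, VarianceComponents(0.0, 1, 1, 1), max_iter=1)
        with pytest.raises(ValueError):
            VarianceComponents(1, 1, 1, 0.0)
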