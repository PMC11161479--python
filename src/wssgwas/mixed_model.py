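"""Maternal-effects animal model: design matrices, Henderson's
mixed-model equations and REML variance components.

The model for one trait is

    y = X b + Z a + W p + S m + e

with a ~ N(0, K sigma2_a) the direct additive effects, m ~ N(0, K
sigma2_m) the maternal genetic effects (both spanning every pedigree
animal, with K = A under pedigree BLUP or H under single-step),
p ~ N(0, I sigma2_p) the maternal permanent-environment effects of the
dams, and e ~ N(0, I sigma2_e).  The direct-maternal genetic covariance
is fixed at zero.  Fixed effects are categorical (sex, birth type, herd,
birth year, dam age class), dummy-coded with an intercept and the first
sorted level of each effect dropped for identifiability.

Weaning weights are pre-adjusted to a constant age of 90 days from the
recorded weight, birth weight and age at weighing.

REML uses EM updates (monotone in the restricted likelihood) on the MME;
traces of the inverse coefficient matrix are exact, from a sparse LU
factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from ._sparse_inv import HAVE_NUMBA, factor_spd, logdet_from_factor, selected_inverse
from .pedigree import Pedigree, RelationshipMatrix

DEFAULT_FIXED_EFFECTS = ("sex", "birth_type", "herd", "birth_year", "dam_age")


def adjust_weaning_weight(ww_raw: float, bw: float, age_days: float) -> float:
    """Adjust a weaning weight to 90 days: ((WW - BW) / age) * 90.

    Accepts scalars or aligned arrays.
    """
    age_days = np.asarray(age_days, dtype=float)
    if np.any(age_days <= 0):
        raise ValueError("age at weaning must be positive")
    out = (np.asarray(ww_raw, dtype=float) - np.asarray(bw, dtype=float)) / age_days * 90.0
    return float(out) if out.ndim == 0 else out


@dataclass
class VarianceComponents:
    """Variances (kg^2) of the four random terms of the maternal model."""

    sigma2_a: float  # direct additive genetic
    sigma2_m: float  # maternal genetic
    sigma2_p: float  # maternal permanent environment
    sigma2_e: float  # residual

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_m", "sigma2_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma2_a, self.sigma2_m, self.sigma2_p, self.sigma2_e])


@dataclass
class DesignMatrices:
    """Model terms for one trait: y, X and the three incidence matrices."""

    y: np.ndarray
    X: np.ndarray
    Zd: sparse.csr_matrix  # records -> animal direct effect
    W: sparse.csr_matrix  # records -> dam permanent environment
    S: sparse.csr_matrix  # records -> dam maternal genetic effect
    fixed_labels: list[str]  # column labels of X
    animal_ids: list[str]  # order of the a / m blocks (pedigree order)
    dam_ids: list[str]  # order of the p block

    @property
    def n_records(self) -> int:
        return len(self.y)


@dataclass
class SolutionSet:
    """Solutions of the MME, keyed by original labels."""

    fixed_solutions: pd.Series  # indexed by X column label
    a_hat: pd.Series  # direct GEBV per pedigree animal
    m_hat: pd.Series  # maternal GEBV per pedigree animal
    p_hat: pd.Series  # permanent environment per dam

    def gebv(self, ids: list[str], effect: str = "direct") -> np.ndarray:
        vec = self.a_hat if effect == "direct" else self.m_hat
        return vec.loc[list(ids)].to_numpy()


def build_design(
    phenos: pd.DataFrame,
    ped: Pedigree,
    fixed_effects: tuple[str, ...] = DEFAULT_FIXED_EFFECTS,
    trait: str = "trait",
) -> DesignMatrices:
    """Assemble y, X, Zd, W, S from a phenotype table.

    Every record's animal and dam must resolve in the (sorted) pedigree;
    a maternal model needs a known dam for each record.  X carries an
    intercept plus drop-first dummy coding of each categorical effect.
    """
    phenos = phenos.reset_index(drop=True)
    n = len(phenos)
    if n == 0:
        raise ValueError("empty phenotype table")
    y = phenos[trait].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite trait values present")

    cols = [np.ones((n, 1))]
    labels = ["intercept"]
    for eff in fixed_effects:
        if eff not in phenos.columns:
            raise KeyError(f"fixed effect column {eff!r} missing from phenotypes")
        levels = sorted(phenos[eff].astype(str).unique())
        for lev in levels[1:]:  # first level absorbed by the intercept
            cols.append((phenos[eff].astype(str) == lev).to_numpy(dtype=float)[:, None])
            labels.append(f"{eff}:{lev}")
    X = np.hstack(cols)

    try:
        animal_idx = np.array([ped.index_of(a) for a in phenos["animal"].astype(str)])
    except KeyError as exc:
        raise KeyError(f"record animal {exc.args[0]!r} not in pedigree") from exc
    dams = phenos["dam"].astype(str)
    if (dams.isin(["0", "", "nan", "None"])).any():
        bad = phenos.loc[dams.isin(["0", "", "nan", "None"]), "animal"].iloc[0]
        raise ValueError(f"record for animal {bad!r} has unknown dam; maternal model requires known dams")
    try:
        dam_idx = np.array([ped.index_of(d) for d in dams])
    except KeyError as exc:
        raise KeyError(f"record dam {exc.args[0]!r} not in pedigree") from exc

    q = len(ped)
    rows = np.arange(n)
    Zd = sparse.csr_matrix((np.ones(n), (rows, animal_idx)), shape=(n, q))
    S = sparse.csr_matrix((np.ones(n), (rows, dam_idx)), shape=(n, q))
    # permanent environment: one column per distinct dam, pedigree order
    uniq = np.unique(dam_idx)
    dam_col = {d: j for j, d in enumerate(uniq)}
    W = sparse.csr_matrix(
        (np.ones(n), (rows, np.array([dam_col[d] for d in dam_idx]))), shape=(n, len(uniq))
    )
    return DesignMatrices(
        y=y,
        X=X,
        Zd=Zd,
        W=W,
        S=S,
        fixed_labels=labels,
        animal_ids=list(ped.ids),
        dam_ids=[ped.ids[d] for d in uniq],
    )


def _kinv_csr(K_inv: RelationshipMatrix | np.ndarray | sparse.spmatrix) -> sparse.csr_matrix:
    if isinstance(K_inv, RelationshipMatrix):
        K_inv = K_inv.values
    if sparse.issparse(K_inv):
        return K_inv.tocsr()
    arr = np.asarray(K_inv, dtype=float)
    return sparse.csr_matrix(arr)


class _MMESystem:
    """Cached cross-products for repeated assembly at varying variance ratios.

    Equation ordering: [fixed b | direct a | permanent-env p | maternal m].
    """

    def __init__(self, design: DesignMatrices, K_inv) -> None:
        self.design = design
        self.Kinv = _kinv_csr(K_inv)
        q = len(design.animal_ids)
        if self.Kinv.shape != (q, q):
            raise ValueError(f"K_inv shape {self.Kinv.shape} does not span the {q} pedigree animals")
        X = sparse.csr_matrix(design.X)
        terms = [X, design.Zd, design.W, design.S]
        self.block_sizes = [t.shape[1] for t in terms]
        self.offsets = np.concatenate([[0], np.cumsum(self.block_sizes)])
        Wall = sparse.hstack(terms).tocsr()
        self.base = (Wall.T @ Wall).tocsc()
        self.rhs = Wall.T @ design.y
        self.n_eq = Wall.shape[1]
        self.rank_X = int(np.linalg.matrix_rank(design.X))
        if self.rank_X < design.X.shape[1]:
            raise np.linalg.LinAlgError(
                "fixed-effect design is rank deficient beyond the dropped-level convention"
            )
        # precompute the random-structure augmentations
        p0, p1, p2, p3, p4 = self.offsets
        n_eq = self.n_eq
        ix = sparse.coo_matrix(self.Kinv)
        self.aug_a = sparse.coo_matrix(
            (ix.data, (ix.row + p1, ix.col + p1)), shape=(n_eq, n_eq)
        ).tocsc()
        self.aug_m = sparse.coo_matrix(
            (ix.data, (ix.row + p3, ix.col + p3)), shape=(n_eq, n_eq)
        ).tocsc()
        pe = np.arange(p2, p3)
        self.aug_p = sparse.coo_matrix(
            (np.ones(len(pe)), (pe, pe)), shape=(n_eq, n_eq)
        ).tocsc()
        self.pe_eqs = pe
        self.kinv_coo = (ix.row.astype(np.int64), ix.col.astype(np.int64), ix.data.copy())
        self.slice_a = slice(p1, p2)
        self.slice_p = slice(p2, p3)
        self.slice_m = slice(p3, p4)
        self.slice_b = slice(p0, p1)

    def assemble(self, vc: VarianceComponents) -> sparse.csc_matrix:
        lam_a = vc.sigma2_e / vc.sigma2_a
        lam_m = vc.sigma2_e / vc.sigma2_m
        lam_p = vc.sigma2_e / vc.sigma2_p
        return self.base + lam_a * self.aug_a + lam_m * self.aug_m + lam_p * self.aug_p

    def solve(self, vc: VarianceComponents):
        M = self.assemble(vc)
        try:
            lu = factor_spd(M)
        except RuntimeError as exc:  # SuperLU raises RuntimeError on singularity
            raise np.linalg.LinAlgError(f"singular MME coefficient matrix: {exc}") from exc
        sol = lu.solve(self.rhs)
        return sol, lu

    def inverse_traces(self, lu) -> tuple[float, float, float]:
        """(tr(K^-1 C_aa), tr(K^-1 C_mm), tr(C_pp)) with C = M^-1.

        Uses the Takahashi selected inverse on the factor when numba is
        available; every needed entry lies on the MME sparsity pattern.
        Falls back to a dense inverse otherwise.
        """
        kr, kc, kv = self.kinv_coo
        p1 = self.offsets[1]
        p3 = self.offsets[3]
        if HAVE_NUMBA:
            Z, pr = selected_inverse(lu)
            tr_a = float(np.sum(kv * Z[pr[p1 + kr], pr[p1 + kc]]))
            tr_m = float(np.sum(kv * Z[pr[p3 + kr], pr[p3 + kc]]))
            pe = pr[self.pe_eqs]
            tr_p = float(np.sum(Z[pe, pe]))
        else:  # pragma: no cover - exercised only without numba
            Minv = lu.solve(np.eye(self.n_eq))
            tr_a = float(np.sum(kv * Minv[p1 + kr, p1 + kc]))
            tr_m = float(np.sum(kv * Minv[p3 + kr, p3 + kc]))
            tr_p = float(np.trace(Minv[self.slice_p, self.slice_p]))
        return tr_a, tr_m, tr_p

    def to_solution_set(self, sol: np.ndarray) -> SolutionSet:
        d = self.design
        return SolutionSet(
            fixed_solutions=pd.Series(sol[self.slice_b], index=d.fixed_labels),
            a_hat=pd.Series(sol[self.slice_a], index=d.animal_ids),
            m_hat=pd.Series(sol[self.slice_m], index=d.animal_ids),
            p_hat=pd.Series(sol[self.slice_p], index=d.dam_ids),
        )


def solve_mme(
    design: DesignMatrices,
    K_inv: RelationshipMatrix | np.ndarray | sparse.spmatrix,
    vc: VarianceComponents,
) -> SolutionSet:
    """Solve Henderson's MME for the maternal-effects model.

    ``K_inv`` is A^-1 for pedigree BLUP or H^-1 for single-step; it must
    span every pedigree animal in pedigree order.
    """
    if min(vc.sigma2_a, vc.sigma2_m, vc.sigma2_p) <= 0:
        raise ValueError("solve_mme requires strictly positive variance components")
    sys = _MMESystem(design, K_inv)
    sol, lu = sys.solve(vc)
    # contract: MME residual small relative to the RHS
    M = sys.assemble(vc)
    res = np.linalg.norm(M @ sol - sys.rhs)
    rhs_norm = np.linalg.norm(sys.rhs)
    if rhs_norm > 0 and res > 1e-8 * max(rhs_norm, 1.0):
        sol = sol + lu.solve(sys.rhs - M @ sol)  # one refinement step
    return sys.to_solution_set(sol)


@dataclass
class REMLInfo:
    converged: bool
    n_iter: int
    loglik: list[float]
    method: str = "em"


def _em_update(sys: "_MMESystem", vc: VarianceComponents, sol, tr_a, tr_m, tr_p, yty) -> np.ndarray:
    n = len(sys.design.y)
    q = len(sys.design.animal_ids)
    n_dam = len(sys.design.dam_ids)
    a_hat = sol[sys.slice_a]
    m_hat = sol[sys.slice_m]
    p_hat = sol[sys.slice_p]
    se = vc.sigma2_e
    return np.array(
        [
            (float(a_hat @ (sys.Kinv @ a_hat)) + se * tr_a) / q,
            (float(m_hat @ (sys.Kinv @ m_hat)) + se * tr_m) / q,
            (float(p_hat @ p_hat) + se * tr_p) / n_dam,
            (yty - float(sol @ sys.rhs)) / (n - sys.rank_X),
        ]
    )


def _scores_and_ai(sys: "_MMESystem", vc: VarianceComponents, sol, lu, tr_a, tr_m, tr_p):
    """REML gradient and average-information matrix for (a, m, p, e).

    Uses the standard MME identities: for a genetic term u with structure
    K, tr(P V_u) = q/s2 - s2e tr(K^-1 C_uu)/s2^2 and
    y'P V_u P y = u' K^-1 u / s2^2; the AI matrix is (1/2) f_i' P f_j with
    working vectors f_a = Zd a/s2a, f_m = S m/s2m, f_p = W p/s2p,
    f_e = e/s2e, and P g evaluated through one MME solve per vector.
    """
    d = sys.design
    n = len(d.y)
    q = len(d.animal_ids)
    n_dam = len(d.dam_ids)
    sa, sm, sp, se = vc.as_array()
    a_hat = sol[sys.slice_a]
    m_hat = sol[sys.slice_m]
    p_hat = sol[sys.slice_p]
    b_hat = sol[sys.slice_b]
    e_hat = d.y - d.X @ b_hat - d.Zd @ a_hat - d.W @ p_hat - d.S @ m_hat

    quad_a = float(a_hat @ (sys.Kinv @ a_hat))
    quad_m = float(m_hat @ (sys.Kinv @ m_hat))
    quad_p = float(p_hat @ p_hat)
    lam = [se / sa, se / sm, se / sp]
    tr_P = (n - sys.n_eq + lam[0] * tr_a + lam[1] * tr_m + lam[2] * tr_p) / se
    # y'P V_u P y = u'K^-1 u / s2_u^2 and tr(P V_u) = (q - lam_u tr(K^-1 C_uu)) / s2_u
    score = 0.5 * np.array(
        [
            (quad_a + se * tr_a) / sa**2 - q / sa,
            (quad_m + se * tr_m) / sm**2 - q / sm,
            (quad_p + se * tr_p) / sp**2 - n_dam / sp,
            float(e_hat @ e_hat) / se**2 - tr_P,
        ]
    )

    f = [
        (d.Zd @ a_hat) / sa,
        (d.S @ m_hat) / sm,
        (d.W @ p_hat) / sp,
        e_hat / se,
    ]
    Wmats = [sparse.csr_matrix(d.X), d.Zd, d.W, d.S]
    Pf = []
    for g in f:
        wg = np.concatenate([Wm.T @ g for Wm in Wmats])
        t = lu.solve(wg)
        wt = (
            d.X @ t[sys.slice_b]
            + d.Zd @ t[sys.slice_a]
            + d.W @ t[sys.slice_p]
            + d.S @ t[sys.slice_m]
        )
        Pf.append((g - wt) / se)
    AI = np.empty((4, 4))
    for i in range(4):
        for j in range(i, 4):
            AI[i, j] = AI[j, i] = 0.5 * float(f[i] @ Pf[j])
    return score, AI


def estimate_varcomps_reml(
    design: DesignMatrices,
    K_inv: RelationshipMatrix | np.ndarray | sparse.spmatrix,
    init: VarianceComponents,
    max_iter: int = 200,
    tol: float = 1e-4,
    method: str = "em",
    return_info: bool = False,
):
    """REML for (sigma2_a, sigma2_m, sigma2_p, sigma2_e).

    ``method="em"`` (the baseline) iterates the monotone EM updates

        sigma2_a <- (a' K^-1 a + sigma2_e tr(K^-1 C_aa)) / q
        sigma2_m <- (m' K^-1 m + sigma2_e tr(K^-1 C_mm)) / q
        sigma2_p <- (p' p     + sigma2_e tr(C_pp)) / n_dams
        sigma2_e <- (y'y - sol' rhs) / (n - rank X)

    with C = M^-1 the inverse MME coefficient matrix; the restricted
    likelihood is non-decreasing across sweeps.  ``method="ai"`` takes
    average-information Newton steps from the exact REML gradient and
    falls back to an EM sweep whenever the AI update fails or leaves the
    parameter space; both converge to the same stationary point, AI in
    far fewer iterations.  All traces are exact (Takahashi selected
    inverse of the sparse factor).  Estimates drifting to zero are pinned
    at a floor of 1e-8 times the phenotypic variance.
    """
    if min(init.sigma2_a, init.sigma2_m, init.sigma2_p, init.sigma2_e) <= 0:
        raise ValueError("REML starting values must be strictly positive")
    if method not in ("em", "ai"):
        raise ValueError(f"method must be 'em' or 'ai', got {method!r}")
    sys = _MMESystem(design, K_inv)
    y = design.y
    n = len(y)
    q = len(design.animal_ids)
    n_dam = len(design.dam_ids)
    yty = float(y @ y)
    floor = 1e-8 * float(np.var(y))
    # log|K| is constant across iterations; needed only for an absolute logL
    logdet_kinv = logdet_from_factor(factor_spd(sys.Kinv.tocsc()))

    vc = VarianceComponents(*init.as_array())
    logliks: list[float] = []
    converged = False
    for it in range(max_iter):
        sol, lu = sys.solve(vc)
        tr_a, tr_m, tr_p = sys.inverse_traces(lu)

        # restricted log-likelihood at the *current* vc (monotonicity check)
        se = vc.sigma2_e
        log_C = logdet_from_factor(lu) - sys.n_eq * np.log(se)
        log_G = (
            q * np.log(vc.sigma2_a)
            + q * np.log(vc.sigma2_m)
            - 2.0 * logdet_kinv
            + n_dam * np.log(vc.sigma2_p)
        )
        yPy = (yty - float(sol @ sys.rhs)) / se
        logliks.append(-0.5 * (n * np.log(se) + log_G + log_C + yPy))

        old = vc.as_array()
        new = None
        if method == "ai" and it > 0:  # first sweep is EM, stabilising the start
            score, AI = _scores_and_ai(sys, vc, sol, lu, tr_a, tr_m, tr_p)
            try:
                delta = np.linalg.solve(AI, score)
                cand = old + delta
                # step-halve into the parameter space
                for _ in range(12):
                    if np.all(cand > 0):
                        break
                    delta *= 0.5
                    cand = old + delta
                if np.all(cand > 0) and np.all(np.isfinite(cand)):
                    new = cand
            except np.linalg.LinAlgError:
                new = None
        if new is None:
            new = _em_update(sys, vc, sol, tr_a, tr_m, tr_p, yty)
        new = np.maximum(new, floor)
        rel = np.max(np.abs(new - old) / np.maximum(old, floor))
        vc = VarianceComponents(*new)
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"REML ({method}) did not converge in {max_iter} iterations "
            f"(last relative change {rel:.2e})",
            RuntimeWarning,
        )
    info = REMLInfo(converged=converged, n_iter=it + 1, loglik=logliks, method=method)
    return (vc, info) if return_info else vc
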