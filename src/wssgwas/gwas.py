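"""Iterative weighted single-step GWAS and window variance decomposition.

The engine alternates between single-step GBLUP and SNP re-weighting:

1. start with equal SNP weights, D = I;
2. build G = Z D Z' / sum 2p(1-p), blend with A22, assemble H^-1 and
   solve the maternal-effects MME for GEBVs;
3. convert the genotyped animals' GEBVs to SNP effects,
   u_hat = lambda D Z' G^-1 a_hat_g  (lambda = 1 / sum 2p(1-p));
4. re-weight each SNP with the nonlinearA rule
   d_i = CT^(|u_i|/sd(u) - 2), CT = 1.125, exponent capped at 5;
5. rescale the weights so their sum (the trace of D) is unchanged,
   keeping the total genetic variance constant;
6. rebuild G with the new D and loop (3 iterations by default).

Afterwards each genetic variance component is decomposed over fixed,
non-overlapping 1-Mb windows: the window's share is
100 * var(sum_j Z_j u_j) / sigma2, the variance taken across genotyped
individuals, and the top-k windows are reported per effect type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .genotypes import GenotypeMatrix, MarkerMap, allele_frequencies, center_gene_content
from .mixed_model import DesignMatrices, SolutionSet, VarianceComponents, solve_mme
from .pedigree import Pedigree, RelationshipMatrix, build_A, build_A_inverse, extract_A22
from .relmat import SNPWeights, blend_G, build_G, invert_spd, scaling_denominator, single_step_h_inverse

DEFAULT_CT = 1.125
DEFAULT_CAP = 5.0
DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_TOP_K = 10


@dataclass
class SnpEffectSet:
    """Per-SNP allele-substitution effects for one effect type."""

    u_hat: np.ndarray  # kg per allele-count unit
    effect_type: str  # "direct" | "maternal"
    iteration: int

    def __post_init__(self) -> None:
        self.u_hat = np.asarray(self.u_hat, dtype=np.float64)
        if not np.all(np.isfinite(self.u_hat)):
            raise ValueError("non-finite SNP effects")
        if self.effect_type not in ("direct", "maternal"):
            raise ValueError(f"unknown effect type {self.effect_type!r}")


@dataclass
class WindowTable:
    """Per-window variance shares; one row per non-empty 1-Mb bin."""

    table: pd.DataFrame

    COLUMNS = (
        "chromosome",
        "window_start_bp",
        "window_end_bp",
        "first_snp_bp",
        "last_snp_bp",
        "n_snps",
        "pct_variance",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"window table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


def backsolve_snp_effects(
    Z: np.ndarray,
    d: SNPWeights,
    G_used: RelationshipMatrix | np.ndarray,
    gebv_genotyped: np.ndarray,
    lam: float,
    effect_type: str = "direct",
    iteration: int = 1,
) -> SnpEffectSet:
    """SNP effects from genotyped GEBVs: u = lam * D Z' G^-1 a_g.

    ``G_used`` is the (blended) genomic matrix whose inverse entered
    H^-1; ``lam`` is 1 / sum 2p(1-p) from the same frequencies as Z.
    """
    G_vals = G_used.values if isinstance(G_used, RelationshipMatrix) else np.asarray(G_used)
    gebv = np.asarray(gebv_genotyped, dtype=float)
    if G_vals.shape[0] != len(gebv):
        raise ValueError("GEBV vector does not match G dimension")
    try:
        c, low = linalg.cho_factor(G_vals)
        g_inv_a = linalg.cho_solve((c, low), gebv)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("G is singular; blend with A22 before back-solving") from exc
    u = lam * d.d * (Z.T @ g_inv_a)
    return SnpEffectSet(u_hat=u, effect_type=effect_type, iteration=iteration)


def nonlinearA_weights(
    u_hat: SnpEffectSet | np.ndarray,
    ct: float = DEFAULT_CT,
    cap: float = DEFAULT_CAP,
    iteration: int = 0,
    sd: float | None = None,
) -> SNPWeights:
    """nonlinearA re-weighting: d_i = ct^(|u_i|/sd(u) - 2), exponent capped.

    The departure |u_i|/sd(u) - 2 is limited from above at ``cap`` (so
    the largest weight is ct^cap); weights grow monotonically with |u_i|
    below the cap.  ``sd`` defaults to the standard deviation of the
    effects themselves.  A degenerate sd of zero yields all-ones weights.
    """
    u = u_hat.u_hat if isinstance(u_hat, SnpEffectSet) else np.asarray(u_hat, dtype=float)
    sd = float(np.std(u)) if sd is None else float(sd)
    if sd == 0.0:
        warnings.warn("sd of SNP effects is zero; returning equal weights", RuntimeWarning)
        return SNPWeights(d=np.ones(len(u)), iteration=iteration)
    expo = np.minimum(np.abs(u) / sd, cap + 2.0) - 2.0
    return SNPWeights(d=np.power(ct, expo), iteration=iteration)


def normalize_weights(d_new: SNPWeights, d_prev: SNPWeights) -> SNPWeights:
    """Rescale d_new so its sum (trace of D) equals d_prev's, keeping the
    total genetic variance constant across iterations."""
    if len(d_new) != len(d_prev):
        raise ValueError("weight vectors differ in length")
    s_new = float(np.sum(d_new.d))
    s_prev = float(np.sum(d_prev.d))
    if s_new <= 0 or s_prev <= 0:
        raise ValueError("weight sums must be positive")
    return SNPWeights(d=d_new.d * (s_prev / s_new), iteration=d_new.iteration)


@dataclass
class WssgwasIteration:
    """All artifacts retained from one weighting iteration."""

    iteration: int
    weights: SNPWeights  # D(t) used to build G(t)
    solutions: SolutionSet
    snp_effects: dict[str, SnpEffectSet]  # keyed by effect type
    G_omega: RelationshipMatrix


@dataclass
class WssgwasResult:
    iterations: list[WssgwasIteration]
    Z: np.ndarray
    freqs: np.ndarray
    lam: float
    genotyped_ids: list[str]
    markers: MarkerMap
    vc: VarianceComponents

    def final(self) -> WssgwasIteration:
        return self.iterations[-1]


def run_wssgwas(
    design: DesignMatrices,
    ped: Pedigree,
    genotypes: GenotypeMatrix,
    vc: VarianceComponents,
    n_iter: int = 3,
    alpha: float = 0.95,
    beta: float = 0.05,
    ct: float = DEFAULT_CT,
    cap: float = DEFAULT_CAP,
    weight_source: str = "direct",
    a_inv: RelationshipMatrix | None = None,
    A22: RelationshipMatrix | None = None,
    freqs: np.ndarray | None = None,
) -> WssgwasResult:
    """Run the full weighted single-step iteration.

    ``genotypes`` must be QC-passed and imputed (no missing calls); the
    pedigree must be sorted and cover every genotyped animal.  The SNP
    weights driving D(t+1) come from the ``weight_source`` effect type
    ("direct" by default); maternal SNP effects are re-estimated each
    iteration under the same D.  Pass precomputed ``a_inv`` / ``A22`` to
    skip the pedigree algebra.  ``freqs`` optionally fixes the centering
    allele frequencies (e.g. base-population values); the default is the
    observed panel frequencies, under which the unblended G is singular
    (centered columns sum to zero) and blending with A22 is required.
    """
    if genotypes.has_missing():
        raise ValueError("genotypes contain missing calls; impute before running")
    if weight_source not in ("direct", "maternal"):
        raise ValueError(f"weight_source must be 'direct' or 'maternal', got {weight_source!r}")
    genotyped_ids = list(genotypes.sample_ids)
    if freqs is None:
        freqs = allele_frequencies(genotypes)
    else:
        freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("monomorphic SNPs present; run QC first")
    Z = center_gene_content(genotypes, freqs)
    lam = 1.0 / scaling_denominator(freqs)
    if a_inv is None:
        a_inv = build_A_inverse(ped)
    if A22 is None:
        A22 = extract_A22(build_A(ped), genotyped_ids)

    m = genotypes.n_snps
    weights = SNPWeights.identity(m)
    iterations: list[WssgwasIteration] = []
    for t in range(1, n_iter + 1):
        weights = SNPWeights(d=weights.d, iteration=t)
        G = build_G(Z, weights, freqs, sample_ids=genotyped_ids)
        H_inv, G_w = single_step_h_inverse(a_inv, A22, G, genotyped_ids, alpha=alpha, beta=beta)
        solutions = solve_mme(design, H_inv, vc)
        effects = {}
        for eff, gebv_all in (("direct", solutions.a_hat), ("maternal", solutions.m_hat)):
            gebv_g = gebv_all.loc[genotyped_ids].to_numpy()
            effects[eff] = backsolve_snp_effects(
                Z, weights, G_w, gebv_g, lam, effect_type=eff, iteration=t
            )
        iterations.append(
            WssgwasIteration(
                iteration=t, weights=weights, solutions=solutions, snp_effects=effects, G_omega=G_w
            )
        )
        if t < n_iter:
            d_new = nonlinearA_weights(effects[weight_source], ct=ct, cap=cap, iteration=t + 1)
            weights = normalize_weights(d_new, weights)
    return WssgwasResult(
        iterations=iterations,
        Z=Z,
        freqs=freqs,
        lam=lam,
        genotyped_ids=genotyped_ids,
        markers=genotypes.markers,
        vc=vc,
    )


def window_variance(
    u: SnpEffectSet,
    Z: np.ndarray,
    markers: MarkerMap,
    denom_variance: float,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> WindowTable:
    """Percent of a genetic variance explained by fixed 1-Mb windows.

    Windows are non-overlapping bins anchored at bp 1 within each
    chromosome (bin k spans [(k-1)e6 + 1, k e6]).  For each non-empty
    bin, the window genetic value g_w = sum_{j in w} Z_j u_j is computed
    for every genotyped individual and the row reports
    100 * var(g_w) / denom_variance (sample variance across individuals).
    """
    if denom_variance <= 0:
        raise ValueError("denominator variance must be positive")
    tab = markers.table
    if len(tab) == 0:
        raise ValueError("empty SNP set")
    if Z.shape[1] != len(tab) or Z.shape[1] != len(u.u_hat):
        raise ValueError("Z, marker map and effects disagree in SNP count")
    chrom = tab["chromosome"].to_numpy()
    pos = tab["position_bp"].to_numpy()
    win = (pos - 1) // window_bp
    rows = []
    for ch in np.unique(chrom):
        on_ch = chrom == ch
        for k in np.unique(win[on_ch]):
            sel = on_ch & (win == k)
            gw = Z[:, sel] @ u.u_hat[sel]
            var_w = float(np.var(gw, ddof=1)) if Z.shape[0] > 1 else 0.0
            rows.append(
                {
                    "chromosome": int(ch),
                    "window_start_bp": int(k * window_bp + 1),
                    "window_end_bp": int((k + 1) * window_bp),
                    "first_snp_bp": int(pos[sel].min()),
                    "last_snp_bp": int(pos[sel].max()),
                    "n_snps": int(sel.sum()),
                    "pct_variance": 100.0 * var_w / denom_variance,
                }
            )
    df = pd.DataFrame(rows).sort_values(["chromosome", "window_start_bp"]).reset_index(drop=True)
    return WindowTable(table=df)


def top_windows(wt: WindowTable, k: int = DEFAULT_TOP_K) -> WindowTable:
    """The k windows with the largest variance share, descending; ties
    broken by genome order (chromosome, start)."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > len(wt):
        warnings.warn(f"requested top {k} of {len(wt)} windows; returning all", RuntimeWarning)
        k = len(wt)
    df = wt.table.sort_values(
        by=["pct_variance", "chromosome", "window_start_bp"],
        ascending=[False, True, True],
        kind="mergesort",
    ).head(k)
    return WindowTable(table=df.reset_index(drop=True))


def window_table_for_result(
    result: WssgwasResult,
    effect_type: str = "direct",
    iteration: int | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> WindowTable:
    """Window decomposition for one effect type of a finished run."""
    it = result.iterations[-1] if iteration is None else result.iterations[iteration - 1]
    u = it.snp_effects[effect_type]
    denom = result.vc.sigma2_a if effect_type == "direct" else result.vc.sigma2_m
    return window_variance(u, result.Z, result.markers, denom, window_bp=window_bp)
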