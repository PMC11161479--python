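"""Genomic relationship matrices and the single-step H^-1.

G follows VanRaden with an optional diagonal of per-SNP weights D:

    G = Z D Z' / sum_i 2 p_i (1 - p_i)

where Z is the frequency-centered gene content.  With D = I this is
VanRaden method 1.  G is blended with the pedigree submatrix A22,
G_w = alpha G + beta A22 (defaults 0.95 / 0.05), to guarantee a
positive-definite, invertible matrix; H^-1 then augments A^-1 on the
genotyped block with (G_w^-1 - A22^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .pedigree import RelationshipMatrix


@dataclass
class SNPWeights:
    """Diagonal D of per-SNP variance weights; positive, trace-normalised."""

    d: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.d.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if np.any(self.d <= 0):
            raise ValueError("all SNP weights must be strictly positive")

    @classmethod
    def identity(cls, m: int) -> "SNPWeights":
        return cls(d=np.ones(m), iteration=0)

    def __len__(self) -> int:
        return len(self.d)


@dataclass
class HInverseParts:
    """Inputs to the H^-1 block update, with a shared genotyped ordering."""

    a_inv: RelationshipMatrix
    a22_inv: RelationshipMatrix
    g_omega_inv: RelationshipMatrix
    genotyped_ids: list[str]
    alpha: float = 0.95
    beta: float = 0.05

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-10:
            raise ValueError("alpha + beta must equal 1")
        for name, mat in (("a22_inv", self.a22_inv), ("g_omega_inv", self.g_omega_inv)):
            if list(mat.ids) != list(self.genotyped_ids):
                raise ValueError(f"{name} ids do not match genotyped_ids ordering")


def scaling_denominator(freqs: np.ndarray) -> float:
    """sum_i 2 p_i (1 - p_i) over SNPs — VanRaden's scaling."""
    freqs = np.asarray(freqs, dtype=float)
    return float(np.sum(2.0 * freqs * (1.0 - freqs)))


def build_G(
    Z: np.ndarray,
    d: SNPWeights | np.ndarray | None,
    freqs: np.ndarray,
    sample_ids: list[str] | None = None,
) -> RelationshipMatrix:
    """Weighted VanRaden genomic relationship matrix G = Z D Z' / sum 2p(1-p)."""
    Z = np.asarray(Z, dtype=np.float64)
    n, m = Z.shape
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("monomorphic SNP present (p = 0 or 1): run QC before building G")
    if d is None:
        dv = np.ones(m)
    else:
        dv = d.d if isinstance(d, SNPWeights) else np.asarray(d, dtype=float)
    if len(dv) != m:
        raise ValueError(f"{m} SNPs but {len(dv)} weights")
    denom = scaling_denominator(freqs)
    G = (Z * dv[np.newaxis, :]) @ Z.T / denom
    G = 0.5 * (G + G.T)
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    return RelationshipMatrix(values=G, ids=list(ids))


def blend_G(
    G: RelationshipMatrix, A22: RelationshipMatrix, alpha: float = 0.95, beta: float = 0.05
) -> RelationshipMatrix:
    """G_w = alpha G + beta A22 (elementwise, same animal ordering)."""
    if abs(alpha + beta - 1.0) > 1e-10:
        raise ValueError("alpha + beta must equal 1")
    if list(G.ids) != list(A22.ids):
        raise ValueError("G and A22 must share the same animal ordering")
    return RelationshipMatrix(values=alpha * G.values + beta * A22.values, ids=list(G.ids))


def invert_spd(mat: RelationshipMatrix, what: str = "matrix") -> RelationshipMatrix:
    """Dense symmetric inverse; raises with advice if not positive definite."""
    try:
        c, low = linalg.cho_factor(mat.values)
        inv = linalg.cho_solve((c, low), np.eye(mat.values.shape[0]))
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"{what} is singular / not positive definite; blend with A22 (alpha < 1) first"
        ) from exc
    inv = 0.5 * (inv + inv.T)
    return RelationshipMatrix(values=inv, ids=list(mat.ids))


def build_H_inverse(parts: HInverseParts, all_ids: list[str]) -> RelationshipMatrix:
    """H^-1 = A^-1 with the genotyped block incremented by G_w^-1 - A22^-1.

    Genotyped animals may sit anywhere in the pedigree ordering; the block
    update is a scatter-add on their index set.
    """
    if list(parts.a_inv.ids) != list(all_ids):
        raise ValueError("a_inv ids must match all_ids ordering")
    pos = {a: i for i, a in enumerate(all_ids)}
    missing = [g for g in parts.genotyped_ids if g not in pos]
    if missing:
        raise KeyError(f"genotyped ids not in pedigree: {missing}")
    idx = np.array([pos[g] for g in parts.genotyped_ids], dtype=np.int64)
    H_inv = parts.a_inv.values.copy()
    H_inv[np.ix_(idx, idx)] += parts.g_omega_inv.values - parts.a22_inv.values
    H_inv = 0.5 * (H_inv + H_inv.T)
    return RelationshipMatrix(values=H_inv, ids=list(all_ids))


def single_step_h_inverse(
    a_inv: RelationshipMatrix,
    A22: RelationshipMatrix,
    G: RelationshipMatrix,
    genotyped_ids: list[str],
    alpha: float = 0.95,
    beta: float = 0.05,
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """Convenience wrapper: blend, invert and assemble; returns (H^-1, G_w)."""
    G_w = blend_G(G, A22, alpha=alpha, beta=beta)
    parts = HInverseParts(
        a_inv=a_inv,
        a22_inv=invert_spd(A22, "A22"),
        g_omega_inv=invert_spd(G_w, "G_omega"),
        genotyped_ids=list(genotyped_ids),
        alpha=alpha,
        beta=beta,
    )
    return build_H_inverse(parts, list(a_inv.ids)), G_w
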