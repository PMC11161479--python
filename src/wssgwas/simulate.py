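"""Synthetic pedigree, genotype and phenotype generator.

Emulates the data structure the single-step analysis assumes: a
multi-generation pedigree in which many animals are phenotyped but only
a small, recent subset is genotyped; direct-additive, maternal-genetic,
maternal permanent-environment and residual variance components;
categorical fixed effects; and a sparse set of direct and maternal QTL
embedded among neutral SNPs.

Genetics: founder alleles are drawn per SNP at a frequency uniform on
``maf_range`` and transmitted by gene dropping (each offspring allele is
a uniform pick from the parent's two).  SNPs are unlinked — window
analysis only needs bp coordinates, and no use is made of LD structure.
Breeding values are the sum of a QTL part (allele effects scaled to the
requested share of the genetic variance) and an infinitesimal polygenic
part bred down the pedigree with inbreeding-adjusted Mendelian sampling.

The default configuration is the desk-scale preset used throughout the
test suite: 400 founders plus 4 generations of 400 (2,000 animals),
5,000 SNPs on 5 chromosomes of 100 Mb, 5 direct and 5 maternal QTL each
carrying half of their component's variance, variance components
(2, 1, 0.5, 4) kg^2, and 300 genotyped animals in the last generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MarkerMap
from .mixed_model import VarianceComponents
from .pedigree import Pedigree, build_A


def _default_vc() -> VarianceComponents:
    return VarianceComponents(sigma2_a=2.0, sigma2_m=1.0, sigma2_p=0.5, sigma2_e=4.0)


def _default_fixed_effects() -> dict[str, list[float]]:
    # level effects in kg; levels assigned uniformly at random except
    # birth_year, which tracks the generation number
    return {
        "sex": [0.0, 0.5],
        "birth_type": [0.0, -0.4],
        "herd": [0.0, 0.3, -0.2, 0.1],
        "dam_age": [0.0, 0.2, 0.3, 0.1],
    }


@dataclass
class SimConfig:
    n_founders: int = 400
    n_generations: int = 4
    offspring_per_mating: int = 2
    generation_size: int | None = None  # defaults to n_founders
    n_snps: int = 5000
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl_direct: int = 5
    n_qtl_maternal: int = 5
    prop_var_qtl: float = 0.5
    vc: VarianceComponents = field(default_factory=_default_vc)
    fixed_effect_spec: dict[str, list[float]] = field(default_factory=_default_fixed_effects)
    mean: float = 4.0  # kg, overall trait mean
    genotyped_fraction_last_gen: float = 0.75
    n_genotyped: int | None = None  # exact panel size; overrides the fraction
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders % 2:
            raise ValueError("n_founders must be even (half sires, half dams)")
        if not 0.0 <= self.prop_var_qtl <= 1.0:
            raise ValueError("prop_var_qtl must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if max(self.n_qtl_direct, self.n_qtl_maternal) > self.n_snps:
            raise ValueError("more QTL than SNPs")

    @property
    def gen_size(self) -> int:
        return self.generation_size if self.generation_size is not None else self.n_founders


@dataclass
class SimTruth:
    """Ground truth retained for recovery tests."""

    true_a: pd.Series  # direct breeding value per animal (kg)
    true_m: pd.Series  # maternal breeding value per animal (kg)
    pe: pd.Series  # permanent environment per dam (kg)
    qtl: pd.DataFrame  # columns: snp_id, snp_index, effect_type, allele_effect
    realized: dict[str, float]  # realized variances (kg^2)

    def largest_qtl(self, effect_type: str = "direct") -> pd.Series:
        """The QTL contributing the most genetic variance for an effect type."""
        sub = self.qtl[self.qtl["effect_type"] == effect_type]
        return sub.loc[sub["var_contribution"].idxmax()]


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Discrete generations, random sire x dam pairing without selfing.

    The returned pedigree is sorted and carries a ``meta`` DataFrame
    attribute (animal, generation, sex) used downstream.
    """
    rng = _rng(cfg, 1)
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    gen: list[int] = []
    sex: list[str] = []  # "M" / "F"
    for i in range(cfg.n_founders):
        ids.append(f"G0_{i + 1}")
        sire.append(-1)
        dam.append(-1)
        gen.append(0)
        sex.append("M" if i < cfg.n_founders // 2 else "F")
    prev = np.arange(cfg.n_founders)
    for g in range(1, cfg.n_generations + 1):
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        if not males or not females:
            raise RuntimeError("a generation lacks one sex; enlarge the pedigree")
        n_off = cfg.gen_size
        n_matings = max(1, n_off // cfg.offspring_per_mating)
        cur = []
        k = 0
        for _ in range(n_matings):
            s = int(rng.choice(males))
            d = int(rng.choice(females))
            for _ in range(cfg.offspring_per_mating):
                if k >= n_off:
                    break
                idx = len(ids)
                ids.append(f"G{g}_{k + 1}")
                sire.append(s)
                dam.append(d)
                gen.append(g)
                sex.append("M" if rng.random() < 0.5 else "F")
                cur.append(idx)
                k += 1
        prev = np.array(cur)
    ped = Pedigree(ids=ids, sire=np.array(sire), dam=np.array(dam), sorted=True)
    ped.meta = pd.DataFrame({"animal": ids, "generation": gen, "sex": sex})
    return ped


def simulate_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Gene-drop genotypes for every pedigree animal (complete, no missing).

    Founder allele frequencies are Uniform(maf_range) per SNP; bp
    positions are uniform within chromosomes, then sorted.
    """
    rng = _rng(cfg, 2)
    n, m = len(ped), cfg.n_snps
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    hap1 = np.zeros((n, m), dtype=np.int8)
    hap2 = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            hap1[i] = rng.random(m) < p
            hap2[i] = rng.random(m) < p
        else:
            pick_s = rng.integers(0, 2, size=m).astype(bool)
            hap1[i] = np.where(pick_s, hap2[s], hap1[s]) if s >= 0 else (rng.random(m) < p)
            pick_d = rng.integers(0, 2, size=m).astype(bool)
            hap2[i] = np.where(pick_d, hap2[d], hap1[d]) if d >= 0 else (rng.random(m) < p)
    counts = (hap1 + hap2).astype(np.float64)

    per_chrom = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    per_chrom[: m % cfg.n_chromosomes] += 1
    chroms = np.repeat(np.arange(1, cfg.n_chromosomes + 1), per_chrom)
    pos = np.concatenate(
        [np.sort(rng.choice(cfg.chrom_length_bp, size=c, replace=False) + 1) for c in per_chrom]
    )
    markers = MarkerMap(
        pd.DataFrame(
            {
                "snp_id": [f"snp{j + 1}" for j in range(m)],
                "chromosome": chroms,
                "position_bp": pos,
                "allele_a": "A",
                "allele_b": "B",
            }
        )
    )
    return GenotypeMatrix(counts=counts, sample_ids=list(ped.ids), markers=markers)


def _breed_polygenic(ped: Pedigree, sigma2: float, F: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Infinitesimal breeding values down the pedigree."""
    n = len(ped)
    a = np.zeros(n)
    if sigma2 <= 0:
        return a
    sd0 = np.sqrt(sigma2)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        pa = 0.0
        if s >= 0 and d >= 0:
            pa = 0.5 * (a[s] + a[d])
            ms_var = 0.5 * sigma2 * (1.0 - 0.5 * (F[s] + F[d]))
        elif s >= 0 or d >= 0:
            p_ = s if s >= 0 else d
            pa = 0.5 * a[p_]
            ms_var = 0.75 * sigma2 - 0.25 * sigma2 * F[p_] / 1.0
        else:
            a[i] = rng.normal(0.0, sd0)
            continue
        a[i] = pa + rng.normal(0.0, np.sqrt(max(ms_var, 0.0)))
    return a


def _qtl_values(
    counts: np.ndarray, rng: np.random.Generator, n_qtl: int, target_var: float, markers: MarkerMap
) -> tuple[np.ndarray, pd.DataFrame]:
    if n_qtl == 0 or target_var <= 0:
        return np.zeros(counts.shape[0]), pd.DataFrame(
            columns=["snp_id", "snp_index", "allele_effect"]
        )
    idx = np.sort(rng.choice(counts.shape[1], size=n_qtl, replace=False))
    eff = rng.normal(0.0, 1.0, size=n_qtl)
    v = counts[:, idx] @ eff
    scale = np.sqrt(target_var / np.var(v)) if np.var(v) > 0 else 0.0
    eff *= scale
    v *= scale
    qtl = pd.DataFrame(
        {
            "snp_id": markers.table["snp_id"].to_numpy()[idx],
            "snp_index": idx,
            "allele_effect": eff,
            "var_contribution": np.var(counts[:, idx], axis=0) * eff**2,
        }
    )
    return v - v.mean(), qtl


def simulate_phenotypes(
    ped: Pedigree, g: GenotypeMatrix, cfg: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotype records y = fixed + a(animal) + m(dam) + pe(dam) + e.

    Founders (no dam) carry no record.  Breeding values combine scaled
    QTL values with an infinitesimal polygenic remainder so that
    var(true_a) is close to sigma2_a with QTL share ``prop_var_qtl``.
    """
    rng = _rng(cfg, 3)
    meta = getattr(ped, "meta", None)
    n = len(ped)
    F = np.diag(build_A(ped).values) - 1.0

    vc = cfg.vc
    qa, qtl_a = _qtl_values(g.counts, rng, cfg.n_qtl_direct, cfg.prop_var_qtl * vc.sigma2_a, g.markers)
    qm, qtl_m = _qtl_values(
        g.counts, rng, cfg.n_qtl_maternal, cfg.prop_var_qtl * vc.sigma2_m, g.markers
    )
    poly_a = _breed_polygenic(ped, (1.0 - cfg.prop_var_qtl) * vc.sigma2_a, F, rng)
    poly_m = _breed_polygenic(ped, (1.0 - cfg.prop_var_qtl) * vc.sigma2_m, F, rng)
    true_a = qa + poly_a
    true_m = qm + poly_m

    has_dam = ped.dam >= 0
    rec_idx = np.flatnonzero(has_dam)
    dams = np.unique(ped.dam[rec_idx])
    pe = {int(d): rng.normal(0.0, np.sqrt(vc.sigma2_p)) if vc.sigma2_p > 0 else 0.0 for d in dams}

    rows = []
    for i in rec_idx:
        d = int(ped.dam[i])
        fixed_sum = cfg.mean
        rec: dict[str, object] = {"animal": ped.ids[i], "dam": ped.ids[d]}
        for eff, levels in cfg.fixed_effect_spec.items():
            if eff == "sex" and meta is not None:
                lev = 0 if meta["sex"].iloc[i] == "M" else min(1, len(levels) - 1)
            else:
                lev = int(rng.integers(0, len(levels)))
            rec[eff] = f"{eff[0]}{lev + 1}"
            fixed_sum += levels[lev]
        gen_lev = int(meta["generation"].iloc[i]) if meta is not None else 1
        rec["birth_year"] = f"y{gen_lev}"
        fixed_sum += 0.15 * (gen_lev - 1)
        e = rng.normal(0.0, np.sqrt(vc.sigma2_e))
        rec["trait"] = fixed_sum + true_a[i] + true_m[d] + pe[d] + e
        rows.append(rec)
    phenos = pd.DataFrame(rows)

    realized = {
        "var_true_a": float(np.var(true_a)),
        "var_true_m": float(np.var(true_m)),
        "var_pe": float(np.var(list(pe.values()))) if len(pe) > 1 else 0.0,
        "var_qtl_a": float(np.var(qa)),
        "var_qtl_m": float(np.var(qm)),
    }
    qtl_a = qtl_a.assign(effect_type="direct")
    qtl_m = qtl_m.assign(effect_type="maternal")
    truth = SimTruth(
        true_a=pd.Series(true_a, index=ped.ids),
        true_m=pd.Series(true_m, index=ped.ids),
        pe=pd.Series({ped.ids[d]: v for d, v in pe.items()}),
        qtl=pd.concat([qtl_a, qtl_m], ignore_index=True),
        realized=realized,
    )
    return phenos, truth


def release_genotyped_subset(g: GenotypeMatrix, ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """The released genotype panel: a random fraction of the last
    generation, with calls masked missing at ``missing_rate``."""
    rng = _rng(cfg, 4)
    meta = getattr(ped, "meta", None)
    if meta is None:
        raise ValueError("pedigree lacks simulation metadata")
    last = meta.index[meta["generation"] == meta["generation"].max()].to_numpy()
    if cfg.n_genotyped is not None:
        n_geno = min(cfg.n_genotyped, len(last))
    else:
        n_geno = int(round(cfg.genotyped_fraction_last_gen * len(last)))
    chosen = np.sort(rng.choice(last, size=n_geno, replace=False))
    counts = g.counts[chosen].copy()
    if cfg.missing_rate > 0:
        mask = rng.random(counts.shape) < cfg.missing_rate
        counts[mask] = np.nan
    return GenotypeMatrix(
        counts=counts, sample_ids=[ped.ids[i] for i in chosen], markers=g.markers
    )


@dataclass
class SimDataset:
    ped: Pedigree
    genotypes_full: GenotypeMatrix  # every animal, complete
    genotypes: GenotypeMatrix  # released panel (recent subset, with missing)
    phenotypes: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """End-to-end simulation: pedigree, genotypes, phenotypes, released panel."""
    ped = simulate_pedigree(cfg)
    g_full = simulate_genotypes(ped, cfg)
    phenos, truth = simulate_phenotypes(ped, g_full, cfg)
    released = release_genotyped_subset(g_full, ped, cfg)
    return SimDataset(
        ped=ped,
        genotypes_full=g_full,
        genotypes=released,
        phenotypes=phenos,
        truth=truth,
        config=cfg,
    )
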