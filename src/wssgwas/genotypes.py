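"""SNP genotype handling: quality control, imputation, allele frequencies
and the centered gene-content matrix Z.

Genotypes are reference-allele counts in {0, 1, 2}; missing calls are
``np.nan``.  QC applies, in order: (1) drop SNPs with unknown map position
or on sex chromosomes, (2) drop individuals below the call-rate threshold,
(3) drop SNPs below the call-rate threshold, (4) drop SNPs below the MAF
threshold, (5) drop SNPs failing the Hardy-Weinberg exact test.  The
thresholds default to the conventional 50K-chip values (0.95 / 0.95 /
0.05 / 1e-6).

Imputation fills missing calls by a Hardy-Weinberg draw at the SNP's
observed allele frequency — adequate at low missingness on a small
genotyped panel, and free of external phasing tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: chromosome codes treated as non-autosomal / unmapped (PLINK convention:
#: 0 = unplaced; X/Y/XY/MT are coded above the autosome range for sheep, 27+)
SEX_CHROM_MIN = 27


@dataclass
class MarkerMap:
    """Per-SNP map: id, chromosome, bp position and the two alleles."""

    table: pd.DataFrame  # columns: snp_id, chromosome, position_bp, allele_a, allele_b

    REQUIRED = ("snp_id", "chromosome", "position_bp", "allele_a", "allele_b")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count matrix with its marker map."""

    counts: np.ndarray  # float, entries in {0,1,2} or nan
    sample_ids: list[str]
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        n, m = self.counts.shape
        if n != len(self.sample_ids):
            raise ValueError(f"{n} genotype rows but {len(self.sample_ids)} sample ids")
        if m != len(self.markers):
            raise ValueError(f"{m} genotype columns but {len(self.markers)} markers")
        bad = ~(np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("genotype counts must be 0, 1, 2 or missing (nan)")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.counts).any())


@dataclass
class QCThresholds:
    min_ind_call_rate: float = 0.95
    min_snp_call_rate: float = 0.95
    min_maf: float = 0.05
    min_hwe_p: float = 1e-6

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Counts removed at each filter step plus what remains."""

    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, kind: str, removed: int, remaining: int) -> None:
        self.steps.append(
            {"step": step, "kind": kind, "items_removed": int(removed), "items_remaining": int(remaining)}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def total_removed(self, kind: str) -> int:
        return sum(s["items_removed"] for s in self.steps if s["kind"] == kind)


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value (Wigginton et al. style).

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts no more likely than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    # possible heterozygote counts share the parity of n_rare
    het_obs = n_Aa
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    if len(hets) == 0:
        return 1.0
    # unnormalized probabilities via the symmetric recurrence:
    # P(h+2)/P(h) = 4 * n_homR(h) * n_homC(h) / ((h+2)(h+1))
    # where homR = (n_rare - h)/2, homC = n - h - homR
    logp = np.zeros(len(hets))
    for k in range(1, len(hets)):
        h = hets[k - 1]
        hom_r = (n_rare - h) / 2.0
        hom_c = n - h - hom_r
        logp[k] = logp[k - 1] + np.log(4.0 * hom_r * hom_c) - np.log((h + 2.0) * (h + 1.0))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == het_obs]
    if len(p_obs) != 1:
        raise ValueError(f"heterozygote count {het_obs} impossible for allele counts")
    return float(min(1.0, p[p <= p_obs[0] * (1.0 + 1e-12)].sum()))


def allele_frequencies(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Counted-allele frequency per SNP: mean allele count / 2 over
    non-missing calls."""
    counts = g.counts if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.nanmean(counts, axis=0) / 2.0


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    obs = col[~np.isnan(col)]
    return int(np.sum(obs == 2)), int(np.sum(obs == 1)), int(np.sum(obs == 0))


def apply_qc(g: GenotypeMatrix, thr: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Run the five-step QC; raises if no SNP or individual survives."""
    thr = thr or QCThresholds()
    report = QCReport()
    counts = g.counts
    samples = list(g.sample_ids)
    mtab = g.markers.table

    # 1. map: unknown position or non-autosome
    chrom = mtab["chromosome"].to_numpy()
    pos = mtab["position_bp"].to_numpy()
    keep_snp = (chrom >= 1) & (chrom < SEX_CHROM_MIN) & (pos >= 1)
    report.add("map", "snp", (~keep_snp).sum(), keep_snp.sum())
    counts = counts[:, keep_snp]
    mtab = mtab.loc[keep_snp].reset_index(drop=True)

    # 2. individual call rate
    if counts.shape[1] > 0:
        ind_cr = 1.0 - np.isnan(counts).mean(axis=1)
    else:
        ind_cr = np.ones(len(samples))
    keep_ind = ind_cr >= thr.min_ind_call_rate
    report.add("individual_call_rate", "individual", (~keep_ind).sum(), keep_ind.sum())
    counts = counts[keep_ind, :]
    samples = [s for s, k in zip(samples, keep_ind) if k]

    if len(samples) == 0:
        raise ValueError("no individuals survive QC")

    # 3. SNP call rate
    snp_cr = 1.0 - np.isnan(counts).mean(axis=0)
    keep_snp = snp_cr >= thr.min_snp_call_rate
    report.add("snp_call_rate", "snp", (~keep_snp).sum(), keep_snp.sum())
    counts = counts[:, keep_snp]
    mtab = mtab.loc[keep_snp].reset_index(drop=True)

    # 4. MAF
    freqs = allele_frequencies(counts)
    maf = np.minimum(freqs, 1.0 - freqs)
    keep_snp = maf >= thr.min_maf
    report.add("maf", "snp", (~keep_snp).sum(), keep_snp.sum())
    counts = counts[:, keep_snp]
    mtab = mtab.loc[keep_snp].reset_index(drop=True)

    # 5. HWE exact test
    keep = np.ones(counts.shape[1], dtype=bool)
    for j in range(counts.shape[1]):
        nAA, nAa, naa = _genotype_counts(counts[:, j])
        if nAA + nAa + naa == 0:
            keep[j] = False
            continue
        keep[j] = hwe_exact_p(nAA, nAa, naa) >= thr.min_hwe_p
    report.add("hwe", "snp", (~keep).sum(), keep.sum())
    counts = counts[:, keep]
    mtab = mtab.loc[keep].reset_index(drop=True)

    if counts.shape[1] == 0:
        raise ValueError("no SNPs survive QC")

    return GenotypeMatrix(counts=counts, sample_ids=samples, markers=MarkerMap(mtab)), report


def impute_missing(g: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill missing calls with Hardy-Weinberg draws at the observed
    per-SNP frequency p: P(0,1,2) = ((1-p)^2, 2p(1-p), p^2).
    Deterministic given ``seed``."""
    if not g.has_missing():
        return g
    rng = np.random.default_rng(seed)
    counts = g.counts.copy()
    freqs = allele_frequencies(g)
    if np.isnan(freqs).any():
        bad = int(np.flatnonzero(np.isnan(freqs))[0])
        raise ValueError(f"SNP {g.markers.table['snp_id'][bad]!r} has no observed genotypes")
    for j in np.flatnonzero(np.isnan(counts).any(axis=0)):
        miss = np.isnan(counts[:, j])
        p = freqs[j]
        counts[miss, j] = rng.choice(
            [0.0, 1.0, 2.0], size=miss.sum(), p=[(1 - p) ** 2, 2 * p * (1 - p), p**2]
        )
    return GenotypeMatrix(counts=counts, sample_ids=list(g.sample_ids), markers=g.markers)


def center_gene_content(g: GenotypeMatrix | np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Z = counts - 2p columnwise (gene content adjusted for allele
    frequency: genotypes map to 0-2p, 1-2p, 2-2p)."""
    counts = g.counts if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if counts.shape[1] != freqs.shape[0]:
        raise ValueError(f"{counts.shape[1]} SNPs but {freqs.shape[0]} frequencies")
    if np.isnan(counts).any():
        raise ValueError("impute missing genotypes before centering")
    return counts - 2.0 * freqs[np.newaxis, :]
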