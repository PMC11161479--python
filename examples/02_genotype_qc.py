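"""Genotype quality control and imputation on a simulated 50K-style panel.

Simulates a small population, applies the standard filter battery
(map -> individual call rate -> SNP call rate -> MAF -> exact HWE test)
and fills the surviving missing calls with Hardy-Weinberg draws.
"""

from wssgwas import QCThresholds, apply_qc, impute_missing
from wssgwas.simulate import SimConfig, simulate_dataset

sim = simulate_dataset(
    SimConfig(n_founders=100, n_generations=2, n_snps=2000, missing_rate=0.03, seed=11)
)
g = sim.genotypes
print(f"released panel: {g.n_individuals} individuals x {g.n_snps} SNPs, "
      f"{100 * float((g.counts != g.counts).mean()):.1f}% missing calls")

gq, report = apply_qc(g, QCThresholds(min_ind_call_rate=0.95, min_snp_call_rate=0.95,
                                      min_maf=0.05, min_hwe_p=1e-6))
print("\nQC report (items removed per filter):")
print(report.to_frame().to_string(index=False))

gq = impute_missing(gq, seed=11)
print(f"\nafter QC + imputation: {gq.n_individuals} x {gq.n_snps}, missing: {gq.has_missing()}")
print("Each removed SNP failed exactly one filter; the counts sum to the")
print("difference between input and output panel sizes.")
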