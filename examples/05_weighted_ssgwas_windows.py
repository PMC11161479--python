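"""The full weighted single-step GWAS: iterative SNP re-weighting and
1-Mb window variance decomposition.

Simulates a population with 5 direct and 5 maternal QTL, runs three
weighting iterations (nonlinearA, CT = 1.125) and prints the top-10
windows for each genetic effect, flagging the windows that contain a
simulated QTL.
"""

import numpy as np

from wssgwas import (
    apply_qc, build_A, build_A_inverse, build_design, extract_A22,
    impute_missing, run_wssgwas, top_windows,
)
from wssgwas.gwas import window_table_for_result
from wssgwas.simulate import SimConfig, simulate_dataset

cfg = SimConfig(n_founders=400, generation_size=750, n_generations=4,
                offspring_per_mating=4, n_genotyped=300, n_snps=5000, seed=5)
sim = simulate_dataset(cfg)
gq, _ = apply_qc(sim.genotypes)
gq = impute_missing(gq, seed=5)
design = build_design(sim.phenotypes, sim.ped)

res = run_wssgwas(
    design, sim.ped, gq, cfg.vc, n_iter=3, alpha=0.95, beta=0.05, ct=1.125, cap=5.0,
    a_inv=build_A_inverse(sim.ped), A22=extract_A22(build_A(sim.ped), list(gq.sample_ids)),
)

qtl = sim.truth.qtl
mt = sim.genotypes_full.markers.table
qtl_windows = {
    (int(mt["chromosome"][r.snp_index]),
     (int(mt["position_bp"][r.snp_index]) - 1) // 1_000_000 * 1_000_000 + 1): r.effect_type
    for r in qtl.itertuples()
}

for eff in ("direct", "maternal"):
    wt = window_table_for_result(res, effect_type=eff)
    tk = top_windows(wt, 10).table
    total = tk["pct_variance"].sum()
    print(f"\ntop 10 {eff} windows ({total:.2f}% of the {eff} genetic variance):")
    for r in tk.itertuples(index=False):
        tag = qtl_windows.get((r.chromosome, r.window_start_bp), "")
        star = f"  <- simulated {tag} QTL" if tag else ""
        print(f"  chr{r.chromosome:>2} {r.window_start_bp:>11,}-{r.window_end_bp:<11,} "
              f"{r.n_snps:>3} SNPs  {r.pct_variance:.4f}%{star}")

print("\nPercentages are var(sum_j Z_j u_j) across the genotyped animals,")
print("relative to the REML-scale genetic variance of that effect; the")
print("iterative weighting concentrates signal into the QTL windows.")
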