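"""REML variance components for a maternal-effects animal model.

Simulates phenotypes at known variance components and re-estimates them
from the pedigree and records alone: direct additive, maternal genetic,
maternal permanent-environment and residual variances.
"""

import warnings

import numpy as np

from wssgwas import VarianceComponents, build_A_inverse, build_design
from wssgwas.mixed_model import estimate_varcomps_reml
from wssgwas.simulate import SimConfig, simulate_dataset

truth = VarianceComponents(sigma2_a=2.0, sigma2_m=1.0, sigma2_p=0.5, sigma2_e=4.0)
sim = simulate_dataset(
    SimConfig(n_founders=400, generation_size=750, n_generations=4,
              offspring_per_mating=4, n_snps=100, vc=truth, seed=1)
)
design = build_design(sim.phenotypes, sim.ped)
print(f"{len(design.y)} records, {len(design.dam_ids)} dams, {len(sim.ped)} pedigree animals")

a_inv = build_A_inverse(sim.ped, sparse_out=True)
vy = float(np.var(design.y))
init = VarianceComponents(0.3 * vy, 0.15 * vy, 0.1 * vy, 0.45 * vy)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    vc, info = estimate_varcomps_reml(design, a_inv, init, max_iter=60, tol=1e-5,
                                      method="ai", return_info=True)

print(f"\nconverged in {info.n_iter} iterations ({info.method} updates)\n")
print(f"{'component':<28}{'true':>8}{'estimate':>10}")
for name, t, e in [
    ("direct additive", truth.sigma2_a, vc.sigma2_a),
    ("maternal genetic", truth.sigma2_m, vc.sigma2_m),
    ("maternal permanent env.", truth.sigma2_p, vc.sigma2_p),
    ("residual", truth.sigma2_e, vc.sigma2_e),
]:
    print(f"{name:<28}{t:>8.2f}{e:>10.3f}")
tot = sum(vc.as_array())
print(f"\ndirect heritability h2 = {vc.sigma2_a / tot:.3f}, "
      f"maternal h2 = {vc.sigma2_m / tot:.3f}")
print("Estimates fluctuate around the truth with the sampling noise of a")
print("single 3,000-record replicate; medians over seeds are unbiased.")
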