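"""Simulate a layer population: pedigree, sire genotypes, daughter survival.

Builds a small version of the study design — sires over several pedigree
generations, part genotyped, daughters housed five paternal half-sibs per
cage, survival censored at batch-specific endpoints — and prints its shape.
"""
from layersel import SimConfig, simulate_genotypes, simulate_pedigree, simulate_survival

cfg = SimConfig(n_generations=3, n_sires_per_gen=50, dams_per_sire=4,
                daughters_per_dam=5, n_snps=400, prop_sires_genotyped=0.8, seed=1)
ped = simulate_pedigree(cfg)
geno = simulate_genotypes(ped, cfg)
phenos = simulate_survival(ped, cfg)

print(f"pedigree animals:      {ped.n} over {cfg.n_generations} generations")
print(f"genotyped sires:       {geno.n_animals} x {geno.n_snps} SNPs")
print(f"phenotyped daughters:  {phenos.n} in cages of {cfg.cage_size}")
print(f"fraction censored:     {phenos.fraction_censored():.2f}")
print(f"true sire-effect var:  {phenos.true_sire_effects.var():.0f} days^2 "
      f"(generating value {cfg.sigma2_u:.0f})")
# The censored fraction reflects the batch endpoints relative to mean
# survival; the sire-effect variance is sigma2_u up to sampling error.
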