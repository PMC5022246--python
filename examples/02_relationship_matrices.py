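"""Genotype QC and the A, G and blended H^-1 relationship matrices.

Filters SNPs on call rate, minor allele frequency and Hardy-Weinberg
chi-square, builds the pedigree relationship matrix and VanRaden's genomic
matrix, blends them into the single-step H inverse, and prints the linkage
summary Me = 1/var(G - A22), the effective number of chromosome segments.
"""
import numpy as np

from layersel import SimConfig, relmat, simulate_genotypes, simulate_pedigree

cfg = SimConfig(n_generations=3, n_sires_per_gen=60, dams_per_sire=4,
                daughters_per_dam=5, n_snps=500, prop_sires_genotyped=1.0, seed=2)
ped = simulate_pedigree(cfg)
geno = simulate_genotypes(ped, cfg)

filtered, report = relmat.qc_filter(geno)
print(report.to_string(index=False))

A = relmat.build_A(ped)
A_inv = relmat.A_inverse(ped, A)
A22 = relmat.subset_A(A, ped, filtered.ids)
G = relmat.build_G(filtered)
H_inv = relmat.blend_H_inverse(A_inv, A22, G, np.asarray(filtered.ids) - 1,
                               alpha=0.95)
arch = relmat.compute_Me(G, A22)

print(f"\nmean diag(A22) = {np.diag(A22).mean():.3f}, mean diag(G) = {np.diag(G).mean():.3f}")
print(f"var of off-diagonal pedigree relationships: {arch.var_offdiag_A:.5f}")
print(f"Me = 1/var(G - A22) = {arch.Me:.0f}")
# A smaller Me means more genome-wide linkage disequilibrium among the
# genotyped sires and hence more accurate genomic prediction for a given
# reference size.
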