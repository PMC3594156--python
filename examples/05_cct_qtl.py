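"""Quantitative-trait scan: a central-corneal-thickness QTL.

Simulates CCT (mean 556 um, sd 35 um) with a -20 um per-allele QTL at a
common allele (frequency pinned to 0.35), measured on only 280 of the
800 patients, scans every SNP by linear regression of trait on
minor-allele count, and prints the QTL's estimate with its
genotype-class means.
"""

import numpy as np

import recipgwas as rg

QTL = 25
qt = rg.QuantTraitSpec(
    trait_name="CCT", mean=556, sd=35, qtl_snp_index=QTL,
    per_allele_effect=-20, n_measured=280,
)
spec = rg.CohortSpec(
    n_snps=300,
    n_normals=0,
    planted=[rg.PlantedEffect(QTL, "quantitative", 0.35, 0.35)],
    qt_spec=qt,
    seed=4,
)
g = rg.generate_cohorts(spec)
trait = g.samples["CCT"].to_numpy()
print(f"CCT measured for {np.isfinite(trait).sum()} of {g.n_samples} patients")

scan = rg.qt_scan(trait, g.calls)
top = scan.sort_values("p_corrected").index[0]
qtl_row = scan.loc[QTL]
print(f"top SNP by corrected p: index {top} (planted QTL index {QTL})")
print(
    f"QTL estimate: slope {qtl_row['slope']:.1f} um/allele "
    f"(SE {qtl_row['se']:.1f}), p_corrected {qtl_row['p_corrected']:.2e}"
)

measured = np.isfinite(trait)
for geno in (0, 1, 2):
    sel = measured & (g.calls[:, QTL] == geno)
    print(f"genotype {geno}: mean CCT {trait[sel].mean():.1f} um (n={sel.sum()})")

# The genotype-class means fall by ~20 um per minor-allele copy: minor-
# allele carriers have thinner corneas, the pattern a real CCT risk
# locus produces, and the regression recovers the planted slope within
# two standard errors.
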