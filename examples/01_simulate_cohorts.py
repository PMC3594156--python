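"""Simulate a two-disease study and look at its structure.

Builds the standard design — two disease cohorts of 400 split into
primary/validation halves of 200, plus 100 normals — with one planted
AMD risk locus, and prints the group allele frequencies at the planted
SNP next to a null SNP.
"""

import recipgwas as rg

planted = [rg.PlantedEffect(10, "AMD", maf_in_target=0.45, maf_elsewhere=0.18)]
spec = rg.CohortSpec(n_snps=50, planted=planted, seed=1)
g = rg.generate_cohorts(spec)

print(f"samples: {g.n_samples} (per cell:")
print(g.samples.groupby(["disease", "phase"]).size(), ")")
print(f"SNPs: {g.n_snps}")

for j, label in [(10, "planted AMD SNP"), (11, "null SNP")]:
    mafs = {
        d: g.minor_allele_freq(g.sample_mask(disease=d))[j]
        for d in ("AMD", "NORMAL", "POAG")
    }
    print(
        f"{label}: MAF AMD/NL/POAG = "
        f"{mafs['AMD']:.2f}/{mafs['NORMAL']:.2f}/{mafs['POAG']:.2f}"
    )

# The planted SNP shows the AMD cohort shifted to ~0.45 while normals and
# POAG stay near 0.18; the null SNP shows one shared frequency everywhere.
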