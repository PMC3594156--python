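import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import recipgwas as rg

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_study():
    """A small two-locus study: one AMD locus and one POAG locus, 5 SNPs each."""
    planted = [
        rg.PlantedEffect(100 + k, "AMD", maf_in_target=0.39, maf_elsewhere=0.16)
        for k in range(5)
    ] + [
        rg.PlantedEffect(400 + k, "POAG", maf_in_target=0.48, maf_elsewhere=0.20)
        for k in range(5)
    ]
    spec = rg.CohortSpec(n_snps=800, planted=planted, seed=42)
    return spec, rg.generate_cohorts(spec)


@pytest.fixture(scope="session")
def null_study():
    """No planted effects, no stratification: pure sampling noise."""
    spec = rg.CohortSpec(n_snps=1500, seed=7)
    return spec, rg.generate_cohorts(spec)


@pytest.fixture()
def tiny_matrix():
    """Hand-sized 4-sample, 3-SNP matrix for I/O and QC edge cases."""
    import pandas as pd

    calls = np.array(
        [
            [0, 1, 2],
            [1, 0, rg.MISSING],
            [2, 1, 0],
            [0, 2, 1],
        ],
        dtype=np.int8,
    )
    snps = pd.DataFrame(
        {
            "id": ["rs1", "rs2", "rs3"],
            "chrom": ["1", "1", "2"],
            "pos": [1000, 5000, 200],
            "allele_minor": ["A", "C", "G"],
            "allele_major": ["G", "T", "T"],
        }
    )
    samples = pd.DataFrame(
        {
            "id": ["s1", "s2", "s3", "s4"],
            "disease": ["AMD", "AMD", "POAG", "POAG"],
            "phase": ["primary", "validation", "primary", "validation"],
            "gender": ["female", "male", "female", "male"],
            "subphenotype": ["Dry", "UCNV", "HTG", "NTG"],
        }
    )
    return rg.GenotypeMatrix(calls=calls, snps=snps, samples=samples)
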