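"""Synthetic two-disease cohort generator.

Emulates the study design the pipeline assumes: two disease cohorts
(AMD and POAG by default) of 400 patients each, split into matched
primary/validation halves of 200, plus a clinic cohort of 100 disease-free
normals. Biallelic autosomal SNPs are drawn under Hardy-Weinberg
equilibrium — each sample's minor-allele count is binomial(2, p) at the
group's allele frequency — with no linkage-disequilibrium model: the
single-SNP tests downstream never look at haplotypes, and locus-cluster
behaviour is exercised by planting several nearby SNPs that share one
frequency shift.

Risk SNPs are "planted" by perturbing the minor-allele frequency in
exactly one disease cohort while normals and the other disease keep the
background frequency, mirroring how a real disease association appears
in the reciprocal design. Optional two-subpopulation stratification
follows the Balding-Nichols model (per-subpopulation frequencies drawn
from a Beta distribution around the ancestral frequency with divergence
F), with each cohort drawing samples from the subpopulations in
configurable proportions; planted SNPs are exempt so their target
frequencies stay exact. A quantitative trait (central corneal thickness
by default) is simulated as an additive single-QTL linear model with
Gaussian noise, optionally measured on only a subset of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, NORMAL, PHASE_NONE, PHASES, GenotypeMatrix

# Gender and sub-phenotype proportions default to the study's cohort
# composition (AMD: dry / unilateral CNV / bilateral CNV; POAG: normal-
# vs high-tension glaucoma, NTG the minority subclass).
DEFAULT_FEMALE_FRACTION = {"AMD": 0.635, "POAG": 0.5625, NORMAL: 0.5}
DEFAULT_SUBPHENOTYPES = {
    "AMD": (("Dry", 0.2575), ("UCNV", 0.38), ("BCNV", 0.3625)),
    "POAG": (("NTG", 0.2), ("HTG", 0.8)),
    NORMAL: (("none", 1.0),),
}

_NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class PlantedEffect:
    """A risk SNP: frequency perturbed in one disease cohort only.

    ``target_disease`` may also be ``"quantitative"``, which pins the
    SNP's frequency everywhere to ``maf_in_target`` (for QTL planting).
    """

    snp_index: int
    target_disease: str
    maf_in_target: float
    maf_elsewhere: float

    def validate(self) -> None:
        for f in (self.maf_in_target, self.maf_elsewhere):
            if not 0 < f < 1:
                raise ValueError(f"planted frequency {f} outside (0, 1)")
        if (
            self.target_disease != "quantitative"
            and self.maf_in_target == self.maf_elsewhere
        ):
            raise ValueError("planted effect is trivial: equal frequencies")


@dataclass
class StratSpec:
    """Two-subpopulation Balding-Nichols stratification.

    ``divergence`` is the F parameter scaling per-SNP frequency drift;
    ``mixing`` maps each cohort label (diseases and NORMAL) to its
    subpopulation proportions, which must sum to 1.
    """

    n_subpops: int = 2
    divergence: float = 0.02
    mixing: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def validate(self, cohort_labels: tuple[str, ...]) -> None:
        if self.n_subpops < 2:
            raise ValueError("stratification needs at least 2 subpopulations")
        if not 0 < self.divergence < 1:
            raise ValueError("divergence must lie in (0, 1)")
        for label in cohort_labels:
            props = self.mixing.get(label, self._uniform())
            if len(props) != self.n_subpops or abs(sum(props) - 1) > 1e-9:
                raise ValueError(f"mixing for {label} must sum to 1 over subpopulations")

    def _uniform(self) -> tuple[float, ...]:
        return tuple([1 / self.n_subpops] * self.n_subpops)

    def proportions(self, label: str) -> tuple[float, ...]:
        return tuple(self.mixing.get(label, self._uniform()))


@dataclass
class QuantTraitSpec:
    """Additive single-QTL model for a quantitative trait."""

    trait_name: str = "CCT"
    mean: float = 556.0
    sd: float = 35.0
    qtl_snp_index: int = 0
    per_allele_effect: float = -10.0
    n_measured: int | None = None

    def validate(self, n_snps: int) -> None:
        if self.sd <= 0:
            raise ValueError("trait sd must be positive")
        if not 0 <= self.qtl_snp_index < n_snps:
            raise ValueError("qtl_snp_index out of range")


@dataclass
class CohortSpec:
    """Full description of a synthetic two-disease study."""

    n_snps: int
    n_per_disease_per_phase: int = 200
    diseases: tuple[str, str] = ("AMD", "POAG")
    n_normals: int = 100
    baseline_maf_range: tuple[float, float] = (0.05, 0.5)
    planted: list[PlantedEffect] = field(default_factory=list)
    stratification: StratSpec | None = None
    qt_spec: QuantTraitSpec | None = None
    missing_rate: float = 0.0
    n_chromosomes: int = 1
    snp_spacing: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.baseline_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("baseline_maf_range must lie within (0, 0.5]")
        if self.n_snps < 1 or self.n_per_disease_per_phase < 1:
            raise ValueError("need at least one SNP and one sample per cell")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for eff in self.planted:
            eff.validate()
            if not 0 <= eff.snp_index < self.n_snps:
                raise ValueError(f"planted snp_index {eff.snp_index} out of range")
        if self.stratification is not None:
            self.stratification.validate((*self.diseases, NORMAL))
        if self.qt_spec is not None:
            self.qt_spec.validate(self.n_snps)


def generate_cohorts(spec: CohortSpec) -> GenotypeMatrix:
    """Simulate the full study: genotypes, labels, and optional trait.

    Deterministic given ``spec.seed``. Group-specific allele frequencies
    are honoured exactly for planted SNPs; all other SNPs share one
    frequency across every cohort (perturbed per subpopulation when
    stratification is on).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    baseline = rng.uniform(*spec.baseline_maf_range, size=spec.n_snps)
    planted_idx = np.array([e.snp_index for e in spec.planted], dtype=int)

    samples = _sample_table(spec, rng)
    n_samples = len(samples)

    # per-sample subpopulation assignment
    if spec.stratification is not None:
        subpop = np.empty(n_samples, dtype=int)
        for label in (*spec.diseases, NORMAL):
            mask = (samples["disease"] == label).to_numpy()
            subpop[mask] = rng.choice(
                spec.stratification.n_subpops,
                size=mask.sum(),
                p=spec.stratification.proportions(label),
            )
        subpop_freqs = _balding_nichols(
            baseline, spec.stratification, rng
        )  # (n_subpops, n_snps)
    else:
        subpop = np.zeros(n_samples, dtype=int)
        subpop_freqs = baseline[None, :]

    # per-sample x per-SNP generating frequency
    freqs = subpop_freqs[subpop]
    for eff in spec.planted:
        if eff.target_disease == "quantitative":
            freqs[:, eff.snp_index] = eff.maf_in_target
        else:
            target = (samples["disease"] == eff.target_disease).to_numpy()
            freqs[target, eff.snp_index] = eff.maf_in_target
            freqs[~target, eff.snp_index] = eff.maf_elsewhere

    calls = rng.binomial(2, freqs).astype(np.int8)
    if spec.missing_rate > 0:
        calls[rng.random(calls.shape) < spec.missing_rate] = MISSING

    snps = _snp_table(spec, rng)
    g = GenotypeMatrix(calls=calls, snps=snps, samples=samples)

    if spec.qt_spec is not None:
        trait = generate_quantitative_trait(
            g, spec.qt_spec, seed=int(rng.integers(2**31))
        )
        g.samples[spec.qt_spec.trait_name] = trait
    return g


def generate_quantitative_trait(
    g: GenotypeMatrix, spec: QuantTraitSpec, seed: int
) -> np.ndarray:
    """Simulate ``trait = mean + effect * minor-allele count + noise``.

    When ``spec.n_measured`` is set, only that many randomly chosen
    samples receive a value; the rest are NaN (emulating a trait
    recorded for a subset of the genotyped patients). Missing genotype
    calls at the QTL contribute zero dosage.
    """
    spec.validate(g.n_snps)
    rng = np.random.default_rng(seed)
    dosage = np.maximum(g.calls[:, spec.qtl_snp_index], 0).astype(float)
    trait = spec.mean + spec.per_allele_effect * dosage + rng.normal(0, spec.sd, g.n_samples)
    if spec.n_measured is not None:
        if not 0 < spec.n_measured <= g.n_samples:
            raise ValueError("n_measured out of range")
        measured = rng.choice(g.n_samples, size=spec.n_measured, replace=False)
        masked = np.full(g.n_samples, np.nan)
        masked[measured] = trait[measured]
        trait = masked
    return trait


def normative_frequencies(spec: CohortSpec) -> pd.DataFrame:
    """The generator's true normal-population frequency per SNP.

    This is what a HapMap-style annotation file provides in a real
    study: the expected minor-allele frequency in an unaffected
    reference population. Planted disease SNPs report their
    ``maf_elsewhere`` (normals keep the background frequency).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    baseline = rng.uniform(*spec.baseline_maf_range, size=spec.n_snps)
    for eff in spec.planted:
        baseline[eff.snp_index] = (
            eff.maf_in_target
            if eff.target_disease == "quantitative"
            else eff.maf_elsewhere
        )
    ids = [f"SNP{j:06d}" for j in range(spec.n_snps)]
    return pd.DataFrame({"snp_id": ids, "maf": baseline})


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _sample_table(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for disease in spec.diseases:
        for phase in PHASES:
            for i in range(spec.n_per_disease_per_phase):
                rows.append((f"{disease}_{phase}_{i:04d}", disease, phase))
    for i in range(spec.n_normals):
        rows.append((f"NORMAL_{i:04d}", NORMAL, PHASE_NONE))
    table = pd.DataFrame(rows, columns=["id", "disease", "phase"])

    gender = np.empty(len(table), dtype=object)
    subph = np.empty(len(table), dtype=object)
    for label in (*spec.diseases, NORMAL):
        mask = (table["disease"] == label).to_numpy()
        f = DEFAULT_FEMALE_FRACTION.get(label, 0.5)
        gender[mask] = np.where(rng.random(mask.sum()) < f, "female", "male")
        names, probs = zip(*DEFAULT_SUBPHENOTYPES.get(label, (("none", 1.0),)))
        subph[mask] = rng.choice(names, size=mask.sum(), p=probs)
    table["gender"] = gender
    table["subphenotype"] = subph
    return table


def _snp_table(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = int(np.ceil(spec.n_snps / spec.n_chromosomes))
    chroms, positions = [], []
    for j in range(spec.n_snps):
        chroms.append(str(1 + j // per_chrom))
        positions.append(1 + (j % per_chrom) * spec.snp_spacing)
    # two distinct nucleotides per SNP
    first = rng.integers(0, 4, size=spec.n_snps)
    second = (first + rng.integers(1, 4, size=spec.n_snps)) % 4
    return pd.DataFrame(
        {
            "id": [f"SNP{j:06d}" for j in range(spec.n_snps)],
            "chrom": chroms,
            "pos": positions,
            "allele_minor": _NUCLEOTIDES[first],
            "allele_major": _NUCLEOTIDES[second],
        }
    )


def _balding_nichols(
    baseline: np.ndarray, strat: StratSpec, rng: np.random.Generator
) -> np.ndarray:
    """Per-subpopulation frequencies drawn Beta around the ancestral MAF."""
    f = strat.divergence
    scale = (1 - f) / f
    alpha = baseline * scale
    beta = (1 - baseline) * scale
    freqs = rng.beta(alpha, beta, size=(strat.n_subpops, baseline.size))
    return np.clip(freqs, 1e-6, 1 - 1e-6)
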