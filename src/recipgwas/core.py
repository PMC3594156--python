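"""Central data model for the reciprocal two-disease GWAS pipeline.

The pipeline's one in-memory container is :class:`GenotypeMatrix`: a
samples x SNPs matrix of minor-allele counts plus SNP and sample metadata
tables. Genotypes are coded 0/1/2 (copies of the minor allele) with -1 for
a missing call; the minor allele is fixed per SNP across all cohorts so
that per-group allele frequencies are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call
MISSING: int = -1

#: canonical disease labels of the reciprocal design
DISEASES = ("AMD", "POAG")
NORMAL = "NORMAL"

#: study phases; normals sit outside the two-phase design
PHASES = ("primary", "validation")
PHASE_NONE = "none"

SNP_COLUMNS = ["id", "chrom", "pos", "allele_minor", "allele_major"]
SAMPLE_COLUMNS = ["id", "disease", "phase", "gender", "subphenotype"]


class GenotypeDataError(ValueError):
    """Inconsistent genotype data (dimension mismatch, bad call codes...)."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele count matrix with metadata.

    Parameters
    ----------
    calls
        Integer array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2, MISSING}``.
    snps
        One row per SNP with columns ``id, chrom, pos, allele_minor,
        allele_major``; positions are 1-based and sorted within each
        chromosome.
    samples
        One row per sample with columns ``id, disease, phase, gender,
        subphenotype`` plus any number of quantitative-trait columns
        (``NaN`` marks a trait not measured for that sample).
    """

    calls: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.calls.ndim != 2:
            raise GenotypeDataError("calls must be a 2-D samples x SNPs array")
        n_samples, n_snps = self.calls.shape
        if len(self.samples) != n_samples:
            raise GenotypeDataError(
                f"sample metadata has {len(self.samples)} rows for "
                f"{n_samples} call-matrix rows"
            )
        if len(self.snps) != n_snps:
            raise GenotypeDataError(
                f"SNP metadata has {len(self.snps)} rows for "
                f"{n_snps} call-matrix columns"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeDataError(
                f"invalid genotype code {self.calls[i, j]} at sample "
                f"{self.samples['id'].iloc[i]}, SNP {self.snps['id'].iloc[j]}"
            )
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise GenotypeDataError(f"SNP table lacks columns {missing_cols}")
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise GenotypeDataError(f"sample table lacks columns {missing_cols}")
        if self.snps["id"].duplicated().any():
            dup = self.snps.loc[self.snps["id"].duplicated(), "id"].iloc[0]
            raise GenotypeDataError(f"duplicate SNP id {dup!r}")
        if n_snps and (self.snps["pos"] < 1).any():
            raise GenotypeDataError("SNP positions must be >= 1 (1-based)")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise GenotypeDataError(
                    f"SNPs on chromosome {chrom} are not sorted by position"
                )
        normals = self.samples["disease"] == NORMAL
        if (self.samples.loc[normals, "phase"] != PHASE_NONE).any():
            raise GenotypeDataError("NORMAL samples must have phase 'none'")

    # -- shape helpers ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def sample_mask(self, disease: str | None = None, phase: str | None = None) -> np.ndarray:
        """Boolean row mask for a disease and/or phase."""
        mask = np.ones(self.n_samples, dtype=bool)
        if disease is not None:
            mask &= (self.samples["disease"] == disease).to_numpy()
        if phase is not None:
            mask &= (self.samples["phase"] == phase).to_numpy()
        return mask

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[mask], self.snps.copy(), self.samples.loc[mask].copy()
        )

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = mask
        else:
            cols = np.zeros(self.n_snps, dtype=bool)
            cols[mask] = True
        return GenotypeMatrix(
            self.calls[:, cols], self.snps.loc[cols].copy(), self.samples.copy()
        )

    # -- summaries ----------------------------------------------------------

    def genotype_counts(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP genotype counts, shape ``(n_snps, 3)`` = (n0, n1, n2).

        Missing calls are excluded; ``mask`` restricts to a sample subset.
        """
        calls = self.calls if mask is None else self.calls[mask]
        counts = np.empty((self.n_snps, 3), dtype=np.int64)
        for g in (0, 1, 2):
            counts[:, g] = (calls == g).sum(axis=0)
        return counts

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP over all samples."""
        return (self.calls != MISSING).mean(axis=0)

    def minor_allele_freq(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP minor-allele frequency in a sample subset (NaN if no calls)."""
        counts = self.genotype_counts(mask)
        alleles = 2 * counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                alleles > 0, (counts[:, 1] + 2 * counts[:, 2]) / alleles, np.nan
            )


@dataclass
class QCReport:
    """Outcome of the per-SNP quality filters.

    ``removed_low_callrate`` lists SNPs eliminated outright; ``hwe_flagged``
    lists (snp_id, p) pairs queued for manual review rather than removed,
    since a Hardy-Weinberg failure can reflect a genuine association as
    easily as a genotyping artifact. ``monomorphic`` lists SNPs with no
    minor-allele copies, which carry no association information.
    """

    removed_low_callrate: list[str] = field(default_factory=list)
    hwe_flagged: list[tuple[str, float]] = field(default_factory=list)
    monomorphic: list[str] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a TSV-ready table: snp_id, reason, value, threshold."""
        rows: list[tuple[str, str, float, float]] = []
        for snp in self.removed_low_callrate:
            rows.append(
                (snp, "low_call_rate", np.nan, self.thresholds.get("callrate_min", np.nan))
            )
        for snp, p in self.hwe_flagged:
            rows.append((snp, "hwe_flag", p, self.thresholds.get("hwe_alpha", np.nan)))
        for snp in self.monomorphic:
            rows.append((snp, "monomorphic", np.nan, np.nan))
        return pd.DataFrame(rows, columns=["snp_id", "reason", "value", "threshold"])
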