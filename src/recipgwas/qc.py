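"""Per-SNP quality control: call-rate filtering and Hardy-Weinberg checks.

Two filters run before association testing:

* SNPs with a call rate strictly below the threshold (default 85%) are
  eliminated; a SNP at exactly the threshold is retained.
* Genotype counts are tested against Hardy-Weinberg proportions at
  p < 0.001. Failing SNPs are *flagged for manual review*, not removed —
  a genuine disease association distorts pooled genotype proportions in
  exactly the way a genotyping artifact does, so Hardy-Weinberg tests
  default to running within each disease cohort separately, flagging a
  SNP if any cohort fails.

The default Hardy-Weinberg test is the 1-df goodness-of-fit chi-square on
expected counts from the observed allele frequency; the conditional exact
test is available via ``method="exact"``.
"""

from __future__ import annotations

from math import lgamma, log

import numpy as np
from scipy import stats

from .core import NORMAL, GenotypeMatrix, QCReport


def hwe_test(genotype_counts: tuple[int, int, int], method: str = "chisq") -> float:
    """Hardy-Weinberg equilibrium p-value for one SNP.

    Parameters
    ----------
    genotype_counts
        ``(n_AA, n_Aa, n_aa)`` with ``a`` the minor allele.
    method
        ``"chisq"`` for the 1-df goodness-of-fit chi-square (default) or
        ``"exact"`` for the conditional exact test on heterozygote count.

    Monomorphic counts (no copies of one allele) return p = 1: no
    departure from equilibrium is testable.
    """
    n0, n1, n2 = (int(c) for c in genotype_counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("all-zero genotype counts: HWE undefined")
    n_minor = n1 + 2 * n2
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0
    if method == "chisq":
        q = n_minor / (2 * n)
        expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
        chi2 = float((((np.array([n0, n1, n2]) - expected) ** 2) / expected).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(n, n_minor, n1)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n: int, n_minor: int, n_het_obs: int) -> float:
    """Conditional exact HWE p: sum of heterozygote-count probabilities
    no larger than the observed one, given n and the minor-allele count."""
    n_major = 2 * n - n_minor
    # log P(n_het | n, n_minor) up to a shared constant
    hets = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    logp = np.array(
        [
            h * log(2)
            - lgamma((n_minor - h) / 2 + 1)
            - lgamma(h + 1)
            - lgamma((n_major - h) / 2 + 1)
            for h in hets
        ]
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == n_het_obs][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def filter_call_rate(
    g: GenotypeMatrix, min_rate: float = 0.85
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs whose call rate is strictly below ``min_rate``.

    A SNP with call rate exactly ``min_rate`` is retained ("less than"
    is exclusive). Idempotent: filtering a filtered matrix is a no-op.
    """
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must lie in (0, 1]")
    rates = g.call_rate()
    keep = rates >= min_rate
    report = QCReport(
        removed_low_callrate=list(g.snps.loc[~keep, "id"]),
        thresholds={"callrate_min": min_rate},
    )
    return g.subset_snps(keep), report


def run_qc(
    g: GenotypeMatrix,
    min_call_rate: float = 0.85,
    hwe_alpha: float = 0.001,
    hwe_scope: str = "per-cohort",
    hwe_method: str = "chisq",
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC pass: call-rate filter, then Hardy-Weinberg flagging.

    ``hwe_scope`` is ``"per-cohort"`` (test within each disease cohort and
    the normals separately; flag if any fails — the default, robust to
    genuine associations) or ``"pooled"`` (one test over all samples).
    Returns the call-rate-filtered matrix and a report whose HWE entries
    are flags for manual inspection, not removals.
    """
    filtered, report = filter_call_rate(g, min_call_rate)
    report.thresholds["hwe_alpha"] = hwe_alpha

    if hwe_scope == "pooled":
        groups = [np.ones(filtered.n_samples, dtype=bool)]
    elif hwe_scope == "per-cohort":
        labels = [d for d in filtered.samples["disease"].unique()]
        groups = [filtered.sample_mask(disease=d) for d in labels]
    else:
        raise ValueError(f"unknown hwe_scope {hwe_scope!r}")

    worst = np.ones(filtered.n_snps)
    for mask in groups:
        counts = filtered.genotype_counts(mask)
        for j in range(filtered.n_snps):
            if counts[j].sum() == 0:
                continue
            p = hwe_test(tuple(counts[j]), method=hwe_method)
            worst[j] = min(worst[j], p)

    pooled = filtered.genotype_counts()
    minor_copies = pooled[:, 1] + 2 * pooled[:, 2]
    report.monomorphic = list(filtered.snps.loc[minor_copies == 0, "id"])

    flagged = worst < hwe_alpha
    report.hwe_flagged = [
        (snp, float(p))
        for snp, p in zip(filtered.snps.loc[flagged, "id"], worst[flagged])
    ]
    return filtered, report
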