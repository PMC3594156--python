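"""Per-SNP association statistics for the reciprocal case-control design.

The workhorse is the Cochran-Armitage trend test with additive genotype
scores (0, 1, 2 copies of the minor allele), applied to each SNP's
2 x 3 genotype table of one disease cohort against the other. Population
stratification is handled by genomic control: a variance-inflation
factor lambda is estimated from the genome-wide statistic distribution
using 0.1-trimmed means (the central 80% of the observed statistics
against the matching trimmed mean of the chi-square(1) reference), and
each statistic is deflated by lambda before its p-value is taken.
lambda is never allowed below 1 when correcting, so correction can only
make p-values more conservative.

Quantitative traits use single-SNP ordinary least squares of trait on
minor-allele count, with the Wald chi-square corrected through the same
lambda mechanism. Allelic odds ratios are reconstructed from group
minor-allele frequencies with Woolf (log-OR) confidence intervals, and
Fisher's exact test (two-sided, point-probability rule) backs the
disease-of-origin classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_TREND_SCORES = np.array([0.0, 1.0, 2.0])


class UndefinedInputError(ValueError):
    """Raised when an operation receives input it is undefined on."""


# ---------------------------------------------------------------------------
# Cochran-Armitage trend test
# ---------------------------------------------------------------------------

def trend_statistics(case_counts: np.ndarray, control_counts: np.ndarray) -> np.ndarray:
    """Vectorized Cochran-Armitage trend chi-squares.

    Parameters
    ----------
    case_counts, control_counts
        Arrays of shape ``(..., 3)`` of genotype counts (0, 1, 2 minor
        alleles) in cases and controls.

    Returns the 1-df trend chi-square per leading index; degenerate
    tables (no variation in genotype or in status) yield 0.
    """
    r = np.asarray(case_counts, dtype=float)
    n = r + np.asarray(control_counts, dtype=float)
    big_r = r.sum(axis=-1)
    big_n = n.sum(axis=-1)
    s_r = (r * _TREND_SCORES).sum(axis=-1)
    s_n = (n * _TREND_SCORES).sum(axis=-1)
    s2_n = (n * _TREND_SCORES**2).sum(axis=-1)
    num = big_n * s_r - big_r * s_n
    var = big_r * (big_n - big_r) / np.where(big_n > 0, big_n, 1.0) * (
        big_n * s2_n - s_n**2
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(var > 0, num**2 / np.where(var > 0, var, 1.0), 0.0)
    return chi2


def armitage_trend(
    case_counts: tuple[int, int, int] | np.ndarray,
    control_counts: tuple[int, int, int] | np.ndarray,
) -> tuple[float, float]:
    """Cochran-Armitage trend test for one 2 x 3 genotype table.

    Returns ``(statistic, p_raw)`` with the p-value from the upper tail
    of chi-square(1). Identical case and control genotype distributions
    give statistic 0, p = 1.
    """
    case_counts = np.asarray(case_counts, dtype=float)
    control_counts = np.asarray(control_counts, dtype=float)
    if case_counts.sum() <= 0 or control_counts.sum() <= 0:
        raise UndefinedInputError("both rows of the trend table must be non-empty")
    chi2 = float(trend_statistics(case_counts, control_counts))
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Genomic control
# ---------------------------------------------------------------------------

@dataclass
class InflationEstimate:
    """Variance-inflation factor from trimmed genome-wide statistics."""

    lambda_: float
    trim_fraction: float
    n_snps_used: int

    @property
    def corrective(self) -> float:
        """lambda floored at 1: correction never deflates p-values."""
        return max(1.0, self.lambda_)


def estimate_inflation(
    statistics: np.ndarray, trim_fraction: float = 0.1
) -> InflationEstimate:
    """Estimate lambda from a vector of trend chi-squares.

    lambda is the ratio of the trimmed mean of the observed statistics to
    the identically-trimmed mean of the chi-square(1) reference
    distribution, computed numerically. With ``trim_fraction = 0`` this
    reduces to mean-based genomic control (the chi-square(1) mean is 1).
    """
    statistics = np.asarray(statistics, dtype=float)
    if statistics.size == 0:
        raise UndefinedInputError("cannot estimate inflation from zero statistics")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    observed = stats.trim_mean(statistics, trim_fraction)
    if trim_fraction == 0:
        reference = 1.0
    else:
        lo, hi = stats.chi2.ppf([trim_fraction, 1 - trim_fraction], df=1)
        reference = stats.chi2.expect(lb=lo, ub=hi, conditional=True, args=(1,))
    return InflationEstimate(
        lambda_=float(observed / reference),
        trim_fraction=trim_fraction,
        n_snps_used=int(statistics.size),
    )


def correct_pvalue(statistic: float | np.ndarray, inflation: InflationEstimate) -> np.ndarray:
    """Inflation-corrected p-value: upper chi-square(1) tail of stat/lambda."""
    return stats.chi2.sf(np.asarray(statistic, dtype=float) / inflation.corrective, df=1)


# ---------------------------------------------------------------------------
# Quantitative traits
# ---------------------------------------------------------------------------

@dataclass
class QtResult:
    """Single-SNP linear-regression result for a quantitative trait."""

    slope: float
    se: float
    statistic: float
    p_raw: float
    p_corrected: float
    n: int
    untestable: bool = False


def qt_association(
    trait: np.ndarray,
    genotypes: np.ndarray,
    inflation: InflationEstimate | None = None,
) -> QtResult:
    """Regress a quantitative trait on minor-allele count at one SNP.

    Missing entries (NaN trait or negative genotype code) are dropped
    pairwise. The Wald chi-square ``(slope/se)^2`` is corrected through
    the genomic-control lambda when an estimate is supplied. A SNP with
    no genotype variance among the measured samples is reported as
    untestable rather than raising.
    """
    trait = np.asarray(trait, dtype=float)
    genotypes = np.asarray(genotypes, dtype=float)
    ok = ~np.isnan(trait) & (genotypes >= 0)
    trait, genotypes = trait[ok], genotypes[ok]
    n = trait.size
    if n < 3:
        raise UndefinedInputError("need at least 3 non-missing (trait, genotype) pairs")
    if np.ptp(genotypes) == 0:
        return QtResult(np.nan, np.nan, np.nan, np.nan, np.nan, n, untestable=True)
    fit = stats.linregress(genotypes, trait)
    wald = (fit.slope / fit.stderr) ** 2
    p_raw = float(stats.chi2.sf(wald, df=1))
    if inflation is None:
        p_corr = p_raw
    else:
        p_corr = float(correct_pvalue(wald, inflation))
    return QtResult(
        slope=float(fit.slope),
        se=float(fit.stderr),
        statistic=float(wald),
        p_raw=p_raw,
        p_corrected=p_corr,
        n=n,
    )


def qt_scan(
    trait: np.ndarray,
    calls: np.ndarray,
    trim_fraction: float = 0.1,
) -> pd.DataFrame:
    """Genome-wide quantitative-trait scan with genomic control.

    ``calls`` is the samples x SNPs matrix; SNPs with no genotype
    variance are reported with NaN results. lambda is estimated from the
    Wald chi-squares of the testable SNPs, then applied to all of them.
    """
    results = []
    for j in range(calls.shape[1]):
        try:
            res = qt_association(trait, calls[:, j])
        except UndefinedInputError:
            res = QtResult(np.nan, np.nan, np.nan, np.nan, np.nan, 0, untestable=True)
        results.append(res)
    stats_vec = np.array([r.statistic for r in results])
    testable = ~np.isnan(stats_vec)
    if testable.sum() >= 2:
        inflation = estimate_inflation(stats_vec[testable], trim_fraction)
        p_corr = np.full(len(results), np.nan)
        p_corr[testable] = correct_pvalue(stats_vec[testable], inflation)
        lam = inflation.lambda_
    else:
        p_corr = np.array([r.p_raw for r in results])
        lam = 1.0
    frame = pd.DataFrame(
        {
            "slope": [r.slope for r in results],
            "se": [r.se for r in results],
            "statistic": stats_vec,
            "p_raw": [r.p_raw for r in results],
            "p_corrected": p_corr,
            "n": [r.n for r in results],
        }
    )
    frame.attrs["lambda"] = lam
    return frame


# ---------------------------------------------------------------------------
# Logistic covariate check
# ---------------------------------------------------------------------------

@dataclass
class LogisticCheck:
    """Genotype p-value from disease ~ genotype + gender, or a separation flag."""

    p_value: float
    separated: bool


def logistic_check(
    disease_labels: np.ndarray, genotypes: np.ndarray, gender: np.ndarray
) -> LogisticCheck:
    """Logistic regression of disease status on genotype plus gender.

    A sanity check that gender imbalance between the cohorts is not
    driving an association: on gender-balanced data the genotype p-value
    tracks the trend-test conclusion. Perfect separation is flagged and
    the p-value reported as missing.
    """
    import statsmodels.api as sm

    disease_labels = np.asarray(disease_labels)
    diseases = np.unique(disease_labels)
    if diseases.size != 2:
        raise UndefinedInputError("exactly two disease labels required")
    genders = np.unique(np.asarray(gender))
    if genders.size != 2:
        raise UndefinedInputError("both genders must be present")
    y = (disease_labels == diseases[1]).astype(float)
    x = sm.add_constant(
        np.column_stack(
            [np.asarray(genotypes, dtype=float), (np.asarray(gender) == genders[1]).astype(float)]
        )
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
            return LogisticCheck(p_value=np.nan, separated=True)
        return LogisticCheck(p_value=float(fit.pvalues[1]), separated=False)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return LogisticCheck(p_value=np.nan, separated=True)


# ---------------------------------------------------------------------------
# Allelic odds ratios and Fisher's exact test
# ---------------------------------------------------------------------------

@dataclass
class OddsRatio:
    value: float
    ci_low: float
    ci_high: float
    zero_cell_corrected: bool = False


def allelic_odds_ratio(
    maf_case: float,
    maf_ctrl: float,
    n_case_alleles: int,
    n_ctrl_alleles: int,
) -> OddsRatio:
    """Allelic odds ratio with a Woolf 95% confidence interval.

    Allele counts are reconstructed from the group minor-allele
    frequencies (``round(maf * n_alleles)``); a zero cell triggers the
    Haldane-Anscombe +0.5 correction on all four cells and is flagged.
    """
    for f in (maf_case, maf_ctrl):
        if not 0 <= f <= 1:
            raise ValueError("allele frequencies must lie in [0, 1]")
    a = round(maf_case * n_case_alleles)
    b = n_case_alleles - a
    c = round(maf_ctrl * n_ctrl_alleles)
    d = n_ctrl_alleles - c
    return odds_ratio_from_counts(a, b, c, d)


def odds_ratio_from_counts(a: float, b: float, c: float, d: float) -> OddsRatio:
    """Odds ratio (a/b)/(c/d) with Woolf CI; Haldane correction on zero cells."""
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    value = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    log_or = np.log(value)
    return OddsRatio(
        value=float(value),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        zero_cell_corrected=corrected,
    )


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value (point-probability rule) for a 2x2 table."""
    table = np.asarray(table)
    if (table < 0).any():
        raise ValueError("Fisher table counts must be non-negative")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Whole-phase scan
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """One SNP's association record within one phase (or the joint analysis)."""

    snp_id: str
    statistic: float
    p_raw: float
    p_corrected: float
    phase: str
    maf_by_group: dict[str, float]
    odds_ratio: OddsRatio


def trend_scan(
    g,
    phase: str | None,
    case_disease: str = "AMD",
    control_disease: str = "POAG",
    trim_fraction: float = 0.1,
) -> pd.DataFrame:
    """Trend-test every SNP, one disease cohort against the other.

    ``phase`` restricts to the primary or validation cohorts; ``None``
    pools both phases (the joint analysis). The genomic-control lambda is
    estimated from this scan's own statistics and applied uniformly; the
    result table records raw and corrected p-values, per-group MAFs (the
    normals included when present), and the case-vs-control allelic odds
    ratio. The scan's lambda is stored in ``frame.attrs['lambda']``.
    """
    from .core import NORMAL

    case_mask = g.sample_mask(disease=case_disease, phase=phase)
    ctrl_mask = g.sample_mask(disease=control_disease, phase=phase)
    if case_mask.sum() == 0 or ctrl_mask.sum() == 0:
        raise UndefinedInputError(
            f"no samples for {case_disease} or {control_disease} in phase {phase!r}"
        )
    case_counts = g.genotype_counts(case_mask)
    ctrl_counts = g.genotype_counts(ctrl_mask)
    chi2 = trend_statistics(case_counts, ctrl_counts)
    p_raw = stats.chi2.sf(chi2, df=1)
    inflation = estimate_inflation(chi2, trim_fraction)
    p_corr = correct_pvalue(chi2, inflation)

    maf_case = g.minor_allele_freq(case_mask)
    maf_ctrl = g.minor_allele_freq(ctrl_mask)
    normal_mask = g.sample_mask(disease=NORMAL)
    maf_normal = (
        g.minor_allele_freq(normal_mask) if normal_mask.any() else np.full(g.n_snps, np.nan)
    )
    n_case_alleles = 2 * case_counts.sum(axis=1)
    n_ctrl_alleles = 2 * ctrl_counts.sum(axis=1)
    ors = np.full((g.n_snps, 3), np.nan)
    for j in range(g.n_snps):
        if n_case_alleles[j] == 0 or n_ctrl_alleles[j] == 0:
            continue
        orr = allelic_odds_ratio(
            maf_case[j], maf_ctrl[j], int(n_case_alleles[j]), int(n_ctrl_alleles[j])
        )
        ors[j] = (orr.value, orr.ci_low, orr.ci_high)

    frame = pd.DataFrame(
        {
            "snp_id": g.snps["id"].to_numpy(),
            "chrom": g.snps["chrom"].to_numpy(),
            "pos": g.snps["pos"].to_numpy(),
            "phase": "joint" if phase is None else phase,
            "statistic": chi2,
            "p_raw": p_raw,
            "p_corrected": p_corr,
            f"maf_{case_disease.lower()}": maf_case,
            "maf_normal": maf_normal,
            f"maf_{control_disease.lower()}": maf_ctrl,
            "or": ors[:, 0],
            "ci_low": ors[:, 1],
            "ci_high": ors[:, 2],
        }
    )
    frame.attrs["lambda"] = inflation.lambda_
    frame.attrs["case_disease"] = case_disease
    frame.attrs["control_disease"] = control_disease
    return frame
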