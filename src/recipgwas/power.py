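"""Simulated power of the case-control trend test under a penetrance model.

The disease model is multiplicative on the odds scale: the non-risk
homozygote dd carries a baseline disease risk (0.001 by default) and each
copy of the risk allele D multiplies the odds of disease by a fixed odds
ratio, so odds(Dd) = OR x odds(dd) and odds(DD) = OR^2 x odds(dd). With
genotype frequencies at Hardy-Weinberg proportions for the risk-allele
frequency, Bayes' rule gives the genotype distribution among cases
(proportional to frequency x risk) and among controls (proportional to
frequency x (1 - risk)). Power is estimated retrospectively: each
replicate draws fixed numbers of cases and controls directly from those
conditional genotype distributions — equivalent to prospective population
sampling under the model and far faster at a 0.001 baseline risk — and
applies the uncorrected Cochran-Armitage trend test; power at a
significance level is the fraction of replicates rejecting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import trend_statistics

DEFAULT_ALPHAS = (5e-7, 1e-5, 5e-5)


@dataclass
class PowerSpec:
    """One cell of the power grid.

    ``odds_ratio`` is the per-genotype-step disease odds ratio (Dd vs dd,
    equal to DD vs Dd). ``maf`` is the frequency of the *minor, non-risk*
    allele d: the risk allele D is the major allele at frequency
    ``1 - maf``, so the baseline-risk genotype dd is the rare homozygote.
    400 cases and 400 controls per replicate by default.
    """

    odds_ratio: float
    maf: float
    baseline_risk: float = 0.001
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    n_cases: int = 400
    n_controls: int = 400
    n_reps: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.baseline_risk < 1:
            raise ValueError("baseline_risk must lie in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if any(not 0 < a < 1 for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1)")


@dataclass
class PowerResult:
    spec: PowerSpec
    power_by_alpha: dict[float, float]
    mc_se_by_alpha: dict[float, float] = field(default_factory=dict)


def penetrance_model(spec: PowerSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotype distributions implied by the multiplicative-odds model.

    Returns ``(case_dist, control_dist, population_freqs)``, each a
    length-3 simplex ordered by risk-allele copies (dd, Dd, DD). With
    OR = 1 both conditional distributions equal the Hardy-Weinberg
    population frequencies; as baseline risk tends to 0 the control
    distribution tends to the population frequencies.
    """
    spec.validate()
    p = 1 - spec.maf  # risk allele D is the major allele
    freqs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    odds0 = spec.baseline_risk / (1 - spec.baseline_risk)
    odds = odds0 * spec.odds_ratio ** np.arange(3)
    risk = odds / (1 + odds)
    case = freqs * risk
    control = freqs * (1 - risk)
    return case / case.sum(), control / control.sum(), freqs


def simulate_power(spec: PowerSpec) -> PowerResult:
    """Monte-Carlo power of the trend test for one grid cell.

    Deterministic given ``spec.seed``; all replicates are drawn and
    tested vectorized. The Monte-Carlo standard error per level is
    ``sqrt(p(1-p)/n_reps)``.
    """
    spec.validate()
    case_dist, control_dist, _ = penetrance_model(spec)
    rng = np.random.default_rng(spec.seed)
    case_counts = rng.multinomial(spec.n_cases, case_dist, size=spec.n_reps)
    control_counts = rng.multinomial(spec.n_controls, control_dist, size=spec.n_reps)
    chi2 = trend_statistics(case_counts, control_counts)
    power: dict[float, float] = {}
    mc_se: dict[float, float] = {}
    for alpha in spec.alphas:
        critical = stats.chi2.isf(alpha, df=1)
        p = float((chi2 > critical).mean())
        power[alpha] = p
        mc_se[alpha] = float(np.sqrt(p * (1 - p) / spec.n_reps))
    return PowerResult(spec=spec, power_by_alpha=power, mc_se_by_alpha=mc_se)


def power_grid(
    or_values: tuple[float, ...] = (1.75, 2.0, 2.5),
    maf_values: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40),
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    baseline_risk: float = 0.001,
    n_cases: int = 400,
    n_controls: int = 400,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate the full OR x MAF x alpha power grid.

    Each cell gets an independent child seed derived from ``seed`` so
    the grid is reproducible and cells are order-independent. Returns
    one row per (OR, MAF) with a power column per significance level.
    """
    if not or_values or not maf_values or not alphas:
        raise ValueError("grids must be non-empty")
    children = np.random.SeedSequence(seed).spawn(len(or_values) * len(maf_values))
    rows = []
    k = 0
    for orr in or_values:
        for maf in maf_values:
            spec = PowerSpec(
                odds_ratio=orr,
                maf=maf,
                baseline_risk=baseline_risk,
                alphas=tuple(alphas),
                n_cases=n_cases,
                n_controls=n_controls,
                n_reps=n_reps,
                seed=int(children[k].generate_state(1)[0] % 2**31),
            )
            k += 1
            result = simulate_power(spec)
            row = {"odds_ratio": orr, "maf": maf}
            for alpha in alphas:
                row[f"power_alpha_{alpha:g}"] = result.power_by_alpha[alpha]
            rows.append(row)
    return pd.DataFrame(rows)
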