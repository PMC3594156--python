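"""Two-stage discovery: replication, locus clustering, classification.

The reciprocal design tests every SNP in a primary cohort pair (200 AMD
vs 200 POAG), again in an independent validation pair, and jointly in
the pooled 400 vs 400 comparison. A SNP is *retained* at the significant
tier when its joint p-value clears genome-wide significance (5e-7) and
both phases replicate it (phase p below the replication threshold), or
at the suggestive tier (joint p < 1e-5) with nominal replication in both
phases. Retained SNPs are then chained into locus clusters: consecutive
SNPs on one chromosome at most 200 kb apart, with at least three members
required to call a locus.

Because either disease cohort could be driving an association, each
cluster is classified by comparing its peak SNP's allele counts in each
disease against a normative control population (a genotyped normal
cohort, or expected counts from published reference frequencies) with
Fisher's exact test: the locus is assigned to the disease whose counts
differ from normal (p < 0.05) in both phases while the other disease
stays consistent with normal (p > 0.05) in both phases; anything else is
left unclassified.

Candidate-region evaluation restricts the scan to a priori intervals
(monogenic-glaucoma linkage intervals, candidate gene panels) under a
gene-level Bonferroni correction: panel alpha divided by the number of
genes evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import fisher_exact
from .core import NORMAL, GenotypeMatrix


@dataclass
class Thresholds:
    """Significance machinery of the two-stage design (defaults as studied)."""

    significant: float = 5e-7
    suggestive: float = 1e-5
    cluster_min_snps: int = 3
    cluster_max_gap: int = 200_000
    classify_alpha: float = 0.05
    #: per-phase replication p-value required at each tier
    replication_significant: float = 1e-5
    replication_suggestive: float = 0.05

    def __post_init__(self) -> None:
        if not self.significant < self.suggestive:
            raise ValueError("significant threshold must be below suggestive")
        if self.cluster_min_snps < 1 or self.cluster_max_gap <= 0:
            raise ValueError("cluster rule parameters out of range")


@dataclass
class LocusCluster:
    """A genomic interval of co-associated, replicated SNPs."""

    chrom: str
    start: int
    end: int
    member_snps: list[str]
    peak_snp: str
    tier: str
    p_primary: float
    p_validation: float
    p_joint: float
    classification: str = "unclassified"
    classification_detail: dict = field(default_factory=dict)


@dataclass
class CandidateRegion:
    """An a priori interval (linkage locus or candidate gene), 1-based closed."""

    name: str
    chrom: str
    start: int
    end: int
    n_genes_in_panel: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start > end")


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

def two_stage_select(
    primary: pd.DataFrame,
    validation: pd.DataFrame,
    joint: pd.DataFrame,
    t: Thresholds,
    p_column: str = "p_corrected",
) -> pd.DataFrame:
    """Retain SNPs that are jointly significant/suggestive and replicate.

    All three scans must cover the same SNP panel; a SNP missing from
    any scan is excluded and listed in ``frame.attrs['excluded']``. The
    returned table carries the joint scan's rows for retained SNPs plus
    ``p_primary``, ``p_validation`` and ``tier`` columns.
    """
    key = "snp_id"
    merged = joint.merge(
        primary[[key, p_column]].rename(columns={p_column: "p_primary"}), on=key
    ).merge(
        validation[[key, p_column]].rename(columns={p_column: "p_validation"}),
        on=key,
    )
    excluded = sorted(
        set(joint[key]) ^ set(primary[key]) | set(joint[key]) ^ set(validation[key])
    )
    p_joint = merged[p_column].to_numpy()
    p1 = merged["p_primary"].to_numpy()
    p2 = merged["p_validation"].to_numpy()
    sig = (
        (p_joint < t.significant)
        & (p1 < t.replication_significant)
        & (p2 < t.replication_significant)
    )
    sug = (
        (p_joint < t.suggestive)
        & (p1 < t.replication_suggestive)
        & (p2 < t.replication_suggestive)
        & ~sig
    )
    retained = merged.loc[sig | sug].copy()
    retained["tier"] = np.where(sig[sig | sug], "significant", "suggestive")
    retained = retained.rename(columns={p_column: "p_joint"})
    retained.attrs["excluded"] = excluded
    return retained


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_loci(retained: pd.DataFrame, t: Thresholds) -> list[LocusCluster]:
    """Chain retained SNPs into loci by single-linkage on position.

    Within each chromosome, consecutive retained SNPs at most
    ``cluster_max_gap`` base pairs apart (closed bound) join one
    cluster; fragments with fewer than ``cluster_min_snps`` members are
    discarded. The peak SNP minimizes the joint p-value, ties broken by
    the smaller position. A cluster is tier "significant" when at least
    ``cluster_min_snps`` members are significant-tier SNPs, else
    "suggestive". Output is independent of input row order.
    """
    if retained.empty:
        return []
    table = retained.sort_values(["chrom", "pos"], kind="mergesort")
    clusters: list[LocusCluster] = []
    for chrom, grp in table.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > t.cluster_max_gap) + 1
        for chunk in np.split(np.arange(len(grp)), breaks):
            members = grp.iloc[chunk]
            if len(members) < t.cluster_min_snps:
                continue
            peak = members.sort_values(["p_joint", "pos"], kind="mergesort").iloc[0]
            n_sig = int((members["tier"] == "significant").sum())
            clusters.append(
                LocusCluster(
                    chrom=str(chrom),
                    start=int(members["pos"].min()),
                    end=int(members["pos"].max()),
                    member_snps=list(members["snp_id"]),
                    peak_snp=str(peak["snp_id"]),
                    tier="significant" if n_sig >= t.cluster_min_snps else "suggestive",
                    p_primary=float(peak["p_primary"]),
                    p_validation=float(peak["p_validation"]),
                    p_joint=float(peak["p_joint"]),
                )
            )
    return clusters


def clusters_to_frame(clusters: list[LocusCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "n_snps": [len(c.member_snps) for c in clusters],
            "peak_snp": [c.peak_snp for c in clusters],
            "tier": [c.tier for c in clusters],
            "p_primary": [c.p_primary for c in clusters],
            "p_validation": [c.p_validation for c in clusters],
            "p_joint": [c.p_joint for c in clusters],
            "classification": [c.classification for c in clusters],
        }
    )


def clusters_to_bed(clusters: list[LocusCluster]) -> pd.DataFrame:
    """BED representation: 0-based half-open intervals from 1-based closed."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start - 1 for c in clusters],
            "end": [c.end for c in clusters],
            "name": [f"{c.classification}:{c.peak_snp}" for c in clusters],
        }
    )


# ---------------------------------------------------------------------------
# disease-of-origin classification
# ---------------------------------------------------------------------------

def peak_allele_counts(
    g: GenotypeMatrix,
    snp_id: str,
    normative_freqs: pd.Series | None = None,
    reference_n: int = 100,
) -> dict[tuple[str, str], tuple[int, int]]:
    """Minor/major allele counts at one SNP per (disease, phase) cell.

    The normative cell is keyed ``(NORMAL, 'none')``. If a genotyped
    normal cohort is present it is counted directly; otherwise, when a
    reference frequency table is supplied, expected counts are formed at
    ``reference_n`` diploid individuals.
    """
    j = int(np.flatnonzero((g.snps["id"] == snp_id).to_numpy())[0])
    counts: dict[tuple[str, str], tuple[int, int]] = {}
    for disease in g.samples["disease"].unique():
        if disease == NORMAL:
            continue
        for phase in g.samples.loc[
            g.samples["disease"] == disease, "phase"
        ].unique():
            mask = g.sample_mask(disease=disease, phase=phase)
            gcounts = g.genotype_counts(mask)[j]
            minor = int(gcounts[1] + 2 * gcounts[2])
            total = int(2 * gcounts.sum())
            counts[(disease, phase)] = (minor, total - minor)
    normal_mask = g.sample_mask(disease=NORMAL)
    if normal_mask.any():
        gcounts = g.genotype_counts(normal_mask)[j]
        minor = int(gcounts[1] + 2 * gcounts[2])
        total = int(2 * gcounts.sum())
        counts[(NORMAL, "none")] = (minor, total - minor)
    elif normative_freqs is not None and snp_id in normative_freqs.index:
        maf = float(normative_freqs.loc[snp_id])
        minor = round(2 * reference_n * maf)
        counts[(NORMAL, "none")] = (minor, 2 * reference_n - minor)
    return counts


def classify_locus(
    cluster: LocusCluster,
    counts: dict[tuple[str, str], tuple[int, int]],
    t: Thresholds,
    diseases: tuple[str, str] = ("AMD", "POAG"),
    phases: tuple[str, str] = ("primary", "validation"),
) -> str:
    """Assign a cluster to a disease against normative allele counts.

    For each disease, the peak SNP's allele counts are compared to the
    normative counts with Fisher's exact test in each phase. The cluster
    is classified as disease D when D differs from normal (p < alpha) in
    both phases while the other disease is indistinguishable from normal
    (p > alpha) in both phases; otherwise it stays unclassified. The
    rule is symmetric in the two disease labels. Missing normative
    counts leave the cluster unclassified with a recorded reason.
    """
    normal = counts.get((NORMAL, "none"))
    if normal is None:
        cluster.classification = "unclassified"
        cluster.classification_detail = {"reason": "no normative counts for peak SNP"}
        return cluster.classification
    pvals: dict[str, list[float]] = {}
    for disease in diseases:
        pvals[disease] = []
        for phase in phases:
            cell = counts.get((disease, phase))
            if cell is None:
                cluster.classification = "unclassified"
                cluster.classification_detail = {
                    "reason": f"missing counts for {disease}/{phase}"
                }
                return cluster.classification
            pvals[disease].append(fisher_exact([list(cell), list(normal)]))
    alpha = t.classify_alpha
    label = "unclassified"
    for disease, other in (diseases, diseases[::-1]):
        if all(p < alpha for p in pvals[disease]) and all(
            p > alpha for p in pvals[other]
        ):
            label = disease
            break
    cluster.classification = label
    cluster.classification_detail = {
        d: tuple(ps) for d, ps in pvals.items()
    }
    return label


# ---------------------------------------------------------------------------
# candidate regions
# ---------------------------------------------------------------------------

def evaluate_candidate_regions(
    joint: pd.DataFrame,
    primary: pd.DataFrame,
    validation: pd.DataFrame,
    regions: list[CandidateRegion],
    panel_alpha: float = 0.05,
    p_column: str = "p_corrected",
) -> pd.DataFrame:
    """Region-restricted evaluation under a gene-level Bonferroni rule.

    Per region: the member SNPs (closed-interval overlap), the best SNP
    by joint p-value, best p per phase, the panel-corrected threshold
    ``panel_alpha / n_genes_in_panel``, and the count of member SNPs
    whose joint p falls below that threshold (the multi-SNP support
    count). Regions overlapping no SNPs are reported as untested.
    """
    if not regions:
        raise ValueError("no candidate regions supplied")
    p_by_phase = {
        "primary": primary.set_index("snp_id")[p_column],
        "validation": validation.set_index("snp_id")[p_column],
    }
    rows = []
    for region in regions:
        inside = joint[
            (joint["chrom"].astype(str) == str(region.chrom))
            & (joint["pos"] >= region.start)
            & (joint["pos"] <= region.end)
        ]
        threshold = panel_alpha / region.n_genes_in_panel
        if inside.empty:
            rows.append(
                {
                    "region": region.name,
                    "status": "untested",
                    "n_snps": 0,
                    "best_snp": None,
                    "best_p_joint": np.nan,
                    "best_p_primary": np.nan,
                    "best_p_validation": np.nan,
                    "threshold": threshold,
                    "n_support": 0,
                }
            )
            continue
        best = inside.sort_values([p_column, "pos"], kind="mergesort").iloc[0]
        n_support = int((inside[p_column] < threshold).sum())
        rows.append(
            {
                "region": region.name,
                "status": "significant" if best[p_column] < threshold else "tested",
                "n_snps": len(inside),
                "best_snp": best["snp_id"],
                "best_p_joint": float(best[p_column]),
                "best_p_primary": float(
                    p_by_phase["primary"].get(best["snp_id"], np.nan)
                ),
                "best_p_validation": float(
                    p_by_phase["validation"].get(best["snp_id"], np.nan)
                ),
                "threshold": threshold,
                "n_support": n_support,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end discovery
# ---------------------------------------------------------------------------

def run_discovery(
    g: GenotypeMatrix,
    t: Thresholds | None = None,
    normative_freqs: pd.Series | None = None,
    reference_n: int = 100,
    diseases: tuple[str, str] = ("AMD", "POAG"),
    trim_fraction: float = 0.1,
) -> tuple[list[LocusCluster], dict[str, pd.DataFrame]]:
    """Scan, replicate, cluster and classify in one call.

    Runs the trend scan per phase and jointly (one disease as case, the
    other as control — the test statistic is symmetric in that choice),
    applies the two-stage retention rule, chains clusters and classifies
    each against the normative counts. Returns the clusters and the
    three scan tables keyed ``primary``/``validation``/``joint``.
    """
    from .association import trend_scan

    t = t or Thresholds()
    scans = {
        "primary": trend_scan(g, "primary", *diseases, trim_fraction=trim_fraction),
        "validation": trend_scan(g, "validation", *diseases, trim_fraction=trim_fraction),
        "joint": trend_scan(g, None, *diseases, trim_fraction=trim_fraction),
    }
    retained = two_stage_select(scans["primary"], scans["validation"], scans["joint"], t)
    clusters = cluster_loci(retained, t)
    for cluster in clusters:
        counts = peak_allele_counts(
            g, cluster.peak_snp, normative_freqs=normative_freqs, reference_n=reference_n
        )
        classify_locus(cluster, counts, t, diseases=diseases)
    return clusters, scans
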