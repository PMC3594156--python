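"""Two-stage selection, locus clustering, classification, candidate regions."""

import numpy as np
import pandas as pd
import pytest

import recipgwas as rg
from recipgwas.discovery import Thresholds, classify_locus, cluster_loci


def make_results(rows):
    """Build minimal scan frames: rows of (snp_id, chrom, pos, p1, p2, pj)."""
    base = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p1", "p2", "pj"])
    primary = base.assign(p_corrected=base["p1"])[["snp_id", "chrom", "pos", "p_corrected"]]
    validation = base.assign(p_corrected=base["p2"])[["snp_id", "chrom", "pos", "p_corrected"]]
    joint = base.assign(p_corrected=base["pj"])[["snp_id", "chrom", "pos", "p_corrected"]]
    return primary, validation, joint


class TestTwoStageSelect:
    def test_replication_failure_is_not_retained(self):
        primary, validation, joint = make_results(
            [("rs1", "1", 100, 1e-8, 0.5, 1e-8)]
        )
        retained = rg.two_stage_select(primary, validation, joint, Thresholds())
        assert retained.empty

    def test_tiers_assigned_by_joint_p_and_replication(self):
        primary, validation, joint = make_results(
            [
                ("sig", "1", 100, 1e-7, 1e-6, 1e-9),
                ("sug", "1", 200, 1e-3, 1e-2, 5e-6),
                ("weak", "1", 300, 0.2, 0.3, 1e-6),
            ]
        )
        retained = rg.two_stage_select(primary, validation, joint, Thresholds())
        tiers = dict(zip(retained["snp_id"], retained["tier"]))
        assert tiers == {"sig": "significant", "sug": "suggestive"}

    def test_snp_missing_from_one_phase_excluded_and_logged(self):
        primary, validation, joint = make_results(
            [("rs1", "1", 100, 1e-8, 1e-8, 1e-9), ("rs2", "1", 200, 1e-8, 1e-8, 1e-9)]
        )
        retained = rg.two_stage_select(
            primary.iloc[:1], validation, joint, Thresholds()
        )
        assert list(retained["snp_id"]) == ["rs1"]
        assert retained.attrs["excluded"] == ["rs2"]


def retained_frame(positions, chrom="5", p=1e-9, tier="significant"):
    n = len(positions)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": chrom,
            "pos": positions,
            "p_joint": p if np.ndim(p) else [p] * n,
            "p_primary": [1e-6] * n,
            "p_validation": [1e-6] * n,
            "tier": [tier] * n,
        }
    )


class TestClusterLoci:
    def test_six_snp_locus_geometry(self):
        """Six SNPs spanning chr5:40,965,351-40,991,318 form one cluster."""
        positions = [40965351, 40970000, 40975000, 40980000, 40985000, 40991318]
        clusters = cluster_loci(retained_frame(positions), Thresholds())
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.chrom, c.start, c.end, len(c.member_snps)) == ("5", 40965351, 40991318, 6)

    def test_two_snps_below_minimum_count(self):
        clusters = cluster_loci(retained_frame([1000, 2000]), Thresholds())
        assert clusters == []

    def test_gap_boundary_is_closed_at_200kb(self):
        """Gaps of 199,999 and 200,001 bp split 3 SNPs into fragments of
        2 and 1, so no cluster reaches the 3-member minimum; an exact
        200,000 gap chains."""
        t = Thresholds()
        split = cluster_loci(retained_frame([1, 200_000, 400_001]), t)
        assert split == []
        chained = cluster_loci(retained_frame([1, 200_001, 400_001]), t)
        assert len(chained) == 1 and len(chained[0].member_snps) == 3

    def test_brute_force_partition_oracle(self):
        """Cluster memberships equal a brute-force scan of consecutive gaps."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            positions = np.sort(rng.choice(np.arange(1, 2_000_001), 12, replace=False))
            t = Thresholds()
            clusters = cluster_loci(retained_frame(list(positions)), t)
            # oracle: split positions wherever the gap exceeds the bound
            groups, current = [], [positions[0]]
            for prev, nxt in zip(positions, positions[1:]):
                if nxt - prev > t.cluster_max_gap:
                    groups.append(current)
                    current = []
                current.append(nxt)
            groups.append(current)
            expected = [g for g in groups if len(g) >= t.cluster_min_snps]
            assert [(c.start, c.end, len(c.member_snps)) for c in clusters] == [
                (g[0], g[-1], len(g)) for g in expected
            ]

    def test_order_invariance_and_peak_tie_break(self):
        frame = retained_frame([1000, 2000, 3000], p=[1e-9, 1e-9, 1e-12])
        shuffled = frame.sample(frac=1, random_state=4)
        a = cluster_loci(frame, Thresholds())
        b = cluster_loci(shuffled, Thresholds())
        assert a[0].peak_snp == b[0].peak_snp == "rs2"
        tie = retained_frame([1000, 2000, 3000], p=[1e-9, 1e-9, 1e-9])
        assert cluster_loci(tie, Thresholds())[0].peak_snp == "rs0"  # smaller pos

    def test_emitted_clusters_satisfy_their_invariants(self, planted_study):
        _, g = planted_study
        clusters, _ = rg.run_discovery(g)
        t = Thresholds()
        for c in clusters:
            assert len(c.member_snps) >= t.cluster_min_snps
            assert c.start <= c.end
            positions = g.snps.set_index("id").loc[c.member_snps, "pos"].to_numpy()
            assert (np.diff(np.sort(positions)) <= t.cluster_max_gap).all()


def counts_from_mafs(maf_amd, maf_nl, maf_poag, n_amd=400, n_nl=100, n_poag=400):
    def cell(maf, n):
        minor = round(2 * n * maf)
        return (minor, 2 * n - minor)

    counts = {}
    for phase in ("primary", "validation"):
        counts[("AMD", phase)] = cell(maf_amd, n_amd // 2)
        counts[("POAG", phase)] = cell(maf_poag, n_poag // 2)
    counts[("NORMAL", "none")] = cell(maf_nl, n_nl)
    return counts


def blank_cluster():
    return rg.LocusCluster(
        chrom="1", start=1, end=2, member_snps=["rs1", "rs2", "rs3"],
        peak_snp="rs1", tier="significant",
        p_primary=1e-8, p_validation=1e-8, p_joint=1e-10,
    )


class TestClassifyLocus:
    def test_amd_enriched_triple_classifies_amd(self):
        """MAFs 0.45/0.18/0.20 (AMD/normal/POAG) at 400/100/400."""
        counts = counts_from_mafs(0.45, 0.18, 0.20)
        assert classify_locus(blank_cluster(), counts, Thresholds()) == "AMD"

    def test_poag_enriched_triple_classifies_poag(self):
        """MAFs 0.36/0.36/0.48 classify to POAG."""
        counts = counts_from_mafs(0.36, 0.36, 0.48)
        assert classify_locus(blank_cluster(), counts, Thresholds()) == "POAG"

    def test_identical_frequencies_unclassified(self):
        counts = counts_from_mafs(0.3, 0.3, 0.3)
        assert classify_locus(blank_cluster(), counts, Thresholds()) == "unclassified"

    def test_symmetric_under_disease_label_swap(self):
        counts = counts_from_mafs(0.45, 0.18, 0.20)
        swapped = {
            ("AMD" if d == "POAG" else "POAG" if d == "AMD" else d, ph): v
            for (d, ph), v in counts.items()
        }
        a = classify_locus(blank_cluster(), counts, Thresholds())
        b = classify_locus(blank_cluster(), swapped, Thresholds())
        assert (a, b) == ("AMD", "POAG")

    def test_missing_normative_counts_leaves_unclassified_with_reason(self):
        counts = counts_from_mafs(0.45, 0.18, 0.20)
        del counts[("NORMAL", "none")]
        cluster = blank_cluster()
        assert classify_locus(cluster, counts, Thresholds()) == "unclassified"
        assert "no normative counts" in cluster.classification_detail["reason"]


class TestPeakAlleleCounts:
    def test_counts_from_genotyped_normals(self, planted_study):
        spec, g = planted_study
        counts = rg.peak_allele_counts(g, g.snps["id"].iloc[100])
        assert set(counts) == {
            ("AMD", "primary"), ("AMD", "validation"),
            ("POAG", "primary"), ("POAG", "validation"), ("NORMAL", "none"),
        }
        minor, major = counts[("AMD", "primary")]
        assert minor + major == 2 * 200

    def test_counts_from_frequency_table_at_reference_n(self, planted_study):
        spec, g = planted_study
        no_normals = g.subset_samples(~g.sample_mask(disease="NORMAL"))
        freqs = rg.normative_frequencies(spec).set_index("snp_id")["maf"]
        snp = g.snps["id"].iloc[100]
        counts = rg.peak_allele_counts(no_normals, snp, normative_freqs=freqs)
        minor, major = counts[("NORMAL", "none")]
        assert minor + major == 200  # 100 diploid reference individuals
        assert minor == round(200 * freqs.loc[snp])


class TestCandidateRegions:
    def test_eight_gene_panel_threshold(self):
        """A panel of 8 genes yields the 0.05/8 = 0.00625 threshold."""
        primary, validation, joint = make_results(
            [("rs1", "1", 100, 0.004, 0.003, 0.002)]
        )
        regions = [rg.CandidateRegion("GENE1", "1", 50, 150, n_genes_in_panel=8)]
        report = rg.evaluate_candidate_regions(joint, primary, validation, regions)
        assert report["threshold"].iloc[0] == pytest.approx(0.00625)
        assert report["status"].iloc[0] == "significant"
        assert report["n_support"].iloc[0] == 1

    def test_planted_region_supported(self, planted_study):
        spec, g = planted_study
        _, scans = rg.run_discovery(g)
        start = int(g.snps["pos"].iloc[100])
        end = int(g.snps["pos"].iloc[104])
        regions = [
            rg.CandidateRegion("PLANTED", "1", start, end, n_genes_in_panel=8),
            rg.CandidateRegion("EMPTY", "22", 1, 1000, n_genes_in_panel=8),
        ]
        report = rg.evaluate_candidate_regions(
            scans["joint"], scans["primary"], scans["validation"], regions
        ).set_index("region")
        assert report.loc["PLANTED", "status"] == "significant"
        assert report.loc["PLANTED", "n_support"] >= 1
        assert report.loc["EMPTY", "status"] == "untested"

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            rg.evaluate_candidate_regions(None, None, None, [])


class TestBedConversion:
    def test_one_based_closed_to_zero_based_half_open(self):
        clusters = cluster_loci(retained_frame([1000, 2000, 3000]), Thresholds())
        bed = rg.clusters_to_bed(clusters)
        assert bed.iloc[0]["start"] == 999  # 1-based 1000 -> 0-based 999
        assert bed.iloc[0]["end"] == 3000  # closed end kept as half-open bound
        assert bed.iloc[0]["end"] - bed.iloc[0]["start"] == 2001  # span in bp


class TestEndToEnd:
    def test_planted_loci_recovered_and_classified(self, planted_study):
        spec, g = planted_study
        freqs = rg.normative_frequencies(spec).set_index("snp_id")["maf"]
        clusters, _ = rg.run_discovery(g, normative_freqs=freqs)
        assert len(clusters) == 2
        by_class = {c.classification for c in clusters}
        assert by_class == {"AMD", "POAG"}

    def test_null_genome_yields_no_clusters(self, null_study):
        _, g = null_study
        clusters, _ = rg.run_discovery(g)
        assert clusters == []
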