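"""Locus definition: clumping, merging, novelty, variance explained."""

import random

import numpy as np
import pandas as pd
import pytest

import zmanova as zm


def make_results(rows):
    """rows: (rsid, chrom, pos, pvalue) for a single group."""
    df = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "pvalue"])
    df["group"] = "g"
    df["log10p"] = np.log10(df["pvalue"])
    return df


def snp_map_of(results):
    m = results[["rsid", "chrom", "pos"]].copy()
    m["ref_allele"] = "A"
    m["eff_allele"] = "G"
    return m


class TestLdR2Z:
    def test_self_is_one(self):
        z = np.array([1.0, 2.0, -1.0, 0.5])
        assert zm.ld_r2_z(z, z) == pytest.approx(1.0)

    def test_perfect_anticorrelation_squares_to_one(self):
        assert zm.ld_r2_z(np.array([1, 2, 3, 4.0]), np.array([4, 3, 2, 1.0])) == (
            pytest.approx(1.0)
        )

    def test_hand_computed_pearson(self):
        r2 = zm.ld_r2_z(np.array([1, 2, 3, 4.0]), np.array([1, 1, 2, 2.0]))
        assert r2 == pytest.approx(0.8)

    def test_affine_invariance_and_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        assert zm.ld_r2_z(a, b) == pytest.approx(zm.ld_r2_z(b, a))
        assert zm.ld_r2_z(3.0 * a - 1.0, b) == pytest.approx(zm.ld_r2_z(a, b))
        assert zm.ld_r2_z(a, -0.5 * b + 2.0) == pytest.approx(zm.ld_r2_z(a, b))

    def test_zero_variance_flagged_nan(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(zm.ld_r2_z(np.ones(5), np.arange(5.0)))


class TestClump:
    def test_nothing_significant(self):
        res = make_results([("a", "1", 100, 0.5)])
        assert zm.clump(res, snp_map_of(res), 3.38e-8) == []

    def test_single_snp_window_arithmetic(self):
        res = make_results([("a", "1", 10_000_000, 1e-9)])
        (locus,) = zm.clump(res, snp_map_of(res), 3.38e-8)
        assert (locus.window_start, locus.window_end) == (9_500_000, 10_500_000)
        assert locus.member_snps == ["a"]

    def test_three_loci_toy_instance(self):
        res = make_results(
            [
                ("a", "1", 1_000_000, 1e-9),
                ("b", "1", 1_300_000, 1e-8),
                ("c", "1", 5_000_000, 1e-10),
                ("d", "1", 5_100_000, 0.2),
                ("e", "1", 20_000_000, 1e-9),
                ("f", "1", 20_400_000, 10 ** -8.5),
            ]
        )
        loci = zm.clump(res, snp_map_of(res), 3.38e-8)
        assert [l.lead_snp for l in loci] == ["a", "c", "e"]
        by_lead = {l.lead_snp: set(l.member_snps) for l in loci}
        assert by_lead == {"a": {"a", "b"}, "c": {"c"}, "e": {"e", "f"}}

    def test_leads_separated_and_members_within_window(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(5, 30)
            res = make_results(
                [
                    (f"s{i}", str(rng.integers(1, 4)), int(rng.integers(1, 4_000_000)),
                     float(10 ** -rng.uniform(0, 12)))
                    for i in range(n)
                ]
            )
            loci = zm.clump(res, snp_map_of(res), 1e-4, window_kb=500)
            coords = res.set_index("rsid")
            for a in loci:
                for b in loci:
                    if a is not b and a.chrom == b.chrom:
                        assert abs(a.pos - b.pos) > 500_000
                for m in a.member_snps:
                    assert coords.loc[m, "chrom"] == a.chrom
                    assert abs(int(coords.loc[m, "pos"]) - a.pos) <= 500_000
                assert a.pvalue == min(coords.loc[m, "pvalue"] for m in a.member_snps)


def brute_force_clump(res, threshold, window=500_000):
    """Independent oracle: explicit scan-and-assign enumeration."""
    sig = [
        (row.pvalue, int(row.chrom), row.pos, row.rsid)
        for row in res.itertuples()
        if row.pvalue < threshold
    ]
    leads = []
    unassigned = dict((s[3], s) for s in sorted(sig))
    while unassigned:
        best = min(unassigned.values())
        members = sorted(
            rsid
            for rsid, s in unassigned.items()
            if s[1] == best[1] and abs(s[2] - best[2]) <= window
        )
        leads.append((best[3], members))
        for m in members:
            del unassigned[m]
    return sorted(leads)


class TestClumpOracle:
    def test_greedy_equals_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            res = make_results(
                [
                    (f"s{i}", str(rng.integers(1, 3)),
                     int(rng.integers(1, 3_000_000)),
                     float(10 ** -rng.uniform(2, 12)))
                    for i in range(n)
                ]
            )
            # distinct p-values so both procedures share one optimum
            res["pvalue"] *= 1 + 1e-9 * np.arange(n)
            loci = zm.clump(res, snp_map_of(res), 1e-4)
            got = sorted((l.lead_snp, sorted(l.member_snps)) for l in loci)
            assert got == brute_force_clump(res, 1e-4)


class TestMergeLoci:
    def locus(self, lead, chrom, pos, p, group="g", window=500_000):
        return zm.Locus(
            lead_snp=lead, chrom=chrom, pos=pos, group=group, pvalue=p,
            log10p=np.log10(p), window_start=max(1, pos - window),
            window_end=pos + window, member_snps=[lead],
        )

    def test_disjoint_and_unlinked_left_alone(self):
        rng = np.random.default_rng(3)
        z = zm.ZMatrix(pd.DataFrame(
            rng.standard_normal((2, 10)), index=["a", "b"],
            columns=[f"t{i}" for i in range(10)],
        ))
        loci = [self.locus("a", "1", 1_000_000, 1e-9),
                self.locus("b", "1", 9_000_000, 1e-10)]
        merged = zm.merge_loci(loci, z, ld_merge_r2=0.999)
        assert len(merged) == 2

    def test_overlapping_windows_union(self):
        loci = [self.locus("a", "1", 1_000_000, 1e-9),
                self.locus("b", "1", 1_600_000, 1e-10)]
        (m,) = zm.merge_loci(loci, ld_merge_r2=None)
        assert m.lead_snp == "b"  # smaller p wins the merged lead
        assert (m.window_start, m.window_end) == (500_000, 2_100_000)
        assert sorted(m.merged_from) == ["a", "b"]

    def test_high_lead_ld_merges_distant_windows(self):
        profile = np.arange(10.0)
        z = zm.ZMatrix(pd.DataFrame(
            [profile, profile * 2 + 1], index=["a", "b"],
            columns=[f"t{i}" for i in range(10)],
        ))
        loci = [self.locus("a", "1", 1_000_000, 1e-9),
                self.locus("b", "1", 9_000_000, 1e-10)]
        (m,) = zm.merge_loci(loci, z, ld_merge_r2=0.7)
        assert m.window_start == 500_000 and m.window_end == 9_500_000

    def test_configured_region_collapses_its_loci(self):
        # three loci inside the chr6 22-42 Mb block collapse to one
        loci = [self.locus("a", "6", 23_000_000, 1e-9),
                self.locus("b", "6", 30_000_000, 1e-12),
                self.locus("c", "6", 41_000_000, 1e-10),
                self.locus("d", "7", 30_000_000, 1e-9)]
        merged = zm.merge_loci(
            loci, merge_regions=[{"chrom": "6", "start": 22_000_000,
                                  "end": 42_000_000}], ld_merge_r2=None,
        )
        assert len(merged) == 2
        big = next(m for m in merged if m.chrom == "6")
        assert big.lead_snp == "b"
        assert sorted(big.merged_from) == ["a", "b", "c"]

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(4)
        loci = [
            self.locus(f"s{i}", str(rng.integers(1, 3)),
                       int(rng.integers(1, 20) * 400_000 + 500_000),
                       float(10 ** -rng.uniform(8, 15)))
            for i in range(12)
        ]
        merged = zm.merge_loci(loci, ld_merge_r2=None)
        again = zm.merge_loci(merged, ld_merge_r2=None)
        assert [vars(l) for l in again] == [vars(l) for l in merged]
        for seed in range(5):
            shuffled = loci.copy()
            random.Random(seed).shuffle(shuffled)
            assert [vars(l) for l in zm.merge_loci(shuffled, ld_merge_r2=None)] == [
                vars(l) for l in merged
            ]

    def test_cross_group_overlap_keeps_minimal_p_group_label(self):
        loci = [self.locus("a", "1", 1_000_000, 1e-9, group="MFat"),
                self.locus("b", "1", 1_200_000, 1e-12, group="MMass")]
        (m,) = zm.merge_loci(loci, ld_merge_r2=None)
        assert m.group == "MMass"
        assert m.groups == ("MFat", "MMass")


class TestNovelty:
    def locus(self):
        return zm.Locus(
            lead_snp="lead", chrom="2", pos=5_000_000, group="g", pvalue=1e-9,
            log10p=-9, window_start=4_500_000, window_end=5_500_000,
            member_snps=["lead", "m1"],
        )

    def test_empty_known_table_all_novel(self):
        known = pd.DataFrame(columns=["name", "chrom", "start", "end"])
        (out,) = zm.annotate_novelty([self.locus()], known)
        assert out.novel is True

    def test_known_entry_at_lead_position(self):
        known = pd.DataFrame(
            [{"name": "geneX", "chrom": "2", "start": 5_000_000, "end": 5_000_000}]
        )
        (out,) = zm.annotate_novelty([self.locus()], known)
        assert out.novel is False

    def test_interval_overlap_and_rsid_match(self):
        gene = pd.DataFrame(
            [{"name": "geneY", "chrom": "2", "start": 4_000_000, "end": 4_600_000}]
        )
        assert zm.annotate_novelty([self.locus()], gene)[0].novel is False
        by_rsid = pd.DataFrame(
            [{"name": "m1", "chrom": "9", "start": 1, "end": 1}]
        )
        assert zm.annotate_novelty([self.locus()], by_rsid)[0].novel is False
        elsewhere = pd.DataFrame(
            [{"name": "geneZ", "chrom": "2", "start": 8_000_000, "end": 9_000_000}]
        )
        assert zm.annotate_novelty([self.locus()], elsewhere)[0].novel is True


class TestVarianceExplained:
    def test_p_one_explains_nothing(self):
        assert zm.variance_explained(1.0, 10613) == 0.0

    def test_reference_cohort_value(self):
        assert zm.variance_explained(0.05, 10613) == pytest.approx(0.03620, abs=5e-6)

    def test_monotone_in_p_and_inverse_in_n(self):
        ps = np.linspace(0.001, 1.0, 50)
        ve = [zm.variance_explained(p, 1000) for p in ps]
        assert all(a > b for a, b in zip(ve, ve[1:]))
        assert zm.variance_explained(0.01, 500) == pytest.approx(
            2 * zm.variance_explained(0.01, 1000)
        )

    def test_p_zero_rejected(self):
        with pytest.raises(ValueError):
            zm.variance_explained(0.0, 10613)

    def test_min_univariate_pvalue(self, toy_zmatrix):
        from scipy import stats

        rsid = toy_zmatrix.snps[0]
        expected = 2 * stats.norm.sf(np.abs(toy_zmatrix.z.loc[rsid]).max())
        assert zm.min_univariate_pvalue(toy_zmatrix, rsid) == pytest.approx(expected)


class TestExports:
    def test_bed_is_zero_based_half_open(self, tmp_path):
        locus = zm.Locus(
            lead_snp="a", chrom="1", pos=1_000_000, group="g", pvalue=1e-9,
            log10p=-9, window_start=500_000, window_end=1_500_000,
            member_snps=["a"],
        )
        path = zm.loci_to_bed([locus], tmp_path / "loci.bed")
        fields = path.read_text().strip().split("\t")
        assert fields[:4] == ["1", "499999", "1500000", "a"]
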