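"""Reference-set gene overlap, candidate genes, and interval intersection."""

import pytest

from cnvburden.burden_stats import fisher_two_tailed, odds_ratio_woolf
from cnvburden.overlap_analysis import (
    OverlapResult,
    compile_denovo_only_genes,
    denovo_enrichment_test,
    intersect_intervals,
    known_region_report,
    match_reference_cnvs,
)
from cnvburden.types import CnvCall, CopyState, ExonIndex, GeneModel, GenomicInterval, ReferenceCnv

from conftest import make_call


@pytest.fixture
def grid_index():
    return ExonIndex(
        GeneModel(f"G{i}", "chr1", [(i * 1_000_000 + 1, i * 1_000_000 + 50_000)])
        for i in range(1, 21)
    )


def _ref(cnv_id, genes, state=CopyState.DELETION):
    return ReferenceCnv(cnv_id, "chr1", 1, 1000, state, genes)


class TestReferenceMatching:
    def test_half_of_reference_genes_matches(self, grid_index):
        patient = make_call("P", start=900_000, end=2_100_000, cn=1)  # G1, G2
        ref = _ref("r1", ["G1", "G2", "G3", "G4"])
        (res,) = match_reference_cnvs([patient], [ref], grid_index)
        assert res.matched  # exactly 50%, inclusive

    def test_quarter_of_reference_genes_does_not_match(self, grid_index):
        patient = make_call("P", start=900_000, end=1_100_000, cn=1)  # G1 only
        ref = _ref("r1", ["G1", "G2", "G3", "G4"])
        (res,) = match_reference_cnvs([patient], [ref], grid_index)
        assert not res.matched

    def test_copy_state_ignored_unless_strict(self, grid_index):
        patient = make_call("P", start=900_000, end=2_100_000, cn=3)
        ref = _ref("r1", ["G1", "G2"], CopyState.DELETION)
        assert match_reference_cnvs([patient], [ref], grid_index)[0].matched
        assert not match_reference_cnvs(
            [patient], [ref], grid_index, require_same_state=True
        )[0].matched

    def test_empty_reference_gene_list_rejected(self, grid_index):
        with pytest.raises(ValueError, match="empty gene list"):
            match_reference_cnvs([make_call("P")], [_ref("r1", [])], grid_index)

    def test_matches_equal_bruteforce_on_reference_fixture(self, grid_index, rng):
        # a reference set of 231 CNVs (138 deletions, 93 duplications) and
        # random patient CNVs, checked against a direct set-intersection scan
        refs = []
        for i in range(231):
            n = int(rng.integers(1, 8))
            genes = [f"G{int(g)}" for g in rng.choice(range(1, 21), size=n, replace=False)]
            state = CopyState.DELETION if i < 138 else CopyState.DUPLICATION
            refs.append(_ref(f"r{i}", genes, state))
        patients = []
        for i in range(40):
            start = int(rng.integers(1, 15_000_000))
            patients.append(
                CnvCall(f"P{i}", "chr1", start, start + int(rng.integers(500_000, 6_000_000)),
                        int(rng.choice([1, 3])), 20, 50.0)
            )
        results = match_reference_cnvs(patients, refs, grid_index)
        for p, res in zip(patients, results):
            genes_p = grid_index.gene_content(p)
            expected = [
                r.cnv_id
                for r in refs
                if len(genes_p.intersection(r.genes)) / len(r.genes) >= 0.5
            ]
            assert res.matched_reference_ids == expected

    def test_adding_genes_never_unmatches(self, grid_index):
        ref = _ref("r1", ["G1", "G2", "G3", "G4"])
        small = make_call("P", start=900_000, end=2_100_000, cn=1)
        big = make_call("P", start=900_000, end=4_100_000, cn=1)
        assert match_reference_cnvs([small], [ref], grid_index)[0].matched
        assert match_reference_cnvs([big], [ref], grid_index)[0].matched


class TestDenovoEnrichment:
    def test_counts_assemble_and_delegate(self):
        overlaps = (
            [OverlapResult(make_call("P"), ["r"], True)] * 13
            + [OverlapResult(make_call("P"), [], False)] * 21
            + [OverlapResult(make_call("P"), ["r"], True)] * 5
            + [OverlapResult(make_call("P"), [], False)] * 61
        )
        labels = ["de_novo"] * 34 + ["inherited"] * 66
        res = denovo_enrichment_test(overlaps, labels)
        assert (res.a, res.b, res.c, res.d) == (13, 21, 5, 61)
        assert round(res.odds_ratio, 2) == 7.55
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (2.40, 23.72)
        assert res.p_raw == pytest.approx(fisher_two_tailed(13, 21, 5, 61))
        assert res.p_corrected == res.p_raw  # single test, no correction

    def test_equal_rates_give_or_near_one(self):
        overlaps = (
            [OverlapResult(make_call("P"), ["r"], True)] * 10
            + [OverlapResult(make_call("P"), [], False)] * 10
        ) * 2
        labels = ["de_novo"] * 20 + ["inherited"] * 20
        res = denovo_enrichment_test(overlaps, labels)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_degenerate_margin_is_an_error(self):
        overlaps = [OverlapResult(make_call("P"), ["r"], True)] * 4
        with pytest.raises(ValueError, match="margin"):
            denovo_enrichment_test(overlaps, ["de_novo"] * 4)


class TestDenovoOnlyGenes:
    def test_same_state_control_excludes_gene(self, grid_index):
        denovo = make_call("P", start=900_000, end=1_100_000, cn=1)  # G1 deleted
        control = make_call("C", start=900_000, end=1_100_000, cn=1)
        assert compile_denovo_only_genes([denovo], ["de_novo"], [control], grid_index) == []

    def test_opposite_state_control_retains_gene(self, grid_index):
        denovo = make_call("P", start=900_000, end=1_100_000, cn=1)
        control = make_call("C", start=900_000, end=1_100_000, cn=3)
        assert compile_denovo_only_genes([denovo], ["de_novo"], [control], grid_index) == ["G1"]

    def test_equals_bruteforce_three_set_rule(self, grid_index, rng):
        patients, labels, controls = [], [], []
        for i in range(60):
            start = int(rng.integers(1, 15_000_000))
            call = CnvCall(f"P{i}", "chr1", start, start + int(rng.integers(300_000, 4_000_000)),
                           int(rng.choice([1, 3])), 20, 50.0)
            patients.append(call)
            labels.append(str(rng.choice(["de_novo", "inherited", "unknown"])))
        for i in range(60):
            start = int(rng.integers(1, 15_000_000))
            controls.append(
                CnvCall(f"C{i}", "chr1", start, start + int(rng.integers(300_000, 4_000_000)),
                        int(rng.choice([1, 3])), 20, 50.0)
            )
        got = compile_denovo_only_genes(patients, labels, controls, grid_index)
        denovo, banned = set(), set()
        for call, lab in zip(patients, labels):
            for g in grid_index.gene_content(call):
                if lab == "de_novo":
                    denovo.add((g, call.copy_state))
                elif lab == "inherited":
                    banned.add((g, call.copy_state))
        for call in controls:
            for g in grid_index.gene_content(call):
                banned.add((g, call.copy_state))
        expected = sorted({g for g, s in denovo if (g, s) not in banned})
        assert got == expected


class TestIntervalIntersection:
    def test_reproduces_8p_critical_region(self):
        # the two smallest 8p duplications narrow a 10.7 Mb critical region
        a = GenomicInterval("chr8", 22_609_566, 43_689_385)
        b = GenomicInterval("chr8", 12_538_636, 33_311_183)
        result = intersect_intervals([a, b])
        assert (result.start, result.end) == (22_609_566, 33_311_183)
        assert result.length_mb(1) == 10.7

    def test_disjoint_intervals_empty(self):
        a = GenomicInterval("chr1", 100, 200)
        b = GenomicInterval("chr1", 300, 400)
        assert intersect_intervals([a, b]).is_empty

    def test_self_intersection_identity(self):
        x = GenomicInterval("chr3", 5, 50)
        assert intersect_intervals([x, x]) == x

    def test_associative_and_commutative(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr1", 50, 150)
        c = GenomicInterval("chr1", 75, 200)
        abc = intersect_intervals([a, b, c])
        assert abc == intersect_intervals([intersect_intervals([a, b]), c])
        assert abc == intersect_intervals([c, a, b])
        assert abc.length_bp <= min(x.length_bp for x in (a, b, c))

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="chromosomes"):
            intersect_intervals(
                [GenomicInterval("chr1", 1, 10), GenomicInterval("chr2", 1, 10)]
            )


class TestKnownRegionReport:
    def test_cnv_inside_region_counted_once(self):
        cnv = make_call("P", start=1_000_000, end=1_100_000)
        df = known_region_report([cnv], [("chr1", 900_000, 1_200_000, "R1")], ["de_novo"])
        assert df.loc[0, "n_overlapping_cnvs"] == 1
        assert df.loc[0, "n_de_novo"] == 1

    def test_cnv_spanning_two_regions_counted_for_both(self):
        cnv = make_call("P", start=1_000_000, end=3_000_000)
        catalog = [("chr1", 900_000, 1_200_000, "R1"), ("chr1", 2_500_000, 3_500_000, "R2")]
        df = known_region_report([cnv], catalog)
        assert list(df["n_overlapping_cnvs"]) == [1, 1]

    def test_counts_equal_bruteforce_scan(self, rng):
        cnvs, labels = [], []
        for i in range(50):
            start = int(rng.integers(1, 20_000_000))
            cnvs.append(make_call(f"P{i}", start=start, end=start + int(rng.integers(50_000, 3_000_000))))
            labels.append(str(rng.choice(["de_novo", "inherited"])))
        catalog = []
        for i in range(15):
            start = int(rng.integers(1, 20_000_000))
            catalog.append(("chr1", start, start + int(rng.integers(100_000, 5_000_000)), f"R{i}"))
        df = known_region_report(cnvs, catalog, labels).set_index("region")
        for chrom, rs, re_, name in catalog:
            hits = [
                (c, l)
                for c, l in zip(cnvs, labels)
                if c.start <= re_ and c.end >= rs
            ]
            assert df.at[name, "n_overlapping_cnvs"] == len(hits)
            assert df.at[name, "n_de_novo"] == sum(1 for _, l in hits if l == "de_novo")
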