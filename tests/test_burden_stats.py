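"""Exact 2x2 statistics and the stratified burden scan."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvburden.burden_stats import (
    DEFAULT_SCHEME,
    bonferroni,
    fisher_one_tailed_greater,
    fisher_two_tailed,
    gene_association_tests,
    make_association,
    odds_ratio_woolf,
    run_burden_scan,
)
from cnvburden.rare_cnv import CopyMode, gene_carrier_counts
from cnvburden.types import CnvCall, ExonIndex

from conftest import make_call, make_sample


class TestFisher:
    def test_identical_rows_give_p_one(self):
        for k, n in [(1, 5), (3, 10), (7, 20)]:
            assert fisher_two_tailed(k, n - k, k, n - k) == pytest.approx(1.0)

    def test_zero_margin_gives_p_one(self):
        assert fisher_two_tailed(0, 0, 3, 5) == 1.0
        assert fisher_two_tailed(0, 5, 0, 7) == 1.0

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            expected = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert fisher_two_tailed(a, b, c, d) == pytest.approx(expected, rel=1e-9)

    def test_symmetric_under_row_and_column_swap(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            p = fisher_two_tailed(a, b, c, d)
            assert fisher_two_tailed(d, c, b, a) == pytest.approx(p, rel=1e-12)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_p_in_unit_interval_and_transpose_invariant(self, table):
        a, b, c, d = table
        p = fisher_two_tailed(a, b, c, d)
        assert 0.0 < p <= 1.0
        # conditioning on margins makes the statistic transpose-symmetric
        assert fisher_two_tailed(a, c, b, d) == pytest.approx(p, rel=1e-12)
        assert p <= 33 * p or p == 0  # Bonferroni never decreases p

    def test_one_tailed_is_upper_tail(self):
        # P(X >= a) from the hypergeometric on the observed margins
        expected = scipy.stats.hypergeom(100, 30, 40).sf(19)
        assert fisher_one_tailed_greater(20, 20, 10, 50) == pytest.approx(
            expected, rel=1e-12
        )


class TestWoolf:
    @pytest.mark.parametrize(
        "table, or_expected, ci_expected",
        [
            ((13, 21, 5, 61), 7.55, (2.40, 23.72)),
            ((20, 185, 64, 1889), 3.19, (1.89, 5.39)),
            ((25, 257, 73, 2806), 3.74, (2.33, 5.99)),
        ],
    )
    def test_reproduces_printed_or_and_ci(self, table, or_expected, ci_expected):
        or_, lo, hi, corrected = odds_ratio_woolf(*table)
        assert round(or_, 2) == or_expected
        assert round(lo, 2) == ci_expected[0]
        assert round(hi, 2) == ci_expected[1]
        assert not corrected

    def test_balanced_table_symmetric_on_log_scale(self):
        or_, lo, hi, _ = odds_ratio_woolf(5, 5, 5, 5)
        assert or_ == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)

    def test_zero_cell_triggers_continuity_correction(self):
        or_, lo, hi, corrected = odds_ratio_woolf(5, 0, 3, 10)
        assert corrected
        assert 0 < lo <= or_ <= hi < np.inf

    def test_ci_contains_or_and_widens_with_smaller_cells(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(1, 50, size=4))
            or_, lo, hi, _ = odds_ratio_woolf(a, b, c, d)
            assert lo <= or_ <= hi
            if a > 1:
                _, lo2, hi2, _ = odds_ratio_woolf(a - 1, b, c, d)
                assert np.log(hi2 / lo2) > np.log(hi / lo)


class TestBonferroni:
    def test_reproduces_corrected_burden_p(self):
        # the printed corrected value 1.48e-3 is the raw 4.49e-5 times 33
        assert bonferroni(4.49e-5, 33) == pytest.approx(1.48e-3, rel=0.005)

    def test_caps_at_one(self):
        assert bonferroni(0.5, 33) == 1.0

    def test_monotone_in_p_and_m(self, rng):
        ps = np.sort(rng.uniform(size=20))
        corrected = [bonferroni(float(p), 7) for p in ps]
        assert corrected == sorted(corrected)
        assert bonferroni(0.001, 10) <= bonferroni(0.001, 20)


def _cohort_samples(n_patients, n_controls):
    return [make_sample(f"P{i}") for i in range(n_patients)] + [
        make_sample(f"C{i}", ("control",)) for i in range(n_controls)
    ]


class TestBurdenScan:
    def test_emits_165_unique_tests(self, exon_index):
        samples = _cohort_samples(5, 50)
        calls = [make_call("P0"), make_call("C0", start=2_000_500, end=2_100_000)]
        results = run_burden_scan(calls, exon_index, samples)
        assert len(results) == 165
        assert len({r.test_id for r in results}) == 165
        assert DEFAULT_SCHEME.tests_per_size_class == 33

    def test_empty_patient_group_is_an_error(self, exon_index):
        with pytest.raises(ValueError, match="patient"):
            run_burden_scan([], exon_index, [make_sample("C0", ("control",))])

    def test_hand_computed_small_fixture(self, exon_index):
        # P0 carries a rare 1.5 Mb deletion (genes G01-G02); P1 nothing;
        # C0 carries a rare 60 kb duplication; the other 199 controls nothing.
        # With 202 individuals every impacted gene sits at 1/202 < 1%.
        samples = _cohort_samples(2, 200)
        calls = [
            make_call("P0", start=1_000_000, end=2_500_000, cn=1, n_snps=500),
            make_call("C0", start=3_000_500, end=3_060_500, cn=3),
        ]
        results = {r.test_id: r for r in run_burden_scan(calls, exon_index, samples)}
        big = results["ge1Mb|count_ge1|joint"]
        assert (big.a, big.b, big.c, big.d) == (1, 1, 0, 200)
        assert big.p_raw == pytest.approx(
            scipy.stats.fisher_exact([[1, 1], [0, 200]])[1]
        )
        assert big.p_corrected == pytest.approx(min(1.0, big.p_raw * 33))
        dels = results["ge1Mb|count_ge1|deletion_only"]
        assert (dels.a, dels.c) == (1, 0)
        dups = results["ge30kb|count_ge1|duplication_only"]
        assert (dups.a, dups.c) == (0, 1)
        # the deletion spans G01 and G02 -> gene bin 2-5
        assert results["ge1Mb|genes_2-5|joint"].a == 1
        assert results["ge1Mb|genes_1|joint"].a == 0

    def test_count_categories_partition_ge1(self, small_study):
        cfg, bundle = small_study
        index = ExonIndex(bundle.genes)
        samples = [s for s in bundle.samples if "parent" not in s.groups]
        ids = {s.sample_id for s in samples}
        calls = [c for c in bundle.calls if c.sample_id in ids and index.gene_content(c)]
        results = {r.test_id: r for r in run_burden_scan(calls, index, samples)}
        for size in ("ge30kb", "ge1Mb", "500kb-1Mb", "100-500kb", "30-100kb"):
            for mode in ("joint", "deletion_only", "duplication_only"):
                total_a = sum(
                    results[f"{size}|count_{k}|{mode}"].a for k in ("1", "2", "3", "4", "ge5")
                )
                total_c = sum(
                    results[f"{size}|count_{k}|{mode}"].c for k in ("1", "2", "3", "4", "ge5")
                )
                assert total_a == results[f"{size}|count_ge1|{mode}"].a
                assert total_c == results[f"{size}|count_ge1|{mode}"].c


class TestGeneAssociation:
    def test_patient_only_gene_included_control_only_excluded(self, exon_index):
        samples = _cohort_samples(10, 100)
        calls = [make_call(f"P{i}") for i in range(5)] + [
            make_call("C0", start=2_000_500, end=2_060_500),
        ]
        table = gene_carrier_counts(calls, exon_index, samples)
        rows = gene_association_tests(table, ["G01", "G02"])
        tested = {r.test_id for r, _ in rows}
        assert "G01" in tested  # 5 patients, 0 controls
        assert "G02" not in tested  # controls only

    def test_bh_qvalues_monotone_with_sorted_p(self, rng):
        samples = _cohort_samples(20, 200)
        # several genes at varying carrier counts
        calls = []
        for gi, n_carriers in enumerate([6, 4, 2, 1], start=1):
            for k in range(n_carriers):
                calls.append(
                    make_call(f"P{k}", start=gi * 1_000_000 + 500, end=gi * 1_000_000 + 60_500)
                )
        table = gene_carrier_counts(calls, exon_index=_index10(), samples=samples)
        rows = gene_association_tests(table, list(table.table.index))
        by_p = sorted(rows, key=lambda t: t[0].p_raw)
        qs = [r.p_corrected for r, _ in by_p]
        assert qs == sorted(qs)


def _index10():
    from cnvburden.types import GeneModel

    return ExonIndex(
        GeneModel(
            f"G{i:02d}",
            "chr1",
            [(i * 1_000_000 + 1, i * 1_000_000 + 2_000),
             (i * 1_000_000 + 10_000, i * 1_000_000 + 12_000)],
        )
        for i in range(1, 11)
    )
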