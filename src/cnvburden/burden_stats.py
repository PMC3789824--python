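"""2x2 exact statistics and the stratified genome-wide burden scan.

The burden scan compares, for every combination of CNV size class, burden
category, and copy mode, the proportion of patients versus controls
satisfying the category.  Size classes: all >= 30 kb, >= 1 Mb,
500 kb-1 Mb, 100-500 kb, 30-100 kb (lower bound inclusive, upper bound
exclusive).  Categories: five gene-content bins (1, 2-5, 6-10, 11-20,
> 20 genes) and six per-genome count bins (>= 1, exactly 1, 2, 3, 4,
>= 5 CNVs).  With three copy modes (joint, deletions, duplications) that
is (5 + 6) x 3 = 33 tests per size class; each raw two-tailed Fisher
p-value is Bonferroni-corrected by that factor.

Per-gene association tests use the same Fisher statistic with
Benjamini-Hochberg FDR control instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .rare_cnv import (
    RARE_THRESHOLD,
    CopyMode,
    GeneFrequencyTable,
    gene_carrier_counts,
    select_rare_calls,
)
from .types import AssociationResult, CnvCall, ExonIndex, SampleRecord

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_two_tailed",
    "fisher_one_tailed_greater",
    "odds_ratio_woolf",
    "bonferroni",
    "make_association",
    "BurdenScheme",
    "run_burden_scan",
    "gene_association_tests",
]

#: Relative slack when comparing hypergeometric point probabilities, so
#: that tables tied with the observed one (up to rounding) are included.
_TIE_SLACK = 1e-7


def _hypergeom_log_pmf(r1: int, c1: int, n: int) -> tuple[int, np.ndarray]:
    """Log point probabilities of all 2x2 tables with margins (r1, c1, n).

    Returns ``(k_min, logp)`` where ``logp[i]`` is the probability that
    the top-left cell equals ``k_min + i``.
    """
    k_min = max(0, c1 - (n - r1))
    k_max = min(r1, c1)
    k = np.arange(k_min, k_max + 1)
    logp = (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(n - r1 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(n - r1 - (c1 - k) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return k_min, logp


def _check_table(a: int, b: int, c: int, d: int) -> None:
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 cells must be non-negative")


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p-value for the table [[a, b], [c, d]].

    The two-tailed rule is the point-probability convention: the sum of
    hypergeometric probabilities of every table (same margins) whose
    point probability does not exceed the observed one (within a 1e-7
    relative tie slack).  A zero margin yields p = 1 by convention.
    """
    _check_table(a, b, c, d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        logger.debug("degenerate margin in (%d,%d,%d,%d); p=1", a, b, c, d)
        return 1.0
    k_min, logp = _hypergeom_log_pmf(r1, c1, n)
    log_obs = logp[a - k_min]
    mask = logp <= log_obs + math.log1p(_TIE_SLACK)
    p = float(np.exp(logp[mask]).sum())
    return min(p, 1.0)


def fisher_one_tailed_greater(a: int, b: int, c: int, d: int) -> float:
    """One-tailed Fisher p-value for enrichment of the first row
    (P[top-left cell >= a] under the null)."""
    _check_table(a, b, c, d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    k_min, logp = _hypergeom_log_pmf(r1, c1, n)
    p = float(np.exp(logp[a - k_min :]).sum())
    return min(p, 1.0)


def odds_ratio_woolf(
    a: int, b: int, c: int, d: int
) -> tuple[float, float, float, bool]:
    """Odds ratio with Woolf (log-method) 95% CI.

    Returns ``(OR, ci_low, ci_high, corrected)``; when any cell is zero,
    0.5 is added to all cells (Haldane-Anscombe) and ``corrected`` is True.
    """
    _check_table(a, b, c, d)
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = 1.959963984540054 * se
    return or_, math.exp(math.log(or_) - half), math.exp(math.log(or_) + half), corrected


def bonferroni(p_raw: float, m: int = 33) -> float:
    """Bonferroni correction: min(1, p * m)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p_raw * m)


def make_association(
    test_id: str, a: int, b: int, c: int, d: int, m: int = 1
) -> AssociationResult:
    """Bundle Fisher p, Bonferroni correction, and Woolf OR/CI for one table."""
    p = fisher_two_tailed(a, b, c, d)
    or_, lo, hi, corrected = odds_ratio_woolf(a, b, c, d)
    return AssociationResult(
        test_id=test_id,
        a=a,
        b=b,
        c=c,
        d=d,
        p_raw=p,
        p_corrected=bonferroni(p, m),
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        continuity_corrected=corrected,
    )


_INF = float("inf")


@dataclass(frozen=True)
class BurdenScheme:
    """Stratification of the burden scan; the default is the 33-test design."""

    # (name, lower bp inclusive, upper bp exclusive)
    size_classes: tuple = (
        ("ge30kb", 30_000, _INF),
        ("ge1Mb", 1_000_000, _INF),
        ("500kb-1Mb", 500_000, 1_000_000),
        ("100-500kb", 100_000, 500_000),
        ("30-100kb", 30_000, 100_000),
    )
    # (name, min genes inclusive, max genes inclusive)
    gene_categories: tuple = (
        ("genes_1", 1, 1),
        ("genes_2-5", 2, 5),
        ("genes_6-10", 6, 10),
        ("genes_11-20", 11, 20),
        ("genes_gt20", 21, 10**9),
    )
    # (name, min count inclusive, max count inclusive)
    count_categories: tuple = (
        ("count_ge1", 1, 10**9),
        ("count_1", 1, 1),
        ("count_2", 2, 2),
        ("count_3", 3, 3),
        ("count_4", 4, 4),
        ("count_ge5", 5, 10**9),
    )
    copy_modes: tuple = (
        CopyMode.JOINT,
        CopyMode.DELETION_ONLY,
        CopyMode.DUPLICATION_ONLY,
    )

    @property
    def tests_per_size_class(self) -> int:
        return (len(self.gene_categories) + len(self.count_categories)) * len(
            self.copy_modes
        )


DEFAULT_SCHEME = BurdenScheme()


def run_burden_scan(
    calls: Sequence[CnvCall],
    exon_index: ExonIndex,
    samples: Sequence[SampleRecord],
    scheme: BurdenScheme = DEFAULT_SCHEME,
    threshold: float = RARE_THRESHOLD,
    freq_tables: Optional[Mapping[CopyMode, GeneFrequencyTable]] = None,
) -> list[AssociationResult]:
    """The stratified genome-wide rare-CNV burden scan.

    ``calls`` are filtered/merged calls from the patients of one
    malformation group plus the controls in ``samples``.  Rare flags are
    computed per copy mode (joint tables from all calls, deletion and
    duplication tables from the respective subsets) unless precomputed
    ``freq_tables`` are supplied.  Emits one :class:`AssociationResult`
    per (size class x category x mode) — 165 under the default scheme —
    with two-tailed Fisher p, Bonferroni x tests-per-size-class, and
    Woolf OR/CI.
    """
    patients = [s for s in samples if not s.is_control]
    controls = [s for s in samples if s.is_control]
    if not patients:
        raise ValueError("burden scan requires a non-empty patient group")
    if not controls:
        raise ValueError("burden scan requires a non-empty control group")
    patient_ids = {s.sample_id for s in patients}
    m = scheme.tests_per_size_class

    results: list[AssociationResult] = []
    for mode in scheme.copy_modes:
        if freq_tables is not None and mode in freq_tables:
            table = freq_tables[mode]
        else:
            table = gene_carrier_counts(calls, exon_index, samples, mode)
        rare = select_rare_calls(calls, table, exon_index, threshold)
        gene_counts = {id(c): len(exon_index.gene_content(c)) for c in rare}

        for size_name, lo, hi in scheme.size_classes:
            in_class = [c for c in rare if lo <= c.length_bp < hi]
            per_sample: dict[str, list[CnvCall]] = {}
            for c in in_class:
                per_sample.setdefault(c.sample_id, []).append(c)

            for cat_name, gmin, gmax in scheme.gene_categories:
                carriers = {
                    sid
                    for sid, cs in per_sample.items()
                    if any(gmin <= gene_counts[id(c)] <= gmax for c in cs)
                }
                results.append(
                    _category_result(
                        f"{size_name}|{cat_name}|{mode.value}",
                        carriers,
                        patient_ids,
                        len(patients),
                        len(controls),
                        m,
                    )
                )
            for cat_name, cmin, cmax in scheme.count_categories:
                carriers = {
                    sid for sid, cs in per_sample.items() if cmin <= len(cs) <= cmax
                }
                results.append(
                    _category_result(
                        f"{size_name}|{cat_name}|{mode.value}",
                        carriers,
                        patient_ids,
                        len(patients),
                        len(controls),
                        m,
                    )
                )
    return results


def _category_result(
    test_id: str,
    carriers: set[str],
    patient_ids: set[str],
    n_patients: int,
    n_controls: int,
    m: int,
) -> AssociationResult:
    a = sum(1 for sid in carriers if sid in patient_ids)
    c = len(carriers) - a
    return make_association(test_id, a, n_patients - a, c, n_controls - c, m)


def gene_association_tests(
    freq_table: GeneFrequencyTable,
    rare_genes: Iterable[str],
    fdr: float = 0.05,
) -> list[tuple[AssociationResult, bool]]:
    """Per-gene case-control Fisher tests with Benjamini-Hochberg FDR.

    Only rare genes are tested, and genes impacted in controls but never
    in patients are excluded before testing.  Returns (result, significant)
    pairs; ``p_corrected`` holds the BH q-value (monotone after step-up).
    """
    t = freq_table.table
    candidates = [
        g
        for g in rare_genes
        if g in t.index and t.at[g, "carriers_patients"] > 0
    ]
    if not candidates:
        return []
    n_p, n_c = freq_table.n_patients, freq_table.n_controls
    raw: list[AssociationResult] = []
    for g in candidates:
        a = int(t.at[g, "carriers_patients"])
        c = int(t.at[g, "carriers_controls"])
        p = fisher_two_tailed(a, n_p - a, c, n_c - c)
        or_, lo, hi, corrected = odds_ratio_woolf(a, n_p - a, c, n_c - c)
        raw.append(
            AssociationResult(g, a, n_p - a, c, n_c - c, p, 1.0, or_, lo, hi, corrected)
        )
    reject, qvals, _, _ = multipletests(
        [r.p_raw for r in raw], alpha=fdr, method="fdr_bh"
    )
    out = []
    for r, q, rej in zip(raw, qvals, reject):
        r.p_corrected = float(q)
        out.append((r, bool(rej)))
    return out
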