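"""Sample-level array QC and CNV-level filtering and merging.

Sample QC keeps individuals with SNP call rate > 98%, LRR standard
deviation < 0.30, GC wave factor strictly inside (-0.04, 0.04), and a raw
CNV call count < 100.  Call-level filtering keeps calls spanning >= 10
SNPs, >= 30 kb, caller confidence >= 10, and overlapping >= 1 bp of >= 1
exon (UTRs included).  Adjacent same-state calls within one individual
are then merged when they lie < 50 kb apart, or up to 200 kb apart when
one of them exceeds 1 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .types import CnvCall, ExonIndex, SampleRecord

__all__ = [
    "QcThresholds",
    "filter_samples",
    "filter_calls",
    "merge_calls",
]


@dataclass(frozen=True)
class QcThresholds:
    """All QC and filter cutoffs in one place; defaults follow the study design."""

    min_call_rate: float = 0.98
    max_lrr_sd: float = 0.30
    gcwf_range: tuple[float, float] = (-0.04, 0.04)  # open interval
    max_cnv_calls: int = 100
    min_snps: int = 10
    min_length_bp: int = 30_000
    min_confidence: float = 10.0
    merge_gap_bp: int = 50_000
    merge_gap_large_bp: int = 200_000
    large_cnv_bp: int = 1_000_000


#: Sample rules in the order violations are reported.
_SAMPLE_RULES = ("call_rate", "lrr_sd", "gcwf", "cnv_call_count")


def filter_samples(
    samples: Iterable[SampleRecord], thresholds: QcThresholds = QcThresholds()
) -> tuple[list[SampleRecord], list[tuple[SampleRecord, str]]]:
    """Split samples into QC-passing and failing (with first violated rule).

    Boundary semantics: call rate strictly > min; LRR SD strictly < max;
    GCWF strictly inside the open interval; call count strictly < max.
    A missing metric raises, naming the sample.
    """
    t = thresholds
    passed: list[SampleRecord] = []
    failed: list[tuple[SampleRecord, str]] = []
    for s in samples:
        for metric in _SAMPLE_RULES:
            if getattr(s, metric) is None:
                raise ValueError(f"sample {s.sample_id}: missing QC metric {metric!r}")
        if not s.call_rate > t.min_call_rate:
            failed.append((s, "call_rate"))
        elif not s.lrr_sd < t.max_lrr_sd:
            failed.append((s, "lrr_sd"))
        elif not (t.gcwf_range[0] < s.gcwf < t.gcwf_range[1]):
            failed.append((s, "gcwf"))
        elif not s.cnv_call_count < t.max_cnv_calls:
            failed.append((s, "cnv_call_count"))
        else:
            passed.append(s)
    return passed, failed


#: Call rules in first-fail order.
_CALL_RULES = ("n_snps", "length", "confidence", "exonic")


def filter_calls(
    calls: Iterable[CnvCall],
    exon_index: ExonIndex,
    thresholds: QcThresholds = QcThresholds(),
    return_reasons: bool = False,
):
    """Keep calls passing the four retention rules (SNPs, length, confidence,
    exon overlap), in that first-fail order.

    Returns the kept list, or ``(kept, dropped_with_reason)`` when
    ``return_reasons`` is set.
    """
    t = thresholds
    kept: list[CnvCall] = []
    dropped: list[tuple[CnvCall, str]] = []
    for c in calls:
        if c.n_snps < t.min_snps:
            dropped.append((c, "n_snps"))
        elif c.length_bp < t.min_length_bp:
            dropped.append((c, "length"))
        elif not c.confidence >= t.min_confidence:  # NaN confidence fails here
            dropped.append((c, "confidence"))
        elif not exon_index.gene_content(c):
            dropped.append((c, "exonic"))
        else:
            kept.append(c)
    return (kept, dropped) if return_reasons else kept


def _gap(left: CnvCall, right: CnvCall) -> int:
    """Gap between two calls sorted by start; <= 0 when they overlap."""
    return right.start - left.end


def _mergeable(a: CnvCall, b: CnvCall, t: QcThresholds) -> bool:
    left, right = (a, b) if a.start <= b.start else (b, a)
    gap = _gap(left, right)
    if gap < t.merge_gap_bp:
        return True
    return gap <= t.merge_gap_large_bp and (
        max(a.length_bp, b.length_bp) > t.large_cnv_bp
    )


def _merge_pair(a: CnvCall, b: CnvCall) -> CnvCall:
    # deletions keep the lowest constituent copy number, duplications the
    # highest (the more extreme state wins); SNPs sum, confidence is the min
    cn = (
        min(a.copy_number, b.copy_number)
        if a.copy_number < 2
        else max(a.copy_number, b.copy_number)
    )
    return CnvCall(
        sample_id=a.sample_id,
        chrom=a.chrom,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        copy_number=cn,
        n_snps=a.n_snps + b.n_snps,
        confidence=min(a.confidence, b.confidence),
    )


def _merge_group(group: list[CnvCall], t: QcThresholds) -> list[CnvCall]:
    """Merge one (sample, chromosome, copy-state) group to a fixed point.

    Each pass sorts by start and fuses adjacent mergeable calls; lengths
    are re-evaluated on the current (possibly already merged) spans, so a
    growing call can chain further neighbours in.  Iterating to the fixed
    point makes the operation idempotent and input-order invariant.
    """
    current = list(group)
    changed = True
    while changed:
        changed = False
        current.sort(key=lambda c: (c.start, c.end))
        out: list[CnvCall] = []
        for call in current:
            if out and _mergeable(out[-1], call, t):
                out[-1] = _merge_pair(out[-1], call)
                changed = True
            else:
                out.append(call)
        current = out
    return current


def merge_calls(
    calls: Sequence[CnvCall], thresholds: QcThresholds = QcThresholds()
) -> list[CnvCall]:
    """Merge nearby same-state calls within each individual.

    Calls are grouped by (sample, chromosome, copy state); a deletion is
    never merged with a duplication.  Within a group, calls < 50 kb apart
    are fused, as are calls up to 200 kb apart when one exceeds 1 Mb;
    overlapping calls always fuse (gap <= 0).  Merged calls span the
    union, sum SNP counts, and keep the minimum confidence.
    """
    groups: dict[tuple[str, str, str], list[CnvCall]] = {}
    for c in calls:
        groups.setdefault((c.sample_id, c.chrom, c.copy_state.value), []).append(c)
    merged: list[CnvCall] = []
    for key in sorted(groups):
        merged.extend(_merge_group(groups[key], thresholds))
    merged.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end))
    return merged
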