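"""Gene-based overlap with a reference de novo CNV set, candidate-gene
compilation, and physical interval intersection for critical regions.

A patient CNV "matches" a reference CNV when it contains at least 50% of
the reference CNV's genes (the fraction is computed over the reference
set, inclusive at the boundary).  Copy-state agreement is not required
by default; a strict mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .burden_stats import fisher_two_tailed, odds_ratio_woolf
from .types import (
    AssociationResult,
    CnvCall,
    ExonIndex,
    GenomicInterval,
    ReferenceCnv,
)

__all__ = [
    "OverlapResult",
    "match_reference_cnvs",
    "denovo_enrichment_test",
    "compile_denovo_only_genes",
    "intersect_intervals",
    "known_region_report",
]


@dataclass
class OverlapResult:
    """Gene-based match of one patient CNV against a reference set."""

    patient_cnv: CnvCall
    matched_reference_ids: list[str]
    matched: bool


def match_reference_cnvs(
    patient_cnvs: Sequence[CnvCall],
    reference: Sequence[ReferenceCnv],
    exon_index: ExonIndex,
    require_same_state: bool = False,
    min_fraction: float = 0.5,
) -> list[OverlapResult]:
    """Match each patient CNV against every reference CNV by gene content.

    Patient CNV p matches reference r iff
    ``|genes(p) & genes(r)| / |genes(r)| >= min_fraction``.
    """
    for r in reference:
        if not r.genes:
            raise ValueError(f"reference CNV {r.cnv_id} has an empty gene list")
    results = []
    for p in patient_cnvs:
        genes_p = exon_index.gene_content(p)
        hits = []
        for r in reference:
            if require_same_state and r.copy_state is not p.copy_state:
                continue
            frac = len(genes_p.intersection(r.genes)) / len(r.genes)
            if frac >= min_fraction:
                hits.append(r.cnv_id)
        results.append(OverlapResult(p, hits, bool(hits)))
    return results


def denovo_enrichment_test(
    overlaps: Sequence[OverlapResult],
    inheritance_labels: Sequence[str],
) -> AssociationResult:
    """Do de novo CNVs match the reference set more often than inherited ones?

    Builds the 2x2 (de novo matched / unmatched vs inherited matched /
    unmatched); CNVs labeled anything other than ``de_novo`` or
    ``inherited`` are excluded.  Single test: no multiplicity correction.
    """
    if len(overlaps) != len(inheritance_labels):
        raise ValueError("one inheritance label per overlap result required")
    a = b = c = d = 0
    for ov, label in zip(overlaps, inheritance_labels):
        if label == "de_novo":
            a, b = (a + 1, b) if ov.matched else (a, b + 1)
        elif label == "inherited":
            c, d = (c + 1, d) if ov.matched else (c, d + 1)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("degenerate margin: need matched and unmatched CNVs in both groups")
    p = fisher_two_tailed(a, b, c, d)
    or_, lo, hi, corrected = odds_ratio_woolf(a, b, c, d)
    return AssociationResult(
        "denovo_vs_inherited_overlap", a, b, c, d, p, p, or_, lo, hi, corrected
    )


def compile_denovo_only_genes(
    patient_cnvs: Sequence[CnvCall],
    inheritance_labels: Sequence[str],
    control_calls: Sequence[CnvCall],
    exon_index: ExonIndex,
) -> list[str]:
    """Genes impacted by >= 1 de novo CNV but never, at the same copy
    state, by an inherited patient CNV or any control CNV."""
    if len(patient_cnvs) != len(inheritance_labels):
        raise ValueError("one inheritance label per patient CNV required")
    denovo: set[tuple[str, str]] = set()
    inherited: set[tuple[str, str]] = set()
    for cnv, label in zip(patient_cnvs, inheritance_labels):
        target = denovo if label == "de_novo" else inherited if label == "inherited" else None
        if target is None:
            continue
        for g in exon_index.gene_content(cnv):
            target.add((g, cnv.copy_state.value))
    control: set[tuple[str, str]] = set()
    for cnv in control_calls:
        for g in exon_index.gene_content(cnv):
            control.add((g, cnv.copy_state.value))
    keep = {g for g, state in denovo if (g, state) not in inherited | control}
    return sorted(keep)


def intersect_intervals(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Intersection of physical intervals on one chromosome.

    Returns the empty interval when the inputs do not all overlap.  Used
    to narrow a critical region from the CNVs of phenotype-concordant
    patients.
    """
    if not intervals:
        raise ValueError("need at least one interval")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise ValueError(f"cannot intersect intervals on different chromosomes: {sorted(chroms)}")
    chrom = intervals[0].chrom
    start = max(iv.start for iv in intervals)
    end = min(iv.end for iv in intervals)
    if start >= end:
        return GenomicInterval.empty(chrom)
    return GenomicInterval(chrom, start, end)


def known_region_report(
    patient_cnvs: Sequence[CnvCall],
    catalog: Sequence[tuple[str, int, int, str]],
    inheritance_labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per catalog region: how many patient CNVs physically overlap it
    (>= 1 bp) and how many of those are de novo."""
    labels = inheritance_labels or [""] * len(patient_cnvs)
    if len(labels) != len(patient_cnvs):
        raise ValueError("one inheritance label per patient CNV required")
    rows = []
    for chrom, rstart, rend, name in catalog:
        hits = [
            (c, lab)
            for c, lab in zip(patient_cnvs, labels)
            if c.chrom == chrom and c.start <= rend and c.end >= rstart
        ]
        rows.append(
            {
                "region": name,
                "chrom": chrom,
                "start": rstart,
                "end": rend,
                "n_overlapping_cnvs": len(hits),
                "n_de_novo": sum(1 for _, lab in hits if lab == "de_novo"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["region", "chrom", "start", "end", "n_overlapping_cnvs", "n_de_novo"],
    )
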