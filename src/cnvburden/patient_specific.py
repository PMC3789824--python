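"""Patient-specific CNV selection by gene sharing, recurrent-region
removal, and pathogenicity scoring.

A patient CNV is *patient-specific* when no single control individual
carries, at the same copy state, 100% of the genes it impacts — whether
by one contiguous CNV or by several calls that could not be merged.  The
comparison is gene-based, so the CNVs need not physically overlap, and a
control CNV of the opposite copy state never disqualifies a patient CNV
even with identical gene content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .types import CnvCall, ExonIndex

__all__ = [
    "SpecificityVerdict",
    "build_control_gene_sets",
    "max_gene_sharing",
    "patient_specific_scan",
    "apply_region_blacklist",
    "PathogenicityRubric",
    "score_pathogenicity",
]


@dataclass
class SpecificityVerdict:
    """Outcome of the gene-sharing scan for one patient CNV."""

    cnv: CnvCall
    max_shared_fraction: float
    best_control_id: Optional[str]
    is_specific: bool
    excluded_reason: Optional[str] = None  # "full_gene_overlap" | "blacklist_region"


def build_control_gene_sets(
    control_calls: Iterable[CnvCall], exon_index: ExonIndex
) -> dict[tuple[str, str], set[str]]:
    """Pool each control individual's impacted genes per copy state.

    Keyed by ``(control_id, copy_state.value)``; pooling across that
    individual's calls implements the "one contiguous CNV or several
    CNVs" rule.
    """
    pools: dict[tuple[str, str], set[str]] = {}
    for call in control_calls:
        genes = exon_index.gene_content(call)
        if genes:
            pools.setdefault(
                (call.sample_id, call.copy_state.value), set()
            ).update(genes)
    return pools


def max_gene_sharing(
    patient_cnv: CnvCall,
    control_calls: Iterable[CnvCall] | dict[tuple[str, str], set[str]],
    exon_index: ExonIndex,
) -> SpecificityVerdict:
    """Fraction of the patient CNV's genes covered by the best-matching
    single control individual (same copy state only).

    ``control_calls`` may be raw calls or a prebuilt pool from
    :func:`build_control_gene_sets` (reuse it when scanning many CNVs).
    """
    genes = exon_index.gene_content(patient_cnv)
    if not genes:
        raise ValueError(
            f"patient CNV {patient_cnv.chrom}:{patient_cnv.start}-{patient_cnv.end}"
            " impacts no genes"
        )
    pools = (
        control_calls
        if isinstance(control_calls, dict)
        else build_control_gene_sets(control_calls, exon_index)
    )
    state = patient_cnv.copy_state.value
    best_frac, best_id = 0.0, None
    for (control_id, pool_state), pool in pools.items():
        if pool_state != state:
            continue
        frac = len(genes & pool) / len(genes)
        if frac > best_frac or (frac == best_frac and best_id is None):
            best_frac, best_id = frac, control_id
    specific = best_frac < 1.0
    return SpecificityVerdict(
        cnv=patient_cnv,
        max_shared_fraction=best_frac,
        best_control_id=best_id,
        is_specific=specific,
        excluded_reason=None if specific else "full_gene_overlap",
    )


def patient_specific_scan(
    patient_calls: Sequence[CnvCall],
    control_calls: Sequence[CnvCall],
    exon_index: ExonIndex,
) -> list[SpecificityVerdict]:
    """Gene-sharing verdict for every patient CNV against all controls."""
    pools = build_control_gene_sets(control_calls, exon_index)
    return [max_gene_sharing(c, pools, exon_index) for c in patient_calls]


def _overlap_bp(start: int, end: int, rstart: int, rend: int) -> int:
    return max(0, min(end, rend) - max(start, rstart))


def apply_region_blacklist(
    verdicts: Sequence[SpecificityVerdict],
    blacklist: Sequence[tuple[str, int, int, str]],
    patient_calls: Sequence[CnvCall] = (),
    control_calls: Sequence[CnvCall] = (),
    n_patients: int = 0,
    n_controls: int = 0,
    recurrence_threshold: float = 0.05,
    min_blacklist_overlap: float = 0.5,
) -> list[SpecificityVerdict]:
    """Mark CNVs falling in highly polymorphic regions as excluded.

    A CNV is blacklisted when >= 50% of its length lies inside listed
    regions, or when the fraction of individuals with a physically
    overlapping call exceeds ``recurrence_threshold`` in *both* cohorts.
    Verdicts are updated in place and returned.
    """
    for v in verdicts:
        if not v.is_specific:
            continue
        c = v.cnv
        in_black = sum(
            _overlap_bp(c.start, c.end, rs, re)
            for chrom, rs, re, _ in blacklist
            if chrom == c.chrom
        )
        blacklisted = in_black >= min_blacklist_overlap * c.length_bp
        if not blacklisted and n_patients and n_controls:
            pat_rec = _recurrence(c, patient_calls) / n_patients
            con_rec = _recurrence(c, control_calls) / n_controls
            blacklisted = (
                pat_rec > recurrence_threshold and con_rec > recurrence_threshold
            )
        if blacklisted:
            v.is_specific = False
            v.excluded_reason = "blacklist_region"
    return list(verdicts)


def _recurrence(cnv: CnvCall, calls: Sequence[CnvCall]) -> int:
    """Number of distinct individuals with a call overlapping the CNV."""
    return len(
        {
            c.sample_id
            for c in calls
            if c.chrom == cnv.chrom and _overlap_bp(c.start, c.end, cnv.start, cnv.end) > 0
        }
    )


@dataclass(frozen=True)
class PathogenicityRubric:
    """Additive scoring weights for ranking candidate CNVs.

    The components mirror the evidence classes used when triaging CNVs in
    developmental-disorder cohorts: physical size, inheritance (a de novo
    event is far stronger evidence), gene content, overlap with known
    neurodevelopmental / brain-malformation regions, and a penalty for
    polymorphic (blacklisted) regions.  The score floors at 0.
    """

    size_bins: tuple = (
        (1_000_000, 4),
        (500_000, 3),
        (100_000, 2),
        (30_000, 1),
    )  # (min length_bp inclusive, points), evaluated largest first
    inheritance_points: tuple = (("de_novo", 6), ("unknown", 2), ("inherited", 0))
    gene_bins: tuple = (
        (21, 4),
        (11, 3),
        (6, 2),
        (2, 1),
        (1, 0),
    )  # (min genes inclusive, points)
    known_region_points: int = 6
    blacklist_penalty: int = -4


DEFAULT_RUBRIC = PathogenicityRubric()


def score_pathogenicity(
    cnv: CnvCall,
    inheritance: str,
    n_genes: int,
    in_known_region: bool = False,
    in_blacklist: bool = False,
    rubric: PathogenicityRubric = DEFAULT_RUBRIC,
) -> int:
    """Additive pathogenicity score; higher means more likely pathogenic."""
    if inheritance not in {k for k, _ in rubric.inheritance_points}:
        raise ValueError(f"unknown inheritance label {inheritance!r}")
    score = 0
    for min_len, pts in rubric.size_bins:
        if cnv.length_bp >= min_len:
            score += pts
            break
    score += dict(rubric.inheritance_points)[inheritance]
    for min_genes, pts in rubric.gene_bins:
        if n_genes >= min_genes:
            score += pts
            break
    if in_known_region:
        score += rubric.known_region_points
    if in_blacklist:
        score += rubric.blacklist_penalty
    return max(0, score)
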