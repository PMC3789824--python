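"""Core domain types shared by every stage of the CNV pipeline.

All genomic intervals held in memory are 1-based inclusive.  CNV lengths
are computed as ``end - start`` (no +1); this convention reproduces the
lengths conventionally printed for SNP-array CNV calls (e.g. a call at
chr5:116416478-120055246 is reported as 3.64 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "CopyState",
    "CnvCall",
    "GeneModel",
    "SampleRecord",
    "ReferenceCnv",
    "GenomicInterval",
    "AssociationResult",
    "ExonIndex",
    "normalize_chrom",
]


class CopyState(str, Enum):
    """Direction of a copy-number change relative to the diploid state."""

    DELETION = "deletion"
    DUPLICATION = "duplication"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_CHROM_ALIASES = {"23": "X", "24": "Y", "25": "XY", "26": "M", "MT": "M"}


def normalize_chrom(chrom: str) -> str:
    """Normalize chromosome names to the ``chrN`` convention.

    Numeric sex-chromosome encodings (23/24) map to chrX/chrY.
    """
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    name = _CHROM_ALIASES.get(name, name)
    return f"chr{name}"


def _copy_state_from_cn(copy_number: int) -> CopyState:
    if copy_number in (0, 1):
        return CopyState.DELETION
    if copy_number in (3, 4):
        return CopyState.DUPLICATION
    raise ValueError(f"copy-neutral call (cn={copy_number}) has no copy state")


@dataclass
class CnvCall:
    """One CNV interval observed in one individual.

    ``length_bp`` is ``end - start`` by convention (see module docstring).
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    n_snps: int
    confidence: float
    copy_state: CopyState = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.end <= self.start:
            raise ValueError(
                f"CNV {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.n_snps < 1:
            raise ValueError("CNV must span at least one SNP")
        derived = _copy_state_from_cn(self.copy_number)
        if self.copy_state is None:
            self.copy_state = derived
        elif CopyState(self.copy_state) is not derived:
            raise ValueError(
                f"copy_state {self.copy_state} inconsistent with cn={self.copy_number}"
            )
        else:
            self.copy_state = CopyState(self.copy_state)

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start, self.end)


def _normalize_exons(exons: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort exon intervals and merge any that touch or overlap."""
    exons = sorted((int(s), int(e)) for s, e in exons)
    merged: list[tuple[int, int]] = []
    for s, e in exons:
        if e < s:
            raise ValueError(f"exon ({s}, {e}) has end < start")
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    """A gene as a set of exon intervals (UTRs included), 1-based inclusive."""

    gene_id: str
    chrom: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons = _normalize_exons(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


#: Recognized cohort labels.  A patient may belong to several (e.g. ACC and
#: ACC_ONLY); controls carry only "control"; simulated parents "parent".
KNOWN_GROUPS = frozenset(
    {"ACC", "ACC_PLUS", "ACC_ONLY", "CBLH", "PMG", "control", "parent"}
)


@dataclass
class SampleRecord:
    """One genotyped individual with array QC metrics and trio links."""

    sample_id: str
    groups: frozenset[str]
    ethnicity: str = "Caucasian"
    call_rate: Optional[float] = None
    lrr_sd: Optional[float] = None
    gcwf: Optional[float] = None
    cnv_call_count: Optional[int] = None
    father_id: Optional[str] = None
    mother_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.groups = frozenset(self.groups)
        if self.call_rate is not None and not (0.0 <= self.call_rate <= 1.0):
            raise ValueError(f"{self.sample_id}: call_rate outside [0, 1]")
        if "ACC_PLUS" in self.groups and "ACC_ONLY" in self.groups:
            raise ValueError(f"{self.sample_id}: ACC_PLUS and ACC_ONLY are disjoint")
        if ("ACC_PLUS" in self.groups or "ACC_ONLY" in self.groups) and (
            "ACC" not in self.groups
        ):
            raise ValueError(f"{self.sample_id}: ACC subgroups require ACC membership")

    @property
    def is_control(self) -> bool:
        return "control" in self.groups


@dataclass
class ReferenceCnv:
    """A CNV from an external reference set with precomputed gene content."""

    cnv_id: str
    chrom: str
    start: int
    end: int
    copy_state: CopyState
    genes: list[str]

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.copy_state = CopyState(self.copy_state)


@dataclass(frozen=True)
class GenomicInterval:
    """A physical interval, 1-based inclusive; ``start == end == 0`` is empty."""

    chrom: str
    start: int
    end: int

    @property
    def is_empty(self) -> bool:
        return self.end <= self.start

    @property
    def length_bp(self) -> int:
        return 0 if self.is_empty else self.end - self.start

    def length_mb(self, decimals: int = 1) -> float:
        return round(self.length_bp / 1e6, decimals)

    @classmethod
    def empty(cls, chrom: str = "") -> "GenomicInterval":
        return cls(chrom, 0, 0)


@dataclass
class AssociationResult:
    """A 2x2 case-control comparison: counts, Fisher p, OR with Woolf CI.

    Cells: a = patient carriers, b = patient non-carriers,
    c = control carriers, d = control non-carriers.
    """

    test_id: str
    a: int
    b: int
    c: int
    d: int
    p_raw: float
    p_corrected: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool = False


class ExonIndex:
    """Interval index over exons for fast CNV -> gene-content lookups."""

    def __init__(self, genes: Iterable[GeneModel]):
        from intervaltree import IntervalTree

        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, "IntervalTree"] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {gene.gene_id}")
            self.genes[gene.gene_id] = gene
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            for s, e in gene.exons:
                # interval tree is half-open; inclusive exon [s, e] -> [s, e+1)
                tree.addi(s, e + 1, gene.gene_id)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        """Gene ids with >= 1 bp of exon inside the inclusive interval."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end + 1)}

    def gene_content(self, call: CnvCall) -> set[str]:
        return self.genes_overlapping(call.chrom, call.start, call.end)

    def __len__(self) -> int:
        return len(self.genes)
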