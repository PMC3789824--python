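"""Per-gene carrier frequencies and the <1% rare-CNV rule.

A gene's carrier frequency is the fraction of the combined population
(patients of one malformation group plus controls) with at least one
in-mode CNV overlapping one of its exons; each individual counts at most
once per gene.  A CNV is *rare* when at least one of its genes has a
combined carrier frequency strictly below the threshold (default 1%).
Deletions+duplications can be assessed jointly or separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .types import CnvCall, CopyState, ExonIndex, SampleRecord

__all__ = [
    "CopyMode",
    "GeneFrequencyTable",
    "gene_carrier_counts",
    "flag_rare_cnvs",
    "select_rare_calls",
    "rare_gene_universe",
]

RARE_THRESHOLD = 0.01


class CopyMode(str, Enum):
    """Which copy states enter a frequency table or burden test."""

    JOINT = "joint"
    DELETION_ONLY = "deletion_only"
    DUPLICATION_ONLY = "duplication_only"

    def admits(self, call: CnvCall) -> bool:
        if self is CopyMode.JOINT:
            return True
        if self is CopyMode.DELETION_ONLY:
            return call.copy_state is CopyState.DELETION
        return call.copy_state is CopyState.DUPLICATION


@dataclass
class GeneFrequencyTable:
    """Per-gene carrier counts and combined frequencies for one copy mode."""

    mode: CopyMode
    n_patients: int
    n_controls: int
    table: pd.DataFrame  # index gene_id; carriers_patients, carriers_controls,
    #                      combined_frequency

    @property
    def n_total(self) -> int:
        return self.n_patients + self.n_controls

    def frequency(self, gene_id: str) -> float:
        """Combined carrier frequency; 0 for genes never impacted."""
        if gene_id in self.table.index:
            return float(self.table.at[gene_id, "combined_frequency"])
        return 0.0

    def to_tsv(self, path) -> None:
        out = self.table.reset_index().rename(columns={"index": "gene_id"})
        out.insert(1, "mode", self.mode.value)
        out.to_csv(path, sep="\t", index=False)


def gene_carrier_counts(
    calls: Iterable[CnvCall],
    exon_index: ExonIndex,
    samples: Sequence[SampleRecord],
    mode: CopyMode = CopyMode.JOINT,
) -> GeneFrequencyTable:
    """Count, per gene, the patients and controls carrying an in-mode CNV.

    ``samples`` defines the combined population (and its denominator);
    a call from a sample absent from it is an error.
    """
    by_id = {s.sample_id: s for s in samples}
    n_controls = sum(1 for s in samples if s.is_control)
    n_patients = len(samples) - n_controls

    carriers: dict[str, set[str]] = {}
    for call in calls:
        if call.sample_id not in by_id:
            raise ValueError(f"sample {call.sample_id} not in manifest")
        if not mode.admits(call):
            continue
        for gene in exon_index.gene_content(call):
            carriers.setdefault(gene, set()).add(call.sample_id)

    rows = []
    for gene in sorted(carriers):
        pat = sum(1 for sid in carriers[gene] if not by_id[sid].is_control)
        con = len(carriers[gene]) - pat
        rows.append(
            {
                "gene_id": gene,
                "carriers_patients": pat,
                "carriers_controls": con,
                "combined_frequency": (pat + con) / (n_patients + n_controls),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "carriers_patients", "carriers_controls", "combined_frequency"],
    ).set_index("gene_id")
    return GeneFrequencyTable(mode, n_patients, n_controls, table)


def flag_rare_cnvs(
    calls: Sequence[CnvCall],
    freq_table: GeneFrequencyTable,
    exon_index: ExonIndex,
    threshold: float = RARE_THRESHOLD,
) -> list[bool]:
    """Flag each call rare/not-rare (parallel to the input order).

    Rare iff >= 1 overlapped gene sits strictly below the threshold.  A
    call overlapping zero genes is an error: exon overlap is a retention
    rule upstream, so gene-free calls should never reach this point.
    """
    flags = []
    for call in calls:
        genes = exon_index.gene_content(call)
        if not genes:
            raise ValueError(
                f"CNV {call.chrom}:{call.start}-{call.end} overlaps no genes"
            )
        flags.append(any(freq_table.frequency(g) < threshold for g in genes))
    return flags


def select_rare_calls(
    calls: Sequence[CnvCall],
    freq_table: GeneFrequencyTable,
    exon_index: ExonIndex,
    threshold: float = RARE_THRESHOLD,
) -> list[CnvCall]:
    """The in-mode calls flagged rare (convenience over :func:`flag_rare_cnvs`)."""
    in_mode = [c for c in calls if freq_table.mode.admits(c)]
    flags = flag_rare_cnvs(in_mode, freq_table, exon_index, threshold)
    return [c for c, rare in zip(in_mode, flags) if rare]


def rare_gene_universe(
    freq_table: GeneFrequencyTable, threshold: float = RARE_THRESHOLD
) -> list[str]:
    """Genes impacted at a combined frequency strictly below the threshold."""
    t = freq_table.table
    return sorted(t.index[t["combined_frequency"] < threshold])
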