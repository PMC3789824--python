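"""Readers and writers for every external text format the pipeline touches.

Formats
-------
* PennCNV ``rawcnv`` call lists (whitespace-separated ``key=value`` tokens).
* BED (0-based half-open) for gene/exon annotation and region lists;
  coordinates are converted to the in-memory 1-based inclusive convention
  on read and converted back on write.
* TSV for sample manifests, reference CNV sets, and all reports.

Every reader/writer pair round-trips: ``read(write(x)) == x``.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import fields as dataclass_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    AssociationResult,
    CnvCall,
    CopyState,
    GeneModel,
    ReferenceCnv,
    SampleRecord,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_penncnv_calls",
    "write_penncnv_calls",
    "read_gene_bed",
    "write_gene_bed",
    "read_sample_manifest",
    "write_sample_manifest",
    "read_reference_cnvs",
    "write_reference_cnvs",
    "read_region_bed",
    "write_region_bed",
    "write_report",
    "read_report",
]

_INTERVAL_RE = re.compile(r"^(?P<chrom>\w+):(?P<start>\d+)-(?P<end>\d+)$")
_STATE_RE = re.compile(r"^state(?P<state>\d+),cn=(?P<cn>\d+)$")

#: PennCNV HMM state for each copy number (used when re-emitting calls).
_CN_TO_STATE = {0: 1, 1: 2, 3: 5, 4: 6}

_KNOWN_KEYS = {"numsnp", "length", "conf", "startsnp", "endsnp"}


def read_penncnv_calls(path: str | Path) -> list[CnvCall]:
    """Parse a PennCNV ``rawcnv`` file into :class:`CnvCall` records.

    Copy-neutral lines (cn=2) are rejected: a CNV list must not contain
    them.  Unknown ``key=value`` tokens are ignored with a warning; the
    single bare token on each line is taken as the sample identifier.
    """
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                calls.append(_parse_rawcnv_line(line))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return calls


def _parse_rawcnv_line(line: str) -> CnvCall:
    tokens = line.split()
    m = _INTERVAL_RE.match(tokens[0])
    if m is None:
        raise ValueError(f"malformed interval token {tokens[0]!r}")
    chrom = normalize_chrom(m["chrom"])
    start, end = int(m["start"]), int(m["end"])

    cn = None
    numsnp = None
    conf = None
    sample_id = None
    for tok in tokens[1:]:
        sm = _STATE_RE.match(tok)
        if sm:
            cn = int(sm["cn"])
            continue
        if "=" in tok:
            key, _, value = tok.partition("=")
            if key == "numsnp":
                numsnp = int(value)
            elif key == "conf":
                conf = float(value)
            elif key not in _KNOWN_KEYS:
                logger.warning("ignoring unknown rawcnv token %r", tok)
            continue
        if sample_id is None:
            sample_id = tok
        else:
            logger.warning("ignoring extra bare token %r", tok)
    if cn is None:
        raise ValueError("missing stateN,cn=C token")
    if cn == 2:
        raise ValueError("copy-neutral call (cn=2)")
    if numsnp is None:
        raise ValueError("missing numsnp= token")
    if sample_id is None:
        raise ValueError("missing sample identifier token")
    return CnvCall(
        sample_id=sample_id,
        chrom=chrom,
        start=start,
        end=end,
        copy_number=cn,
        n_snps=numsnp,
        confidence=conf if conf is not None else float("nan"),
    )


def _format_float(x: float) -> str:
    """Compact float formatting that survives a read/write round trip."""
    if isinstance(x, float) and math.isnan(x):
        return "nan"
    return repr(float(x)) if float(x) != int(x) else str(int(x))


def write_penncnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Emit calls in the rawcnv dialect accepted by :func:`read_penncnv_calls`."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}:{c.start}-{c.end} "
                f"numsnp={c.n_snps} "
                f"length={c.length_bp:,} "
                f"state{_CN_TO_STATE[c.copy_number]},cn={c.copy_number} "
                f"{c.sample_id} "
                f"conf={_format_float(c.confidence)}\n"
            )


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Read exon annotation from a BED-like file (chrom, start, end, gene_id).

    The file is declared 0-based half-open; rows sharing a gene_id are
    grouped into one :class:`GeneModel` with 1-based inclusive exons.
    """
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    chrom_by_gene: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}, line {lineno}: expected >= 4 BED columns")
            chrom, start, end, gene_id = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}, line {lineno}: invalid BED interval {start}-{end}"
                )
            chrom = normalize_chrom(chrom)
            prev = chrom_by_gene.setdefault(gene_id, chrom)
            if prev != chrom:
                raise ValueError(
                    f"{path}, line {lineno}: gene {gene_id} spans chromosomes"
                )
            if gene_id not in exons_by_gene:
                order.append(gene_id)
            # BED half-open [start, end) -> 1-based inclusive [start+1, end]
            exons_by_gene.setdefault(gene_id, []).append((start + 1, end))
    return [GeneModel(g, chrom_by_gene[g], exons_by_gene[g]) for g in order]


def write_gene_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write exon annotation as 0-based half-open BED, one row per exon."""
    with open(path, "w") as fh:
        for gene in genes:
            for s, e in gene.exons:
                fh.write(f"{gene.chrom}\t{s - 1}\t{e}\t{gene.gene_id}\n")


_MANIFEST_COLUMNS = [
    "sample_id",
    "groups",
    "ethnicity",
    "call_rate",
    "lrr_sd",
    "gcwf",
    "cnv_call_count",
    "father_id",
    "mother_id",
]


def read_sample_manifest(path: str | Path) -> list[SampleRecord]:
    """Read a TSV sample manifest (named columns, groups comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(_MANIFEST_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                groups=frozenset(str(row.groups).split(",")),
                ethnicity=_opt_str(getattr(row, "ethnicity", None)) or "Caucasian",
                call_rate=_opt_float(getattr(row, "call_rate", None)),
                lrr_sd=_opt_float(getattr(row, "lrr_sd", None)),
                gcwf=_opt_float(getattr(row, "gcwf", None)),
                cnv_call_count=_opt_int(getattr(row, "cnv_call_count", None)),
                father_id=_opt_str(getattr(row, "father_id", None)),
                mother_id=_opt_str(getattr(row, "mother_id", None)),
            )
        )
    return records


def _opt_float(x):
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return float(x)


def _opt_int(x):
    f = _opt_float(x)
    return None if f is None else int(f)


def _opt_str(x):
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return str(x)


def write_sample_manifest(samples: Iterable[SampleRecord], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "groups": ",".join(sorted(s.groups)),
                "ethnicity": s.ethnicity,
                "call_rate": s.call_rate,
                "lrr_sd": s.lrr_sd,
                "gcwf": s.gcwf,
                "cnv_call_count": s.cnv_call_count,
                "father_id": s.father_id,
                "mother_id": s.mother_id,
            }
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reference_cnvs(path: str | Path) -> list[ReferenceCnv]:
    """Read a reference CNV set as TSV (cnv_id, chrom, start, end, copy_state, genes)."""
    df = pd.read_csv(path, sep="\t", dtype={"cnv_id": str, "genes": str})
    refs = []
    for row in df.itertuples(index=False):
        genes = [g for g in str(row.genes).split(",") if g]
        refs.append(
            ReferenceCnv(
                cnv_id=str(row.cnv_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                copy_state=CopyState(row.copy_state),
                genes=genes,
            )
        )
    return refs


def write_reference_cnvs(refs: Iterable[ReferenceCnv], path: str | Path) -> None:
    rows = [
        {
            "cnv_id": r.cnv_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "copy_state": r.copy_state.value,
            "genes": ",".join(r.genes),
        }
        for r in refs
    ]
    pd.DataFrame(rows, columns=["cnv_id", "chrom", "start", "end", "copy_state", "genes"]).to_csv(
        path, sep="\t", index=False
    )


def read_region_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a (optionally labeled) BED region list -> 1-based inclusive tuples."""
    regions = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}, line {lineno}: expected >= 3 BED columns")
            chrom = normalize_chrom(parts[0])
            start, end = int(parts[1]), int(parts[2])
            if start < 0 or end <= start:
                raise ValueError(f"{path}, line {lineno}: invalid interval")
            label = parts[3] if len(parts) > 3 else f"region_{lineno}"
            regions.append((chrom, start + 1, end, label))
    return regions


def write_region_bed(
    regions: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in regions:
            fh.write(f"{normalize_chrom(chrom)}\t{start - 1}\t{end}\t{label}\n")


_ASSOC_COLUMNS = [f.name for f in dataclass_fields(AssociationResult)]


def write_report(results: Sequence, path: str | Path, sort_key=None) -> None:
    """Write association results (or dict rows) as a deterministic TSV.

    Rows are sorted by ``test_id`` (or the first column) unless a
    ``sort_key`` callable is given; floats use repr so numeric fields
    survive a round trip exactly.
    """
    results = list(results)
    if results and isinstance(results[0], AssociationResult):
        rows = [{k: getattr(r, k) for k in _ASSOC_COLUMNS} for r in results]
        columns = _ASSOC_COLUMNS
    else:
        rows = [dict(r) for r in results]
        columns = list(rows[0].keys()) if rows else ["test_id"]
    key = sort_key or (lambda row: str(row[columns[0]]))
    rows.sort(key=key)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(
                {
                    k: (_format_float(v) if isinstance(v, float) else v)
                    for k, v in row.items()
                }
            )


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_QPCR_COLUMNS = [
    "sample_id",
    "locus_id",
    "individual",
    "assay_kind",  # target | reference
    "assay_id",
    "replicate",
    "ct",
]


def write_qpcr_table(panels: Iterable, path: str | Path) -> None:
    """Write qPCR panels as a tidy TSV, one well replicate per row."""
    rows = []
    for panel in panels:
        targets = set(panel.primers)
        for (individual, assay), reps in sorted(panel.ct.items()):
            kind = "target" if assay in targets else "reference"
            for i, ct in enumerate(reps, start=1):
                rows.append(
                    {
                        "sample_id": panel.sample_id,
                        "locus_id": panel.locus_id,
                        "individual": individual,
                        "assay_kind": kind,
                        "assay_id": assay,
                        "replicate": i,
                        "ct": ct,
                    }
                )
    pd.DataFrame(rows, columns=_QPCR_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_qpcr_table(path: str | Path) -> list:
    """Read a tidy qPCR TSV back into :class:`~cnvburden.qpcr_inheritance.QpcrPanel`
    objects, one per (sample, locus)."""
    from .qpcr_inheritance import QpcrPanel

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual": str})
    panels = []
    for (sample_id, locus_id), grp in df.groupby(["sample_id", "locus_id"], sort=True):
        primers = tuple(sorted(grp.loc[grp.assay_kind == "target", "assay_id"].unique()))
        refs = tuple(sorted(grp.loc[grp.assay_kind == "reference", "assay_id"].unique()))
        calibrators = tuple(
            sorted(set(grp.individual.unique()) - {str(sample_id)})
        )
        ct: dict[tuple[str, str], list[float]] = {}
        for row in grp.sort_values(["individual", "assay_id", "replicate"]).itertuples():
            ct.setdefault((str(row.individual), str(row.assay_id)), []).append(
                float(row.ct)
            )
        panels.append(
            QpcrPanel(str(sample_id), str(locus_id), primers, refs, calibrators, ct)
        )
    return panels
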