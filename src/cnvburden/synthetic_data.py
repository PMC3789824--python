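"""Synthetic genomes, case-control cohorts, trios, and qPCR data.

The generator emulates the statistical structure an SNP-array CNV
case-control study assumes:

* a reduced diploid genome with non-overlapping multi-exon genes;
* shared polymorphic CNV loci segregating at fixed population
  frequencies (these create the common CNVs that the <1% rare rule and
  the patient-specificity filter must reject);
* per-genome background CNVs with log-normally distributed sizes
  (median 60 kb, sigma chosen so ~2.5% of genic background CNVs exceed
  1 Mb, the tail observed in large control cohorts);
* a case-specific enrichment of large (>= 1 Mb) multi-gene CNVs injected
  at a rate solved from a target carrier odds ratio against the realized
  control carrier rate;
* trios in which every non-de-novo case CNV is carried by exactly one
  parent; and
* a qPCR forward model in which the target Ct shifts by -log2(dosage/2)
  cycles relative to a two-copy genome, with Gaussian replicate noise.

Every simulated CNV call is paired with exactly one :class:`TruthRecord`
so that downstream recovery can be scored against ground truth.  All
randomness flows from ``SimulationConfig.seed``; fixed seed means
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .qpcr_inheritance import CENSOR_CT, REFERENCE_GENES, QpcrPanel
from .types import CnvCall, CopyState, GeneModel, SampleRecord

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "CohortBundle",
    "generate_genome",
    "generate_cohort",
    "generate_trios",
    "generate_qpcr_panel",
    "generate_qpcr_trio",
    "simulate_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulator; defaults mirror the study conditions
    (205 Caucasian patients vs 1,953 controls, carrier odds ratio ~3.2
    for large rare genic CNVs, ~a quarter of large case CNVs de novo).
    """

    seed: int = 0
    n_chromosomes: int = 10
    chrom_length_bp: int = 30_000_000
    n_genes: int = 1_200
    exons_per_gene: tuple[int, int] = (2, 10)
    n_cases: int = 205
    n_controls: int = 1_953
    background_cnv_rate: float = 3.5  # mean raw calls per genome
    size_median_bp: float = 60_000.0
    # ln-scale spread; calibrated so ~2.5% of the rare genic CNVs that
    # survive filtering in controls exceed 1 Mb (the filters condition on
    # genic content and length, so this sits below the raw 2.5% quantile)
    size_sigma: float = 1.20
    polymorphic_loci: int = 30
    polymorphic_freq_range: tuple[float, float] = (0.005, 0.08)
    enrichment_or: float = 3.2
    denovo_fraction: float = 0.25
    qpcr_ct_sigma: float = 0.1
    qc_fail_fraction: float = 0.02  # per QC rule
    large_cnv_bp: int = 1_000_000
    acc_plus_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 1:
            raise ValueError("cohort sizes must be positive")
        lo, hi = self.polymorphic_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("polymorphic frequencies must lie in (0, 1)")
        if self.enrichment_or < 1.0:
            raise ValueError("enrichment_or must be >= 1")
        if not 0.0 <= self.denovo_fraction <= 1.0:
            raise ValueError("denovo_fraction must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth for one simulated CNV call.

    ``origin`` is one of polymorphic, background, injected_case,
    transmitted, de_novo; ``injected`` stays True for case-injected CNVs
    after trio generation relabels them transmitted/de_novo.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_state: CopyState
    origin: str
    injected: bool = False
    parent_id: Optional[str] = None  # carrier parent for transmitted CNVs


@dataclass
class CohortBundle:
    """Everything one simulated study produces."""

    genes: list[GeneModel]
    calls: list[CnvCall]
    samples: list[SampleRecord]
    truth: list[TruthRecord]


def _rng_for(config: SimulationConfig, stage: str) -> np.random.Generator:
    """Independent, reproducible stream per pipeline stage.

    Streams are derived from the single config seed with a fixed stage
    tag, so each stage is deterministic on its own and a full run is
    byte-identical under a fixed seed.
    """
    tag = int.from_bytes(stage.encode(), "little") % (2**31)
    return np.random.default_rng([config.seed, tag])


def generate_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[GeneModel]:
    """Place multi-exon genes uniformly and without overlap.

    Genes are dealt round-robin across chromosomes; within each
    chromosome the inter-gene gaps are a uniform random partition of the
    sequence not covered by gene bodies, so placement is uniform
    conditional on no overlap.
    """
    rng = rng if rng is not None else _rng_for(config, "genome")
    if config.n_genes == 0:
        return []
    lo, hi = config.exons_per_gene
    genes: list[GeneModel] = []
    per_chrom: list[list[tuple[str, list[tuple[int, int]]]]] = [
        [] for _ in range(config.n_chromosomes)
    ]
    for i in range(config.n_genes):
        n_exons = int(rng.integers(lo, hi + 1))
        exon_lens = rng.integers(150, 1_501, size=n_exons)
        intron_lens = rng.integers(2_000, 15_001, size=max(0, n_exons - 1))
        offsets = []
        pos = 0
        for j, el in enumerate(exon_lens):
            offsets.append((pos, pos + int(el) - 1))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        per_chrom[i % config.n_chromosomes].append((f"G{i + 1:05d}", offsets))

    for ci, chrom_genes in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        spans = [offs[-1][1] + 1 for _, offs in chrom_genes]
        free = config.chrom_length_bp - sum(spans)
        if free < len(chrom_genes) + 1:
            raise ValueError(
                f"gene footprint exceeds chromosome length on {chrom}"
            )
        fractions = rng.random(len(chrom_genes) + 1)
        gaps = np.floor(fractions / fractions.sum() * free).astype(int)
        pos = 1
        for (gene_id, offsets), gap, span in zip(chrom_genes, gaps, spans):
            pos += int(gap)
            exons = [(pos + s, pos + e) for s, e in offsets]
            genes.append(GeneModel(gene_id, chrom, exons))
            pos += span
    genes.sort(key=lambda g: g.gene_id)
    return genes


@dataclass(frozen=True)
class _PolymorphicLocus:
    chrom: str
    start: int
    end: int
    copy_number: int
    n_snps: int
    frequency: float


def _draw_polymorphic_loci(
    config: SimulationConfig, genes: Sequence[GeneModel], rng: np.random.Generator
) -> list[_PolymorphicLocus]:
    """Fixed genic CNV loci shared across individuals."""
    loci = []
    if not genes:
        return loci
    lo_f, hi_f = config.polymorphic_freq_range
    anchors = rng.choice(len(genes), size=config.polymorphic_loci, replace=False) if (
        config.polymorphic_loci <= len(genes)
    ) else rng.integers(0, len(genes), size=config.polymorphic_loci)
    for a in anchors:
        g = genes[int(a)]
        length = int(np.clip(rng.lognormal(math.log(80_000), 0.5), 40_000, 400_000))
        start = max(1, g.start - int(rng.integers(5_000, 20_000)))
        freq = math.exp(rng.uniform(math.log(lo_f), math.log(hi_f)))
        loci.append(
            _PolymorphicLocus(
                chrom=g.chrom,
                start=start,
                end=start + length,
                copy_number=int(rng.choice([1, 3])),
                n_snps=max(10, length // 2_500),
                frequency=freq,
            )
        )
    return loci


def _draw_background_call(
    config: SimulationConfig, sample_id: str, rng: np.random.Generator
) -> CnvCall:
    chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
    length = int(
        np.clip(
            rng.lognormal(math.log(config.size_median_bp), config.size_sigma),
            5_000,
            config.chrom_length_bp // 2,
        )
    )
    start = int(rng.integers(1, config.chrom_length_bp - length))
    # occasional homozygous deletions / high-grade amplifications
    if rng.random() < 0.5:
        cn = 0 if rng.random() < 0.05 else 1
    else:
        cn = 4 if rng.random() < 0.05 else 3
    n_snps = max(3, int(rng.poisson(length / 2_500)))
    conf = float(np.round(rng.lognormal(math.log(30.0), 0.8), 3))
    return CnvCall(sample_id, chrom, start, start + length, cn, n_snps, conf)


def _sample_qc_metrics(
    rng: np.random.Generator, fail_fraction: float, n_calls: int
) -> dict:
    """QC metrics passing each rule unless that rule is drawn to fail."""
    fails = rng.random(4) < fail_fraction
    call_rate = (
        float(rng.uniform(0.95, 0.98)) if fails[0] else float(rng.uniform(0.985, 0.999))
    )
    lrr_sd = float(rng.uniform(0.30, 0.50)) if fails[1] else float(rng.uniform(0.08, 0.25))
    gcwf = (
        float(rng.choice([-1, 1]) * rng.uniform(0.04, 0.08))
        if fails[2]
        else float(rng.uniform(-0.03, 0.03))
    )
    count = int(rng.integers(100, 150)) if fails[3] else n_calls
    return dict(call_rate=call_rate, lrr_sd=lrr_sd, gcwf=gcwf, cnv_call_count=count)


def _genic_large_carrier(
    calls: Sequence[CnvCall], genes_by_chrom: dict, large_bp: int
) -> bool:
    for c in calls:
        if c.length_bp >= large_bp and _n_genes(c, genes_by_chrom) >= 1:
            return True
    return False


def _n_genes(call: CnvCall, genes_by_chrom: dict) -> int:
    hits = 0
    for g in genes_by_chrom.get(call.chrom, ()):
        if g.start <= call.end and g.end >= call.start:
            hits += 1
    return hits


def generate_cohort(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    rng: Optional[np.random.Generator] = None,
) -> CohortBundle:
    """Generate controls then cases with calibrated case enrichment.

    Controls carry polymorphic-locus and background CNVs.  Cases carry
    the same plus an injected large (>= 1 Mb, >= 2 genes) CNV with
    probability ``p_inj`` chosen so the case carrier probability for a
    large genic CNV equals ``p1 = OR*q / (1 - q + OR*q)``, with ``q``
    the realized control carrier rate.  Draw order: polymorphic loci,
    then per control (carriage, background, QC), then per case
    (carriage, background, injection, QC).
    """
    rng = rng if rng is not None else _rng_for(config, "cohort")
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    loci = _draw_polymorphic_loci(config, genes, rng)

    calls: list[CnvCall] = []
    samples: list[SampleRecord] = []
    truth: list[TruthRecord] = []

    def emit(call: CnvCall, origin: str, injected: bool = False) -> None:
        calls.append(call)
        truth.append(
            TruthRecord(
                call.sample_id,
                call.chrom,
                call.start,
                call.end,
                call.copy_state,
                origin,
                injected=injected,
            )
        )

    def person_calls(sample_id: str) -> list[CnvCall]:
        mine: list[CnvCall] = []
        for locus in loci:
            if rng.random() < locus.frequency:
                conf = float(np.round(rng.lognormal(math.log(60.0), 0.4), 3))
                mine.append(
                    CnvCall(
                        sample_id,
                        locus.chrom,
                        locus.start,
                        locus.end,
                        locus.copy_number,
                        locus.n_snps,
                        max(12.0, conf),
                    )
                )
        for _ in range(int(rng.poisson(config.background_cnv_rate))):
            mine.append(_draw_background_call(config, sample_id, rng))
        return mine

    control_carriers = 0
    for i in range(config.n_controls):
        sid = f"C{i + 1:05d}"
        mine = person_calls(sid)
        for c in mine:
            origin = (
                "polymorphic"
                if any(
                    c.chrom == l.chrom and c.start == l.start and c.end == l.end
                    for l in loci
                )
                else "background"
            )
            emit(c, origin)
        if _genic_large_carrier(mine, genes_by_chrom, config.large_cnv_bp):
            control_carriers += 1
        qc = _sample_qc_metrics(rng, config.qc_fail_fraction, len(mine))
        samples.append(
            SampleRecord(sid, frozenset({"control"}), ethnicity="Caucasian", **qc)
        )

    q = control_carriers / config.n_controls
    or_ = config.enrichment_or
    p1 = or_ * q / (1 - q + or_ * q) if q > 0 else 0.0
    if p1 >= 1.0:
        raise ValueError("enrichment_or unachievable: case carrier rate would reach 1")
    p_inj = max(0.0, (p1 - q) / (1 - q)) if q < 1 else 0.0

    for i in range(config.n_cases):
        sid = f"P{i + 1:05d}"
        mine = person_calls(sid)
        for c in mine:
            origin = (
                "polymorphic"
                if any(
                    c.chrom == l.chrom and c.start == l.start and c.end == l.end
                    for l in loci
                )
                else "background"
            )
            emit(c, origin)
        if rng.random() < p_inj:
            inj = _draw_injected_call(config, sid, genes_by_chrom, rng)
            emit(inj, "injected_case", injected=True)
            mine.append(inj)
        qc = _sample_qc_metrics(rng, config.qc_fail_fraction, len(mine))
        subgroup = "ACC_PLUS" if rng.random() < config.acc_plus_fraction else "ACC_ONLY"
        samples.append(
            SampleRecord(
                sid, frozenset({"ACC", subgroup}), ethnicity="Caucasian", **qc
            )
        )

    return CohortBundle(list(genes), calls, samples, truth)


def _draw_injected_call(
    config: SimulationConfig,
    sample_id: str,
    genes_by_chrom: dict,
    rng: np.random.Generator,
) -> CnvCall:
    """A large (>= 1 Mb) CNV covering >= 2 genes at a random position."""
    for _ in range(200):
        chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
        length = int(rng.uniform(config.large_cnv_bp, 4 * config.large_cnv_bp))
        if length >= config.chrom_length_bp:
            continue
        start = int(rng.integers(1, config.chrom_length_bp - length))
        call = CnvCall(
            sample_id,
            chrom,
            start,
            start + length,
            int(rng.choice([1, 3])),
            max(10, length // 2_500),
            float(np.round(rng.lognormal(math.log(150.0), 0.3), 3)),
        )
        if _n_genes(call, genes_by_chrom) >= 2:
            return call
    raise ValueError("could not place an injected CNV covering >= 2 genes")


def generate_trios(
    config: SimulationConfig,
    cohort: CohortBundle,
    rng: Optional[np.random.Generator] = None,
) -> CohortBundle:
    """Add two parents per case and decide transmission.

    Each case-injected CNV becomes de novo with probability
    ``denovo_fraction``; every other case CNV is copied into exactly one
    parent (fair coin).  Parents carry only transmitted copies; their
    QC metrics always pass.  Truth records of case CNVs are relabeled
    transmitted / de_novo; parental copies get their own transmitted
    truth records, preserving the call<->truth bijection.
    """
    rng = rng if rng is not None else _rng_for(config, "trios")
    by_id = {s.sample_id: s for s in cohort.samples}
    new_samples: list[SampleRecord] = []
    new_calls: list[CnvCall] = []
    new_truth: list[TruthRecord] = []

    cases = [s for s in cohort.samples if not s.is_control and "parent" not in s.groups]
    for case in cases:
        father, mother = f"{case.sample_id}-F", f"{case.sample_id}-M"
        case.father_id, case.mother_id = father, mother
        for pid in (father, mother):
            new_samples.append(
                SampleRecord(
                    pid,
                    frozenset({"parent"}),
                    ethnicity=case.ethnicity,
                    call_rate=0.995,
                    lrr_sd=0.15,
                    gcwf=0.0,
                    cnv_call_count=0,
                )
            )

    case_ids = {s.sample_id for s in cases}
    for call, tr in zip(cohort.calls, cohort.truth):
        if call.sample_id not in case_ids:
            continue
        if tr.injected and rng.random() < config.denovo_fraction:
            tr.origin = "de_novo"
            continue
        carrier = (
            f"{call.sample_id}-F" if rng.random() < 0.5 else f"{call.sample_id}-M"
        )
        tr.origin = "transmitted"
        tr.parent_id = carrier
        copy = CnvCall(
            carrier,
            call.chrom,
            call.start,
            call.end,
            call.copy_number,
            call.n_snps,
            call.confidence,
        )
        new_calls.append(copy)
        new_truth.append(
            TruthRecord(
                carrier,
                call.chrom,
                call.start,
                call.end,
                call.copy_state,
                "transmitted",
                injected=tr.injected,
            )
        )

    cohort.samples.extend(new_samples)
    cohort.calls.extend(new_calls)
    cohort.truth.extend(new_truth)
    return cohort


def generate_qpcr_panel(
    sample_id: str,
    locus_id: str,
    dosage: int,
    rng: np.random.Generator,
    ct_sigma: float = 0.1,
    basal_target_ct: float = 26.0,
    basal_reference_ct: float = 24.0,
    n_primers: int = 2,
    n_references: int = 2,
    n_calibrators: int = 2,
) -> QpcrPanel:
    """Forward-simulate one qPCR panel given the true locus dosage.

    Target Ct = basal - log2(dosage / 2) + N(0, sigma) per replicate;
    reference-gene Ct is independent of the locus dosage; calibrators
    are two-copy individuals.  Dosage 0 censors the target wells at the
    no-amplification ceiling and flags the panel.
    """
    primers = tuple(f"{locus_id}-p{i + 1}" for i in range(n_primers))
    references = REFERENCE_GENES[:n_references]
    calibrators = tuple(f"NC{i + 1}" for i in range(n_calibrators))
    censored = dosage == 0
    ct: dict[tuple[str, str], list[float]] = {}

    def wells(individual: str, assay: str, mean_ct: float, censor: bool = False):
        if censor:
            ct[(individual, assay)] = [CENSOR_CT] * 3
        else:
            ct[(individual, assay)] = [
                float(mean_ct + rng.normal(0.0, ct_sigma)) for _ in range(3)
            ]

    target_ct = basal_target_ct - (math.log2(dosage / 2.0) if dosage > 0 else 0.0)
    for p in primers:
        wells(sample_id, p, target_ct, censor=censored)
        for c in calibrators:
            wells(c, p, basal_target_ct)
    for g in references:
        wells(sample_id, g, basal_reference_ct)
        for c in calibrators:
            wells(c, g, basal_reference_ct)
    return QpcrPanel(
        sample_id, locus_id, primers, references, calibrators, ct, censored=censored
    )


def generate_qpcr_trio(
    locus_id: str,
    child_id: str,
    child_dosage: int,
    father_dosage: int,
    mother_dosage: int,
    rng: np.random.Generator,
    ct_sigma: float = 0.1,
) -> dict[str, QpcrPanel]:
    """Panels for child, father, and mother at one locus."""
    return {
        "child": generate_qpcr_panel(child_id, locus_id, child_dosage, rng, ct_sigma),
        "father": generate_qpcr_panel(
            f"{child_id}-F", locus_id, father_dosage, rng, ct_sigma
        ),
        "mother": generate_qpcr_panel(
            f"{child_id}-M", locus_id, mother_dosage, rng, ct_sigma
        ),
    }


def simulate_study(config: SimulationConfig, with_trios: bool = True) -> CohortBundle:
    """Genome + cohort (+ trios) in the documented stage order."""
    genome_rng = _rng_for(config, "genome")
    cohort_rng = _rng_for(config, "cohort")
    genes = generate_genome(config, genome_rng)
    bundle = generate_cohort(config, genes, cohort_rng)
    if with_trios:
        generate_trios(config, bundle, _rng_for(config, "trios"))
    return bundle
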