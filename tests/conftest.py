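"""Shared fixtures: a small hand-built genome and synthetic cohorts."""

import numpy as np
import pytest

from cnvburden.synthetic_data import SimulationConfig, simulate_study
from cnvburden.types import CnvCall, ExonIndex, GeneModel, SampleRecord


@pytest.fixture
def small_genome() -> list[GeneModel]:
    """Ten two-exon genes spaced 1 Mb apart on chr1, one gene on chr2."""
    genes = [
        GeneModel(
            f"G{i:02d}",
            "chr1",
            [(i * 1_000_000 + 1, i * 1_000_000 + 2_000),
             (i * 1_000_000 + 10_000, i * 1_000_000 + 12_000)],
        )
        for i in range(1, 11)
    ]
    genes.append(GeneModel("H01", "chr2", [(500_000, 502_000)]))
    return genes


@pytest.fixture
def exon_index(small_genome) -> ExonIndex:
    return ExonIndex(small_genome)


def make_call(
    sample="S1",
    chrom="chr1",
    start=1_000_500,
    end=1_060_500,
    cn=1,
    n_snps=20,
    conf=50.0,
) -> CnvCall:
    return CnvCall(sample, chrom, start, end, cn, n_snps, conf)


def make_sample(sample_id="S1", groups=("ACC", "ACC_ONLY"), **qc) -> SampleRecord:
    defaults = dict(call_rate=0.995, lrr_sd=0.15, gcwf=0.0, cnv_call_count=20)
    defaults.update(qc)
    return SampleRecord(sample_id, frozenset(groups), **defaults)


@pytest.fixture(scope="session")
def small_study():
    """A reduced but complete simulated study reused by slower tests."""
    cfg = SimulationConfig(
        seed=7, n_cases=60, n_controls=400, n_genes=600, n_chromosomes=6,
        qc_fail_fraction=0.0,
    )
    return cfg, simulate_study(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
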