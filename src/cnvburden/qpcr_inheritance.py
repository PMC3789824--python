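"""qPCR relative quantification (ddCt), copy-state calling, and trio
inheritance classification.

Each array-predicted CNV is re-tested by SYBR-green qPCR: the target
locus is amplified with >= 2 independent primer pairs in the proband
(and parents, when available) alongside 2-4 unrelated normal calibrator
individuals, normalizing against >= 2 of four reference genes (ALB,
RPP14, HEM3, GPR15), everything in triplicate.  The ddCt method yields
one relative quantity (RQ) per (primer, reference gene, calibrator)
combination — at least 8 RQ values per sample.  RQ ~ 1 is two-copy
normal, ~ 0.5 a heterozygous deletion, ~ 1.5 a duplication.

Copy-state decision rule: the 95% confidence interval of the mean RQ
(t-distribution, since n is small) is compared with the (0.7, 1.3)
window — entirely inside is normal, entirely below 0.7 a deletion,
entirely above 1.3 a duplication; a CI straddling a threshold supports
no call and is reported inconclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "REFERENCE_GENES",
    "QpcrPanel",
    "QpcrResult",
    "compute_rq",
    "call_copy_state",
    "classify_inheritance",
]

REFERENCE_GENES = ("ALB", "RPP14", "HEM3", "GPR15")

#: Ct value recorded for wells where the target failed to amplify
#: (homozygous deletion); flagged via QpcrPanel.censored.
CENSOR_CT = 40.0


@dataclass
class QpcrPanel:
    """Triplicate Ct measurements for one (sample, locus) qPCR experiment.

    ``ct[(individual, assay)]`` holds the three replicate Ct values,
    where ``individual`` is the tested sample or a calibrator id and
    ``assay`` is a target primer id or a reference gene id.
    """

    sample_id: str
    locus_id: str
    primers: tuple[str, ...]
    reference_genes: tuple[str, ...]
    calibrators: tuple[str, ...]
    ct: dict[tuple[str, str], list[float]]
    censored: bool = False

    def validate(self) -> None:
        if len(self.primers) < 2:
            raise ValueError("panel requires >= 2 independent primer pairs")
        if len(self.reference_genes) < 2:
            raise ValueError("panel requires >= 2 reference genes")
        if not 2 <= len(self.calibrators) <= 4:
            raise ValueError("panel requires 2-4 calibrator individuals")
        for individual in (self.sample_id, *self.calibrators):
            for assay in (*self.primers, *self.reference_genes):
                well = (individual, assay)
                reps = self.ct.get(well)
                if reps is None or len(reps) != 3 or any(
                    r is None or math.isnan(r) for r in reps
                ):
                    raise ValueError(f"missing replicate in well {well}")


@dataclass
class QpcrResult:
    """RQ summary and copy-state call for one (sample, locus)."""

    sample_id: str
    locus_id: str
    rq_values: list[float]
    mean_rq: float
    ci_low: float
    ci_high: float
    call: str  # "normal" | "deletion" | "duplication" | "inconclusive"


def compute_rq(panel: QpcrPanel) -> list[float]:
    """All ddCt relative quantities for a panel.

    For every (primer p, reference gene g, calibrator c):
    ``dCt_sample = mean Ct(sample, p) - mean Ct(sample, g)``, likewise
    for the calibrator, and ``RQ = 2**-(dCt_sample - dCt_calibrator)``.
    With 2 primers x 2 reference genes x 2 calibrators this yields the
    canonical 8 values.
    """
    panel.validate()
    rqs = []
    for p in panel.primers:
        for g in panel.reference_genes:
            d_sample = _mean_ct(panel, panel.sample_id, p) - _mean_ct(
                panel, panel.sample_id, g
            )
            for c in panel.calibrators:
                d_cal = _mean_ct(panel, c, p) - _mean_ct(panel, c, g)
                rqs.append(2.0 ** -(d_sample - d_cal))
    return rqs


def _mean_ct(panel: QpcrPanel, individual: str, assay: str) -> float:
    return float(np.mean(panel.ct[(individual, assay)]))


def call_copy_state(
    rqs: list[float],
    sample_id: str = "",
    locus_id: str = "",
    lower: float = 0.7,
    upper: float = 1.3,
    confidence: float = 0.95,
) -> QpcrResult:
    """Copy-state call from the t-based CI of the mean RQ (>= 8 values).

    normal if the CI lies inside (lower, upper); deletion if entirely
    below ``lower``; duplication if entirely above ``upper``; otherwise
    inconclusive.
    """
    if len(rqs) < 8:
        raise ValueError("insufficient replicates: need >= 8 RQ values")
    arr = np.asarray(rqs, dtype=float)
    n = arr.size
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    half = stats.t.ppf(0.5 + confidence / 2, n - 1) * sd / math.sqrt(n)
    lo, hi = mean - half, mean + half
    if hi < lower:
        call = "deletion"
    elif lo > upper:
        call = "duplication"
    elif lower < lo and hi < upper:
        call = "normal"
    else:
        call = "inconclusive"
    return QpcrResult(sample_id, locus_id, list(rqs), mean, lo, hi, call)


def classify_inheritance(
    child: QpcrResult,
    father: Optional[QpcrResult],
    mother: Optional[QpcrResult],
) -> str:
    """Trio inheritance of a confirmed CNV from per-individual qPCR calls.

    * child normal -> ``false_positive`` (the array call did not confirm);
    * child non-normal and a parent shares the same non-normal state ->
      ``inherited``;
    * child non-normal and both parents tested normal -> ``de_novo``;
    * a needed parent absent or inconclusive (and no parent sharing the
      state) -> ``not_determined``.
    """
    if child.call == "inconclusive":
        return "not_determined"
    if child.call == "normal":
        return "false_positive"
    parent_calls = [p.call for p in (father, mother) if p is not None]
    if child.call in parent_calls:
        return "inherited"
    if len(parent_calls) == 2 and all(c == "normal" for c in parent_calls):
        return "de_novo"
    return "not_determined"
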