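"""Patient-level PET parameters, reduction ratios and response labels.

A patient is a responder on a given parameter when the reduction ratio

    RR = -(value_PET2 - value_PET1) / value_PET1 * 100

is strictly greater than 30% (a tie at exactly 30% is a non-response).
Parameters are SUVmax, SUVmean, MTV (mL) and TL = SUVmean * MTV.

Multi-lesion aggregation on a patient basis: SUVmax is the maximum over
lesions, MTV and TL are summed, and SUVmean is the volume-weighted mean
(TL / MTV) — the only aggregation under which the defining identity
TL = SUVmean * MTV survives summation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .errors import EmptyMaskError, MixedLesionClassError, UndefinedBaselineError
from .imaging import PETVolume, ROIMask

PARAMETERS = ("SUVmax", "SUVmean", "MTV", "TL")
RESPONSE_THRESHOLD_PCT = 30.0

__all__ = [
    "PARAMETERS",
    "RESPONSE_THRESHOLD_PCT",
    "TraditionalParams",
    "ReductionRecord",
    "patient_params",
    "reduction_ratio",
    "classify_response",
    "cohort_table",
    "summarize_counts",
]


@dataclass(frozen=True)
class TraditionalParams:
    """SUVmax / SUVmean / MTV / TL aggregated over a patient's lesions."""

    suvmax: float
    suvmean: float
    mtv_ml: float
    tl: float
    lesion_class: str
    n_lesions: int

    def value(self, parameter: str) -> float:
        return {
            "SUVmax": self.suvmax,
            "SUVmean": self.suvmean,
            "MTV": self.mtv_ml,
            "TL": self.tl,
        }[parameter]


@dataclass(frozen=True)
class ReductionRecord:
    parameter: str
    value_pet1: float
    value_pet2: float
    rr_percent: float
    responder: bool


def patient_params(volume: PETVolume, lesion_masks: Sequence[ROIMask]) -> TraditionalParams:
    """Aggregate the four traditional parameters over a patient's lesions."""
    masks = [m for m in lesion_masks]
    if not masks or all(m.is_empty() for m in masks):
        raise EmptyMaskError("patient_params requires at least one non-empty lesion mask")
    classes = {m.lesion_class for m in masks}
    if len(classes) > 1:
        raise MixedLesionClassError(f"mixed lesion classes: {sorted(classes)}")
    suvmax = 0.0
    mtv_ml = 0.0
    tl = 0.0
    n = 0
    for m in masks:
        if m.is_empty():
            continue
        vals = volume.values[m.values]
        lesion_mtv = m.n_voxels * m.voxel_volume_mm3 / 1000.0
        suvmax = max(suvmax, float(vals.max()))
        mtv_ml += lesion_mtv
        tl += float(vals.mean()) * lesion_mtv
        n += 1
    return TraditionalParams(
        suvmax=suvmax,
        suvmean=tl / mtv_ml,
        mtv_ml=mtv_ml,
        tl=tl,
        lesion_class=classes.pop(),
        n_lesions=n,
    )


def reduction_ratio(value_pet1: float, value_pet2: float) -> float:
    """Percent reduction from baseline; positive when the parameter decreased."""
    if value_pet1 <= 0:
        raise UndefinedBaselineError(f"baseline value must be positive, got {value_pet1}")
    return float(-(value_pet2 - value_pet1) / value_pet1 * 100.0)


def classify_response(
    params_pet1: TraditionalParams, params_pet2: TraditionalParams
) -> List[ReductionRecord]:
    """One reduction record per parameter; responder iff RR > 30 (strict)."""
    if params_pet1.lesion_class != params_pet2.lesion_class:
        raise MixedLesionClassError(
            f"lesion class mismatch: {params_pet1.lesion_class} vs {params_pet2.lesion_class}"
        )
    records = []
    for p in PARAMETERS:
        v1, v2 = params_pet1.value(p), params_pet2.value(p)
        rr = reduction_ratio(v1, v2)
        records.append(
            ReductionRecord(
                parameter=p,
                value_pet1=v1,
                value_pet2=v2,
                rr_percent=rr,
                responder=rr > RESPONSE_THRESHOLD_PCT,
            )
        )
    return records


def summarize_counts(
    counts: Dict[str, Tuple[int, int]]
) -> Tuple[Dict[str, Tuple[int, int, float]], int]:
    """Per-parameter (responders, non-responders, percent) and the
    across-parameter average responder percentage truncated to integer."""
    table = {}
    pcts = []
    for p in PARAMETERS:
        r, nr = counts[p]
        pct = 100.0 * r / (r + nr)
        table[p] = (r, nr, pct)
        pcts.append(pct)
    return table, int(np.mean(pcts))  # truncation, not rounding


def cohort_table(
    patient_records: Iterable[Sequence[ReductionRecord]],
) -> Tuple[Dict[str, Tuple[int, int, float]], int]:
    """Tabulate responder counts per parameter across a cohort of one
    lesion class, plus the truncated across-parameter average percent."""
    counts = {p: [0, 0] for p in PARAMETERS}
    for records in patient_records:
        for rec in records:
            counts[rec.parameter][0 if rec.responder else 1] += 1
    return summarize_counts({p: tuple(v) for p, v in counts.items()})
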