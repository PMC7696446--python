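"""Forecast accuracy metrics: RMSE, MAPE, and Clarke error-grid analysis.

All metrics operate on reference/predicted glucose pairs in mg/dL.  The
Clarke error grid partitions pairs into five clinical-consequence zones:

* A — clinically accurate (within 20% of reference, or both hypoglycemic),
* B — benign over/underestimation,
* C — overcorrection errors,
* D — dangerous failure to detect hypo-/hyperglycemia,
* E — erroneous treatment (hypo and hyper confused).

The standard programmatic rule chain (with the 175/3 mg/dL breakpoint) is
applied in fixed order A, E, C, D, else B, so every pair lands in exactly
one zone and boundary ties resolve toward the earlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["ZONES", "rmse", "mape", "clarke_zone", "clarke_zones",
           "clarke_grid", "evaluate", "EvalReport"]

ZONES = ("A", "B", "C", "D", "E")


def _check_pair(reference, predicted, positive_ref: bool = False):
    ref = np.asarray(reference, dtype=np.float64).ravel()
    pred = np.asarray(predicted, dtype=np.float64).ravel()
    if ref.size != pred.size:
        raise ValidationError(f"length mismatch: {ref.size} vs {pred.size}")
    if ref.size == 0:
        raise ValidationError("empty input vectors")
    if positive_ref and np.any(ref <= 0):
        raise ValidationError("reference glucose must be positive")
    return ref, pred


def rmse(reference, predicted) -> float:
    """Root mean squared error in mg/dL."""
    ref, pred = _check_pair(reference, predicted)
    return float(np.sqrt(np.mean((ref - pred) ** 2)))


def mape(reference, predicted) -> float:
    """Mean absolute percentage error, in percent of the reference value."""
    ref, pred = _check_pair(reference, predicted, positive_ref=True)
    return float(100.0 * np.mean(np.abs(ref - pred) / ref))


def clarke_zones(reference, predicted) -> np.ndarray:
    """Vectorized Clarke zone assignment; returns an array of 'A'..'E'."""
    ref, pred = _check_pair(reference, predicted, positive_ref=True)
    if np.any(pred <= 0):
        raise ValidationError("predicted glucose must be positive")

    zone_a = (np.abs(pred - ref) <= 0.2 * ref) | ((ref < 70) & (pred < 70))
    zone_e = ((ref >= 180) & (pred <= 70)) | ((ref <= 70) & (pred >= 180))
    zone_c = ((ref >= 70) & (ref <= 290) & (pred >= ref + 110)) | \
             ((ref >= 130) & (ref <= 180) & (pred <= (7.0 / 5.0) * ref - 182.0))
    zone_d = ((ref >= 240) & (pred >= 70) & (pred <= 180)) | \
             ((ref <= 175.0 / 3.0) & (pred >= 70) & (pred <= 180)) | \
             ((ref >= 175.0 / 3.0) & (ref <= 70) & (pred >= (6.0 / 5.0) * ref))

    out = np.full(ref.shape, "B", dtype="<U1")
    # reverse-priority writes so earlier rules win ties
    out[zone_d] = "D"
    out[zone_c] = "C"
    out[zone_e] = "E"
    out[zone_a] = "A"
    return out


def clarke_zone(reference: float, predicted: float) -> str:
    """Clarke zone of a single (reference, predicted) pair."""
    return str(clarke_zones([reference], [predicted])[0])


def clarke_grid(reference, predicted) -> tuple[dict[str, int], dict[str, float]]:
    """Aggregate zone counts and percentages over paired vectors."""
    zones = clarke_zones(reference, predicted)
    counts = {z: int(np.sum(zones == z)) for z in ZONES}
    n = zones.size
    percentages = {z: 100.0 * counts[z] / n for z in ZONES}
    return counts, percentages


@dataclass(frozen=True)
class EvalReport:
    """All accuracy metrics for one patient/model pair."""

    patient_id: str
    n_pairs: int
    rmse: float
    mape: float
    zone_counts: dict[str, int]
    zone_percentages: dict[str, float]
    pairs: pd.DataFrame = field(repr=False, compare=False, default=None)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "n_pairs": self.n_pairs,
            "rmse": self.rmse,
            "mape": self.mape,
            "zone_counts": dict(self.zone_counts),
            "zone_percentages": dict(self.zone_percentages),
        }


def evaluate(reference, predicted, patient_id: str = "unknown") -> EvalReport:
    """Assemble RMSE, MAPE and Clarke-grid statistics into one report.

    The report carries the per-pair table (reference, predicted, zone) for
    error-grid scatter plotting.
    """
    ref, pred = _check_pair(reference, predicted, positive_ref=True)
    zones = clarke_zones(ref, pred)
    counts = {z: int(np.sum(zones == z)) for z in ZONES}
    percentages = {z: 100.0 * counts[z] / ref.size for z in ZONES}
    pairs = pd.DataFrame({"reference_mg_dl": ref, "predicted_mg_dl": pred,
                          "zone": zones})
    return EvalReport(
        patient_id=patient_id,
        n_pairs=int(ref.size),
        rmse=rmse(ref, pred),
        mape=mape(ref, pred),
        zone_counts=counts,
        zone_percentages=percentages,
        pairs=pairs,
    )
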