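"""Trace cleaning, grid regularization, and value scaling.

Out-of-range readings are *removed* (they become missing grid slots), never
imputed — CGM devices themselves refuse to report outside their measuring
range, and filling gaps would leak fabricated values into training windows.
Scaling is fitted on the training period only and inverted exactly before
any metric is reported, so all evaluation happens in mg/dL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .trace import GlucoseTrace

__all__ = ["clean_trace", "regularize", "Scaler", "fit_scaler",
           "apply_scaler", "invert_scaler",
           "DEFAULT_VALID_RANGE", "STRICT_VALID_RANGE"]

logger = logging.getLogger(__name__)

#: Permissive sensor range (observed clinical extremes span 40-506 mg/dL).
DEFAULT_VALID_RANGE = (40.0, 400.0)
#: Literal Dexcom G5 reporting range ("does not record over 400 or below 60").
STRICT_VALID_RANGE = (60.0, 400.0)


def clean_trace(trace: GlucoseTrace,
                valid_range: tuple[float, float] = DEFAULT_VALID_RANGE
                ) -> tuple[GlucoseTrace, int]:
    """Drop readings outside ``valid_range``; they become missing slots.

    The time grid is unchanged.  Returns ``(cleaned trace, n_removed)``.
    An empty result is allowed and logged.
    """
    low, high = valid_range
    if low >= high:
        raise ValidationError("valid_range must satisfy low < high")
    keep = (trace.values >= low) & (trace.values <= high)
    n_removed = int((~keep).sum())
    cleaned = GlucoseTrace(
        patient_id=trace.patient_id,
        start_time=trace.start_time,
        interval=trace.interval,
        indices=trace.indices[keep],
        values=trace.values[keep],
    )
    if len(cleaned) == 0:
        logger.warning("clean_trace: patient %s has no readings left in [%g, %g]",
                       trace.patient_id, low, high)
    return cleaned, n_removed


def regularize(data: GlucoseTrace | pd.DataFrame, interval: int,
               *, patient_id: str | None = None,
               start_time: pd.Timestamp | str | None = None) -> GlucoseTrace:
    """Snap timestamped readings onto a regular ``interval``-minute grid.

    Accepts a :class:`GlucoseTrace` (re-gridding to a new interval) or a
    DataFrame with ``timestamp`` and ``glucose_mg_dl`` columns.  Each
    observation moves to its nearest grid slot (within ``interval/2`` by
    construction); slots with no observation stay missing; when two
    observations map to one slot the nearer-in-time one wins.
    """
    if interval <= 0:
        raise ValidationError("interval must be positive minutes")
    if isinstance(data, GlucoseTrace):
        times = data.times
        values = np.asarray(data.values, dtype=np.float64)
        patient_id = patient_id or data.patient_id
        start_time = start_time if start_time is not None else data.start_time
    else:
        times = pd.DatetimeIndex(pd.to_datetime(data["timestamp"]))
        values = data["glucose_mg_dl"].to_numpy(dtype=np.float64)
        patient_id = patient_id or (
            str(data["patient_id"].iloc[0]) if "patient_id" in data and len(data) else "unknown")
    if len(times) == 0:
        return GlucoseTrace(patient_id=patient_id or "unknown",
                            start_time=start_time or pd.Timestamp("1970-01-01"),
                            interval=interval)
    if np.any(np.diff(times.asi8) < 0):
        raise DataError("timestamps must be non-decreasing")

    if start_time is None:
        start_time = times[0].floor(f"{interval}min")
    start_time = pd.Timestamp(start_time)

    offset_min = (times.asi8 - start_time.value) / 60e9
    slots = np.rint(offset_min / interval).astype(np.int64)
    dist = np.abs(offset_min - slots * interval)

    # Collision resolution: keep the observation nearest its slot center.
    order = np.lexsort((dist, slots))
    slots_sorted, dist_sorted = slots[order], values[order]
    keep_first = np.ones(len(slots_sorted), dtype=bool)
    keep_first[1:] = slots_sorted[1:] != slots_sorted[:-1]
    sel = order[keep_first]
    sel.sort()

    return GlucoseTrace(patient_id=patient_id, start_time=start_time,
                        interval=interval, indices=slots[sel], values=values[sel])


# ---------------------------------------------------------------------------
# Scaling

@dataclass(frozen=True)
class Scaler:
    """Invertible per-patient value scaler fitted on the training period.

    ``zscore`` uses the population (1/n) standard deviation; ``minmax`` maps
    the fitting range onto [0, 1]; ``none`` is the identity.
    """

    method: str = "zscore"
    center: float = 0.0
    scale: float = 1.0

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=np.float64) - self.center) / self.scale

    def invert(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=np.float64) * self.scale + self.center


def fit_scaler(values: np.ndarray, method: str = "zscore") -> Scaler:
    """Fit a :class:`Scaler` on (training-period) values."""
    if method == "none":
        return Scaler("none", 0.0, 1.0)
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValidationError(f"{method} scaling needs at least 2 values")
    if method == "zscore":
        sd = float(np.std(v))  # population convention
        if sd == 0.0:
            raise ValidationError("zscore scaling needs nonzero spread")
        return Scaler("zscore", float(np.mean(v)), sd)
    if method == "minmax":
        lo, hi = float(np.min(v)), float(np.max(v))
        if hi == lo:
            raise ValidationError("minmax scaling needs nonzero spread")
        return Scaler("minmax", lo, hi - lo)
    raise ValidationError(f"unknown scaling method {method!r}")


def apply_scaler(scaler: Scaler, values: np.ndarray) -> np.ndarray:
    return scaler.apply(values)


def invert_scaler(scaler: Scaler, values: np.ndarray) -> np.ndarray:
    return scaler.invert(values)
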