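"""Timestamped CGM glucose trace on a fixed sampling grid.

A :class:`GlucoseTrace` holds one patient's continuous-glucose-monitor
readings in mg/dL on a nominal sampling grid (default 5 minutes).  Missing
readings — e.g. from Bluetooth signal loss — are represented by *absent*
grid indices, never by sentinel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GlucoseTrace"]


@dataclass(frozen=True)
class GlucoseTrace:
    """One patient's glucose series on a regular time grid.

    Parameters
    ----------
    patient_id :
        Identifier of the patient the trace belongs to.
    start_time :
        Wall-clock time of grid index 0 (ISO-8601, naive local time).
    interval :
        Minutes between consecutive grid slots.
    indices :
        Strictly increasing integer grid indices of the *present* readings.
    values :
        Glucose readings in mg/dL, aligned with ``indices``; all > 0.
    """

    patient_id: str
    start_time: pd.Timestamp
    interval: int = 5
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    values: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        val = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "values", val)
        object.__setattr__(self, "start_time", pd.Timestamp(self.start_time))
        if self.interval <= 0:
            raise ValueError("interval must be positive minutes")
        if idx.shape != val.shape or idx.ndim != 1:
            raise ValueError("indices and values must be 1-D and aligned")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("grid indices must be strictly increasing")
        if val.size and np.any(~np.isfinite(val)):
            raise ValueError("glucose values must be finite")
        if val.size and np.any(val <= 0):
            raise ValueError("glucose values must be positive mg/dL")

    # -- basic properties -------------------------------------------------

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def n_present(self) -> int:
        """Number of present (non-missing) readings."""
        return int(self.indices.size)

    @property
    def duration_days(self) -> float:
        """Span from first to last present reading, in days."""
        if self.indices.size == 0:
            return 0.0
        span = int(self.indices[-1] - self.indices[0])
        return span * self.interval / 1440.0

    @property
    def times(self) -> pd.DatetimeIndex:
        """Wall-clock timestamps of the present readings."""
        offsets = pd.to_timedelta(self.indices * self.interval, unit="m")
        return pd.DatetimeIndex(self.start_time + offsets)

    # -- views -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Present readings as a DataFrame (patient_id, timestamp, glucose_mg_dl)."""
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "timestamp": self.times,
                "glucose_mg_dl": self.values,
            }
        )

    def present_mask(self) -> tuple[int, np.ndarray]:
        """Dense presence mask over ``[first_index, last_index]``.

        Returns ``(first_index, mask)`` where ``mask[k]`` is True when grid
        slot ``first_index + k`` holds a reading.  Empty trace gives
        ``(0, empty mask)``.
        """
        if self.indices.size == 0:
            return 0, np.zeros(0, dtype=bool)
        first = int(self.indices[0])
        mask = np.zeros(int(self.indices[-1]) - first + 1, dtype=bool)
        mask[self.indices - first] = True
        return first, mask

    def dense_values(self) -> tuple[int, np.ndarray]:
        """Dense value array over the span, ``nan`` at missing slots."""
        first, mask = self.present_mask()
        dense = np.full(mask.size, np.nan)
        dense[self.indices - first] = self.values
        return first, dense

    def slice_indices(self, lo: int, hi: int) -> "GlucoseTrace":
        """Sub-trace with grid indices in the closed range ``[lo, hi]``."""
        keep = (self.indices >= lo) & (self.indices <= hi)
        return GlucoseTrace(
            patient_id=self.patient_id,
            start_time=self.start_time,
            interval=self.interval,
            indices=self.indices[keep],
            values=self.values[keep],
        )
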