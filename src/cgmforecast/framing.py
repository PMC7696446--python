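"""Sliding-window framing of a trace into supervised (window, target) samples.

A sample pairs ``lookback`` consecutive readings with the single reading
``delay`` steps after the window's last element: with the defaults
(lookback 7, delay 6, 5-minute steps) the model sees 35 minutes of history
and predicts the glucose value 30 minutes ahead.  Windows are slid with a
configurable ``step`` (default 1).  Any window or target touching a missing
grid slot is skipped entirely — missing readings are never interpolated.

For a gap-free trace of N points with step 1 the sample count is exactly
``N - lookback - delay + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .trace import GlucoseTrace

__all__ = ["FramingSpec", "SampleSet", "frame", "chronological_split"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FramingSpec:
    """Window geometry: lookback, delay (horizon), stride, and step length."""

    lookback: int = 7
    delay: int = 6
    step: int = 1
    interval: int = 5

    def __post_init__(self) -> None:
        if self.lookback < 1 or self.delay < 1 or self.step < 1:
            raise ValidationError("lookback, delay and step must be >= 1")
        if self.interval <= 0:
            raise ValidationError("interval must be positive minutes")

    @property
    def horizon_minutes(self) -> int:
        """Prediction horizon: delay steps x minutes per step."""
        return self.delay * self.interval

    @property
    def history_minutes(self) -> int:
        """Input history length: lookback steps x minutes per step."""
        return self.lookback * self.interval


@dataclass(frozen=True)
class SampleSet:
    """Framed supervised samples from one patient's trace.

    ``inputs`` is (n, lookback); ``targets`` (n,); ``target_indices`` the
    absolute grid index of each target, strictly increasing.
    """

    patient_id: str
    spec: FramingSpec
    inputs: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    targets: np.ndarray = field(default_factory=lambda: np.empty(0))
    target_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        if len(self.targets) != len(self.inputs) or len(self.targets) != len(self.target_indices):
            raise ValidationError("inputs, targets and target_indices must align")
        if self.target_indices.size and np.any(np.diff(self.target_indices) <= 0):
            raise ValidationError("target_indices must be strictly increasing")

    def __len__(self) -> int:
        return int(len(self.targets))

    @property
    def n_samples(self) -> int:
        return len(self)

    def to_frame(self) -> pd.DataFrame:
        """Audit table: one row per sample, lookback inputs + target + index."""
        cols = {f"x{j}": self.inputs[:, j] for j in range(self.inputs.shape[1])}
        cols["target"] = self.targets
        cols["target_index"] = self.target_indices
        df = pd.DataFrame(cols)
        df.insert(0, "patient_id", self.patient_id)
        return df

    def scaled(self, scaler) -> "SampleSet":
        """Same samples with inputs and targets passed through ``scaler``."""
        return SampleSet(self.patient_id, self.spec,
                         scaler.apply(self.inputs), scaler.apply(self.targets),
                         self.target_indices)


def frame(trace: GlucoseTrace, spec: FramingSpec) -> SampleSet:
    """Frame a (regularized) trace into supervised samples.

    A window start ``s`` is admissible when the ``lookback`` slots
    ``s .. s+lookback-1`` and the target slot ``s+lookback-1+delay`` are all
    present; starts advance by ``spec.step``.  Too-short traces give an
    empty SampleSet with a warning.
    """
    L, D = spec.lookback, spec.delay
    first, mask = trace.present_mask()
    span = mask.size
    max_start = span - (L + D)  # relative start offsets 0 .. max_start
    if max_start < 0:
        logger.warning("frame: patient %s trace too short (%d < %d points)",
                       trace.patient_id, span, L + D)
        return SampleSet(trace.patient_id, spec,
                         np.empty((0, L)), np.empty(0), np.empty(0, dtype=np.int64))
    _, dense = trace.dense_values()

    starts = np.arange(0, max_start + 1, spec.step)
    # window slots all present: prefix sums of the mask
    csum = np.concatenate(([0], np.cumsum(mask)))
    window_ok = (csum[starts + L] - csum[starts]) == L
    target_ok = mask[starts + L - 1 + D]
    ok = starts[window_ok & target_ok]

    inputs = dense[ok[:, None] + np.arange(L)[None, :]]
    target_pos = ok + L - 1 + D
    targets = dense[target_pos]
    return SampleSet(trace.patient_id, spec, inputs, targets,
                     (target_pos + first).astype(np.int64))


def chronological_split(trace: GlucoseTrace, train_fraction: float,
                        spec: FramingSpec) -> tuple[SampleSet, SampleSet]:
    """Cut the trace in time, then frame each segment independently.

    The cut falls at the grid index nearest ``train_fraction`` of the
    trace's span; no window or target crosses the cut, so every training
    target precedes every test target and nothing from the test period can
    leak into training windows.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must lie strictly between 0 and 1")
    if len(trace) == 0:
        raise DataError("cannot split an empty trace")
    first, last = int(trace.indices[0]), int(trace.indices[-1])
    cut = first + int(round(train_fraction * (last - first)))
    train_trace = trace.slice_indices(first, cut)
    test_trace = trace.slice_indices(cut + 1, last)

    train = frame(train_trace, spec)
    test = frame(test_trace, spec)
    if len(train) == 0:
        raise DataError(
            f"training segment of patient {trace.patient_id} yields no samples "
            f"(fraction {train_fraction})")
    if len(test) == 0:
        raise DataError(
            f"test segment of patient {trace.patient_id} yields no samples "
            f"(fraction {train_fraction})")
    return train, test
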