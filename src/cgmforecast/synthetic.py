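"""Synthetic CGM trace generator for Type-2 inpatient cohorts.

Real inpatient CGM data are not publicly depositable, so every downstream
stage of the pipeline is exercised on simulated traces with the statistical
structure the analysis assumes: a patient-specific basal level, a circadian
oscillation, meal-driven excursions with fast rise and slow decay,
autocorrelated physiological variability, white sensor noise, a bounded
sensor reporting range, and runs of missing readings from signal loss.

The generative model for the scheduled reading at time :math:`t` (minutes) is

.. math::

    g(t) = b + A \\sin\\!\\big(2\\pi (t_h - \\phi)/24\\big)
           + \\sum_m M_m\\, \\hat r(t - t_m) + x(t) + \\epsilon(t)

where :math:`t_h` is the clock hour, :math:`\\hat r` is a double-exponential
meal response normalized to unit peak, :math:`x` is a stationary AR(1)
process, and :math:`\\epsilon` is white sensor noise.  The sum is clipped to
the sensor range, then dropout runs are deleted.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trace import GlucoseTrace

__all__ = [
    "PatientParams",
    "DEFAULT_COHORT_DISTRIBUTIONS",
    "meal_response",
    "simulate_trace",
    "draw_patient_params",
    "simulate_cohort",
    "summarize_trace",
]

#: Clock hour at which the circadian sinusoid peaks (late afternoon).
CIRCADIAN_PEAK_HOUR = 16.0

#: Default wall-clock start of a simulated admission.
DEFAULT_START_TIME = pd.Timestamp("2019-07-01 00:00:00")


@dataclass(frozen=True)
class PatientParams:
    """Patient-level parameters of the synthetic CGM generator.

    All glucose-scaled quantities are in mg/dL, time constants in minutes.
    ``dropout_rate`` is the expected number of missing runs per day;
    ``dropout_mean_len`` the mean run length in grid steps.  The pair
    ``(params, days)`` fully determines the generated trace: identical
    parameters (including ``seed``) give a bit-identical trace.
    """

    patient_id: str = "S001"
    basal_level: float = 170.0
    circadian_amplitude: float = 15.0
    meal_times: tuple[float, ...] = (8.0, 12.0, 18.0)
    meal_magnitude_mean: float = 80.0
    meal_rise_tau: float = 20.0
    meal_decay_tau: float = 90.0
    ar_coefficient: float = 0.9
    process_noise_sd: float = 15.0
    sensor_noise_sd: float = 3.0
    dropout_rate: float = 1.0
    dropout_mean_len: float = 5.0
    sensor_floor: float = 40.0
    sensor_ceiling: float = 400.0
    seed: int = 0
    # Dispersion of individual meals around their per-patient means.
    meal_magnitude_cv: float = 0.2
    meal_time_jitter_min: float = 30.0

    def __post_init__(self) -> None:
        if self.basal_level <= 0:
            raise ValidationError("basal_level must be positive")
        if self.meal_rise_tau <= 0 or self.meal_decay_tau <= 0:
            raise ValidationError("meal time constants must be positive")
        if self.meal_decay_tau <= self.meal_rise_tau:
            raise ValidationError("meal_decay_tau must exceed meal_rise_tau")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValidationError("ar_coefficient must lie in [0, 1)")
        if self.sensor_floor >= self.sensor_ceiling:
            raise ValidationError("sensor_floor must be below sensor_ceiling")
        if min(self.circadian_amplitude, self.meal_magnitude_mean,
               self.process_noise_sd, self.sensor_noise_sd,
               self.dropout_rate, self.meal_magnitude_cv,
               self.meal_time_jitter_min) < 0:
            raise ValidationError("amplitudes, noise SDs and rates must be >= 0")
        if self.dropout_mean_len < 1:
            raise ValidationError("dropout_mean_len must be >= 1 step")
        object.__setattr__(self, "meal_times", tuple(float(h) for h in self.meal_times))
        for h in self.meal_times:
            if not 0.0 <= h < 24.0:
                raise ValidationError("meal_times are clock hours in [0, 24)")

    def replace(self, **kwargs) -> "PatientParams":
        return dataclasses.replace(self, **kwargs)


def meal_response(minutes_since_meal: np.ndarray, rise_tau: float,
                  decay_tau: float) -> np.ndarray:
    """Unit-peak double-exponential meal excursion.

    ``exp(-t/decay) - exp(-t/rise)`` scaled so its maximum is exactly 1;
    zero before the meal.  The peak time has the closed form
    ``t* = rise*decay/(decay-rise) * ln(decay/rise)``.
    """
    if decay_tau <= rise_tau or rise_tau <= 0:
        raise ValidationError("need 0 < rise_tau < decay_tau")
    t = np.asarray(minutes_since_meal, dtype=np.float64)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    norm = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    out = np.where(t >= 0.0, np.exp(-t / decay_tau) - np.exp(-t / rise_tau), 0.0)
    return out / norm


def simulate_trace(params: PatientParams, days: float, *, interval: int = 5,
                   start_time: pd.Timestamp | str = DEFAULT_START_TIME) -> GlucoseTrace:
    """Simulate one patient's CGM trace.

    Generates ``round(days * 1440 / interval)`` scheduled readings, clips
    them to the sensor range and removes dropout runs.  Deterministic under
    ``params.seed``.
    """
    if days <= 0:
        raise ValidationError("days must be positive")
    if interval <= 0:
        raise ValidationError("interval must be positive minutes")

    n = int(round(days * 1440.0 / interval))
    t_min = np.arange(n, dtype=np.float64) * interval
    rng = np.random.default_rng(params.seed)

    t_hours = t_min / 60.0
    glucose = params.basal_level + params.circadian_amplitude * np.sin(
        2.0 * np.pi * (t_hours - (CIRCADIAN_PEAK_HOUR - 6.0)) / 24.0
    )

    # Meal excursions: every scheduled meal on every (possibly partial) day,
    # with jittered onset and per-meal magnitude dispersion.
    n_days = int(math.ceil(days))
    for day in range(n_days):
        for clock_hour in params.meal_times:
            onset = (day * 24.0 + clock_hour) * 60.0
            if params.meal_time_jitter_min > 0:
                onset += rng.uniform(-params.meal_time_jitter_min,
                                     params.meal_time_jitter_min)
            if params.meal_magnitude_cv > 0:
                mag = rng.normal(params.meal_magnitude_mean,
                                 params.meal_magnitude_cv * params.meal_magnitude_mean)
                mag = max(mag, 0.0)
            else:
                mag = params.meal_magnitude_mean
            if mag > 0:
                glucose += mag * meal_response(t_min - onset, params.meal_rise_tau,
                                               params.meal_decay_tau)

    # AR(1) physiological variability, parameterized by its stationary SD.
    if params.process_noise_sd > 0:
        phi = params.ar_coefficient
        innov_sd = params.process_noise_sd * math.sqrt(1.0 - phi * phi)
        innov = rng.normal(0.0, innov_sd, size=n)
        x = np.empty(n)
        x[0] = rng.normal(0.0, params.process_noise_sd)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + innov[i]
        glucose += x

    if params.sensor_noise_sd > 0:
        glucose += rng.normal(0.0, params.sensor_noise_sd, size=n)

    glucose = np.clip(glucose, params.sensor_floor, params.sensor_ceiling)

    # Dropout: Poisson number of runs, geometric run lengths, absent indices.
    present = np.ones(n, dtype=bool)
    if params.dropout_rate > 0:
        n_runs = rng.poisson(params.dropout_rate * days)
        for _ in range(n_runs):
            start = int(rng.integers(0, n))
            length = int(rng.geometric(1.0 / params.dropout_mean_len))
            present[start:start + length] = False

    indices = np.nonzero(present)[0].astype(np.int64)
    return GlucoseTrace(
        patient_id=params.patient_id,
        start_time=pd.Timestamp(start_time),
        interval=interval,
        indices=indices,
        values=glucose[present],
    )


# ---------------------------------------------------------------------------
# Cohort sampling

#: Default sampling distributions for a 20-patient Type-2 inpatient cohort.
#: Each entry is ("constant", v), ("uniform", lo, hi) or
#: ("normal", mu, sd[, lo, hi]) (normal is clipped to [lo, hi] when given).
#: The special key "days" draws the per-patient wear time.
DEFAULT_COHORT_DISTRIBUTIONS: dict[str, tuple] = {
    "basal_level": ("normal", 170.0, 30.0, 100.0, 260.0),
    "circadian_amplitude": ("uniform", 8.0, 25.0),
    "meal_magnitude_mean": ("uniform", 50.0, 110.0),
    "meal_rise_tau": ("uniform", 15.0, 30.0),
    "meal_decay_tau": ("uniform", 70.0, 120.0),
    "ar_coefficient": ("uniform", 0.85, 0.97),
    "process_noise_sd": ("uniform", 8.0, 30.0),
    "sensor_noise_sd": ("uniform", 2.0, 6.0),
    "dropout_rate": ("uniform", 0.5, 2.0),
    "dropout_mean_len": ("uniform", 3.0, 8.0),
    "sensor_floor": ("constant", 40.0),
    "sensor_ceiling": ("constant", 400.0),
    "days": ("uniform", 2.6, 7.4),
}

_PARAM_FIELDS = {f.name for f in dataclasses.fields(PatientParams)}
_DRAWABLE_KEYS = (_PARAM_FIELDS - {"patient_id", "seed"}) | {"days"}


def _draw(dist: tuple, rng: np.random.Generator):
    kind = dist[0]
    if kind == "constant":
        return dist[1]
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "normal":
        v = float(rng.normal(dist[1], dist[2]))
        if len(dist) >= 5:
            v = float(np.clip(v, dist[3], dist[4]))
        return v
    raise ValidationError(f"unknown distribution kind {kind!r}")


def draw_patient_params(
    patient_id: str,
    rng: np.random.Generator,
    distributions: Mapping[str, tuple] | None = None,
) -> tuple[PatientParams, float]:
    """Draw one patient's generator parameters and wear time (days)."""
    dists = dict(DEFAULT_COHORT_DISTRIBUTIONS)
    if distributions:
        for key in distributions:
            if key not in _DRAWABLE_KEYS:
                raise ValidationError(f"unknown PatientParams field {key!r}")
        dists.update(distributions)
    drawn = {k: _draw(v, rng) for k, v in dists.items()}
    days = float(drawn.pop("days"))
    seed = int(rng.integers(0, 2**31 - 1))
    return PatientParams(patient_id=patient_id, seed=seed, **drawn), days


def simulate_cohort(
    n_patients: int,
    param_distributions: Mapping[str, tuple] | None = None,
    seed: int = 0,
    *,
    interval: int = 5,
    return_params: bool = False,
) -> list[GlucoseTrace] | tuple[list[GlucoseTrace], list[PatientParams]]:
    """Simulate a cohort of independently parameterized patients.

    Patient ids are ``S001 ... Snnn``.  The cohort is reproducible from
    ``seed``; with the default distributions the per-patient wear times lie
    in [2.6, 7.4] days and the pooled cohort mean glucose is close to the
    190-195 mg/dL range typical of poorly controlled Type-2 inpatients.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    traces: list[GlucoseTrace] = []
    all_params: list[PatientParams] = []
    for i in range(n_patients):
        pid = f"S{i + 1:03d}"
        params, days = draw_patient_params(pid, rng, param_distributions)
        traces.append(simulate_trace(params, days, interval=interval))
        all_params.append(params)
    if return_params:
        return traces, all_params
    return traces


def summarize_trace(trace: GlucoseTrace) -> dict:
    """Per-patient summary over present readings.

    Returns ``{"patient_id", "days", "max", "min", "mean"}`` with days
    rounded to one decimal, mirroring a cohort description table.
    """
    if len(trace) == 0:
        raise ValidationError("cannot summarize an empty trace")
    return {
        "patient_id": trace.patient_id,
        "days": round(trace.duration_days, 1),
        "max": float(np.max(trace.values)),
        "min": float(np.min(trace.values)),
        "mean": float(np.mean(trace.values)),
    }
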