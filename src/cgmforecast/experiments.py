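"""Cohort-level experiment families and the per-patient training pipeline.

Each experiment trains one *personalized* model per patient (never pooling
patients) under a set of conditions and reports per-patient RMSE/MAPE plus
the unweighted cohort mean per condition:

* algorithm comparison — simple RNN vs GRU vs LSTM baselines,
* architecture comparison — one GRU layer vs bidirectional vs two layers,
* split comparison — chronological train fractions 0.7 down to 0.3,
* improvement grid — batch size 50, shuffling, Adamax, 10/30 epochs.

Per-(patient, condition) seeds are derived deterministically from the
experiment seed so any run can be reproduced bit-identically from its
config snapshot.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .evaluation import EvalReport, evaluate
from .framing import FramingSpec, SampleSet, chronological_split
from .models import ModelSpec, Predictor, TrainConfig, build_model, predict, train
from .preprocessing import DEFAULT_VALID_RANGE, Scaler, clean_trace, fit_scaler
from .synthetic import summarize_trace
from .trace import GlucoseTrace

__all__ = ["PatientRun", "run_patient", "ExperimentResult",
           "run_algorithm_comparison", "run_architecture_comparison",
           "run_split_comparison", "run_improvement_grid", "summarize_cohort"]

logger = logging.getLogger(__name__)


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic child seed (< 2**31) for one patient/condition cell."""
    state = np.random.SeedSequence([int(base_seed), *map(int, indices)])
    return int(state.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PatientRun:
    """Everything produced by one personalized training run."""

    report: EvalReport
    scaler: Scaler
    train_samples: SampleSet   # in mg/dL
    test_samples: SampleSet    # in mg/dL
    predictor: Predictor
    predictions: np.ndarray    # mg/dL, aligned with test_samples.targets
    n_removed: int


def run_patient(trace: GlucoseTrace,
                framing_spec: FramingSpec | None = None,
                model_spec: ModelSpec | None = None,
                train_config: TrainConfig | None = None,
                *,
                train_fraction: float = 0.7,
                valid_range: tuple[float, float] = DEFAULT_VALID_RANGE,
                scaling: str = "zscore") -> PatientRun:
    """Clean, split, scale, train and evaluate one patient's forecaster.

    The scaler is fitted exclusively on training-period values (the framed
    training inputs and targets), so no statistic of the test period can
    reach the model.  Metrics are computed after inversion, in mg/dL.
    """
    framing_spec = framing_spec or FramingSpec()
    model_spec = model_spec or ModelSpec()
    train_config = train_config or TrainConfig()

    cleaned, n_removed = clean_trace(trace, valid_range)
    train_s, test_s = chronological_split(cleaned, train_fraction, framing_spec)

    fit_values = np.concatenate([train_s.inputs.ravel(), train_s.targets])
    scaler = fit_scaler(fit_values, scaling)

    predictor = build_model(model_spec, framing_spec.lookback, seed=train_config.seed)
    train(predictor, train_s.scaled(scaler), train_config)

    preds = predict(predictor, test_s.scaled(scaler), scaler)
    report = evaluate(test_s.targets, preds, patient_id=trace.patient_id)
    return PatientRun(report, scaler, train_s, test_s, predictor, preds, n_removed)


# ---------------------------------------------------------------------------
# experiment results

@dataclass
class ExperimentResult:
    """Per-patient records plus condition-level summary for one experiment."""

    name: str
    records: pd.DataFrame
    config: dict
    seeds: dict[str, int] = field(default_factory=dict)

    @property
    def summary(self) -> pd.DataFrame:
        """Unweighted cohort mean of the per-patient metrics per condition."""
        agg = (self.records.groupby("condition", sort=False)
               .agg(mean_rmse=("rmse", "mean"), mean_mape=("mape", "mean"),
                    n_patients=("patient_id", "nunique")))
        return agg.reset_index()

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.records["condition"]))

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "config": self.config,
            "seeds": dict(self.seeds),
            "records": self.records.to_dict(orient="records"),
            "summary": self.summary.to_dict(orient="records"),
        }


def _run_conditions(name: str,
                    cohort: list[GlucoseTrace],
                    conditions: list[tuple[str, ModelSpec, TrainConfig, float]],
                    framing_spec: FramingSpec,
                    seed: int,
                    config_extra: dict | None = None) -> ExperimentResult:
    rows = []
    seeds: dict[str, int] = {}
    for ci, (label, mspec, tconfig, fraction) in enumerate(conditions):
        for pi, trace in enumerate(cohort):
            cell_seed = derive_seed(seed, ci, pi)
            seeds[f"{label}/{trace.patient_id}"] = cell_seed
            try:
                run = run_patient(trace, framing_spec, mspec,
                                  replace(tconfig, seed=cell_seed),
                                  train_fraction=fraction)
            except (DataError, ValidationError) as exc:
                logger.warning("%s: skipping patient %s under %s: %s",
                               name, trace.patient_id, label, exc)
                continue
            rows.append({
                "patient_id": trace.patient_id,
                "condition": label,
                "rmse": run.report.rmse,
                "mape": run.report.mape,
                "n_train": len(run.train_samples),
                "n_test": len(run.test_samples),
            })
    records = pd.DataFrame(rows, columns=["patient_id", "condition", "rmse",
                                          "mape", "n_train", "n_test"])
    config = {
        "experiment": name,
        "seed": int(seed),
        "framing": asdict(framing_spec),
        "conditions": [
            {"label": label, "model": asdict(mspec), "training": asdict(tconfig),
             "train_fraction": fraction}
            for label, mspec, tconfig, fraction in conditions
        ],
        "patients": [t.patient_id for t in cohort],
    }
    if config_extra:
        config.update(config_extra)
    return ExperimentResult(name=name, records=records, config=config, seeds=seeds)


def run_algorithm_comparison(cohort: list[GlucoseTrace],
                             framing_spec: FramingSpec | None = None,
                             train_config: TrainConfig | None = None,
                             seed: int = 0) -> ExperimentResult:
    """Baseline simple RNN vs GRU vs LSTM at a 7:3 chronological split."""
    framing_spec = framing_spec or FramingSpec()
    tconfig = train_config or TrainConfig()
    conditions = [(cell, ModelSpec(cell=cell), tconfig, 0.7)
                  for cell in ("simple_rnn", "gru", "lstm")]
    return _run_conditions("algorithm_comparison", cohort, conditions,
                           framing_spec, seed)


def run_architecture_comparison(cohort: list[GlucoseTrace],
                                framing_spec: FramingSpec | None = None,
                                train_config: TrainConfig | None = None,
                                seed: int = 0) -> ExperimentResult:
    """GRU capacity variants: one layer, bidirectional, two stacked layers."""
    framing_spec = framing_spec or FramingSpec()
    tconfig = train_config or TrainConfig()
    conditions = [
        ("one_layer", ModelSpec(), tconfig, 0.7),
        ("bidirectional", ModelSpec(bidirectional=True), tconfig, 0.7),
        ("two_layers", ModelSpec(recurrent_layers=2), tconfig, 0.7),
    ]
    return _run_conditions("architecture_comparison", cohort, conditions,
                           framing_spec, seed)


def run_split_comparison(cohort: list[GlucoseTrace],
                         ratios: tuple[float, ...] = (0.7, 0.6, 0.5, 0.4, 0.3),
                         framing_spec: FramingSpec | None = None,
                         train_config: TrainConfig | None = None,
                         seed: int = 0) -> ExperimentResult:
    """GRU baseline across chronological train:test ratios."""
    framing_spec = framing_spec or FramingSpec()
    tconfig = train_config or TrainConfig()
    conditions = [(f"{int(round(r * 10))}:{int(round((1 - r) * 10))}",
                   ModelSpec(), tconfig, r) for r in ratios]
    return _run_conditions("split_comparison", cohort, conditions, framing_spec,
                           seed, config_extra={"ratios": list(ratios)})


def run_improvement_grid(cohort: list[GlucoseTrace],
                         framing_spec: FramingSpec | None = None,
                         base_config: TrainConfig | None = None,
                         seed: int = 0) -> ExperimentResult:
    """Hyper-parameter variations around the GRU baseline.

    Batch 50; batch 50 + shuffling; + Adamax; + RMSprop at 10 and 30 epochs.
    """
    framing_spec = framing_spec or FramingSpec()
    base = base_config or TrainConfig()
    conditions = [
        ("batch50", ModelSpec(),
         replace(base, batch_size=50, shuffle=False), 0.7),
        ("batch50_shuffle", ModelSpec(),
         replace(base, batch_size=50, shuffle=True), 0.7),
        ("batch50_shuffle_adamax", ModelSpec(),
         replace(base, batch_size=50, shuffle=True, optimizer="adamax"), 0.7),
        ("batch50_shuffle_rmsprop_10ep", ModelSpec(),
         replace(base, batch_size=50, shuffle=True, optimizer="rmsprop", epochs=10), 0.7),
        ("batch50_shuffle_rmsprop_30ep", ModelSpec(),
         replace(base, batch_size=50, shuffle=True, optimizer="rmsprop", epochs=30), 0.7),
    ]
    return _run_conditions("improvement_grid", cohort, conditions, framing_spec, seed)


EXPERIMENTS = {
    "algorithm": run_algorithm_comparison,
    "architecture": run_architecture_comparison,
    "split": run_split_comparison,
    "improvement": run_improvement_grid,
}


def summarize_cohort(cohort: list[GlucoseTrace]) -> pd.DataFrame:
    """Per-patient wear time and glucose distribution, plus a Total row.

    The Total row sums the days, takes global extrema, and pools the mean
    over all present readings.
    """
    if not cohort:
        raise ValidationError("cohort is empty")
    rows = [summarize_trace(t) for t in cohort]
    total_n = sum(len(t) for t in cohort)
    pooled_mean = sum(float(np.sum(t.values)) for t in cohort) / total_n
    rows.append({
        "patient_id": "Total",
        "days": round(sum(r["days"] for r in rows), 1),
        "max": max(r["max"] for r in rows),
        "min": min(r["min"] for r in rows),
        "mean": pooled_mean,
    })
    return pd.DataFrame(rows, columns=["patient_id", "days", "max", "min", "mean"])
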