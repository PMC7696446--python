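"""Experiment orchestration: condition sets, aggregation, reproducibility."""

import numpy as np
import pytest

from cgmforecast import (FramingSpec, GlucoseTrace, ModelSpec, TrainConfig, build_model,
                         run_algorithm_comparison, run_architecture_comparison,
                         run_improvement_grid, run_patient, run_split_comparison,
                         simulate_cohort, simulate_trace, summarize_cohort,
                         summarize_trace)
from cgmforecast.synthetic import PatientParams

QUICK = TrainConfig(epochs=2)


@pytest.fixture(scope="module")
def small_cohort():
    dists = {"days": ("uniform", 2.0, 2.5), "dropout_rate": ("uniform", 0.2, 0.6)}
    return simulate_cohort(2, dists, seed=13)


class TestAlgorithmComparison:
    def test_condition_set_and_aggregation(self, small_cohort):
        result = run_algorithm_comparison(small_cohort, train_config=QUICK, seed=1)
        assert result.conditions == ["simple_rnn", "gru", "lstm"]
        # every (patient, condition) pair exactly once
        assert not result.records.duplicated(["patient_id", "condition"]).any()
        assert len(result.records) == 6
        assert np.isfinite(result.records["rmse"]).all()
        # summary mean equals hand re-aggregation of per-patient values
        for cond in result.conditions:
            rows = result.records[result.records["condition"] == cond]
            hand = sum(rows["rmse"]) / len(rows)
            got = result.summary.set_index("condition").loc[cond, "mean_rmse"]
            assert got == pytest.approx(hand)

    def test_constant_glucose_patient_is_trivially_predictable(self, flat_params):
        trace = simulate_trace(flat_params, 2)
        for cell in ("simple_rnn", "gru", "lstm"):
            run = run_patient(trace, model_spec=ModelSpec(cell=cell), scaling="none")
            assert run.report.rmse < 1.0

    def test_insufficient_patient_skipped_with_log(self, small_cohort, caplog):
        stub = simulate_trace(PatientParams(patient_id="TINY", dropout_rate=0.0), 0.1)
        result = run_algorithm_comparison([small_cohort[0], stub],
                                          train_config=QUICK, seed=1)
        assert set(result.records["patient_id"]) == {small_cohort[0].patient_id}
        assert any("TINY" in r.message for r in caplog.records)


class TestArchitectureComparison:
    def test_conditions_and_capacity_ordering(self, small_cohort):
        result = run_architecture_comparison(small_cohort[:1], train_config=QUICK, seed=2)
        assert result.conditions == ["one_layer", "bidirectional", "two_layers"]
        assert np.isfinite(result.records[["rmse", "mape"]].to_numpy()).all()
        n_one = build_model(ModelSpec(), 7).n_params
        n_bi = build_model(ModelSpec(bidirectional=True), 7).n_params
        n_two = build_model(ModelSpec(recurrent_layers=2), 7).n_params
        assert n_one < n_bi and n_one < n_two


class TestSplitComparison:
    def test_five_ratios_and_monotone_train_counts(self, small_cohort):
        result = run_split_comparison(small_cohort[:1], train_config=QUICK, seed=3)
        assert result.conditions == ["7:3", "6:4", "5:5", "4:6", "3:7"]
        counts = result.records.set_index("condition")["n_train"]
        assert list(counts) == sorted(counts, reverse=True)
        assert np.isfinite(result.records["rmse"]).all()

    def test_infeasible_ratio_skips_patient(self, caplog):
        # 60 varying points: enough for a 7:3 split but not for 1:9
        trace = GlucoseTrace(patient_id="SHORT", start_time="2020-01-01",
                             interval=5, indices=np.arange(60),
                             values=150.0 + 20.0 * np.sin(np.arange(60) / 5.0))
        result = run_split_comparison([trace], ratios=(0.7, 0.1),
                                      train_config=TrainConfig(epochs=1), seed=0)
        assert set(result.records["condition"]) == {"7:3"}


class TestImprovementGrid:
    def test_condition_labels(self, small_cohort):
        result = run_improvement_grid(small_cohort[:1], base_config=QUICK, seed=4)
        assert result.conditions == [
            "batch50", "batch50_shuffle", "batch50_shuffle_adamax",
            "batch50_shuffle_rmsprop_10ep", "batch50_shuffle_rmsprop_30ep"]
        cfgs = {c["label"]: c["training"] for c in result.config["conditions"]}
        assert cfgs["batch50"]["batch_size"] == 50
        assert cfgs["batch50"]["shuffle"] is False
        assert cfgs["batch50_shuffle"]["shuffle"] is True
        assert cfgs["batch50_shuffle_adamax"]["optimizer"] == "adamax"
        assert cfgs["batch50_shuffle_rmsprop_10ep"]["epochs"] == 10
        assert cfgs["batch50_shuffle_rmsprop_30ep"]["epochs"] == 30

    def test_shuffle_only_changes_sample_order(self, small_cohort):
        # at zero epochs the shuffle flag cannot matter
        base = TrainConfig(epochs=0, batch_size=50)
        on = run_patient(small_cohort[0], train_config=base)
        off = run_patient(small_cohort[0],
                          train_config=TrainConfig(epochs=0, batch_size=50, shuffle=True))
        assert np.allclose(on.predictions, off.predictions)


class TestReproducibility:
    def test_same_seed_reproduces_records(self, small_cohort):
        a = run_algorithm_comparison(small_cohort[:1], train_config=QUICK, seed=9)
        b = run_algorithm_comparison(small_cohort[:1], train_config=QUICK, seed=9)
        assert a.records.equals(b.records)
        assert a.seeds == b.seeds

    def test_scaler_fitted_on_training_period_only(self, small_cohort):
        run = run_patient(small_cohort[0], train_config=QUICK)
        fit_values = np.concatenate([run.train_samples.inputs.ravel(),
                                     run.train_samples.targets])
        assert run.scaler.center == pytest.approx(fit_values.mean())
        assert run.scaler.scale == pytest.approx(fit_values.std())
        # nothing from the test period reaches those statistics
        assert run.train_samples.target_indices.max() < \
            run.test_samples.target_indices.min()


class TestSummarizeCohort:
    def test_totals_recomputable_from_rows(self, small_cohort):
        table = summarize_cohort(small_cohort)
        assert len(table) == len(small_cohort) + 1
        rows = table.iloc[:-1]
        total = table.iloc[-1]
        assert total["patient_id"] == "Total"
        assert total["days"] == pytest.approx(round(rows["days"].sum(), 1))
        assert total["max"] == rows["max"].max()
        assert total["min"] == rows["min"].min()
        pooled = np.concatenate([t.values for t in small_cohort])
        assert total["mean"] == pytest.approx(pooled.mean())

    def test_single_constant_patient_row(self, flat_trace):
        table = summarize_cohort([flat_trace])
        row = table.iloc[0]
        assert (row["days"], row["max"], row["min"], row["mean"]) == (1.0, 150, 150, 150)
        assert summarize_trace(flat_trace)["mean"] == 150.0
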