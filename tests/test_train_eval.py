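"""Training protocol, aggregation, significance testing, transfer driver."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bolusrec import (
    EvalReport, LSTMChainConfig, ResidualStackConfig, TrainProtocol,
    ValidationError, compare_models, early_stop_epoch, evaluate,
    finetune_subject, pretrain_global, prepare_subject, select_best_seed,
    train_model,
)
from bolusrec.train_eval import (
    SubjectData, _group_encode, _metrics, dataset_loss, fit_baselines,
    horizon_transfer_experiment, predict_examples,
)

TINY_STACK = ResidualStackConfig(
    blocks=2, block=LSTMChainConfig(state_size=6, fc_layers=1, fc_width=12,
                                    extra_features=4))


@pytest.fixture(scope="module")
def subject(sim_subject):
    rec, _ = sim_subject
    return prepare_subject(rec, "bolus_p_c", "inertial")


class TestEarlyStopping:
    def test_halts_patience_epochs_after_last_improvement(self):
        # improvement at epochs 0..4 (0-based), then plateau
        losses = [5, 4, 3, 2, 1] + [1.5] * 30
        assert early_stop_epoch(losses, patience=10) == 15

    def test_runs_to_end_when_still_improving(self):
        assert early_stop_epoch([3, 2, 1], patience=10) == 3

    def test_plateau_does_not_reset_counter(self):
        # ties are not improvements
        losses = [2.0] + [2.0] * 20
        assert early_stop_epoch(losses, patience=5) == 6


class TestMetricsAndReports:
    def test_hand_arithmetic(self):
        rmse, mae = _metrics(np.array([1.0, 5.0]), np.array([2.0, 4.0]))
        assert (rmse, mae) == (1.0, 1.0)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=40),
           st.integers(0, 10 ** 6))
    @settings(max_examples=80, deadline=None)
    def test_mae_never_exceeds_rmse(self, labels, seed):
        labels = np.array(labels)
        preds = labels + np.random.default_rng(seed).normal(size=len(labels))
        rmse, mae = _metrics(labels, preds)
        assert mae <= rmse + 1e-12

    def _fixture_frame(self):
        # 2 subjects x 2 seeds, hand-computed aggregations
        rows = []
        vals = {("a", 1): (4.0, 3.0), ("a", 2): (6.0, 5.0),
                ("b", 1): (2.0, 1.0), ("b", 2): (8.0, 7.0)}
        val_mae = {("a", 1): 2.0, ("a", 2): 1.0, ("b", 1): 0.5, ("b", 2): 0.9}
        for (sid, seed), (rmse, mae) in vals.items():
            rows.append(dict(subject_id=sid, seed=seed, split="test",
                             horizon="all", rmse=rmse, mae=mae, n=10))
            rows.append(dict(subject_id=sid, seed=seed, split="val",
                             horizon="all", rmse=val_mae[(sid, seed)] + 1,
                             mae=val_mae[(sid, seed)], n=10))
        return EvalReport(frame=pd.DataFrame(rows))

    def test_mean_score_hand_computed(self):
        rep = self._fixture_frame()
        # subject a: mean mae 4; subject b: mean mae 4 -> overall 4
        assert rep.mean_score() == {"rmse": 5.0, "mae": 4.0}

    def test_best_score_uses_validation_mae_only(self):
        rep = self._fixture_frame()
        # best val mae: a -> seed 2 (1.0), b -> seed 1 (0.5)
        # test mae of those seeds: 5.0 and 1.0 -> mean 3.0
        assert rep.best_score() == {"rmse": 4.0, "mae": 3.0}

    def test_select_best_seed_sees_only_validation(self):
        assert select_best_seed({1: 2.0, 2: 1.0, 3: 5.0}) == 2
        with pytest.raises(ValidationError):
            select_best_seed({})

    def test_report_csv_round_trip(self, tmp_path):
        rep = self._fixture_frame()
        rep.to_csv(tmp_path / "r.csv")
        back = EvalReport.from_csv(tmp_path / "r.csv")
        assert back.mean_score() == rep.mean_score()
        assert back.best_score() == rep.best_score()


class TestCompareModels:
    def test_identical_scores_p_half(self):
        assert compare_models([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.5

    def test_large_uniform_gap_tiny_p(self):
        rng = np.random.default_rng(0)
        b = 20 + rng.normal(0, 0.01, size=8)
        a = b - 10
        assert compare_models(a, b) < 1e-6

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 10)
        p = compare_models(a, b)
        assert compare_models(b, a) == pytest.approx(1 - p, abs=1e-12)

    def test_pooled_variant_exposed(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert compare_models(a, b, variant="pooled") < 0.05

    def test_too_few_scores_error(self):
        with pytest.raises(ValidationError):
            compare_models([1.0], [2.0])


class TestTrainingLoop:
    def test_max_epochs_one_runs_one_epoch(self, subject):
        from bolusrec import ResidualStack
        tg = _group_encode(subject.train[:40], subject.scaler)
        vg = _group_encode(subject.val[:20], subject.scaler)
        m = ResidualStack(TINY_STACK, seed=1)
        _, hist = train_model(m, tg, vg, TrainProtocol(max_epochs=1), seed=1)
        assert len(hist) == 1

    def test_seed_repeat_identical_params(self, subject):
        from bolusrec import ResidualStack
        tg = _group_encode(subject.train[:60], subject.scaler)
        vg = _group_encode(subject.val[:30], subject.scaler)
        runs = []
        for _ in range(2):
            m = ResidualStack(TINY_STACK, seed=3)
            m, hist = train_model(m, tg, vg, TrainProtocol(max_epochs=2), seed=3)
            runs.append(({k: p.data.copy() for k, p in m.params.items()}, hist))
        (pa, ha), (pb, hb) = runs
        assert ha == hb
        for k in pa:
            np.testing.assert_array_equal(pa[k], pb[k])

    def test_finetune_lr_zero_keeps_params(self, subject):
        from bolusrec import ResidualStack
        m = ResidualStack(TINY_STACK, seed=2)
        before = {k: p.data.copy() for k, p in m.params.items()}
        tuned, _ = finetune_subject(
            m, subject, TrainProtocol(learning_rate=0.0, max_epochs=2), seed=1)
        for k in before:
            np.testing.assert_array_equal(tuned.params[k].data, before[k])
            np.testing.assert_array_equal(m.params[k].data, before[k])

    def test_finetune_empty_split_error(self, subject):
        from bolusrec import ResidualStack
        empty = SubjectData(subject_id="e", scaler=subject.scaler, train=[],
                            val=[], test=[])
        with pytest.raises(ValidationError):
            finetune_subject(ResidualStack(TINY_STACK), empty, TrainProtocol())

    def test_pretrain_two_identical_subjects_matches_single(self, subject):
        """Pooling a subject with its own copy is the same data twice: the
        resulting validation loss should be close to single-subject training."""
        proto = TrainProtocol(max_epochs=3, batch_size=64)
        single, h1 = pretrain_global([subject], "bolus_p_c", "inertial",
                                     "nbeats", proto, seed=5, config=TINY_STACK)
        double, h2 = pretrain_global([subject, subject], "bolus_p_c", "inertial",
                                     "nbeats", proto, seed=5, config=TINY_STACK)
        assert h2[-1] == pytest.approx(h1[-1], rel=0.35)

    def test_pretrain_no_examples_error(self, subject):
        empty = SubjectData(subject_id="e", scaler=subject.scaler, train=[],
                            val=[], test=[])
        with pytest.raises(ValidationError):
            pretrain_global([empty], "bolus_p_c", "inertial", "nbeats",
                            TrainProtocol(max_epochs=1))


class TestEvaluate:
    def test_constant_predictor_equals_global_baseline_row(self, subject):
        glob, _ = fit_baselines(subject)
        rep = evaluate({0: glob}, subject)
        labels = np.array([e.label for e in subject.test])
        rmse, mae = _metrics(labels, np.full(len(labels), glob.mu))
        row = rep.frame[(rep.frame["split"] == "test") &
                        (rep.frame["horizon"] == "all")].iloc[0]
        assert row["rmse"] == pytest.approx(rmse)
        assert row["mae"] == pytest.approx(mae)

    def test_per_horizon_rows_present(self, subject):
        glob, _ = fit_baselines(subject)
        rep = evaluate({0: glob}, subject)
        horizons = set(rep.frame[rep.frame["split"] == "test"]["horizon"])
        assert "all" in horizons and len(horizons) == 14

    def test_empty_test_set_excluded(self, subject):
        empty = SubjectData(subject_id="e", scaler=subject.scaler,
                            train=subject.train, val=subject.val, test=[])
        glob, _ = fit_baselines(subject)
        rep = evaluate({0: glob}, empty)
        assert rep.frame.empty
        assert np.isnan(rep.mean_score()["mae"])


class TestHorizonTransfer:
    def test_report_shape_and_transfer(self, subject):
        proto = TrainProtocol(max_epochs=4, batch_size=64)
        frame = horizon_transfer_experiment(
            [subject], "bolus_p_c", tau_list=(30, 60, 90), protocol=proto,
            config=TINY_STACK, seed=2)
        assert list(frame.columns) == [30, 60, 90, "average"]
        assert set(frame.index) == {("all_tau", "rmse"), ("all_tau", "mae"),
                                    ("one_tau", "rmse"), ("one_tau", "mae")}
        # evaluation on a tau subset uses only that subset's examples
        n30 = sum(1 for e in subject.test if e.tau == 30)
        assert n30 > 0
        # cross-horizon transfer: the all-horizon model should win on a
        # majority of horizons (it sees 13x the data)
        wins = sum(frame.loc[("all_tau", "mae"), t] <=
                   frame.loc[("one_tau", "mae"), t] for t in (30, 60, 90))
        assert wins >= 2

    def test_missing_row_when_insufficient_examples(self, subject):
        proto = TrainProtocol(max_epochs=1)
        frame = horizon_transfer_experiment(
            [subject], "bolus_p_c", tau_list=(30,), protocol=proto,
            config=TINY_STACK, seed=2, min_train=10 ** 6)
        assert np.isnan(frame.loc[("one_tau", "mae"), 30])
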