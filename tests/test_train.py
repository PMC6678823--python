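"""Warm-restart schedule closed form and training-loop contracts."""

import math

import numpy as np
import pandas as pd
import pytest

import enhsnap as es
from tests.conftest import random_encoded


SCHED = es.WarmRestartSchedule(gamma_min=1e-4, gamma_max=0.003, T=200)


class TestSchedule:
    def test_endpoints(self):
        assert es.learning_rate(SCHED, 0) == SCHED.gamma_max
        assert es.learning_rate(SCHED, SCHED.T) == pytest.approx(SCHED.gamma_min)

    def test_midpoint_is_exact_mean(self):
        mid = es.learning_rate(SCHED, SCHED.T / 2)
        assert mid == pytest.approx((SCHED.gamma_min + SCHED.gamma_max) / 2,
                                    abs=1e-18)

    def test_quarter_cycle_closed_form(self):
        # gamma(50) = 1e-4 + 0.00145 * (1 + cos(pi/4)) for the 200-epoch cycle
        expected = 1e-4 + 0.00145 * (1 + math.cos(math.pi / 4))
        assert es.learning_rate(SCHED, 50) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0025753, abs=1e-7)

    def test_strictly_decreasing_within_cycle(self):
        rates = [es.learning_rate(SCHED, t) for t in range(SCHED.T + 1)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_out_of_range_epoch_rejected(self):
        with pytest.raises(ValueError):
            es.learning_rate(SCHED, -1)
        with pytest.raises(ValueError):
            es.learning_rate(SCHED, SCHED.T + 1)

    def test_sawtooth_trace_resets_at_cycle_boundaries(self):
        trace = es.schedule_trace(SCHED, 600)
        assert trace.shape == (600,)
        for start in (0, 200, 400):
            assert trace[start] == SCHED.gamma_max          # per-cycle maxima
        # decreasing inside each cycle, jump back up across the boundary
        assert (np.diff(trace[:200]) < 0).all()
        assert trace[200] > trace[199]
        np.testing.assert_array_equal(trace[:200], trace[200:400])

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            es.WarmRestartSchedule(gamma_min=0.01, gamma_max=0.001, T=10)
        with pytest.raises(ValueError):
            es.WarmRestartSchedule(gamma_min=1e-4, gamma_max=1e-3, T=0)

    def test_epochs_must_be_cycle_multiple(self):
        with pytest.raises(ValueError):
            es.TrainingConfig(epochs=50, schedule=es.WarmRestartSchedule(
                gamma_min=1e-4, gamma_max=1e-3, T=20))


def _quick_config(epochs, T=None, seed=0, lr=1e-3):
    schedule = (es.WarmRestartSchedule(gamma_min=1e-4, gamma_max=3e-3, T=T)
                if T else None)
    return es.TrainingConfig(epochs=epochs, batch_size=8, seed=seed,
                             base_lr=lr, schedule=schedule)


class TestTrainSingle:
    def test_history_bookkeeping(self, rng):
        X, y = random_encoded(rng, n=20, length=16)
        model = es.build_model("gru_1x8", seed=0)
        res = es.train_single(model, X, y, _quick_config(epochs=3))
        assert len(res.history) == 3
        assert set(res.history.columns) >= {"epoch", "lr", "train_loss",
                                            "train_acc", "val_loss", "val_acc"}
        assert res.best_val_accuracy == res.history.val_acc.max()
        assert res.history.val_acc[res.best_epoch] == res.best_val_accuracy

    def test_seeded_runs_reproduce_bitwise(self, rng):
        X, y = random_encoded(rng, n=20, length=16)
        h = []
        for _ in range(2):
            model = es.build_model("gru_1x8", seed=1)
            h.append(es.train_single(model, X, y, _quick_config(epochs=3)).history)
        pd.testing.assert_frame_equal(h[0], h[1])

    def test_empty_and_nonbinary_rejected(self, rng):
        model = es.build_model("gru_1x8", seed=0)
        with pytest.raises(ValueError):
            es.train_single(model, np.empty((0, 10, 10)), np.empty(0),
                            _quick_config(epochs=1))
        X, y = random_encoded(rng, n=10, length=12)
        with pytest.raises(ValueError):
            es.train_single(model, X, y + 1, _quick_config(epochs=1))

    def test_learns_separable_synthetic_data(self):
        # default-strength signal, smallest recurrent model, short sequences
        ds = es.generate(es.SyntheticSpec(n_per_class=60, length=80,
                                          copies_positive=3, copies_strong=6,
                                          seed=5))
        seqs, y = ds.layer(1)
        X, y = es.encode_dataset(seqs, y.tolist())
        model = es.build_model("gru_1x8", seed=0)
        res = es.train_single(model, X, y.astype(float),
                              _quick_config(epochs=50, lr=3e-3, seed=5))
        assert res.history.train_acc.iloc[-1] > 0.9


class TestWarmRestarts:
    def test_snapshot_count_is_epochs_over_T(self, rng):
        X, y = random_encoded(rng, n=20, length=14)
        model = es.build_model("gru_1x8", seed=0)
        snaps = es.train_with_warm_restarts(model, X, y,
                                            _quick_config(epochs=6, T=2))
        assert len(snaps) == 3
        assert [m.cycle for m in snaps.members] == [0, 1, 2]

    def test_snapshot_beats_own_cycle_first_epoch(self, rng):
        X, y = random_encoded(rng, n=24, length=14)
        model = es.build_model("gru_1x8", seed=2)
        snaps = es.train_with_warm_restarts(model, X, y,
                                            _quick_config(epochs=9, T=3))
        val = snaps.history.val_acc.to_numpy()
        for m in snaps.members:
            assert m.val_accuracy >= val[m.cycle * 3]
            assert m.cycle * 3 <= m.epoch < (m.cycle + 1) * 3

    def test_lr_column_follows_sawtooth(self, rng):
        X, y = random_encoded(rng, n=16, length=12)
        model = es.build_model("gru_1x8", seed=0)
        cfg = _quick_config(epochs=6, T=3)
        snaps = es.train_with_warm_restarts(model, X, y, cfg)
        np.testing.assert_allclose(snaps.history.lr.to_numpy(),
                                   es.schedule_trace(cfg.schedule, 6))

    def test_schedule_required(self, rng):
        X, y = random_encoded(rng, n=10, length=12)
        with pytest.raises(ValueError):
            es.train_with_warm_restarts(es.build_model("gru_1x8", seed=0),
                                        X, y, _quick_config(epochs=4))

    def test_degenerate_schedule_equals_constant_rate(self, rng):
        X, y = random_encoded(rng, n=20, length=14)
        flat = es.TrainingConfig(
            epochs=4, batch_size=8, seed=3,
            schedule=es.WarmRestartSchedule(gamma_min=1e-3, gamma_max=1e-3, T=2))
        const = es.TrainingConfig(epochs=4, batch_size=8, seed=3, base_lr=1e-3)
        m1 = es.build_model("gru_1x8", seed=4)
        snaps = es.train_with_warm_restarts(m1, X, y, flat)
        m2 = es.build_model("gru_1x8", seed=4)
        res = es.train_single(m2, X, y, const)
        cols = ["train_loss", "train_acc", "val_loss", "val_acc"]
        pd.testing.assert_frame_equal(snaps.history[cols], res.history[cols])

    def test_snapshot_classifiers_are_materialized_states(self, rng):
        X, y = random_encoded(rng, n=16, length=12)
        model = es.build_model("gru_1x8", seed=0)
        snaps = es.train_with_warm_restarts(model, X, y,
                                            _quick_config(epochs=4, T=2))
        c0, c1 = snaps.classifier(0), snaps.classifier(1)
        assert not np.array_equal(c0.predict_proba(X), c1.predict_proba(X))
        s0 = snaps.members[0].state
        for p, v in zip(c0.params(), s0):
            np.testing.assert_array_equal(p.value, v)
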