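"""Loss conventions, optimizer safeguards, calibration and sweep behavior."""

import math

import numpy as np
import pytest

from spikeseiz import (
    EncoderConfig,
    ModelSpec,
    TrainConfig,
    build_hybrid_snn,
    fit_temperature,
    loss,
    threshold_sweep,
    train,
)
from spikeseiz._autograd import Tensor
from spikeseiz.training import AdamW, OneCycleSchedule, clip_grad_norm
from spikeseiz.windowing import LabeledWindow


def plain_cfg(**kw):
    base = dict(label_smoothing=0.0, seizure_weight=1.0)
    base.update(kw)
    return TrainConfig(**base)


class TestLoss:
    def test_uniform_logits_ln2(self):
        logits = Tensor(np.zeros((4, 2)))
        L = loss(logits, np.array([0, 1, 0, 1]), plain_cfg())
        assert float(L.data) == pytest.approx(math.log(2))

    def test_perfect_logits_approach_zero(self):
        big = 50.0
        logits = np.array([[big, -big], [-big, big]])
        L = loss(Tensor(logits), np.array([0, 1]), plain_cfg())
        assert float(L.data) < 1e-9

    def test_seizure_weighting_ratio(self):
        """All-seizure batch: weighted loss = 1.2/1.1 x unweighted (mean-1 norm)."""
        rng = np.random.default_rng(0)
        logits = Tensor(rng.standard_normal((16, 2)))
        y = np.ones(16, dtype=int)
        unweighted = float(loss(logits, y, plain_cfg()).data)
        weighted = float(loss(logits, y, plain_cfg(seizure_weight=1.2)).data)
        assert weighted / unweighted == pytest.approx(1.2 / 1.1)

    def test_label_smoothing_penalizes_overconfidence(self):
        sharp = np.array([[20.0, -20.0]])
        y = np.array([0])
        cfg = TrainConfig(label_smoothing=0.1, seizure_weight=1.0)
        assert float(loss(Tensor(sharp), y, cfg).data) > float(
            loss(Tensor(sharp), y, plain_cfg()).data)

    def test_bce_single_logit_matches_closed_form(self):
        z = np.array([[0.7], [-1.2]])
        y = np.array([1, 0])
        L = float(loss(Tensor(z), y, plain_cfg()).data)
        expected = np.mean([math.log(1 + math.exp(-0.7)),
                            math.log(1 + math.exp(-1.2))])
        assert L == pytest.approx(expected, rel=1e-9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(label_smoothing=0.7)
        with pytest.raises(ValueError):
            TrainConfig(seizure_weight=0.5)
        with pytest.raises(ValueError):
            TrainConfig(grad_clip_norm=0.0)


class TestOptimizer:
    def test_clip_bounds_global_norm(self, rng):
        from spikeseiz._autograd import Parameter
        params = [Parameter(rng.standard_normal(10)) for _ in range(3)]
        for p in params:
            p.grad = rng.standard_normal(10) * 50
        norm = clip_grad_norm(params, 1.0)
        total = math.sqrt(sum(float((p.grad**2).sum()) for p in params))
        assert total == pytest.approx(1.0, abs=1e-9)
        assert norm <= 1.0 + 1e-12

    def test_adamw_decoupled_decay_moves_toward_zero(self):
        from spikeseiz._autograd import Parameter
        p = Parameter(np.array([10.0]))
        opt = AdamW([p], lr=0.1, weight_decay=0.5)
        p.grad = np.array([0.0])
        opt.step()
        assert p.data[0] < 10.0  # decay acts even with zero gradient

    def test_one_cycle_profile(self):
        sched = OneCycleSchedule(1e-3, total_steps=100)
        lrs = [sched.lr_at(s) for s in range(100)]
        peak = int(np.argmax(lrs))
        assert lrs[peak] == pytest.approx(1e-3, rel=1e-6)
        assert lrs[0] < 1e-4 and lrs[-1] < lrs[0]
        assert all(a <= b + 1e-15 for a, b in zip(lrs[:peak], lrs[1:peak + 1]))


def _make_windows(rng, n_pos, n_neg, C=2, T=128, pid="pa"):
    out = []
    for i in range(n_pos + n_neg):
        label = 1 if i < n_pos else 0
        scale = 4.0 if label else 1.0
        data = rng.standard_normal((C, T)) * scale
        out.append(LabeledWindow(data, label, 0, pid, f"{pid}_r0"))
    return out


class TestTrainLoop:
    def test_zero_epochs_returns_unchanged(self, rng):
        model = build_hybrid_snn(ModelSpec(kind="hybrid_snn", in_channels=4))
        before = {k: v.copy() for k, v in model.state_dict().items()}
        tr = _make_windows(rng, 4, 4)
        va = _make_windows(rng, 2, 2, pid="pb")
        out, hist = train(model, tr, va, cfg=TrainConfig(epochs=0))
        assert hist == []
        for k, v in out.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_single_class_validation_rejected(self, rng):
        model = build_hybrid_snn(ModelSpec(kind="hybrid_snn", in_channels=4))
        tr = _make_windows(rng, 4, 4)
        va = _make_windows(rng, 0, 4, pid="pb")
        with pytest.raises(ValueError):
            train(model, tr, va, cfg=TrainConfig(epochs=1))

    def test_one_epoch_records_history_and_learns_nothing_silly(self, rng):
        model = build_hybrid_snn(ModelSpec(kind="hybrid_snn", in_channels=4))
        tr = _make_windows(rng, 16, 16)
        va = _make_windows(rng, 8, 8, pid="pb")
        _, hist = train(model, tr, va, EncoderConfig(seed=0),
                        TrainConfig(epochs=1, batch_size=16), coder="hybrid")
        assert len(hist) == 1
        assert set(hist[0]) == {"epoch", "train_loss", "val_loss", "val_f1"}


class TestTemperature:
    def _calibrated_logits(self, rng, n=10_000):
        z = rng.standard_normal((n, 2)) * 1.5
        p = np.exp(z[:, 1] - np.logaddexp(z[:, 0], z[:, 1]))
        y = (rng.random(n) < p).astype(int)
        return z, y

    def test_already_calibrated_recovers_T_near_1(self, rng):
        z, y = self._calibrated_logits(rng)
        assert fit_temperature(z, y) == pytest.approx(1.0, abs=0.1)

    def test_doubled_logits_recover_T_near_2(self, rng):
        z, y = self._calibrated_logits(rng)
        assert fit_temperature(2 * z, y) == pytest.approx(2.0, abs=0.2)

    def test_shift_invariance(self, rng):
        z, y = self._calibrated_logits(rng, n=2000)
        t1 = fit_temperature(z, y)
        t2 = fit_temperature(z + 7.3, y)
        assert t1 == pytest.approx(t2, rel=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_temperature(np.zeros((5, 2)), np.ones(5, dtype=int))


class TestThresholdSweep:
    def test_tie_break_returns_lowest(self):
        grid = np.arange(0.05, 0.96, 0.05)
        res = threshold_sweep([0.1, 0.4, 0.9], [0, 0, 1], grid)
        assert res.best_threshold == pytest.approx(0.45)
        assert res.f1_at_threshold == 1.0

    def test_all_negative_degenerate(self):
        grid = np.arange(0.05, 0.96, 0.05)
        res = threshold_sweep([0.2, 0.3], [0, 0], grid)
        assert res.f1_at_threshold == 0.0
        assert res.best_threshold == pytest.approx(0.05)

    def test_grid_order_invariance(self, rng):
        probs = rng.random(50)
        labels = rng.integers(0, 2, 50)
        grid = np.arange(0.05, 0.96, 0.05)
        a = threshold_sweep(probs, labels, grid)
        b = threshold_sweep(probs, labels, rng.permutation(grid))
        assert a.best_threshold == pytest.approx(b.best_threshold)

    def test_probabilities_not_modified(self, rng):
        probs = rng.random(20)
        snapshot = probs.copy()
        threshold_sweep(probs, rng.integers(0, 2, 20))
        np.testing.assert_array_equal(probs, snapshot)


class TestNoValidationLeakage:
    def test_calibration_leaves_weights_untouched(self, rng):
        model = build_hybrid_snn()
        before = {k: v.copy() for k, v in model.state_dict().items()}
        z, y = rng.standard_normal((200, 2)), rng.integers(0, 2, 200)
        fit_temperature(z, y)
        threshold_sweep(rng.random(200), y)
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])


class TestFirstEpochProgress:
    """One epoch on easy synthetic windows reduces the training loss for all
    three architectures (surrogate gradients reach every spiking layer)."""

    @pytest.mark.parametrize("kind", ["hybrid_snn", "conv_snn", "cnn_baseline"])
    def test_loss_decreases_over_first_epoch(self, kind, small_cohort):
        import numpy as np
        from spikeseiz import build_model, EncoderConfig
        from spikeseiz.models import ModelSpec
        from spikeseiz.training import _prepare_inputs, AdamW, clip_grad_norm
        from spikeseiz.windowing import segment, label_windows, zscore, balance_training

        win = 2560 if kind == "cnn_baseline" else 128
        windows = []
        for rec in small_cohort:
            z = zscore(rec)
            segs = segment(z, win=win, step=win)
            windows.extend(label_windows(segs, z.ictal_intervals, z.fs))
        bal = balance_training(windows, seed=0)[:96]
        in_ch = 1 if kind == "cnn_baseline" else 2 * small_cohort[0].n_channels
        spec = ModelSpec(kind=kind, in_channels=in_ch, seed=0)
        model = build_model(spec).train()
        X, y = _prepare_inputs(bal, kind, EncoderConfig(seed=0), "hybrid")

        cfg = TrainConfig(seed=0)
        before = float(loss(model(Tensor(X)), y, cfg).data)
        opt = AdamW(model.parameters(), lr=1e-3)
        batch = 16
        for i in range(0, len(y), batch):
            model.zero_grad()
            L = loss(model(Tensor(X[i:i + batch])), y[i:i + batch], cfg)
            L.backward()
            clip_grad_norm(model.parameters(), 1.0)
            opt.step()
        after = float(loss(model(Tensor(X)), y, cfg).data)
        assert after < before
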