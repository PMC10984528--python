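"""Training protocol: plateau schedule, best-checkpoint selection, evaluate,
predict round-trips."""

import numpy as np
import pytest
from PIL import Image

from conftest import tiny_model_config
from pmffnet.model import PMFFNet, load_checkpoint
from pmffnet.nn import AdamW, ReduceLROnPlateau
from pmffnet.phantom import PhantomConfig, generate_phantom
from pmffnet.train import TrainConfig, evaluate, fit, predict


class TestPlateauSchedule:
    def _trace(self, metrics, patience=10, lr0=1e-4):
        class P:
            def __init__(self):
                self.data = np.zeros(1, np.float32)
                self.grad = None
        opt = AdamW([P()], lr=lr0)
        sched = ReduceLROnPlateau(opt, mode="max", factor=0.5,
                                  patience=patience)
        lrs = []
        for m in metrics:
            sched.step(m)
            lrs.append(opt.lr)
        return lrs

    def test_flat_metric_halves_exactly_once_after_patience(self):
        lrs = self._trace([0.5] * 11)
        assert lrs[:10] == [1e-4] * 10
        assert lrs[10] == 5e-5
        assert lrs.count(5e-5) == 1

    def test_improving_metric_never_reduces(self):
        lrs = self._trace(list(np.linspace(0.1, 0.9, 25)))
        assert set(lrs) == {1e-4}

    def test_improvement_resets_the_counter(self):
        metrics = [0.5] + [0.4] * 9 + [0.6] + [0.4] * 9 + [0.4]
        lrs = self._trace(metrics)
        assert lrs[-2] == 1e-4          # 9 bad epochs after the reset
        assert lrs[-1] == 5e-5          # the 10th triggers the halving

    def test_two_plateaus_halve_twice(self):
        lrs = self._trace([0.5] * 21)
        assert lrs[-1] == 2.5e-5

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            self._trace([0.5], patience=0)
        with pytest.raises(ValueError):
            TrainConfig(plateau_factor=1.5)


class TestFit:
    def test_frozen_model_flat_mdice_single_halving(self, phantom_pairs_96):
        """11 epochs without optimizer steps and a flat validation metric:
        the lr is halved exactly once, at epoch 11."""
        model = PMFFNet(tiny_model_config(), seed=0)
        cfg = TrainConfig(epochs=11, batch_size=8, lr=1e-4, seed=0)
        runlog, _ = fit(model, phantom_pairs_96[:2], phantom_pairs_96[:2],
                        cfg, steps_per_epoch=0, val_metric_fn=lambda e: 0.5)
        assert runlog.lr[:10] == [1e-4] * 10
        assert runlog.lr[10] == 5e-5
        # lr trace is non-increasing, halving exactly at plateau events
        assert all(b <= a for a, b in zip(runlog.lr, runlog.lr[1:]))

    def test_same_seed_identical_loss_trajectory(self, phantom_pairs_96):
        logs = []
        for _ in range(2):
            model = PMFFNet(tiny_model_config(), seed=1)
            cfg = TrainConfig(epochs=2, batch_size=4, lr=3e-4, seed=5)
            runlog, _ = fit(model, phantom_pairs_96[:4], phantom_pairs_96[:2],
                            cfg)
            logs.append(runlog)
        assert logs[0].train_loss == logs[1].train_loss
        assert logs[0].val_mdice == logs[1].val_mdice
        assert logs[0].best_checksum == logs[1].best_checksum

    def test_best_checkpoint_reproduces_logged_mdice(self, tmp_path,
                                                     phantom_pairs_96):
        model = PMFFNet(tiny_model_config(), seed=2)
        cfg = TrainConfig(epochs=3, batch_size=4, lr=1e-3, seed=0)
        path = tmp_path / "best.npz"
        runlog, _ = fit(model, phantom_pairs_96[:4], phantom_pairs_96[4:6],
                        cfg, checkpoint_path=path)
        restored, extra = load_checkpoint(path)
        report, _ = evaluate(restored, phantom_pairs_96[4:6])
        assert abs(report.m_dice - runlog.best_mdice) < 1e-6
        assert extra["epoch"] == runlog.best_epoch

    def test_divergent_loss_aborts_with_diagnostic(self, phantom_pairs_96):
        model = PMFFNet(tiny_model_config(), seed=0)
        model.head.out.bias.data[:] = np.nan
        cfg = TrainConfig(epochs=1, batch_size=2, seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            fit(model, phantom_pairs_96[:2], phantom_pairs_96[:2], cfg)

    def test_empty_sets_rejected(self, phantom_pairs_96):
        model = PMFFNet(tiny_model_config(), seed=0)
        with pytest.raises(ValueError):
            fit(model, [], phantom_pairs_96[:1], TrainConfig())


class _OracleModel:
    """Feeds the ground truth back as the prediction (upper bound)."""

    def __init__(self, pairs):
        self._masks = {p[0].tobytes(): p[1] for p in pairs}

    def predict_proba(self, xs):
        return np.stack([self._masks[x.tobytes()] for x in xs])[:, None]


class _BackgroundModel:
    def predict_proba(self, xs):
        return np.zeros((xs.shape[0], 1, *xs.shape[2:]), np.float32)


class TestEvaluate:
    def test_oracle_model_scores_all_ones(self, phantom_pairs_96):
        report, _ = evaluate(_OracleModel(phantom_pairs_96),
                             phantom_pairs_96)
        assert report.as_percent_dict() == {
            "mAcc": 100.0, "mIoU": 100.0, "mDice": 100.0,
            "mPr": 100.0, "mRe": 100.0}

    def test_all_background_prediction_has_zero_recall(self, phantom_pairs_96):
        report, per = evaluate(_BackgroundModel(), phantom_pairs_96)
        assert report.m_recall == 0.0
        assert report.m_iou == 0.0

    def test_csv_rows_follow_input_order(self, tmp_path, phantom_pairs_96):
        path = tmp_path / "m.csv"
        ids = [f"img{i}" for i in range(len(phantom_pairs_96))]
        evaluate(_OracleModel(phantom_pairs_96), phantom_pairs_96,
                 ids=ids, csv_path=path)
        lines = path.read_text().strip().splitlines()
        assert [ln.split(",")[0] for ln in lines[1:-1]] == ids
        assert lines[1].split(",")[1] == "100.00"

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_BackgroundModel(), [])


class TestPredict:
    def test_geometry_roundtrip_and_determinism(self, tmp_path, tiny_model):
        rec = generate_phantom(PhantomConfig(image_size=(64, 96), seed=33))
        src = tmp_path / "input.png"
        Image.fromarray(rec.image).save(src)
        out1 = predict(tiny_model, src, tmp_path / "m1.png", side=96)
        out2 = predict(tiny_model, src, tmp_path / "m2.png", side=96)
        assert out1.shape == rec.mask.shape
        np.testing.assert_array_equal(out1, out2)
        assert (tmp_path / "m1.png").read_bytes() == \
            (tmp_path / "m2.png").read_bytes()

    def test_activation_export_one_map_per_tap_per_scale(self, tmp_path,
                                                         tiny_model):
        rec = generate_phantom(PhantomConfig(image_size=(64, 64), seed=34))
        src = tmp_path / "input.png"
        Image.fromarray(rec.image).save(src)
        adir = tmp_path / "acts"
        predict(tiny_model, src, tmp_path / "mask.png", side=96,
                activations_dir=adir)
        names = sorted(p.name for p in adir.iterdir())
        expected = sorted([f"{p}_{s}.png" for p in ("v2s", "le", "erf", "mfb")
                           for s in range(4)]
                          + [f"decoder_{i}.png" for i in range(3)])
        assert names == expected

    def test_unreadable_file_errors(self, tmp_path, tiny_model):
        bad = tmp_path / "bad.png"
        bad.write_bytes(b"not an image")
        with pytest.raises(ValueError, match="cannot read"):
            predict(tiny_model, bad, tmp_path / "out.png", side=96)
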