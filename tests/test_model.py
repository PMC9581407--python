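"""Classifier architecture, loss, LOCO splitting and training behavior."""

import numpy as np
import pytest

import chromloop as cl
from chromloop import nn


def _tiny_cfg(**kw):
    base = dict(window_size=23, filters=(3, 4, 5), fc_width=6, seed=1)
    base.update(kw)
    return cl.ModelConfig(**base)


def _expected_param_count(cfg):
    chans = (cfg.in_channels,) + cfg.filters
    n = 0
    for b in range(3):
        k = cfg.kernels[b]
        n += cfg.filters[b] * (chans[b] * k * k) + cfg.filters[b]  # conv W + b
        n += 2 * cfg.filters[b]  # batch-norm gamma + beta
    n += cfg.filters[-1] * cfg.fc_width + cfg.fc_width  # fc1
    n += 2 * cfg.fc_width
    n += cfg.fc_width * cfg.fc_width + cfg.fc_width     # fc2
    n += 2 * cfg.fc_width
    n += cfg.fc_width * 1 + 1                            # output unit
    return n


class TestArchitecture:
    def test_deterministic_init(self):
        a = cl.init_model(_tiny_cfg())
        b = cl.init_model(_tiny_cfg())
        for la, lb in zip(a.layers, b.layers):
            for k in la.params:
                np.testing.assert_array_equal(la.params[k], lb.params[k])

    def test_forward_probability_range(self):
        m = cl.init_model(_tiny_cfg())
        p = m.predict_array(np.zeros((3, 2, 23, 23), dtype=np.float32))
        assert np.all((p > 0) & (p < 1))

    @pytest.mark.parametrize("cfg", [
        _tiny_cfg(),
        _tiny_cfg(filters=(8, 16, 32), kernels=(9, 9, 7)),
        _tiny_cfg(kernels=(3, 3, 3), padding="same"),
    ])
    def test_parameter_count_closed_form(self, cfg):
        assert cl.init_model(cfg).parameter_count() == _expected_param_count(cfg)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            cl.ModelConfig(dropout=1.0)
        with pytest.raises(ValueError):
            cl.ModelConfig(filters=(8, 16))
        with pytest.raises(ValueError):
            cl.ModelConfig(window_size=23, kernels=(11, 11, 7))  # exhausts window

    def test_duplicate_windows_same_probability(self, rng):
        m = cl.init_model(_tiny_cfg())
        x = rng.random((1, 2, 23, 23)).astype(np.float32)
        p = m.predict_array(np.concatenate([x, x]))
        assert p[0] == p[1]

    def test_batching_invariance(self, rng):
        m = cl.init_model(_tiny_cfg())
        x = rng.random((33, 2, 23, 23)).astype(np.float32)
        together = m.predict_array(x)
        singly = np.concatenate([m.predict_array(x[k:k + 1]) for k in range(33)])
        np.testing.assert_allclose(together, singly, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        m = cl.init_model(_tiny_cfg())
        with pytest.raises(ValueError):
            m.predict_array(rng.random((4, 2, 11, 11)))

    def test_checkpoint_round_trip(self, rng, tmp_path):
        m = cl.init_model(_tiny_cfg())
        x = rng.random((5, 2, 23, 23)).astype(np.float32)
        path = tmp_path / "model.npz"
        m.history = [{"epoch": 0, "val_prauc": 0.5}]
        m.save(str(path))
        back = cl.LoopClassifier.load(str(path))
        np.testing.assert_allclose(back.predict_array(x), m.predict_array(x))
        assert back.config == m.config
        assert back.normalization == m.normalization
        assert back.history == m.history


class TestBCELoss:
    def test_perfect_prediction(self):
        assert cl.bce_loss(np.ones(4), np.ones(4)) < 1e-6

    def test_closed_form(self):
        assert cl.bce_loss(np.array([0.0]), np.array([0.5])) == pytest.approx(np.log(2))

    def test_elementwise_oracle(self, rng):
        y = rng.integers(0, 2, 64).astype(float)
        p = rng.random(64) * 0.98 + 0.01
        per_sample = [-(yy * np.log(pp) + (1 - yy) * np.log(1 - pp))
                      for yy, pp in zip(y, p)]
        assert cl.bce_loss(y, p) == pytest.approx(np.mean(per_sample))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cl.bce_loss(np.zeros(3), np.full(4, 0.5))

    def test_nonnegative(self, rng):
        y = rng.integers(0, 2, 32).astype(float)
        p = rng.random(32)
        assert cl.bce_loss(y, p) >= 0


class TestLocoSplit:
    def test_arithmetic_23_chroms(self):
        chroms = [f"chr{k}" for k in range(1, 24)]
        tr, va, te = cl.loco_split(chroms, "chr1", val_fraction=0.2, seed=0)
        assert te == ["chr1"]
        assert len(va) == 4 and len(tr) == 18  # round(0.2 * 22) = 4

    def test_partition(self):
        chroms = [f"chr{k}" for k in range(1, 11)]
        tr, va, te = cl.loco_split(chroms, "chr5", seed=3)
        assert set(tr) | set(va) | set(te) == set(chroms)
        assert not (set(tr) & set(va)) and not (set(tr) & set(te)) and not (set(va) & set(te))

    def test_deterministic(self):
        chroms = [f"chr{k}" for k in range(1, 24)]
        assert cl.loco_split(chroms, "chr2", seed=7) == cl.loco_split(chroms, "chr2", seed=7)

    def test_validation_floor_with_few_chromosomes(self):
        tr, va, te = cl.loco_split(["chr1", "chr2", "chr3"], "chr3", seed=0)
        assert len(tr) == 1 and len(va) == 1 and te == ["chr3"]

    def test_missing_test_chrom(self):
        with pytest.raises(ValueError):
            cl.loco_split(["chr1"], "chrX", seed=0)


class TestTraining:
    def _toy_windows(self, rng, n_per_class=16, w=23):
        out = []
        for label in (0, 1):
            for _ in range(n_per_class):
                hic = rng.random((w, w)) * 0.1
                acc = rng.random((w, w)) * 0.1
                if label:
                    hic[9:14, 9:14] += 0.7
                    acc[11, :] += 0.4
                    acc[:, 11] += 0.4
                out.append(cl.SampleWindow("chrT", (50, 80), w,
                                           np.clip(hic, 0, 0.99), np.clip(acc, 0, 0.99),
                                           label))
        return out

    def test_deterministic_history(self, rng):
        wins = self._toy_windows(rng)
        tc = cl.TrainConfig(seed=5, max_epochs=4, patience=10)
        m1 = cl.train(cl.init_model(_tiny_cfg()), wins, wins, tc)
        m2 = cl.train(cl.init_model(_tiny_cfg()), wins, wins, tc)
        assert m1.history == m2.history
        x = np.stack([w.stacked() for w in wins]).astype(np.float32)
        np.testing.assert_array_equal(m1.predict_array(x), m2.predict_array(x))

    def test_best_prauc_is_max_of_history(self, rng):
        wins = self._toy_windows(rng)
        tc = cl.TrainConfig(seed=5, max_epochs=6, patience=10)
        m = cl.train(cl.init_model(_tiny_cfg()), wins, wins, tc)
        assert m.best_val_prauc == max(h["val_prauc"] for h in m.history)

    def test_single_class_rejected(self, rng):
        wins = [w for w in self._toy_windows(rng) if w.label == 1]
        with pytest.raises(ValueError, match="both classes"):
            cl.train(cl.init_model(_tiny_cfg()), wins, wins, cl.TrainConfig(seed=0))

    def test_adam_step_decreases_loss_on_mislabeled_example(self, rng):
        """Gradient sanity: one optimization step on a single example reduces
        that example's training-mode loss."""
        m = cl.init_model(_tiny_cfg(dropout=0.0))
        x = rng.random((1, 2, 23, 23)).astype(np.float32)
        y = np.array([1.0])
        opt = nn.Adam(m.layers, lr=0.001)
        z0 = m.forward_logits(x, train=True)
        loss0 = nn.bce_with_logits(z0, y)
        m.backward(nn.bce_with_logits_grad(z0, y))
        opt.step()
        z1 = m.forward_logits(x, train=True)
        assert nn.bce_with_logits(z1, y) < loss0

    def test_separable_toy_problem_learned(self, rng):
        """Strongly separable two-channel windows are classified near-perfectly."""
        train_w = self._toy_windows(rng, 24)
        test_w = self._toy_windows(rng, 24)
        tc = cl.TrainConfig(seed=2, max_epochs=60, patience=60, batch_size=16)
        m = cl.train(cl.init_model(_tiny_cfg(filters=(4, 8, 16))), train_w, train_w, tc)
        probs = cl.predict(m, test_w)
        rep = cl.classification_metrics([w.label for w in test_w], probs, 0.5)
        assert rep.f1 >= 0.95


class TestFixtureSeparation:
    def test_held_out_windows_classified(self, trained, study, split):
        """The surrogate for window-level recovery: windows from the held-out
        chromosome are classified with high F1."""
        test_w = study["datasets"]["chr3"]
        probs = cl.predict(trained, test_w)
        rep = cl.classification_metrics([w.label for w in test_w], probs, 0.5)
        assert rep.f1 >= 0.9

    def test_accessibility_channel_consumed(self, study, split):
        """Zeroing the accessibility peaks (uninformative channel 2) must not
        improve held-out window F1 over the informative-channel run."""
        p0 = study["params"]
        import dataclasses
        flat = dataclasses.replace(p0, acc_peak_height=0.0)
        maps, tracks, truth, ds = {}, {}, {}, {}
        for c in flat.chrom_names():
            maps[c], truth[c] = cl.simulate_contact_map(flat, c)
            tracks[c] = cl.simulate_accessibility(flat, truth[c], c)
            ds[c], _ = cl.build_dataset(maps[c], tracks[c], truth[c], seed=11)
        tr, va, te = split
        tc = cl.TrainConfig(seed=3, max_epochs=150, patience=40)
        cfg = cl.ModelConfig(seed=3, filters=(8, 16, 32))

        def f1_of(datasets):
            m = cl.train(cl.init_model(cfg),
                         [w for c in tr for w in datasets[c]],
                         [w for c in va for w in datasets[c]], tc)
            probs = cl.predict(m, datasets[te[0]])
            return cl.classification_metrics(
                [w.label for w in datasets[te[0]]], probs, 0.5).f1

        f1_flat = f1_of(ds)
        f1_informative = f1_of(study["datasets"])
        assert f1_flat <= f1_informative + 0.05
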