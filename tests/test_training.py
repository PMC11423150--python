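"""Loss oracle, sampler contracts, schedule, and capacity checks."""

import numpy as np
import pytest

from conftest import tiny_model_config
from nldnn.model import build_nldnn
from nldnn.nn import Adam, Tensor
from nldnn.training import (
    NegativeSampler,
    TrainConfig,
    epoch_batches,
    learning_rate,
    nldnn_loss,
    rc_windows,
    train,
)


class TestLoss:
    def test_zero_when_equal_and_unpenalized(self, rng):
        z = rng.normal(size=(3, 5))
        assert float(nldnn_loss(Tensor(z), z).data) == 0.0

    def test_worked_example(self):
        pred = Tensor(np.array([[0.0, 0.0]]))
        true = np.array([[2.0, 0.0]])
        assert float(nldnn_loss(pred, true).data) == 2.0  # (4+0)/2

    def test_matches_double_loop_oracle(self, rng):
        """Eq-style oracle: explicit loops over samples and positions plus an
        explicit sum of squared weights."""
        model = build_nldnn(tiny_model_config(seed=2))
        alpha = 1e-3
        for _ in range(5):
            n, length = int(rng.integers(1, 4)), int(rng.integers(2, 9))
            z = rng.normal(size=(n, length))
            zhat = rng.normal(size=(n, length))
            got = float(nldnn_loss(Tensor(z), zhat, model, alpha).data)
            acc = 0.0
            for i in range(n):
                for j in range(length):
                    acc += (z[i, j] - zhat[i, j]) ** 2
            acc /= n * length
            penalty = sum(float((w.data**2).sum()) for w in model.weights())
            assert abs(got - (acc + alpha * penalty)) < 1e-6

    def test_poisson_variant_matches_formula(self, rng):
        z = rng.normal(size=(2, 4))
        zhat = rng.poisson(2.0, size=(2, 4)).astype(float)
        got = float(nldnn_loss(Tensor(z), zhat, loss="poisson").data)
        oracle = float(np.mean(np.exp(z) - zhat * z))
        assert abs(got - oracle) < 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            nldnn_loss(Tensor(np.zeros((2, 3))), np.zeros((2, 4)))


class TestSchedule:
    def test_decay_every_ten_epochs(self):
        cfg = TrainConfig(seed=0)
        assert learning_rate(cfg, 0) == 1e-3
        assert learning_rate(cfg, 9) == 1e-3
        assert np.isclose(learning_rate(cfg, 10), 9e-4)
        assert np.isclose(learning_rate(cfg, 25), 1e-3 * 0.9**2)

    def test_exact_power_law(self):
        cfg = TrainConfig(seed=0)
        for e in range(0, 60, 7):
            assert learning_rate(cfg, e) == cfg.lr0 * cfg.lr_decay ** (e // 10)


class TestNegativeSampler:
    def test_without_replacement_until_pool_exhausted(self):
        s = NegativeSampler(10, np.random.default_rng(0))
        drawn = np.concatenate([s.draw(3), s.draw(3), s.draw(4)])
        assert sorted(drawn) == list(range(10))

    def test_reshuffles_after_exhaustion(self):
        s = NegativeSampler(6, np.random.default_rng(0))
        first = s.draw(6)
        second = s.draw(6)
        assert sorted(first) == sorted(second) == list(range(6))

    def test_union_over_epochs_covers_whole_pool(self):
        """ceil(pool / (3*|pos|)) epochs see every negative at least once."""
        n_pos, pool = 10, 100
        s = NegativeSampler(pool, np.random.default_rng(1))
        cfg = TrainConfig(seed=1, neg_ratio=3, batch_size=16)
        seen = set()
        n_epochs = int(np.ceil(pool / (3 * n_pos)))
        for epoch in range(n_epochs):
            for _, neg_idx in epoch_batches(n_pos, s, cfg, epoch):
                seen.update(neg_idx.tolist())
        assert seen == set(range(pool))

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            NegativeSampler(0, np.random.default_rng(0))


class TestEpochBatches:
    def test_epoch_contains_all_positives_and_three_to_one_negatives(self):
        s = NegativeSampler(100, np.random.default_rng(0))
        cfg = TrainConfig(seed=0, batch_size=16, neg_ratio=3)
        batches = epoch_batches(10, s, cfg, epoch=0)
        pos = np.concatenate([p for p, _ in batches])
        neg = np.concatenate([n for _, n in batches])
        assert sorted(pos) == list(range(10))
        assert len(neg) == 30

    def test_deterministic_given_seed_and_epoch(self):
        cfg = TrainConfig(seed=4, batch_size=8)
        a = epoch_batches(5, NegativeSampler(40, np.random.default_rng([4, 11])), cfg, 2)
        b = epoch_batches(5, NegativeSampler(40, np.random.default_rng([4, 11])), cfg, 2)
        for (pa, na), (pb, nb) in zip(a, b):
            assert np.array_equal(pa, pb) and np.array_equal(na, nb)

    def test_batch_sizes_respect_config(self):
        s = NegativeSampler(90, np.random.default_rng(0))
        cfg = TrainConfig(seed=0, batch_size=25, neg_ratio=3)
        batches = epoch_batches(10, s, cfg, 0)
        sizes = [len(p) + len(n) for p, n in batches]
        assert sum(sizes) == 40
        assert all(sz <= 25 for sz in sizes)


class TestRCWindows:
    def test_reverse_complement_of_onehot(self):
        from nldnn.synthetic import revcomp
        from nldnn.windows import decode_onehot, one_hot

        seq = "ACGTTGCANA"
        x = one_hot(seq)[None]
        y = np.arange(10, dtype=float)[None]
        xr, yr = rc_windows(x, y)
        assert decode_onehot(xr[0]) == revcomp(seq)
        assert np.array_equal(yr[0], y[0, ::-1])

    def test_involution(self, rng):
        x = rng.integers(0, 2, size=(2, 4, 8)).astype(float)
        y = rng.normal(size=(2, 8))
        x2, y2 = rc_windows(*rc_windows(x, y))
        assert np.array_equal(x, x2) and np.array_equal(y, y2)


class TestTrainLoop:
    def test_overfits_eight_windows(self, rng):
        """Capacity check: training loss falls below 10% of its initial value
        within 200 steps on 8 windows."""
        model = build_nldnn(tiny_model_config(seed=0, dropout=0.0))
        x = rng.integers(0, 2, size=(8, 4, 600)).astype(float)
        y = np.abs(rng.normal(size=(8, 600)))
        opt = Adam(model.parameters(), lr=2e-3)
        model.train()
        first = None
        for _ in range(200):
            loss = nldnn_loss(model(Tensor(x)), y)
            if first is None:
                first = float(loss.data)
            model.zero_grad()
            loss.backward()
            opt.step()
        assert float(loss.data) < 0.1 * first

    def test_history_and_best_checkpoint(self, rng):
        model = build_nldnn(tiny_model_config(seed=1, dropout=0.0))
        xp = rng.integers(0, 2, size=(6, 4, 600)).astype(float)
        yp = np.abs(rng.normal(size=(6, 600)))
        xn = rng.integers(0, 2, size=(18, 4, 600)).astype(float)
        yn = np.zeros((18, 600))
        cfg = TrainConfig(batch_size=8, epochs=2, lr0=1e-3, warmup_inits=1, seed=0)
        model, history = train(model, xp, yp, xn, yn, cfg,
                               xp[:3], yp[:3], xn[:3])
        assert len(history) == 2
        assert {"epoch", "lr", "train_loss", "val_prauc"} <= set(history[0])

    def test_two_runs_same_seed_identical(self, rng):
        xp = rng.integers(0, 2, size=(4, 4, 600)).astype(float)
        yp = np.abs(rng.normal(size=(4, 600)))
        xn = rng.integers(0, 2, size=(12, 4, 600)).astype(float)
        yn = np.zeros((12, 600))
        cfg = TrainConfig(batch_size=8, epochs=1, warmup_inits=1, seed=9)
        hashes = []
        for _ in range(2):
            m = build_nldnn(tiny_model_config(seed=9))
            m, _ = train(m, xp, yp, xn, yn, cfg)
            hashes.append(m.param_hash())
        assert hashes[0] == hashes[1]


class TestWarmup:
    def test_returns_best_validation_candidate(self, rng):
        from conftest import tiny_model_config
        from nldnn.training import warmup_select

        xp = rng.integers(0, 2, size=(6, 4, 600)).astype(float)
        yp = np.abs(rng.normal(size=(6, 600)))
        xn = rng.integers(0, 2, size=(18, 4, 600)).astype(float)
        yn = np.zeros((18, 600))
        cfg = TrainConfig(batch_size=8, epochs=1, warmup_inits=2,
                          warmup_epochs=1, seed=0)
        model, prauc = warmup_select(tiny_model_config(seed=0), cfg,
                                     xp, yp, xn, yn, xp[:3], yp[:3], xn[:6])
        assert 0 <= prauc <= 1
        assert model is not None
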