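"""Numeric core: GeM pooling, ArcFace loss, and gradient correctness.

Gradient checks compare every layer's analytic backward pass against
central finite differences through a micro-network — the deepest
correctness guarantee the training loop rests on.
"""

import math

import numpy as np
import pytest

from cbmir import nn


class TestGeM:
    channel = np.array([[1.0, 2.0], [3.0, 4.0]])

    def test_p1_is_average_pooling(self):
        out = nn.gem_pool(self.channel, p=1.0)
        assert out[0] == pytest.approx(2.5, abs=1e-12)

    def test_large_p_approaches_max_pooling(self):
        # power-mean convergence: GeM_p = max * (S/|X|)^(1/p), so the deficit
        # from max is bounded by max * ln|X| / p and vanishes as p grows
        out = nn.gem_pool(self.channel, p=1000.0)
        assert out[0] == pytest.approx(4.0 * 0.25 ** (1 / 1000), rel=1e-9)
        assert abs(out[0] - 4.0) <= 4.0 * np.log(4) / 1000
        out_hi = nn.gem_pool(self.channel, p=1e5)
        assert out_hi[0] == pytest.approx(4.0, abs=1e-3)

    def test_p3_matches_hand_evaluation(self):
        out = nn.gem_pool(self.channel, p=3.0)
        assert out[0] == pytest.approx(25.0 ** (1.0 / 3.0), rel=1e-12)

    def test_p_below_one_rejected(self):
        with pytest.raises(ValueError):
            nn.gem_pool(self.channel, p=0.5)
        with pytest.raises(ValueError):
            nn.GeMPool(p=0.99)

    def test_interpolates_between_avg_and_max(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            fmap = rng.uniform(0, 10, size=(5, 6, 4))
            avg = fmap.mean(axis=(0, 1))
            mx = fmap.max(axis=(0, 1))
            prev = None
            for p in (1.0, 2.0, 3.0, 5.0, 10.0, 50.0):
                g = nn.gem_pool(fmap, p=p)
                assert np.all(g >= avg - 1e-9) and np.all(g <= mx + 1e-9)
                if prev is not None:
                    assert np.all(g >= prev - 1e-9)  # non-decreasing in p
                prev = g

    def test_layer_and_functional_agree(self):
        rng = np.random.default_rng(1)
        fmap = rng.uniform(0, 5, size=(2, 3, 4, 4)).astype(np.float32)  # (N,K,H,W)
        layer = nn.GeMPool(p=3.0)
        out = layer.forward(fmap)
        for i in range(2):
            ref = nn.gem_pool(fmap[i].transpose(1, 2, 0), p=3.0)
            assert np.allclose(out[i], ref, rtol=1e-5)


class TestArcFace:
    def _random_batch(self, rng, n=16, dim=8, classes=5):
        emb = rng.normal(0, 1, size=(n, dim))
        labels = rng.integers(0, classes, size=n)
        params = nn.ArcFaceParams(n_classes=classes, dim=dim, seed=int(rng.integers(1000)))
        return emb, labels, params

    def test_zero_margin_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            emb, labels, params = self._random_batch(rng)
            params = nn.ArcFaceParams(
                n_classes=params.n_classes, dim=params.dim, margin_deg=0.0, weight=params.weight
            )
            loss = nn.arcface_loss(emb, labels, params)
            # independent cross-entropy on s*cos(theta) logits
            e = emb / np.linalg.norm(emb, axis=1, keepdims=True)
            w64 = params.weight.astype(np.float64)
            w = w64 / np.linalg.norm(w64, axis=1, keepdims=True)
            logits = params.scale * np.clip(e @ w.T, -1 + 1e-7, 1 - 1e-7)
            z = logits - logits.max(axis=1, keepdims=True)
            ce = float(np.mean(-z[np.arange(len(labels)), labels] + np.log(np.exp(z).sum(axis=1))))
            assert loss == pytest.approx(ce, abs=1e-6)

    def test_perfectly_aligned_two_class_sample_has_near_zero_loss(self):
        w = np.array([[1.0, 0.0], [-1.0, 0.0]])
        params = nn.ArcFaceParams(n_classes=2, dim=2, scale=64.0, margin_deg=0.0, weight=w)
        loss = nn.arcface_loss(np.array([[1.0, 0.0]]), [0], params)
        assert loss == pytest.approx(math.log(1 + math.exp(-128)), abs=1e-6)
        assert loss < 1e-6

    def test_loss_non_decreasing_in_margin(self):
        rng = np.random.default_rng(3)
        emb, labels, params = self._random_batch(rng)
        # restrict margins so theta_y + m stays below pi for every sample
        e = emb / np.linalg.norm(emb, axis=1, keepdims=True)
        w = params.weight / np.linalg.norm(params.weight, axis=1, keepdims=True)
        cos_y = (e @ w.T)[np.arange(len(labels)), labels]
        max_theta = float(np.arccos(np.clip(cos_y, -1, 1)).max())
        margins = np.linspace(0.0, math.degrees(math.pi - max_theta) - 1e-6, 8)
        losses = [
            nn.arcface_loss(
                emb, labels,
                nn.ArcFaceParams(n_classes=params.n_classes, dim=params.dim,
                                 margin_deg=float(m), weight=params.weight),
            )
            for m in margins
        ]
        assert all(b >= a - 1e-9 for a, b in zip(losses, losses[1:]))

    def test_label_out_of_range_rejected(self):
        params = nn.ArcFaceParams(n_classes=3, dim=4)
        with pytest.raises(ValueError):
            nn.arcface_loss(np.ones((2, 4)), [0, 3], params)

    def test_weight_rows_unit_norm_after_renormalize(self):
        head = nn.ArcFaceHead(nn.ArcFaceParams(n_classes=4, dim=6))
        head.weight.value += 0.3
        head.renormalize()
        assert np.allclose(np.linalg.norm(head.weight.value, axis=1), 1.0, atol=1e-6)


class TestGradients:
    """Analytic vs central finite-difference gradients on a micro-network."""

    def _build(self, seed=0):
        rng = np.random.default_rng(seed)
        net = nn.Sequential(
            nn.Conv2d(2, 3, 3, stride=1, pad=1, rng=rng),
            nn.BatchNorm2d(3),
            nn.ReLU(),
            nn.GeMPool(p=3.0),
            nn.Linear(3, 4, rng=rng),
            nn.BatchNorm1d(4),
            nn.PReLU(),
        )
        head = nn.ArcFaceHead(nn.ArcFaceParams(n_classes=3, dim=4, scale=8.0, margin_deg=20.0, seed=1))
        x = rng.uniform(0.1, 1.0, size=(6, 2, 5, 5)).astype(np.float32)
        y = rng.integers(0, 3, size=6)
        return net, head, x, y

    def _loss(self, net, head, x, y):
        emb = net.forward(x, train=True)
        loss, _ = head.loss(emb, y, train=True)
        return loss

    def test_backward_matches_finite_differences(self):
        # directional derivatives give a far better signal-to-noise ratio
        # than single-entry perturbations under float32 forward arithmetic
        net, head, x, y = self._build()
        self._loss(net, head, x, y)
        g = head.backward()
        net.backward(g)
        params = net.params() + head.params()
        rng = np.random.default_rng(9)
        t = 3e-3
        for p in params:
            d = rng.normal(size=p.value.shape).astype(np.float32)
            d /= np.linalg.norm(d)
            orig = p.value.copy()
            p.value = orig + t * d
            lp = self._loss(net, head, x, y)
            p.value = orig - t * d
            lm = self._loss(net, head, x, y)
            p.value = orig
            numeric = (lp - lm) / (2 * t)
            analytic = float((p.grad * d).sum())
            scale = max(abs(numeric), abs(analytic))
            if scale < 1e-2:
                continue  # true gradient ~0 (e.g. bias absorbed by BatchNorm)
            assert abs(numeric - analytic) / scale < 5e-2, (p.name, numeric, analytic)

    def test_input_gradient_matches_finite_differences(self):
        net, head, x, y = self._build(seed=4)
        self._loss(net, head, x, y)
        g = head.backward()
        dx = net.backward(g)
        rng = np.random.default_rng(5)
        t = 3e-3
        d = rng.normal(size=x.shape).astype(np.float32)
        d /= np.linalg.norm(d)
        lp = self._loss(net, head, x + t * d, y)
        lm = self._loss(net, head, x - t * d, y)
        numeric = (lp - lm) / (2 * t)
        analytic = float((dx * d).sum())
        scale = max(abs(numeric), abs(analytic), 1e-4)
        assert abs(numeric - analytic) / scale < 5e-2


def test_sgd_momentum_update_rule():
    p = nn.Param(np.array([1.0, 2.0]))
    opt = nn.SGD([p], lr=0.1, momentum=0.5)
    p.grad[:] = [1.0, -1.0]
    opt.step()
    assert np.allclose(p.value, [0.9, 2.1])
    p.grad[:] = [1.0, -1.0]
    opt.step()  # velocity = 0.5*1 + 1 = 1.5
    assert np.allclose(p.value, [0.9 - 0.15, 2.1 + 0.15])


def test_batchnorm_requires_batch_of_two_in_train_mode():
    bn = nn.BatchNorm1d(3)
    with pytest.raises(ValueError):
        bn.forward(np.ones((1, 3)), train=True)
    bn.forward(np.ones((1, 3)), train=False)  # inference is fine
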