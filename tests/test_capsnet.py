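"""Model core: convolution, pooling, squash, routing, margin loss, forward."""

import math

import numpy as np
import pytest

from circrb import (
    CapsNetConfig,
    CapsuleNetwork,
    LossConfig,
    conv_feature_maps,
    dynamic_routing,
    encode_sequence,
    global_max_pool,
    margin_loss,
    squash,
)

# ---------------------------------------------------------------------------
# Independent step-by-step routing oracle (pure Python scalar loops)


def oracle_squash(v):
    ns = sum(x * x for x in v)
    if ns == 0:
        return [0.0] * len(v)
    n = math.sqrt(ns)
    return [(ns / (1 + ns)) * (x / n) for x in v]


def oracle_routing(u, T):
    """u: list over n inputs of list over classes of d-vectors."""
    n = len(u)
    ncls = len(u[0])
    b = [[0.0] * ncls for _ in range(n)]
    v = None
    for _ in range(T):
        # softmax over the n inputs, per output class
        c = []
        for j in range(ncls):
            exps = [math.exp(b[i][j]) for i in range(n)]
            z = sum(exps)
            c.append([e / z for e in exps])
        v = []
        for j in range(ncls):
            d = len(u[0][j])
            a = [sum(c[j][i] * u[i][j][t] for i in range(n)) for t in range(d)]
            v.append(oracle_squash(a))
        for i in range(n):
            for j in range(ncls):
                b[i][j] += sum(v[j][t] * u[i][j][t] for t in range(len(v[j])))
    return v


# ---------------------------------------------------------------------------
# Convolution + pooling


def indicator_filter(motif):
    """Filter weights that score +1 per matching base of ``motif``."""
    w = encode_sequence(motif).matrix.reshape(-1)
    return w[None, :], np.zeros(1)


class TestConv:
    def test_hand_convolution_of_indicator_filter(self):
        W, b = indicator_filter("ACG")
        maps = conv_feature_maps(encode_sequence("TACGT").matrix, W, b)
        assert maps.shape == (3, 1)
        assert maps[1, 0] == 3.0
        assert maps.max() == 3.0 and maps.argmax() == 1

    def test_zero_weights_give_zero_maps(self):
        X = encode_sequence("ACGTACGT").matrix
        maps = conv_feature_maps(X, np.zeros((4, 12)), np.zeros(4))
        assert maps.shape == (6, 4)
        assert not maps.any()

    def test_n_padding_never_increases_global_max(self):
        W, b = indicator_filter("ACG")
        base = conv_feature_maps(encode_sequence("TACGT").matrix, W, b).max()
        padded = conv_feature_maps(encode_sequence("NNTACGTNN").matrix, W, b).max()
        assert padded == base

    def test_map_length_and_short_input_rejected(self):
        X = encode_sequence("ACGTA").matrix
        assert conv_feature_maps(X, np.zeros((2, 12)), np.zeros(2)).shape == (3, 2)
        with pytest.raises(ValueError):
            conv_feature_maps(encode_sequence("AC").matrix, np.zeros((2, 12)), np.zeros(2))

    def test_activations_nonnegative(self):
        rng = np.random.default_rng(0)
        X = encode_sequence("ACGTACGTACGT").matrix
        maps = conv_feature_maps(X, rng.normal(size=(8, 12)), rng.normal(size=8))
        assert (maps >= 0).all()


class TestGlobalMaxPool:
    def test_simple_map(self):
        pooled, idx = global_max_pool(np.array([[0.0], [3.0], [1.0]]))
        assert pooled[0] == 3.0 and idx[0] == 1

    def test_leftmost_tie_break(self):
        pooled, idx = global_max_pool(np.array([[2.0], [2.0], [2.0]]))
        assert idx[0] == 0

    def test_pooled_vector_reshapes_to_capsule_grid(self):
        maps = np.random.default_rng(1).random((42, 128))
        pooled, _ = global_max_pool(maps)
        assert pooled.shape == (128,)
        assert pooled.reshape(16, 8).shape == (16, 8)


# ---------------------------------------------------------------------------
# Squash


class TestSquash:
    def test_zero_maps_to_zero(self):
        np.testing.assert_array_equal(squash(np.zeros(5)), np.zeros(5))

    def test_unit_vector_halves(self):
        v = np.array([1.0, 0.0])
        out = squash(v)
        np.testing.assert_allclose(np.linalg.norm(out), 0.5, atol=1e-9)
        np.testing.assert_allclose(out / np.linalg.norm(out), v, atol=1e-9)

    def test_three_four_vector(self):
        np.testing.assert_allclose(squash(np.array([3.0, 4.0])), [75 / 130, 100 / 130], atol=1e-8)

    def test_norm_law_and_monotonicity(self):
        rng = np.random.default_rng(2)
        prev = -1.0
        for r in np.linspace(0.01, 10, 50):
            v = rng.normal(size=6)
            v = v / np.linalg.norm(v) * r
            out_norm = np.linalg.norm(squash(v))
            np.testing.assert_allclose(out_norm, r**2 / (1 + r**2), atol=1e-6)
            assert out_norm < 1.0
        for r in (0.1, 0.5, 1.0, 2.0):
            v = np.ones(4) / 2 * r
            n = np.linalg.norm(squash(v))
            assert n > prev
            prev = n


# ---------------------------------------------------------------------------
# Dynamic routing


class TestRouting:
    def test_t1_is_squash_of_mean(self):
        u = np.random.default_rng(3).normal(size=(5, 2, 4))
        v = dynamic_routing(u, T=1)
        np.testing.assert_allclose(v, squash(u.mean(axis=0), axis=-1), atol=1e-12)

    def test_identical_inputs_fixed_point(self):
        base = np.random.default_rng(4).normal(size=(2, 4))
        u = np.broadcast_to(base, (6, 2, 4)).copy()
        for T in (1, 2, 3):
            np.testing.assert_allclose(dynamic_routing(u, T), squash(base, axis=-1), atol=1e-12)

    def test_against_stepwise_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 5))
            d = int(rng.integers(1, 4))
            T = int(rng.integers(1, 4))
            u = rng.normal(size=(n, 2, d))
            got = dynamic_routing(u, T)
            want = oracle_routing([[list(u[i, j]) for j in range(2)] for i in range(n)], T)
            np.testing.assert_allclose(got, np.array(want), atol=1e-6)

    def test_couplings_positive_and_normalised(self):
        u = np.random.default_rng(6).normal(size=(4, 2, 3))
        _, state = dynamic_routing(u, T=3, return_state=True)
        for c in state.couplings:
            assert (c > 0).all()
            np.testing.assert_allclose(c.sum(axis=0), 1.0, atol=1e-12)

    def test_small_two_input_instance(self):
        u = np.zeros((2, 2, 2))
        u[0, :, :] = [1.0, 0.0]
        u[1, :, :] = [0.0, 1.0]
        want = oracle_routing([[list(u[i, j]) for j in range(2)] for i in range(2)], 2)
        np.testing.assert_allclose(dynamic_routing(u, T=2), np.array(want), atol=1e-9)

    def test_invalid_rounds_rejected(self):
        with pytest.raises(ValueError):
            dynamic_routing(np.zeros((2, 2, 2)), T=0)


# ---------------------------------------------------------------------------
# Margin loss


class TestMarginLoss:
    def test_exactly_at_margins(self):
        assert margin_loss(0.9, 0.1, "positive") == 0.0

    def test_all_zero_scores(self):
        assert abs(margin_loss(0.0, 0.0, "positive") - 0.81) < 1e-12

    def test_all_one_scores(self):
        assert abs(margin_loss(1.0, 1.0, "positive") - 0.405) < 1e-12

    def test_zero_iff_margins_satisfied(self):
        cfg = LossConfig()
        assert margin_loss(0.95, 0.05, "positive", cfg) == 0.0
        assert margin_loss(0.85, 0.05, "positive", cfg) > 0.0
        assert margin_loss(0.95, 0.15, "positive", cfg) > 0.0
        assert margin_loss(0.05, 0.95, "negative", cfg) == 0.0

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            margin_loss(0.5, 0.5, "maybe")


# ---------------------------------------------------------------------------
# Forward pass and persistence


def small_config(**kw):
    kw.setdefault("input_length", 30)
    kw.setdefault("n_filters", 16)
    kw.setdefault("kernel_size", 5)
    return CapsNetConfig(**kw)


class TestForward:
    def test_scores_in_unit_interval(self):
        net = CapsuleNetwork(small_config(), seed=0)
        m = encode_sequence("ACGT" * 7 + "AC")
        sp, sn = net.forward(m)
        assert 0.0 <= sp < 1.0 and 0.0 <= sn < 1.0

    def test_two_digit_capsules(self):
        net = CapsuleNetwork(small_config(), seed=0)
        X = np.random.default_rng(0).random((3, 30, 4))
        assert net.forward_tensor(X).shape == (3, 2)

    def test_forward_deterministic(self):
        net = CapsuleNetwork(small_config(), seed=1)
        m = encode_sequence("ACGTN" * 6)
        assert net.forward(m) == net.forward(m)

    def test_shape_mismatch_rejected(self):
        net = CapsuleNetwork(small_config(), seed=0)
        with pytest.raises(ValueError):
            net.forward(encode_sequence("ACGT"))

    def test_permutation_covariance_in_filters(self):
        """Permuting filters together with capsule wiring leaves scores fixed."""
        cfg = small_config(n_filters=16, caps_dim=8)  # 2 primary capsules
        net = CapsuleNetwork(cfg, seed=3)
        m = encode_sequence("ACGTTGCA" * 3 + "ACGTTG")
        before = net.forward(m)
        # swap the two 8-filter blocks and the corresponding capsule rows
        perm = np.r_[8:16, 0:8]
        net.params["conv_w"].data = net.params["conv_w"].data[perm]
        net.params["conv_b"].data = net.params["conv_b"].data[perm]
        net.params["caps_w"].data = net.params["caps_w"].data[[1, 0]]
        after = net.forward(m)
        np.testing.assert_allclose(after, before, atol=1e-12)

    def test_checkpoint_roundtrip_bit_for_bit(self, tmp_path):
        net = CapsuleNetwork(small_config(routing_iters=3, maxpool=False), seed=5)
        m = encode_sequence("ACGGTTCA" * 3 + "TTACGA")
        path = tmp_path / "model.npz"
        net.save(path)
        clone = CapsuleNetwork.load(path)
        assert clone.config == net.config
        assert clone.forward(m) == net.forward(m)


class TestConfigValidation:
    def test_fragment_shorter_than_window(self):
        with pytest.raises(ValueError):
            CapsNetConfig(input_length=5, kernel_size=9)

    def test_filters_must_divide_into_capsules(self):
        with pytest.raises(ValueError):
            CapsNetConfig(input_length=30, n_filters=12, caps_dim=8)

    def test_capsule_geometry(self):
        cfg = CapsNetConfig(input_length=50, n_filters=128)
        assert cfg.n_primary == 16
        cfg2 = CapsNetConfig(input_length=50, n_filters=128, maxpool=False)
        assert cfg2.n_primary == 128 * 42 // 8
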