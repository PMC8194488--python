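import math

import numpy as np
import pytest

from emoser.model import (Adam, EmotionModel, ModelConfig, ShapeError,
                          TrainConfig, _conv2d_forward,
                          _residual_block_forward, _tree_get, _tree_iter,
                          attention_pool, bilstm_forward, cross_entropy,
                          lstm_step, softmax, train)


def brute_force_conv(x, W, b):
    """Independent direct same-padded convolution (loop oracle)."""
    kh, kw, cin, cout = W.shape
    t, f, _ = x.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((t, f, cout))
    for i in range(t):
        for j in range(f):
            for di in range(kh):
                for dj in range(kw):
                    ii, jj = i + di - ph, j + dj - pw
                    if 0 <= ii < t and 0 <= jj < f:
                        out[i, j] += x[ii, jj] @ W[di, dj]
    return out + b


def _lstm_params(rng, d, h):
    p = {}
    for g in ("f", "i", "c", "o"):
        if g != "c":
            p[f"Wc{g}"] = rng.normal(scale=0.3, size=(h, h))
        p[f"Wh{g}"] = rng.normal(scale=0.3, size=(h, h))
        p[f"Wx{g}"] = rng.normal(scale=0.3, size=(d, h))
        p[f"b{g}"] = rng.normal(scale=0.3, size=h)
    return p


# ---------------------------------------------------------------------------
# convolutional front


def test_conv_matches_brute_force_oracle(rng):
    x = rng.normal(size=(5, 6, 3))
    W = rng.normal(size=(3, 3, 3, 4))
    b = rng.normal(size=4)
    out, _ = _conv2d_forward(x, W, b)
    np.testing.assert_allclose(out, brute_force_conv(x, W, b), atol=1e-5)


def test_residual_block_shape(rng):
    p = {"W1": rng.normal(size=(3, 3, 8, 8)) * 0.1, "b1": np.zeros(8),
         "W2": rng.normal(size=(3, 3, 8, 8)) * 0.1, "b2": np.zeros(8)}
    out, _ = _residual_block_forward(rng.normal(size=(8, 16, 8)), p, 2, 4)
    assert out.shape == (4, 4, 8)


def test_residual_block_zero_convs_pass_input_through(rng):
    """With all-zero conv weights the pre-pool activation is relu(x):
    the skip path is the additive identity."""
    p = {"W1": np.zeros((3, 3, 4, 4)), "b1": np.zeros(4),
         "W2": np.zeros((3, 3, 4, 4)), "b2": np.zeros(4)}
    x = np.abs(rng.normal(size=(4, 8, 4)))  # positive, so relu(x) == x
    out, _ = _residual_block_forward(x, p, 2, 4)
    expected = x.reshape(2, 2, 2, 4, 4).max(axis=(1, 3))
    np.testing.assert_allclose(out, expected)


def test_residual_block_rejects_too_small_maps(rng):
    p = {"W1": np.zeros((3, 3, 4, 4)), "b1": np.zeros(4),
         "W2": np.zeros((3, 3, 4, 4)), "b2": np.zeros(4)}
    with pytest.raises(ShapeError):
        _residual_block_forward(rng.normal(size=(1, 8, 4)), p, 2, 4)


def test_rescnn_sequence_geometry(rng):
    """64 Mel bands collapse to one after three 4x poolings, so each
    frame-step vector has exactly conv_channels entries; 80 frames halve
    three times to 10 steps; block counts scale the length 4:1."""
    cfg3 = ModelConfig(n_classes=3, n_mels=64, conv_channels=8, n_blocks=3,
                       lstm_hidden=4, seed=0)
    m3 = EmotionModel(cfg3)
    v = rng.normal(size=(80, 64, 3))
    seq3 = m3.rescnn_forward(v)
    assert seq3.shape == (10, 8)
    cfg1 = ModelConfig(n_classes=3, n_mels=64, conv_channels=8, n_blocks=1,
                       lstm_hidden=4, seed=0)
    seq1 = EmotionModel(cfg1).rescnn_forward(v)
    assert seq1.shape[0] == 4 * seq3.shape[0]


# ---------------------------------------------------------------------------
# LSTM


def test_lstm_step_zero_weights_closed_form():
    """All-zero parameters: every gate is sigma(0)=0.5, the candidate is
    tanh(0)=0, so c_t = 0.5 c_prev and h_t = 0.5 tanh(c_t)."""
    h = 3
    p = {f"W{a}{g}": np.zeros((h, h)) for a in "chx" for g in "fio"}
    p.update({f"Wh{g}": np.zeros((h, h)) for g in "fico"})
    p.update({f"Wx{g}": np.zeros((h, h)) for g in "fico"})
    p.update({f"b{g}": np.zeros(h) for g in "fico"})
    c_prev = np.array([0.4, -1.0, 2.0])
    h_t, c_t = lstm_step(np.zeros(h), np.zeros(h), c_prev, p)
    np.testing.assert_allclose(c_t, 0.5 * c_prev)
    np.testing.assert_allclose(h_t, 0.5 * np.tanh(0.5 * c_prev))


def test_lstm_step_scalar_hand_computation():
    """One scalar step against direct evaluation of the gate equations."""
    w = dict(Wcf=0.1, Whf=0.2, Wxf=0.3, bf=0.05, Wci=-0.1, Whi=0.15,
             Wxi=0.25, bi=-0.05, Whc=0.4, Wxc=0.5, bc=0.0, Wco=0.2,
             Who=-0.3, Wxo=0.1, bo=0.1)
    p = {k: np.array([[v]]) if k[0] == "W" else np.array([v])
         for k, v in w.items()}
    x, hp, cp = 0.7, -0.2, 0.5

    def sig(z):
        return 1.0 / (1.0 + math.exp(-z))

    f = sig(w["Wcf"] * cp + w["Whf"] * hp + w["Wxf"] * x + w["bf"])
    i = sig(w["Wci"] * cp + w["Whi"] * hp + w["Wxi"] * x + w["bi"])
    g = math.tanh(w["Whc"] * hp + w["Wxc"] * x + w["bc"])
    c = f * cp + i * g
    o = sig(w["Wco"] * c + w["Who"] * hp + w["Wxo"] * x + w["bo"])
    h_expected = o * math.tanh(c)

    h_t, c_t = lstm_step(np.array([x]), np.array([hp]), np.array([cp]), p)
    assert c_t[0] == pytest.approx(c, abs=1e-12)
    assert h_t[0] == pytest.approx(h_expected, abs=1e-12)


def test_lstm_hidden_state_bounded(rng):
    p = _lstm_params(rng, 4, 6)
    h, c = np.zeros(6), np.zeros(6)
    for _ in range(20):
        h, c = lstm_step(rng.normal(scale=5.0, size=4), h, c, p)
        assert np.all(np.abs(h) < 1.0)


# ---------------------------------------------------------------------------
# Bi-LSTM


def test_bilstm_output_width_is_twice_hidden(rng):
    pf, pb = _lstm_params(rng, 5, 128), _lstm_params(rng, 5, 128)
    hs = bilstm_forward(rng.normal(size=(7, 5)), pf, pb)
    assert hs.shape == (7, 256)


def test_bilstm_length_one_sees_same_element(rng):
    pf, pb = _lstm_params(rng, 4, 3), _lstm_params(rng, 4, 3)
    x = rng.normal(size=(1, 4))
    hs = bilstm_forward(x, pf, pb)
    hf, _ = lstm_step(x[0], np.zeros(3), np.zeros(3), pf)
    hb, _ = lstm_step(x[0], np.zeros(3), np.zeros(3), pb)
    np.testing.assert_allclose(hs[0], np.concatenate([hf, hb]))


def test_bilstm_palindrome_symmetry_with_tied_weights(rng):
    """With tied directions and a palindromic input, the forward half of
    the output equals the reversed backward half."""
    p = _lstm_params(rng, 4, 3)
    half = rng.normal(size=(4, 4))
    seq = np.concatenate([half, half[::-1]])
    hs = bilstm_forward(seq, p, p)
    np.testing.assert_allclose(hs[:, :3], hs[::-1, 3:], atol=1e-12)


def test_bilstm_rejects_empty_sequence(rng):
    p = _lstm_params(rng, 4, 3)
    with pytest.raises(ValueError):
        bilstm_forward(np.empty((0, 4)), p, p)


# ---------------------------------------------------------------------------
# attention


def test_attention_uniform_for_identical_steps(rng):
    h = rng.normal(size=4)
    hs = np.tile(h, (6, 1))
    r, alphas = attention_pool(hs, rng.normal(size=4), 0.3)
    np.testing.assert_allclose(alphas, 1 / 6)
    np.testing.assert_allclose(r, h, atol=1e-12)


def test_attention_hand_computation_t2():
    w, b = np.array([1.0, -2.0]), 0.5
    hs = np.array([[0.3, 0.1], [-0.4, 0.6]])

    def sig(z):
        return 1.0 / (1.0 + math.exp(-z))

    s = [sig(0.3 - 0.2 + 0.5), sig(-0.4 - 1.2 + 0.5)]
    e = [math.exp(v) for v in s]
    a_expected = np.array(e) / sum(e)
    r_expected = a_expected @ hs

    r, alphas = attention_pool(hs, w, b)
    np.testing.assert_allclose(alphas, a_expected, atol=1e-12)
    np.testing.assert_allclose(r, r_expected, atol=1e-12)


def test_attention_weights_sum_to_one_and_bounded_ratio(rng):
    """Scores pass through a sigmoid before the softmax, so the exponent
    spans less than one unit: max(alpha)/min(alpha) < e."""
    for _ in range(20):
        hs = rng.normal(scale=4.0, size=(rng.integers(2, 12), 6))
        _, alphas = attention_pool(hs, rng.normal(size=6), rng.normal())
        assert alphas.sum() == pytest.approx(1.0, abs=1e-6)
        assert alphas.max() / alphas.min() < math.e


def test_attention_tanh_variant_escapes_the_bound(rng):
    """The non-default tanh scoring spans 2 units, allowing sharper
    weightings than the sigmoid form."""
    hs = np.array([[10.0], [-10.0]])
    _, a_sig = attention_pool(hs, np.array([1.0]), 0.0, variant="sigmoid")
    _, a_tanh = attention_pool(hs, np.array([1.0]), 0.0, variant="tanh")
    assert a_tanh.max() / a_tanh.min() > a_sig.max() / a_sig.min()


# ---------------------------------------------------------------------------
# classifier head and loss


def test_zero_weight_classifier_is_uniform():
    cfg = ModelConfig(n_classes=5, n_mels=16, conv_channels=4, n_blocks=1,
                      lstm_hidden=3, fc_hidden=4, seed=0)
    m = EmotionModel(cfg)
    for leaf_path, leaf in _tree_iter(m.params):
        leaf[...] = 0.0
    probs = m.classify(np.ones(2 * cfg.lstm_hidden))
    np.testing.assert_allclose(probs, 0.2)


def test_softmax_shift_invariance_and_oracle(rng):
    z = rng.normal(size=7)
    np.testing.assert_allclose(softmax(z), softmax(z + 100.0), atol=1e-12)
    oracle = np.exp(z) / np.exp(z).sum()
    np.testing.assert_allclose(softmax(z), oracle, atol=1e-6)


def test_cross_entropy_cases():
    eye = np.eye(4)
    assert cross_entropy(eye, eye) == pytest.approx(0.0, abs=1e-9)
    assert cross_entropy(np.full((3, 7), 1 / 7), np.eye(7)[:3]) == \
        pytest.approx(np.log(7))
    # N=2 hand case: -(log .6 + log .3)/2
    probs = np.array([[0.6, 0.4], [0.7, 0.3]])
    targets = np.array([[1, 0], [0, 1]])
    expected = -(math.log(0.6) + math.log(0.3)) / 2
    assert cross_entropy(probs, targets) == pytest.approx(expected)


def test_cross_entropy_floors_zero_probability():
    assert np.isfinite(cross_entropy(np.array([[1.0, 0.0]]),
                                     np.array([[0.0, 1.0]])))


def test_prediction_invariants(rng):
    cfg = ModelConfig(n_classes=4, n_mels=16, conv_channels=4, n_blocks=1,
                      lstm_hidden=3, fc_hidden=4, seed=3)
    m = EmotionModel(cfg)
    pred = m.predict(rng.normal(size=(8, 16, 3)))
    assert pred.probs.sum() == pytest.approx(1.0, abs=1e-6)
    assert pred.attention_weights.sum() == pytest.approx(1.0, abs=1e-6)
    assert 0 <= pred.label < 4


# ---------------------------------------------------------------------------
# gradients and training


def test_backprop_matches_numerical_gradient(rng):
    """Analytic gradients of the full network against central differences."""
    cfg = ModelConfig(n_classes=3, n_mels=8, in_channels=2, conv_channels=4,
                      n_blocks=1, lstm_hidden=3, fc_hidden=5, seed=1)
    m = EmotionModel(cfg)
    v = rng.normal(size=(6, 8, 2))
    y = 1

    def loss():
        probs, _, _ = m._forward(v)
        return -np.log(probs[y])

    _, grads = m.loss_and_grads([v], [y])
    eps = 1e-5
    for path, leaf in _tree_iter(m.params):
        flat = leaf.reshape(-1) if leaf.ndim else leaf.reshape(1)
        gflat = _tree_get(grads, path)
        gflat = gflat.reshape(-1) if gflat.ndim else gflat.reshape(1)
        for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss()
            flat[i] = orig - eps
            lm = loss()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - gflat[i]) <= 1e-4 * max(1.0, abs(num)), path


def test_checkpoint_roundtrip(tmp_path, rng):
    cfg = ModelConfig(n_classes=3, n_mels=16, conv_channels=4, n_blocks=1,
                      lstm_hidden=3, fc_hidden=4, seed=2)
    m = EmotionModel(cfg)
    v = rng.normal(size=(8, 16, 3))
    m.save(tmp_path / "ckpt")
    m2 = EmotionModel.load(tmp_path / "ckpt")
    np.testing.assert_allclose(m.predict(v).probs, m2.predict(v).probs)


def _tiny_separable_data(rng, n_per_class=6):
    """Class identity written into disjoint Mel bands."""
    feats, labels = [], []
    for cls in range(2):
        for _ in range(n_per_class):
            v = rng.normal(scale=0.1, size=(8, 16, 3))
            v[:, 4 + 8 * cls: 8 + 8 * cls, 0] += 3.0
            feats.append(v)
            labels.append(cls)
    return feats, labels


def test_training_decreases_loss(rng):
    feats, labels = _tiny_separable_data(rng)
    cfg = ModelConfig(n_classes=2, n_mels=16, conv_channels=6, n_blocks=1,
                      lstm_hidden=6, fc_hidden=8, seed=0)
    _, state = train(feats, labels, cfg, TrainConfig(epochs=10, batch_size=4,
                                                     seed=0))
    assert state.loss_history[-1] < state.loss_history[0]
    assert len(state.loss_history) == 10
    assert all(np.isfinite(state.loss_history))


def test_full_batch_training_invariant_to_duplication(rng):
    """Duplicating every sample leaves full-batch gradients (and hence the
    whole Adam trajectory) unchanged."""
    feats, labels = _tiny_separable_data(rng, n_per_class=3)
    cfg = ModelConfig(n_classes=2, n_mels=16, conv_channels=4, n_blocks=1,
                      lstm_hidden=4, fc_hidden=4, seed=0)
    tc = TrainConfig(epochs=3, batch_size=64, seed=0)
    m1, _ = train(feats, labels, cfg, tc)
    m2, _ = train(feats * 2, labels * 2, cfg, tc)
    for path, leaf in _tree_iter(m1.params):
        np.testing.assert_allclose(leaf, _tree_get(m2.params, path),
                                   atol=1e-10, err_msg=str(path))


def test_training_deterministic_given_seed(rng):
    feats, labels = _tiny_separable_data(rng, n_per_class=3)
    cfg = ModelConfig(n_classes=2, n_mels=16, conv_channels=4, n_blocks=1,
                      lstm_hidden=4, fc_hidden=4, seed=0)
    tc = TrainConfig(epochs=2, batch_size=4, seed=9)
    m1, s1 = train(feats, labels, cfg, tc)
    m2, s2 = train(feats, labels, cfg, tc)
    assert s1.loss_history == s2.loss_history
    for path, leaf in _tree_iter(m1.params):
        np.testing.assert_array_equal(leaf, _tree_get(m2.params, path))


def test_training_warns_on_missing_class(rng):
    feats, labels = _tiny_separable_data(rng, n_per_class=3)
    cfg = ModelConfig(n_classes=3, n_mels=16, conv_channels=4, n_blocks=1,
                      lstm_hidden=4, fc_hidden=4, seed=0)
    with pytest.warns(UserWarning, match="absent"):
        train(feats, labels, cfg, TrainConfig(epochs=1, batch_size=4, seed=0))
    from emoser.model import DegenerateClassError
    with pytest.raises(DegenerateClassError):
        train(feats, labels, cfg, TrainConfig(epochs=1, seed=0),
              strict_classes=True)
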