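import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hierattn.nn import Adam, HierAttnNet, ModelConfig, masked_softmax
from hierattn.nn.functional import masked_softmax_backward

from conftest import random_masked_batch


class TestMaskedSoftmax:
    def test_single_unmasked_entry_gets_all_weight(self):
        w = masked_softmax(np.array([3.0, -1.0, 2.0]), np.array([0, 1, 0]))
        np.testing.assert_allclose(w, [0, 1, 0])

    def test_equal_scores_uniform_over_unmasked(self):
        w = masked_softmax(np.zeros(5), np.array([1, 0, 1, 1, 0]))
        np.testing.assert_allclose(w, [1 / 3, 0, 1 / 3, 1 / 3, 0])

    def test_two_term_softmax_value(self):
        w = masked_softmax(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        np.testing.assert_allclose(w, [0.1192, 0.0, 0.8808], atol=1e-4)

    def test_all_masked_yields_zeros(self):
        w = masked_softmax(np.array([1.0, 2.0]), np.array([0, 0]))
        np.testing.assert_allclose(w, [0.0, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_normalization_and_invariance_properties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal((4, 7))
        mask = (rng.random((4, 7)) > 0.4).astype(float)
        w = masked_softmax(scores, mask)
        assert (w >= 0).all()
        assert (w[mask == 0] == 0).all()
        sums = w.sum(axis=1)
        has = mask.sum(axis=1) > 0
        np.testing.assert_allclose(sums[has], 1.0, atol=1e-6)
        np.testing.assert_allclose(sums[~has], 0.0)
        # shift invariance of the softmax restricted to the mask
        w2 = masked_softmax(scores + 5.0, mask)
        np.testing.assert_allclose(w, w2, atol=1e-6)


def _tiny_net(rnn_type, dense, seed=1):
    cfg = ModelConfig(rnn_type=rnn_type, units=6, dense_before_output=dense,
                      n_variables=5, n_static=2, t_max=4, embed_dim=3,
                      attn_dim=4, seed=seed)
    net = HierAttnNet(cfg, dtype=np.float64)
    net.params = {k: v.astype(np.float64) for k, v in net.params.items()}
    return net


@pytest.mark.parametrize("rnn_type", ["GRU", "LSTM"])
@pytest.mark.parametrize("dense", [0, 1])
def test_backward_matches_finite_differences(rnn_type, dense):
    """Hand-coded backprop equals central finite differences on every
    parameter of a tiny network."""
    rng = np.random.default_rng(0)
    net = _tiny_net(rnn_type, dense)
    x, mv, mt, s = random_masked_batch(rng, 3, 4, 5, dtype=np.float64)
    y = rng.integers(0, 2, 3).astype(float)
    _, grads, _ = net.loss_and_grads(x, mv, mt, s, y)
    eps = 1e-5
    for name, p in net.params.items():
        flat = p.ravel()
        check = np.linspace(0, flat.size - 1, min(flat.size, 12)).astype(int)
        for i in check:
            old = flat[i]
            flat[i] = old + eps
            fp = net.loss_and_grads(x, mv, mt, s, y)[0]
            flat[i] = old - eps
            fm = net.loss_and_grads(x, mv, mt, s, y)[0]
            flat[i] = old
            num = (fp - fm) / (2 * eps)
            ana = np.asarray(grads[name]).ravel()[i]
            assert num == pytest.approx(ana, rel=5e-3, abs=1e-7), \
                f"{name}[{i}]: numeric {num} vs analytic {ana}"


def test_padding_invariance_over_seeded_patients():
    """Adding all-padded periods changes predictions by <= 1e-5 for 100
    random patients."""
    rng = np.random.default_rng(42)
    cfg = ModelConfig(units=16, n_variables=12, n_static=2, t_max=5,
                      embed_dim=4, attn_dim=8, seed=3)
    net = HierAttnNet(cfg)
    x, mv, mt, s = random_masked_batch(rng, 100, 5, 12)
    out1, _ = net.forward(x, mv, mt, s)
    k = 3
    pad = lambda a: np.pad(a, [(0, 0), (k, 0)] + [(0, 0)] * (a.ndim - 2))
    out2, _ = net.forward(pad(x), pad(mv), pad(mt), s)
    assert np.abs(out1.p - out2.p).max() <= 1e-5


def test_missing_value_invariance_is_exact():
    """Perturbing feature values at masked positions changes nothing: the
    masks zero them before they enter the network."""
    rng = np.random.default_rng(7)
    cfg = ModelConfig(units=16, n_variables=12, n_static=2, t_max=5,
                      embed_dim=4, attn_dim=8, seed=3)
    net = HierAttnNet(cfg)
    x, mv, mt, s = random_masked_batch(rng, 20, 5, 12)
    out1, _ = net.forward(x, mv, mt, s)
    x2 = x + (1 - mv) * rng.standard_normal(x.shape).astype(np.float32) * 100
    out2, _ = net.forward(x2, mv, mt, s)
    np.testing.assert_array_equal(out1.p, out2.p)


def test_attention_weights_normalized_and_masked():
    rng = np.random.default_rng(11)
    cfg = ModelConfig(units=8, n_variables=10, n_static=2, t_max=6,
                      embed_dim=4, attn_dim=8, seed=5)
    net = HierAttnNet(cfg)
    x, mv, mt, s = random_masked_batch(rng, 50, 6, 10)
    out, _ = net.forward(x, mv, mt, s)
    assert (out.alpha >= 0).all() and (out.beta >= 0).all()
    assert (out.alpha[mv == 0] == 0).all()
    assert (out.beta[mt == 0] == 0).all()
    alpha_sums = out.alpha.sum(axis=2)
    real = (mt > 0) & (mv.sum(axis=2) > 0)
    np.testing.assert_allclose(alpha_sums[real], 1.0, atol=1e-5)
    np.testing.assert_allclose(out.beta.sum(axis=1), 1.0, atol=1e-5)


def test_probabilities_in_unit_interval_and_deterministic():
    rng = np.random.default_rng(2)
    cfg = ModelConfig(units=8, n_variables=10, n_static=2, t_max=4, seed=9)
    x, mv, mt, s = random_masked_batch(rng, 30, 4, 10)
    p1 = HierAttnNet(cfg).forward(x, mv, mt, s)[0].p
    p2 = HierAttnNet(cfg).forward(x, mv, mt, s)[0].p
    assert ((p1 >= 0) & (p1 <= 1)).all()
    np.testing.assert_array_equal(p1, p2)


def test_degenerate_period_all_variables_missing(caplog):
    """A real period with every variable missing gets zero attention and a
    zero context, with a warning."""
    cfg = ModelConfig(units=8, n_variables=6, n_static=2, t_max=3, seed=0)
    net = HierAttnNet(cfg)
    x = np.zeros((1, 3, 6), np.float32)
    mt = np.ones((1, 3), np.float32)
    mv = np.ones((1, 3, 6), np.float32)
    mv[0, 1] = 0                                  # middle period: nothing recorded
    with caplog.at_level("WARNING"):
        out, cache = net.forward(x, mv, mt, x[:, 0, :2], need_cache=True)
    assert (out.alpha[0, 1] == 0).all()
    assert (cache["C"][0, 1] == 0).all()
    assert "missing" in caplog.text


def test_single_real_period_gets_unit_time_attention():
    cfg = ModelConfig(units=8, n_variables=6, n_static=2, t_max=4, seed=0)
    net = HierAttnNet(cfg)
    rng = np.random.default_rng(0)
    x, mv, mt, s = random_masked_batch(rng, 8, 4, 6)
    mt[0] = np.array([0, 0, 0, 1], np.float32)
    mv[0] *= mt[0][:, None]
    x[0] *= mv[0]
    out, _ = net.forward(x, mv, mt, s)
    np.testing.assert_allclose(out.beta[0], [0, 0, 0, 1], atol=1e-6)


def test_all_periods_padded_is_an_error():
    cfg = ModelConfig(units=8, n_variables=6, n_static=2, t_max=3, seed=0)
    net = HierAttnNet(cfg)
    x = np.zeros((1, 3, 6), np.float32)
    with pytest.raises(ValueError, match="real period"):
        net.forward(x, x.copy(), np.zeros((1, 3), np.float32), x[:, 0, :2])


def test_masked_softmax_backward_matches_numeric():
    rng = np.random.default_rng(3)
    scores = rng.standard_normal(6)
    mask = np.array([1, 1, 0, 1, 0, 1.0])
    dw = rng.standard_normal(6)
    w = masked_softmax(scores, mask)
    ana = masked_softmax_backward(w, dw)
    eps = 1e-6
    for i in range(6):
        sp = scores.copy(); sp[i] += eps
        sm = scores.copy(); sm[i] -= eps
        num = ((masked_softmax(sp, mask) - masked_softmax(sm, mask)) / (2 * eps)) @ dw
        assert num == pytest.approx(ana[i], abs=1e-5)


def test_capacity_on_linearly_separable_task():
    """A 16-unit model reaches training ROC-AUC >= 0.99 within 20 epochs on a
    noise-free one-variable task."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(0)
    n, t, v = 256, 3, 5
    x, mv, mt, s = random_masked_batch(rng, n, t, v, missing=0.0)
    y = (x[:, -1, 0] > 0).astype(float)
    cfg = ModelConfig(units=16, n_variables=v, n_static=2, t_max=t,
                      embed_dim=4, attn_dim=8, seed=1)
    net = HierAttnNet(cfg)
    opt = Adam(net.params, lr=1e-2)
    for epoch in range(20):
        order = rng.permutation(n)
        for lo in range(0, n, 32):
            rows = order[lo:lo + 32]
            _, grads, _ = net.loss_and_grads(x[rows], mv[rows], mt[rows],
                                             s[rows], y[rows])
            opt.step(grads)
        out, _ = net.forward(x, mv, mt, s)
        if roc_auc_score(y, out.p) >= 0.99:
            break
    out, _ = net.forward(x, mv, mt, s)
    assert roc_auc_score(y, out.p) >= 0.99


def test_parameter_save_load_round_trip(tmp_path):
    cfg = ModelConfig(units=8, n_variables=6, n_static=2, t_max=3, seed=4)
    net = HierAttnNet(cfg)
    net.save(tmp_path / "params")
    back = HierAttnNet.load(tmp_path / "params")
    assert back.config == cfg
    for k, v in net.params.items():
        np.testing.assert_array_equal(back.params[k], v)
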