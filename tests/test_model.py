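"""Network components: layers, temporal attention, focal loss, capacity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bspmaf.errors import ConfigurationError
from bspmaf.model import (
    Adam,
    AttentionConfig,
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    NetworkConfig,
    TemporalAttention,
    Tensor,
    build_network,
    cross_entropy_loss,
    focal_loss,
    predict,
    sequences_to_batch,
)


def small_cfg(**kw):
    defaults = dict(input_hwt=(16, 16, 16), base_channels=2, dense_dim=32, dense_hidden=8)
    defaults.update(kw)
    return NetworkConfig(**defaults)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def test_conv3d_matches_direct_convolution(rng):
    """im2col convolution equals a brute-force triple-loop convolution."""
    x = rng.normal(size=(1, 2, 4, 4, 4))
    conv = Conv3d(2, 3, kernel=3, stride=1, rng=rng)
    out = conv(Tensor(x)).data
    w = conv.weight.data.reshape(3, 2, 3, 3, 3)
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    expected = np.zeros_like(out)
    for o in range(3):
        for t in range(4):
            for i in range(4):
                for j in range(4):
                    patch = xp[0, :, t : t + 3, i : i + 3, j : j + 3]
                    expected[0, o, t, i, j] = (patch * w[o]).sum() + conv.bias.data[o]
    np.testing.assert_allclose(out, expected, rtol=1e-10, atol=1e-12)


def test_up_convolution_doubles_dims_and_scatters_blocks(rng):
    up = ConvTranspose3d(2, 1, rng=rng)
    x = rng.normal(size=(1, 2, 2, 3, 2))
    y = up(Tensor(x)).data
    assert y.shape == (1, 1, 4, 6, 4)
    # each input voxel populates its own 2x2x2 output block
    w = up.weight.data.reshape(2, 1, 2, 2, 2)
    expected = x[0, 0, 1, 2, 0] * w[0, 0] + x[0, 1, 1, 2, 0] * w[1, 0] + up.bias.data[0]
    np.testing.assert_allclose(y[0, 0, 2:4, 4:6, 0:2], expected, rtol=1e-12)


def test_batchnorm_normalizes_and_tracks_running_stats(rng):
    bn = BatchNorm3d(3)
    x = Tensor(rng.normal(5.0, 2.0, (4, 3, 2, 2, 2)))
    y = bn(x).data
    assert abs(y.mean()) < 1e-8 and abs(y.std() - 1.0) < 1e-2
    bn.eval()
    y2 = bn(x).data  # running stats differ from batch stats after one update
    assert not np.allclose(y, y2)


# ---------------------------------------------------------------------------
# temporal attention
# ---------------------------------------------------------------------------

def attention_oracle(avg, mx, w1, w2):
    """Independent matrix arithmetic for the gate:
    sigmoid(MLP(center(avg)) + MLP(center(mx))) with a rectifier MLP."""
    def mlp(s):
        return np.maximum((s - s.mean()) @ w1, 0.0) @ w2

    return 1.0 / (1.0 + np.exp(-(mlp(avg) + mlp(mx))))


def test_attention_gate_matches_matrix_oracle():
    """T=4, r=4 (hidden 1), hand-set perceptron, C=1 identity squeeze."""
    att = TemporalAttention(1, 4, AttentionConfig(reduction_r=4), rng=np.random.default_rng(0))
    w1 = np.array([[0.0], [0.0], [0.0], [1.0]])
    w2 = np.array([[1.0, 0.0, -1.0, 2.0]])
    att.w1.data = w1.copy()
    att.w2.data = w2.copy()
    att.squeeze.weight.data = np.ones((1, 1))
    att.squeeze.bias.data = np.zeros(1)
    # frames with spatial means (1,2,3,4) and maxes (2,3,4,5)
    frames = np.zeros((1, 1, 4, 2, 2))
    for t in range(4):
        frames[0, 0, t] = [[t + 1.0, t + 1.0], [t - 1.0, t + 3.0]]
    gate = att.gate(Tensor(frames)).data[0]
    expected = attention_oracle(
        np.array([1.0, 2.0, 3.0, 4.0]), np.array([2.0, 3.0, 4.0, 5.0]), w1, w2
    )
    # hand check: centered stats are (-1.5,-0.5,0.5,1.5) for both pools,
    # hidden = relu(1.5), scores = 2 * 1.5 * (1,0,-1,2) -> sigmoid
    np.testing.assert_allclose(expected, 1 / (1 + np.exp(-np.array([3.0, 0, -3, 6]))))
    np.testing.assert_allclose(gate, expected, rtol=1e-12)


@pytest.mark.parametrize("variant", ["block", "A1", "A2", "A3"])
def test_attention_gate_in_unit_interval_and_rescales_frames(variant, rng):
    att = TemporalAttention(3, 8, AttentionConfig(variant=variant), rng=rng)
    x = rng.normal(size=(2, 3, 8, 4, 4))
    gate = att.gate(Tensor(x)).data
    assert gate.shape == (2, 8)
    assert np.all((gate > 0.0) & (gate < 1.0))
    out = att(Tensor(x)).data
    np.testing.assert_allclose(out, x * gate[:, None, :, None, None], rtol=1e-12)


@pytest.mark.parametrize("variant", ["block", "A1", "A2", "A3"])
def test_attention_uniform_gate_for_time_constant_input(variant, rng):
    att = TemporalAttention(2, 8, AttentionConfig(variant=variant), rng=rng)
    frame = rng.normal(size=(1, 2, 1, 5, 5))
    x = np.repeat(frame, 8, axis=2)  # identical frames
    gate = att.gate(Tensor(x)).data[0]
    np.testing.assert_allclose(gate, gate[0], rtol=1e-12)


def test_attention_learns_to_upweight_informative_frames(rng):
    """Trained on a task where only frames 4..7 differ between classes, the
    gate should end up larger on the informative frames."""
    n, t = 24, 16
    x = rng.uniform(0.4, 0.6, size=(n, 8, 8, t))
    y = np.arange(n) % 2
    for i in range(n):
        if y[i] == 1:
            x[i, :4, :4, 4:8] += 0.4  # class signal confined to frames 4..7
    cfg = small_cfg(input_hwt=(8, 8, 16))
    net = build_network(cfg, seed=0)
    opt = Adam(net.parameters(), lr0=3e-3)
    for _ in range(30):
        probs = net.predict_proba(sequences_to_batch(x))
        loss = net.loss(probs, y)
        net.zero_grad()
        loss.backward()
        opt.step()
    deep_t = t // 8
    # at T/8 = 2 deep frames, informative frames 4..7 map to deep frame 0 vs 1
    net.eval()
    f1 = net.contract(sequences_to_batch(x))[3]
    gates = net.attention.gate(f1).data
    assert gates.shape == (n, deep_t)
    assert gates[:, 0].mean() > gates[:, 1].mean()


# ---------------------------------------------------------------------------
# focal loss
# ---------------------------------------------------------------------------

def test_focal_loss_hand_computed_points():
    p = Tensor(np.array([0.5]))
    assert float(focal_loss(p, np.array([1]), alpha=0.5, gamma=0.0).data) == pytest.approx(
        0.5 * -np.log(0.5), rel=1e-6
    )
    p = Tensor(np.array([0.9]))
    assert float(focal_loss(p, np.array([1]), alpha=0.25, gamma=2.0).data) == pytest.approx(
        -0.25 * 0.01 * np.log(0.9), rel=1e-6
    )


def test_focal_loss_vanishes_for_confident_correct_prediction():
    p = Tensor(np.array([1.0 - 1e-9]))
    assert float(focal_loss(p, np.array([1])).data) < 1e-6


@settings(max_examples=50, deadline=None)
@given(
    p=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=8),
    bits=st.lists(st.booleans(), min_size=8, max_size=8),
)
def test_focal_gamma0_alpha_half_is_half_cross_entropy(p, bits):
    y = np.array([1 if b else -1 for b in bits[: len(p)]])
    pt = Tensor(np.array(p))
    fl = float(focal_loss(pt, y, alpha=0.5, gamma=0.0).data)
    ce = float(cross_entropy_loss(pt, y).data)
    assert fl == pytest.approx(0.5 * ce, rel=1e-9)


def test_focal_loss_clamps_degenerate_probabilities():
    p = Tensor(np.array([0.0, 1.0]))
    val = float(focal_loss(p, np.array([1, -1])).data)
    assert np.isfinite(val)


# ---------------------------------------------------------------------------
# network contracts
# ---------------------------------------------------------------------------

def test_network_counts_eight_conv_and_three_fc_layers():
    net = build_network(small_cfg(), seed=0)
    assert net.count_layers() == (8, 3)


def test_forward_probabilities_normalized_and_deterministic(rng):
    net = build_network(small_cfg(), seed=7)
    x = rng.uniform(size=(3, 16, 16, 16))
    p1 = predict(net, x)
    p2 = predict(net, x)
    np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_array_equal(p1, p2)
    # identical inputs give identical rows
    pdup = predict(net, np.stack([x[0], x[0]]))
    np.testing.assert_allclose(pdup[0], pdup[1], atol=1e-12)


def test_same_seed_same_initialization():
    n1, n2 = build_network(small_cfg(), seed=3), build_network(small_cfg(), seed=3)
    for a, b in zip(n1.parameters(), n2.parameters()):
        np.testing.assert_array_equal(a.data, b.data)


def test_input_size_must_match_downsampling_factor():
    with pytest.raises(ConfigurationError):
        NetworkConfig(input_hwt=(20, 16, 16)).validate()


def test_gradient_reaches_input(rng):
    net = build_network(small_cfg(), seed=0)
    x = Tensor(rng.uniform(size=(2, 1, 16, 16, 16)), requires_grad=True)
    loss = net.loss(net.predict_proba(x), np.array([1, 0]))
    loss.backward()
    assert np.abs(x.grad).max() > 0


def test_overfits_eight_labeled_sequences(rng):
    """Capacity check: a tiny separable set is driven to 100% training ACC."""
    x = rng.uniform(0.4, 0.6, size=(8, 16, 16, 16))
    y = np.array([0, 1] * 4)
    x[y == 1, 8:, :, :] += 0.3  # spatially distinct class
    net = build_network(small_cfg(), seed=1)
    net.dropout.rate = 0.0
    opt = Adam(net.parameters(), lr0=3e-3)
    for _ in range(40):
        probs = net.predict_proba(sequences_to_batch(x))
        loss = net.loss(probs, y)
        net.zero_grad()
        loss.backward()
        opt.step()
        if ((predict(net, x)[:, 1] >= 0.5).astype(int) == y).all():
            break
    acc = ((predict(net, x)[:, 1] >= 0.5).astype(int) == y).mean()
    assert acc == 1.0
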