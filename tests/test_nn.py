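"""Network building blocks: gradient correctness, architecture contracts,
attention behaviour, Monte Carlo sampling determinism."""

import numpy as np
import pytest

import brainext as bx
from brainext.errors import ConfigurationError, DimensionError
from brainext.nlunet import (
    ModelConfig,
    build_model,
    forward,
    forward_mc,
    get_attention_map,
    load_checkpoint,
    save_checkpoint,
)
from brainext.nn import layers as L
from brainext.trainer import dice_loss, dice_loss_grad


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.mark.parametrize(
    "make_layer",
    [
        lambda rng: L.Conv2d(3, 4, 3, rng, np.float64),
        lambda rng: L.ConvTranspose2x2(3, 2, rng, np.float64),
        lambda rng: L.BatchNorm2d(3, dtype=np.float64),
        lambda rng: L.ELU(),
        lambda rng: L.Sigmoid(),
        lambda rng: L.NonLocalBlock(3, rng, np.float64),
    ],
    ids=["conv", "convT", "batchnorm", "elu", "sigmoid", "nonlocal"],
)
def test_layer_gradients_match_finite_differences(make_layer):
    rng = np.random.default_rng(0)
    layer = make_layer(rng)
    if isinstance(layer, L.NonLocalBlock):
        layer.w_z.data = rng.normal(size=layer.w_z.data.shape)  # exercise full path
    x = rng.normal(size=(2, 3, 4, 4)).astype(np.float64)
    w = rng.normal(size=layer.forward(x.copy()).shape)

    def loss():
        return float((layer.forward(x) * w).sum())

    loss()
    dx = layer.backward(w.copy())
    assert np.abs(dx - numeric_grad(loss, x)).max() < 1e-5
    for p in layer.params():
        loss()
        layer.backward(w.copy())
        assert np.abs(p.grad - numeric_grad(loss, p.data)).max() < 1e-5


def test_full_model_gradient_matches_finite_differences():
    cfg = ModelConfig(depth=2, base_channels=2, in_plane_size=8,
                      dropout_rate=0.0, seed=3, dtype="float64")
    m = build_model(cfg)
    rng = np.random.default_rng(1)
    x = rng.random((2, 1, 8, 8))
    t = (rng.random((2, 8, 8)) > 0.5).astype(float)

    def loss():
        return dice_loss(m.forward(x, mode="train")[:, 0], t, 1.0)

    p = m.forward(x, mode="train")[:, 0]
    m.backward(dice_loss_grad(p, t, 1.0)[:, None])
    grads = {q.name: q.grad.copy() for q in m.parameters()}
    for q in m.parameters()[:4] + m.parameters()[-2:]:
        assert np.abs(grads[q.name] - numeric_grad(loss, q.data)).max() < 1e-5


def manual_param_count(depth, base, attention=True, head_kernel=3):
    """Layer-by-layer count written out independently of the model code."""
    ch = [base * 2 ** k for k in range(depth)]
    total = 0
    in_ch = 1
    for k in range(depth):  # encoder blocks
        total += ch[k] * in_ch * 9 + ch[k] + 2 * ch[k]  # conv1 + bn1
        total += ch[k] * ch[k] * 9 + ch[k] + 2 * ch[k]  # conv2 + bn2
        in_ch = ch[k]
    if attention:
        inter = max(1, ch[-1] // 2)
        total += 3 * inter * ch[-1] + ch[-1] * inter + ch[-1]
    for k in range(depth - 2, -1, -1):  # decoder
        total += ch[k + 1] * ch[k] * 4 + ch[k]  # transposed conv
        total += ch[k] * 2 * ch[k] * 9 + ch[k] + 2 * ch[k]
        total += ch[k] * ch[k] * 9 + ch[k] + 2 * ch[k]
    total += 1 * ch[0] * head_kernel ** 2 + 1
    return total


class TestArchitecture:
    def test_default_encoder_widths_double_from_16(self):
        assert ModelConfig().channel_widths == (16, 32, 64, 128, 256)

    @pytest.mark.parametrize("depth,base", [(2, 4), (3, 8)])
    def test_param_count_matches_manual_count(self, depth, base):
        cfg = ModelConfig(depth=depth, base_channels=base,
                          in_plane_size=2 ** (depth + 3))
        assert build_model(cfg).param_count() == manual_param_count(depth, base)

    def test_head_kernel_switch(self):
        a = build_model(ModelConfig(depth=2, base_channels=4, in_plane_size=32))
        b = build_model(ModelConfig(depth=2, base_channels=4, in_plane_size=32,
                                    head_kernel=1))
        assert a.param_count() - b.param_count() == 4 * 9 - 4 * 1

    def test_halving_channels_reduces_params(self):
        big = build_model(ModelConfig(depth=3, base_channels=8, in_plane_size=32))
        small = build_model(ModelConfig(depth=3, base_channels=4, in_plane_size=32))
        assert small.param_count() < big.param_count()

    def test_attention_off_removes_exactly_the_nonlocal_params(self):
        on = build_model(ModelConfig(depth=3, base_channels=8, in_plane_size=32))
        off = build_model(ModelConfig(depth=3, base_channels=8, in_plane_size=32,
                                      attention=False))
        assert on.param_count() - off.param_count() == on.attention.param_count()

    def test_indivisible_size_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(depth=5, base_channels=8, in_plane_size=100)

    def test_output_shape_and_open_range(self, rng):
        m = build_model(ModelConfig(depth=3, base_channels=4, in_plane_size=32))
        x = rng.random((4, 1, 32, 32)).astype(np.float32)
        y = m.forward(x, mode="eval")
        assert y.shape == (4, 1, 32, 32)
        assert np.all((y > 0) & (y < 1))

    def test_same_seed_identical_initial_parameters(self):
        cfg = ModelConfig(depth=3, base_channels=4, in_plane_size=32, seed=9)
        a, b = build_model(cfg), build_model(cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_wrong_in_plane_size_rejected_at_forward(self, rng):
        m = build_model(ModelConfig(depth=3, base_channels=4, in_plane_size=32))
        with pytest.raises(DimensionError):
            m.forward(rng.random((1, 1, 16, 16)))

    def test_batch_permutation_equivariance(self, rng):
        m = build_model(ModelConfig(depth=3, base_channels=4, in_plane_size=32))
        x = rng.random((5, 1, 32, 32)).astype(np.float32)
        perm = np.array([3, 0, 4, 1, 2])
        assert np.allclose(m.forward(x, mode="eval")[perm],
                           m.forward(x[perm], mode="eval"), atol=1e-6)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        m = build_model(ModelConfig(depth=2, base_channels=4, in_plane_size=16))
        x = rng.random((2, 1, 16, 16)).astype(np.float32)
        save_checkpoint(m, tmp_path / "m.npz")
        back = load_checkpoint(tmp_path / "m.npz")
        assert back.cfg == m.cfg
        assert np.array_equal(back.forward(x), m.forward(x))


class TestAttention:
    def test_affinity_rows_sum_to_one(self, rng):
        block = L.NonLocalBlock(4, rng, np.float64)
        block.forward(rng.normal(size=(2, 4, 5, 5)))
        sums = block.last_affinity.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_uniform_input_gives_uniform_affinity(self, rng):
        block = L.NonLocalBlock(4, rng, np.float64)
        x = np.ones((1, 4, 3, 3))
        block.forward(x)
        assert np.allclose(block.last_affinity, 1.0 / 9.0, atol=1e-12)

    def test_residual_preserves_shape(self, rng):
        block = L.NonLocalBlock(6, rng, np.float64)
        x = rng.normal(size=(2, 6, 4, 4))
        assert block.forward(x).shape == x.shape

    def test_saliency_in_unit_interval(self, rng):
        m = build_model(ModelConfig(depth=3, base_channels=4, in_plane_size=32))
        sal = get_attention_map(m, rng.random((2, 32, 32)).astype(np.float32))
        assert sal.shape == (2, 32, 32)
        assert sal.min() >= 0.0 and sal.max() <= 1.0


class TestMonteCarlo:
    def cfg(self, dropout=0.2):
        return ModelConfig(depth=3, base_channels=4, in_plane_size=32,
                           dropout_rate=dropout)

    def test_deterministic_without_dropout(self, rng):
        m = build_model(self.cfg())
        x = rng.random((3, 1, 32, 32)).astype(np.float32)
        assert np.array_equal(forward(m, x), forward(m, x))

    def test_fixed_master_seed_reproduces_sample_list(self, rng):
        m = build_model(self.cfg())
        x = rng.random((3, 32, 32)).astype(np.float32)
        a = forward_mc(m, x, T=4, seed=11)
        b = forward_mc(m, x, T=4, seed=11)
        assert all(np.array_equal(s, t) for s, t in zip(a, b))

    def test_samples_actually_vary(self, rng):
        m = build_model(self.cfg())
        x = rng.random((3, 32, 32)).astype(np.float32)
        samples = np.stack(forward_mc(m, x, T=6, seed=0))
        assert samples.var(axis=0).max() > 0

    def test_zero_dropout_rate_rejected(self, rng):
        m = build_model(self.cfg(dropout=0.0))
        with pytest.raises(ConfigurationError):
            forward_mc(m, rng.random((2, 32, 32)).astype(np.float32), T=4)

    def test_t_below_two_rejected(self, rng):
        m = build_model(self.cfg())
        with pytest.raises(ConfigurationError):
            forward_mc(m, rng.random((2, 32, 32)).astype(np.float32), T=1)
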