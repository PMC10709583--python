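"""ConvLSTM closed forms, BConvLSTM behaviour, dense-block wiring, the
architecture contracts of the default and unpruned configurations, and
vessel labelling of the single-channel output."""

import numpy as np
import pytest

from aortacine.cine_io import LABEL_AAO, LABEL_DAO, CineSequence
from aortacine.nn import engine as eg
from aortacine.nn.convlstm import (BConvLSTMParams, ConvLSTMParams, bconvlstm,
                                   convlstm_step)
from aortacine.nn.network import (DenseBlockParams, GeometryShapeError,
                                  NetworkConfig, binarize_and_label,
                                  build_network, dense_block, segment_sequence)


def scalar_params(**overrides):
    """1x1-kernel, single-channel ConvLSTM parameters, default all zeros."""
    def P(v):
        return eg.Parameter(np.full((1, 1, 1, 1), float(v)))

    def B(v):
        return eg.Parameter(np.array([float(v)]))

    vals = dict(w_xi=0, w_hi=0, w_xf=0, w_hf=0, w_xc=0, w_hc=0, w_xo=0, w_ho=0,
                b_i=0, b_f=0, b_c=0, b_o=0)
    vals.update(overrides)
    kernels = {k: P(v) for k, v in vals.items() if k.startswith("w")}
    biases = {k: B(v) for k, v in vals.items() if k.startswith("b")}
    return ConvLSTMParams(**kernels, **biases)


def tensor_scalar(v):
    return eg.Tensor(np.full((1, 1, 1, 1), float(v)))


class TestConvLSTMStep:
    def test_zero_parameters_are_zero_map(self, rng):
        params = scalar_params()
        x = tensor_scalar(rng.standard_normal())
        h, c = convlstm_step(x, tensor_scalar(0), tensor_scalar(0), params)
        # gates = 0.5 and tanh(0) = 0, so c = 0.5*0 + 0.5*0 = 0 and h = 0
        assert h.item() == 0.0
        assert c.item() == 0.0

    def test_scalar_closed_form(self):
        # gates ~ 1 via large biases, candidate path W_xc = 1:
        # c = tanh(0.5), h = tanh(tanh(0.5))
        params = scalar_params(w_xc=1, b_i=50, b_f=50, b_o=50)
        h, c = convlstm_step(tensor_scalar(0.5), tensor_scalar(0),
                             tensor_scalar(0), params)
        assert c.item() == pytest.approx(np.tanh(0.5), abs=1e-12)
        assert h.item() == pytest.approx(np.tanh(np.tanh(0.5)), abs=1e-12)

    def test_forget_gate_to_zero_limit_detaches_cell_state(self):
        params = scalar_params(w_xc=1, b_i=50, b_f=-1000, b_o=50)
        for c_prev in (0.0, 5.0, -7.0):
            _, c = convlstm_step(tensor_scalar(0.5), tensor_scalar(0),
                                 tensor_scalar(c_prev), params)
            assert c.item() == pytest.approx(np.tanh(0.5), abs=1e-12)


def zero_bclstm(in_ch=1, hidden=1, b_y=0.0):
    rng = np.random.default_rng(0)
    params = BConvLSTMParams.create(rng, in_ch, hidden, hidden, kernel=1,
                                    dtype=np.float64)
    for p in params.parameters():
        p.data[...] = 0.0
    params.b_y.data[...] = b_y
    return params


class TestBConvLSTM:
    def test_zero_parameters_give_zero_sequence(self):
        params = zero_bclstm()
        out = bconvlstm([tensor_scalar(v) for v in (1.0, -2.0, 3.0)], params)
        assert len(out) == 3
        for y in out:
            assert y.item() == 0.0

    def test_bias_passthrough(self):
        params = zero_bclstm(b_y=0.3)
        out = bconvlstm([tensor_scalar(1.0)] * 4, params)
        for y in out:
            assert y.item() == pytest.approx(0.3, abs=1e-12)

    def test_symmetric_hidden_states_cancel(self):
        # Y = tanh(1*0.5 + 1*(-0.5)) = 0 when combining kernels are identity
        params = zero_bclstm()
        params.w_y_fwd.data[...] = 1.0
        params.w_y_bwd.data[...] = 1.0
        hf, hb = tensor_scalar(0.5), tensor_scalar(-0.5)
        combined = eg.tanh(eg.add(eg.conv2d(hf, params.w_y_fwd),
                                  eg.conv2d(hb, params.w_y_bwd)))
        assert combined.item() == pytest.approx(0.0, abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            bconvlstm([], zero_bclstm())

    def test_time_reversal_equivariance(self, rng):
        """Reversing the input and swapping forward/backward parameter roles
        reverses the output sequence."""
        params = BConvLSTMParams.create(rng, 2, 3, 2, dtype=np.float64)
        for p in params.parameters():
            p.data[...] = rng.standard_normal(p.data.shape) * 0.3
        frames = [eg.Tensor(rng.standard_normal((1, 2, 4, 4))) for _ in range(5)]
        out = bconvlstm(frames, params)
        swapped = BConvLSTMParams(forward=params.backward, backward=params.forward,
                                  w_y_fwd=params.w_y_bwd, w_y_bwd=params.w_y_fwd,
                                  b_y=params.b_y)
        out_rev = bconvlstm(frames[::-1], swapped)
        for y, yr in zip(out, out_rev[::-1]):
            np.testing.assert_allclose(y.data, yr.data, atol=1e-12)


class TestDenseBlock:
    def test_single_layer_is_plain_conv_pair(self, rng):
        params = DenseBlockParams.create(rng, 3, 4, 1, 3, np.float64)
        x = eg.Tensor(rng.standard_normal((1, 3, 6, 6)))
        out = dense_block(x, params)
        expected = eg.relu(eg.conv2d(
            eg.relu(eg.conv2d(x, params.layers[0][0].w, params.layers[0][0].b)),
            params.layers[0][1].w, params.layers[0][1].b))
        np.testing.assert_allclose(out.data, expected.data)

    def test_connectivity_count(self, rng):
        params = DenseBlockParams.create(rng, 8, 4, 3, 3, np.float64)
        assert params.connectivity_count == 6  # n(n+1)/2 for n = 3
        # layer i's first conv consumes the block input + (i-1) prior outputs
        in_channels = [pair[0].w.data.shape[1] for pair in params.layers]
        assert in_channels == [8, 8 + 4, 8 + 8]

    def test_spatial_shape_preserved(self, rng):
        params = DenseBlockParams.create(rng, 2, 5, 2, 3, np.float64)
        x = eg.Tensor(rng.standard_normal((2, 2, 8, 8)))
        assert dense_block(x, params).data.shape == (2, 5, 8, 8)


class TestArchitectureContracts:
    def test_default_widths_and_single_bconvlstm(self):
        net = build_network(NetworkConfig())
        assert net.config.widths == [16, 32, 64, 128, 256]
        merges = [step for step in net.dec if "bclstm" in step]
        assert len(merges) == 1
        assert merges[0]["level"] == 2
        spec = net.spec()
        assert sum(1 for l in spec.layers if l.kind == "upconv-bconvlstm") == 1

    def test_unpruned_configuration(self):
        cfg = NetworkConfig.unpruned()
        net = build_network(cfg)
        assert net.config.widths == [64, 128, 256, 512, 1024]
        assert net.bottleneck.n_layers == 3
        assert sum(1 for step in net.dec if "bclstm" in step) == 3

    def test_parameter_count_ordering(self):
        default = build_network(NetworkConfig())
        unpruned = build_network(NetworkConfig.unpruned())
        assert default.n_parameters < unpruned.n_parameters
        assert default.n_parameters == default.spec().n_parameters

    def test_concat_merge_mode_has_no_bconvlstm(self):
        net = build_network(NetworkConfig(merge_mode="concat"))
        assert not any("bclstm" in step for step in net.dec)

    @pytest.mark.parametrize("config", [
        NetworkConfig(filters=(2, 4, 8, 16, 32)),
        NetworkConfig.unpruned(filters=(2, 4, 8, 16, 32)),
    ])
    def test_forward_pass_toy_input(self, config, rng):
        net = build_network(config, seed=0)
        t = 4
        x = eg.Tensor(rng.random((t, 1, 16, 16)).astype(np.float32))
        out = net.forward(x, n_frames=t, training=False)
        assert out.data.shape == (t, 1, 16, 16)
        assert np.all(out.data > 0) and np.all(out.data < 1)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(filters=(16, 32, 64))
        with pytest.raises(ValueError):
            NetworkConfig(bconvlstm_levels=frozenset({0, 5}))
        with pytest.raises(ValueError):
            NetworkConfig(dropout=1.0)


class TestSegmentSequence:
    def make_cine(self, rng, t=3, hw=32):
        return CineSequence(frames=rng.random((t, hw, hw)),
                            pixel_spacing=(1.0, 1.0), study_id="toy")

    def test_inference_deterministic(self, rng):
        net = build_network(NetworkConfig(filters=(2, 4, 8, 16, 32)), seed=1)
        cine = self.make_cine(rng)
        p1 = segment_sequence(net, cine)
        p2 = segment_sequence(net, cine)
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == cine.frames.shape
        assert np.all((p1 > 0) & (p1 < 1))

    def test_batching_independence(self, rng):
        """Per-study output does not depend on which studies share a batch."""
        net = build_network(NetworkConfig(filters=(2, 4, 8, 16, 32)), seed=1)
        a = self.make_cine(rng)
        b = self.make_cine(rng)
        solo = segment_sequence(net, a)
        x = np.concatenate([a.frames[:, None], b.frames[:, None]], axis=0)
        joint = net.forward(eg.Tensor(x.astype(np.float32)), n_frames=3,
                            training=False)
        np.testing.assert_allclose(solo, joint.data[:3, 0], atol=1e-6)

    def test_non_divisible_size_rejected(self, rng):
        net = build_network(NetworkConfig(filters=(2, 4, 8, 16, 32)))
        cine = CineSequence(frames=rng.random((3, 24, 24)),
                            pixel_spacing=(1.0, 1.0))
        with pytest.raises(GeometryShapeError):
            segment_sequence(net, cine)


class TestBinarizeAndLabel:
    def test_truth_masks_round_trip(self, phantom_study):
        _, masks, _ = phantom_study
        probs = (masks.labels > 0).astype(float)
        out = binarize_and_label(probs, pixel_spacing=masks.pixel_spacing)
        np.testing.assert_array_equal(out.labels > 0, masks.labels > 0)
        np.testing.assert_array_equal(out.labels, masks.labels)

    def test_larger_component_is_ascending_aorta(self):
        probs = np.zeros((4, 64, 64))
        probs[:, 10:25, 10:30] = 1.0   # 300 px component
        probs[:, 40:50, 40:55] = 1.0   # 150 px component
        out = binarize_and_label(probs, pixel_spacing=(2.0, 1.0))
        big = out.labels[0, 12, 12]
        small = out.labels[0, 42, 42]
        assert big == LABEL_AAO
        assert small == LABEL_DAO

    def test_empty_probabilities_warn(self):
        with pytest.warns(UserWarning, match="empty"):
            out = binarize_and_label(np.zeros((3, 32, 32)))
        assert out.labels.sum() == 0

    def test_single_component_warns_single_vessel(self):
        probs = np.zeros((3, 32, 32))
        probs[:, 5:15, 5:15] = 1.0
        with pytest.warns(UserWarning, match="fewer than two"):
            out = binarize_and_label(probs)
        assert set(np.unique(out.labels)) == {0, LABEL_AAO}
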