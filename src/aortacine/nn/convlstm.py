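"""Convolutional LSTM cell and its bidirectional sequence wrapper.

A ConvLSTM replaces the dense gate transformations of an LSTM with 2-D
convolutions, so the recurrent state keeps its spatial layout.  The
bidirectional variant runs two independent cells over the frame sequence in
opposite temporal directions and combines the two hidden-state sequences
through a tanh-activated convolutional map plus a bias, returning the full
output sequence (one map per frame, not just the last step).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .engine import (Parameter, Tensor, add, conv2d, he_normal, mul, reshape,
                     sigmoid, tanh)


@dataclass
class ConvLSTMParams:
    """Gate kernels and biases of one ConvLSTM cell.

    ``W_x*`` kernels are (hidden, in_channels, k, k), ``W_h*`` kernels are
    (hidden, hidden, k, k); biases are (hidden,).
    """

    w_xi: Parameter
    w_hi: Parameter
    w_xf: Parameter
    w_hf: Parameter
    w_xc: Parameter
    w_hc: Parameter
    w_xo: Parameter
    w_ho: Parameter
    b_i: Parameter
    b_f: Parameter
    b_c: Parameter
    b_o: Parameter

    @property
    def hidden_channels(self) -> int:
        return self.w_hi.data.shape[0]

    def parameters(self):
        return [getattr(self, f.name) for f in fields(self)]

    @classmethod
    def create(cls, rng: np.random.Generator, in_channels: int,
               hidden_channels: int, kernel: int = 3, dtype=np.float32):
        def wx():
            shape = (hidden_channels, in_channels, kernel, kernel)
            return Parameter(he_normal(rng, shape, in_channels * kernel ** 2, dtype))

        def wh():
            shape = (hidden_channels, hidden_channels, kernel, kernel)
            return Parameter(he_normal(rng, shape, hidden_channels * kernel ** 2, dtype))

        def b():
            return Parameter(np.zeros(hidden_channels, dtype=dtype))

        return cls(wx(), wh(), wx(), wh(), wx(), wh(), wx(), wh(),
                   b(), b(), b(), b())


@dataclass
class BConvLSTMParams:
    """Forward/backward ConvLSTM cells plus the tanh output combination."""

    forward: ConvLSTMParams
    backward: ConvLSTMParams
    w_y_fwd: Parameter  # (out, hidden, k, k) applied to forward hidden states
    w_y_bwd: Parameter  # (out, hidden, k, k) applied to backward hidden states
    b_y: Parameter      # (out,)

    def parameters(self):
        return (self.forward.parameters() + self.backward.parameters()
                + [self.w_y_fwd, self.w_y_bwd, self.b_y])

    @classmethod
    def create(cls, rng: np.random.Generator, in_channels: int,
               hidden_channels: int, out_channels: int, kernel: int = 3,
               dtype=np.float32):
        fwd = ConvLSTMParams.create(rng, in_channels, hidden_channels, kernel, dtype)
        bwd = ConvLSTMParams.create(rng, in_channels, hidden_channels, kernel, dtype)
        shape = (out_channels, hidden_channels, kernel, kernel)
        fan = hidden_channels * kernel ** 2
        return cls(fwd, bwd,
                   Parameter(he_normal(rng, shape, fan, dtype)),
                   Parameter(he_normal(rng, shape, fan, dtype)),
                   Parameter(np.zeros(out_channels, dtype=dtype)))


def convlstm_step(x_t, h_prev, c_prev, params: ConvLSTMParams):
    """One ConvLSTM time step.

    I = sigma(W_xi*x + W_hi*h + b_i);  F = sigma(W_xf*x + W_hf*h + b_f)
    C = F o c_prev + I o tanh(W_xc*x + W_hc*h + b_c)
    O = sigma(W_xo*x + W_ho*h + b_o);  h = O o tanh(C)
    """
    gate_i = sigmoid(add(conv2d(x_t, params.w_xi), conv2d(h_prev, params.w_hi, params.b_i)))
    gate_f = sigmoid(add(conv2d(x_t, params.w_xf), conv2d(h_prev, params.w_hf, params.b_f)))
    cand = tanh(add(conv2d(x_t, params.w_xc), conv2d(h_prev, params.w_hc, params.b_c)))
    c_t = add(mul(gate_f, c_prev), mul(gate_i, cand))
    gate_o = sigmoid(add(conv2d(x_t, params.w_xo), conv2d(h_prev, params.w_ho, params.b_o)))
    h_t = mul(gate_o, tanh(c_t))
    return h_t, c_t


def _run_direction(frames, params: ConvLSTMParams):
    b = frames[0].data.shape[0]
    hw = frames[0].data.shape[2:]
    shape = (b, params.hidden_channels) + hw
    h = Tensor(np.zeros(shape, dtype=frames[0].data.dtype))
    c = Tensor(np.zeros(shape, dtype=frames[0].data.dtype))
    hidden = []
    for x_t in frames:
        h, c = convlstm_step(x_t, h, c, params)
        hidden.append(h)
    return hidden


def bconvlstm(frames, params: BConvLSTMParams):
    """Bidirectional ConvLSTM over a list of per-frame tensors (B, C, H, W).

    Returns the full output sequence: ``Y_j = tanh(Wf * Hf_j + Wb * Hb_j) + b``
    for every frame j, with zero initial hidden/cell states in both
    directions.
    """
    if len(frames) == 0:
        raise ValueError("bconvlstm needs at least one frame")
    h_fwd = _run_direction(frames, params.forward)
    h_bwd = _run_direction(frames[::-1], params.backward)[::-1]
    bias = reshape(params.b_y, (1, -1, 1, 1))
    out = []
    for hf, hb in zip(h_fwd, h_bwd):
        combined = tanh(add(conv2d(hf, params.w_y_fwd), conv2d(hb, params.w_y_bwd)))
        out.append(add(combined, bias))
    return out
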