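"""The spatiotemporal segmentation network.

A time-distributed U-Net over cine frames: four encoder steps (two 3x3
convolutions + ReLU, batch normalisation, 2x2 max-pooling, with dropout in
the last two steps), a densely-connected convolutional block at the bottom,
and four decoder steps (2x nearest up-sampling + 2x2 convolution, skip
merge, two 3x3 convolutions + ReLU; the final decode step has five
convolutions ending in a single sigmoid channel).  At the configured
decoder level(s) — by default only the second up-sampling step — the skip
merge is a bidirectional ConvLSTM over the frame sequence: the up-sampled
decoder features and the encoder skip features are stacked channel-wise per
frame and fed to the BConvLSTM, which joins the spatial and temporal
processing non-linearly.  Everywhere else the merge is a plain channel
concatenation.

The resource-efficient default uses filter widths [16, 32, 64, 128, 256],
one dense block and one BConvLSTM level; the unpruned variant (four times
the filters, three dense blocks, BConvLSTM at three levels) and the
ablation variants are plain configuration changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..cine_io import LABEL_AAO, LABEL_DAO, CineSequence, MaskSequence
from . import engine as eg
from .convlstm import BConvLSTMParams, bconvlstm
from .engine import Parameter, Tensor


class NetworkConfigError(ValueError):
    pass


@dataclass
class NetworkConfig:
    """Declarative description of the segmentation architecture."""

    filters: tuple[int, ...] = (16, 32, 64, 128, 256)
    filter_multiplier: int = 1          # 4 -> "unpruned" filter widths
    dense_blocks_final_encode: int = 1  # 3 -> unpruned bottleneck
    bconvlstm_levels: frozenset[int] = frozenset({2})  # {1,2,3} -> unpruned
    merge_mode: str = "bconvlstm"       # "concat" disables the non-linear merge
    dropout: float = 0.5
    out_channels: int = 1
    conv_kernel: int = 3
    dtype: str = "float32"

    def __post_init__(self):
        if len(self.filters) != 5:
            raise NetworkConfigError("filters must list 5 widths")
        self.bconvlstm_levels = frozenset(self.bconvlstm_levels)
        if not self.bconvlstm_levels <= {1, 2, 3, 4}:
            raise NetworkConfigError("bconvlstm_levels must be within {1..4}")
        if not 0.0 <= self.dropout < 1.0:
            raise NetworkConfigError("dropout must be in [0, 1)")
        if self.filter_multiplier < 1:
            raise NetworkConfigError("filter_multiplier must be >= 1")

    @property
    def widths(self) -> list[int]:
        return [f * self.filter_multiplier for f in self.filters]

    @classmethod
    def unpruned(cls, **overrides) -> "NetworkConfig":
        """The unpruned ancestor: x4 filters, 3 dense blocks, 3 BConvLSTM levels."""
        defaults = dict(filter_multiplier=4, dense_blocks_final_encode=3,
                        bconvlstm_levels=frozenset({1, 2, 3}))
        defaults.update(overrides)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ConvParams:
    w: Parameter
    b: Parameter

    def parameters(self):
        return [self.w, self.b]

    @classmethod
    def create(cls, rng, in_ch, out_ch, k, dtype):
        return cls(Parameter(eg.he_normal(rng, (out_ch, in_ch, k, k),
                                          in_ch * k * k, dtype)),
                   Parameter(np.zeros(out_ch, dtype=dtype)))


@dataclass
class BatchNormParams:
    gamma: Parameter
    beta: Parameter
    running: dict

    def parameters(self):
        return [self.gamma, self.beta]

    @classmethod
    def create(cls, ch, dtype):
        return cls(Parameter(np.ones(ch, dtype=dtype)),
                   Parameter(np.zeros(ch, dtype=dtype)),
                   {"mean": np.zeros(ch, dtype=dtype),
                    "var": np.ones(ch, dtype=dtype)})


@dataclass
class DenseBlockParams:
    """Parameters of one densely connected convolutional block.

    Internal layer ``i`` (1-based) is a pair of 3x3 convolutions whose first
    convolution reads the channel concatenation of the block input and all
    ``i - 1`` previous layer outputs.
    """

    layers: list[tuple[ConvParams, ConvParams]]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def connectivity_count(self) -> int:
        """Total number of concatenation sources across internal layers."""
        return sum(i for i in range(1, self.n_layers + 1))

    def parameters(self):
        return [p for pair in self.layers for conv in pair for p in conv.parameters()]

    @classmethod
    def create(cls, rng, in_ch, width, n_layers, k, dtype):
        layers = []
        for i in range(n_layers):
            c_in = in_ch + i * width
            layers.append((ConvParams.create(rng, c_in, width, k, dtype),
                           ConvParams.create(rng, width, width, k, dtype)))
        return cls(layers)


def dense_block(x: Tensor, params: DenseBlockParams) -> Tensor:
    """Apply a densely connected block: each layer sees all previous outputs."""
    inputs = [x]
    out = x
    for conv1, conv2 in params.layers:
        h = eg.concat_channels(inputs) if len(inputs) > 1 else inputs[0]
        h = eg.relu(eg.conv2d(h, conv1.w, conv1.b))
        out = eg.relu(eg.conv2d(h, conv2.w, conv2.b))
        inputs.append(out)
    return out


# ---------------------------------------------------------------------------
# the assembled network


@dataclass
class LayerInfo:
    name: str
    kind: str
    out_channels: int
    n_parameters: int


@dataclass
class NetworkSpec:
    """Summary of the instantiated layer graph."""

    config: NetworkConfig
    layers: list[LayerInfo]
    n_parameters: int


class SegmentationNetwork:
    """Instantiated network: parameters plus the forward computation."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        dtype = np.dtype(config.dtype).type
        k = config.conv_kernel
        w = config.widths
        self._drop_rng = np.random.default_rng(seed + 1)

        self.enc = []
        in_ch = 1
        for level, width in enumerate(w[:4]):
            self.enc.append({
                "conv1": ConvParams.create(rng, in_ch, width, k, dtype),
                "conv2": ConvParams.create(rng, width, width, k, dtype),
                "bn": BatchNormParams.create(width, dtype),
                "dropout": config.dropout if level >= 2 else 0.0,
            })
            in_ch = width

        self.bottleneck = DenseBlockParams.create(
            rng, w[3], w[4], config.dense_blocks_final_encode, k, dtype)

        self.dec = []
        prev = w[4]
        skip_widths = [w[3], w[2], w[1], w[0]]
        for level in range(1, 5):  # decoder levels 1..4 (coarse to fine)
            width = skip_widths[level - 1]
            step = {"up": ConvParams.create(rng, prev, width, 2, dtype),
                    "level": level, "width": width}
            merged_ch = width + skip_widths[level - 1]
            if config.merge_mode == "bconvlstm" and level in config.bconvlstm_levels:
                step["bclstm"] = BConvLSTMParams.create(
                    rng, merged_ch, width, width, k, dtype)
                conv_in = width
            else:
                conv_in = merged_ch
            n_convs = 5 if level == 4 else 2
            convs = []
            c = conv_in
            for j in range(n_convs - 1 if level == 4 else n_convs):
                convs.append(ConvParams.create(rng, c, width, k, dtype))
                c = width
            if level == 4:
                convs.append(ConvParams.create(rng, c, config.out_channels, k, dtype))
            step["convs"] = convs
            self.dec.append(step)
            prev = width

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for step in self.enc:
            params += step["conv1"].parameters() + step["conv2"].parameters()
            params += step["bn"].parameters()
        params += self.bottleneck.parameters()
        for step in self.dec:
            params += step["up"].parameters()
            if "bclstm" in step:
                params += step["bclstm"].parameters()
            for conv in step["convs"]:
                params += conv.parameters()
        return params

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def spec(self) -> NetworkSpec:
        layers = []
        for i, step in enumerate(self.enc):
            n = sum(p.data.size for p in step["conv1"].parameters()
                    + step["conv2"].parameters() + step["bn"].parameters())
            layers.append(LayerInfo(f"encode{i + 1}", "conv-bn-pool",
                                    step["conv2"].w.data.shape[0], n))
        layers.append(LayerInfo("bottleneck", "dense-block",
                                self.config.widths[4],
                                sum(p.data.size for p in self.bottleneck.parameters())))
        for step in self.dec:
            kind = "upconv-bconvlstm" if "bclstm" in step else "upconv-concat"
            n = sum(p.data.size for p in step["up"].parameters())
            if "bclstm" in step:
                n += sum(p.data.size for p in step["bclstm"].parameters())
            n += sum(p.data.size for conv in step["convs"] for p in conv.parameters())
            layers.append(LayerInfo(f"decode{step['level']}", kind,
                                    step["convs"][-1].w.data.shape[0], n))
        return NetworkSpec(self.config, layers, self.n_parameters)

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        for step in self.enc:
            state.append(step["bn"].running["mean"].copy())
            state.append(step["bn"].running["var"].copy())
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, arr in zip(params, state[:len(params)]):
            p.data = arr.copy()
        it = iter(state[len(params):])
        for step in self.enc:
            step["bn"].running["mean"] = next(it).copy()
            step["bn"].running["var"] = next(it).copy()

    # -- forward -----------------------------------------------------------
    def forward(self, x: Tensor, n_frames: int, training: bool = False) -> Tensor:
        """Run the network on a (B*T, 1, H, W) batch laid out sequence-major.

        Returns per-frame sigmoid probability maps of the same layout with
        ``out_channels`` channels.  ``n_frames`` is T; every 2-D stage is
        applied identically to each frame, the BConvLSTM merge unrolls over
        the T frames of each sequence.
        """
        h_dim, w_dim = x.data.shape[2], x.data.shape[3]
        if h_dim % 16 or w_dim % 16:
            raise GeometryShapeError(
                f"spatial size {h_dim}x{w_dim} must be divisible by 16 (pad first)")
        skips = []
        out = x
        for step in self.enc:
            out = eg.relu(eg.conv2d(out, step["conv1"].w, step["conv1"].b))
            out = eg.relu(eg.conv2d(out, step["conv2"].w, step["conv2"].b))
            if training and step["dropout"] > 0:
                out = eg.dropout(out, step["dropout"], self._drop_rng, training)
            out = eg.batchnorm(out, step["bn"].gamma, step["bn"].beta,
                               step["bn"].running, training)
            skips.append(out)
            out = eg.maxpool2(out)

        out = dense_block(out, self.bottleneck)

        for step in self.dec:
            up = eg.conv2d(eg.upsample2(out), step["up"].w, step["up"].b)
            skip = skips[4 - step["level"]]
            merged = eg.concat_channels([up, skip])
            if "bclstm" in step:
                frames = [eg.stride_rows(merged, t, n_frames)
                          for t in range(n_frames)]
                y = bconvlstm(frames, step["bclstm"])
                out = eg.interleave_rows(y)
            else:
                out = merged
            for conv in step["convs"][:-1]:
                out = eg.relu(eg.conv2d(out, conv.w, conv.b))
            last = step["convs"][-1]
            if step["level"] == 4:
                out = eg.conv2d(out, last.w, last.b)  # linear head
            else:
                out = eg.relu(eg.conv2d(out, last.w, last.b))
        return eg.sigmoid(out)


class GeometryShapeError(ValueError):
    pass


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> SegmentationNetwork:
    """Instantiate the architecture described by ``config`` (He-normal init)."""
    return SegmentationNetwork(config or NetworkConfig(), seed=seed)


def segment_sequence(network: SegmentationNetwork, cine: CineSequence) -> np.ndarray:
    """Per-frame aorta probability maps for one normalized study.

    Returns a (T, H, W) float array with values in (0, 1); inference is
    deterministic (dropout off, batch-norm running statistics).
    """
    t, h, w = cine.frames.shape
    if h % 16 or w % 16:
        raise GeometryShapeError(
            f"spatial size {h}x{w} not divisible by 16; zero-pad the study first")
    dtype = np.dtype(network.config.dtype).type
    x = Tensor(cine.frames[:, None].astype(dtype))
    probs = network.forward(x, n_frames=t, training=False)
    return probs.data[:, 0].astype(np.float64)


def binarize_and_label(probs: np.ndarray, threshold: float = 0.5,
                       pixel_spacing: tuple[float, float] = (1.0, 1.0),
                       study_id: str = "") -> MaskSequence:
    """Threshold per-frame probabilities and assign AAo/DAo labels.

    The single-channel head predicts "aorta vs background"; the two vessels
    are separated by connected-component analysis: the temporal mean of the
    binary maps is labelled, the two largest persistent components become
    the vessel footprints, per-frame components are assigned to the
    footprint they overlap most, and the footprint with the larger mean
    area is called the ascending aorta (AAo areas exceed DAo areas in this
    imaging plane).
    """
    from scipy import ndimage

    binary = np.asarray(probs) >= threshold
    t_n = binary.shape[0]
    labels = np.zeros(binary.shape, dtype=np.uint8)
    mean_map = binary.mean(axis=0) >= 0.5
    comp, n_comp = ndimage.label(mean_map)
    if n_comp == 0:
        warnings.warn("empty segmentation: no persistent component found",
                      stacklevel=2)
        return MaskSequence(labels=labels, pixel_spacing=pixel_spacing,
                            study_id=study_id)
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n_comp + 1))
    order = np.argsort(sizes)[::-1] + 1
    footprints = [comp == order[0]]
    if n_comp >= 2:
        footprints.append(comp == order[1])
    else:
        warnings.warn("fewer than two persistent components; "
                      "emitting a single-vessel labelling", stacklevel=2)

    # Assign per-frame connected components to the nearest footprint.
    assigned = [np.zeros(binary.shape, dtype=bool) for _ in footprints]
    for t in range(t_n):
        fcomp, fn = ndimage.label(binary[t])
        for ci in range(1, fn + 1):
            region = fcomp == ci
            overlaps = [np.count_nonzero(region & fp) for fp in footprints]
            best = int(np.argmax(overlaps))
            if overlaps[best] > 0:
                assigned[best][t] |= region

    mean_areas = [a.sum() / t_n for a in assigned]
    if len(assigned) == 1:
        labels[assigned[0]] = LABEL_AAO
    else:
        aao_idx = int(np.argmax(mean_areas))
        labels[assigned[aao_idx]] = LABEL_AAO
        labels[assigned[1 - aao_idx]] = LABEL_DAO
    return MaskSequence(labels=labels, pixel_spacing=pixel_spacing,
                        study_id=study_id)
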