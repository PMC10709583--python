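"""Dataset splitting, online augmentation, and the optimisation loop.

The reference protocol: random patient-level split (272/68/84 of 424
studies), Adam with a constant learning rate of 0.001 for 250 epochs,
He-normal initialisation, dropout 0.5, and online augmentation with random
rotations in [-30, +30] degrees and integer translations of up to 20 px
per axis, the same transform applied to image (bilinear) and mask
(nearest-neighbour).  A desk-scale preset (64 x 64 grid, T = 12, filter
widths [4, 8, 16, 32, 64], 20 epochs, translations scaled to the smaller
grid) reproduces the behaviour at workstation cost.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cine_io import CineSequence, MaskSequence
from .losses import LossConfig, make_loss
from .metrics import dice
from .nn.engine import Adam, Tensor
from .nn.network import NetworkConfig, SegmentationNetwork

DEFAULT_SPLIT = (272 / 424, 68 / 424, 84 / 424)


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class AugmentConfig:
    max_rotation_deg: float = 30.0
    max_translation_px: int = 20


@dataclass
class TrainConfig:
    epochs: int = 250
    learning_rate: float = 1e-3
    batch_sequences: int = 4  # ~120 frames at 30-40 phases per study
    dropout: float = 0.5
    aug: AugmentConfig = field(default_factory=AugmentConfig)
    split_fractions: tuple[float, float, float] = DEFAULT_SPLIT
    loss: LossConfig = field(default_factory=LossConfig)
    loss_kind: str = "focal_tversky"
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.epochs < 1 or self.batch_sequences < 1:
            raise ValueError("epochs and batch size must be >= 1")


def desk_preset(**overrides) -> TrainConfig:
    """Workstation-scale protocol: train to plateau (~60 epochs on small
    phantom cohorts), translations scaled to 64 px grids."""
    defaults = dict(epochs=60, aug=AugmentConfig(max_rotation_deg=30.0,
                                                 max_translation_px=5))
    defaults.update(overrides)
    return TrainConfig(**defaults)


def desk_network_config(**overrides) -> NetworkConfig:
    defaults = dict(filters=(4, 8, 16, 32, 64))
    defaults.update(overrides)
    return NetworkConfig(**defaults)


# ---------------------------------------------------------------------------
# splitting


def split_dataset(studies: list, fractions: tuple[float, float, float] = DEFAULT_SPLIT,
                  seed: int = 0, patient_ids: list | None = None):
    """Random, seed-reproducible (train, val, test) partition.

    Splitting is patient-level: if ``patient_ids`` is given, all studies of
    one patient land in the same partition.  Partition sizes follow the
    fractions by largest remainder, so 424 studies under the default
    fractions split 272/68/84.
    """
    n = len(studies)
    if n < 3:
        raise ValueError("need at least as many studies as partitions")
    if patient_ids is None:
        patient_ids = list(range(n))
    unique = sorted(set(patient_ids), key=str)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    shuffled_patients = [unique[i] for i in order]

    sizes = _apportion(len(unique), fractions)
    bounds = np.cumsum(sizes)
    groups = (set(shuffled_patients[:bounds[0]]),
              set(shuffled_patients[bounds[0]:bounds[1]]),
              set(shuffled_patients[bounds[1]:]))
    parts = ([], [], [])
    for study, pid in zip(studies, patient_ids):
        for g, part in zip(groups, parts):
            if pid in g:
                part.append(study)
                break
    return parts


def _apportion(n: int, fractions) -> list[int]:
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainder = n - sum(sizes)
    order = np.argsort([s - r for s, r in zip(sizes, raw)])  # largest remainder first
    for i in range(remainder):
        sizes[order[i]] += 1
    return sizes


# ---------------------------------------------------------------------------
# augmentation


def augment(frames: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
            config: AugmentConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One random rotation + integer translation applied to a cine/mask pair.

    Rotation is drawn uniformly from [-max_rotation, +max_rotation] and the
    per-axis translations uniformly from the integer range
    [-max_translation, +max_translation]; images are interpolated
    bilinearly, masks with nearest-neighbour, out-of-canvas pixels are
    zero-filled.  Draws are independent per call (online augmentation).
    """
    config = config or AugmentConfig()
    angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
    shifts = rng.integers(-config.max_translation_px, config.max_translation_px + 1,
                          size=2)
    img, msk = frames, labels
    if angle != 0.0:
        img = ndimage.rotate(img, angle, axes=(1, 2), reshape=False, order=1,
                             mode="constant", cval=0.0)
        msk = ndimage.rotate(msk, angle, axes=(1, 2), reshape=False, order=0,
                             mode="constant", cval=0)
    if shifts.any():
        img = ndimage.shift(img, (0, shifts[0], shifts[1]), order=1,
                            mode="constant", cval=0.0)
        msk = ndimage.shift(msk, (0, shifts[0], shifts[1]), order=0,
                            mode="constant", cval=0)
    return img, msk.astype(labels.dtype)


# ---------------------------------------------------------------------------
# optimisation loop


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_dice: float


def _forward_batch(network: SegmentationNetwork, frames_list, fg_list,
                   loss_fn, training: bool):
    """Average per-sequence loss over a batch (sequence-level reduction)."""
    dtype = np.dtype(network.config.dtype).type
    t_n = frames_list[0].shape[0]
    x = np.concatenate([f[:, None] for f in frames_list], axis=0).astype(dtype)
    probs = network.forward(Tensor(x), n_frames=t_n, training=training)
    losses = []
    for b, fg in enumerate(fg_list):
        # rows of sequence b are b*T .. (b+1)*T - 1 in the sequence-major batch
        seq = _rows(probs, b * t_n, (b + 1) * t_n)
        losses.append(loss_fn(seq, Tensor(fg[:, None].astype(dtype))))
    total = losses[0]
    for extra in losses[1:]:
        total = total + extra
    return total * (1.0 / len(losses)), probs


def _rows(t: Tensor, start: int, stop: int) -> Tensor:
    from .nn import engine as eg

    out_data = t.data[start:stop]

    def backward(g):
        full = np.zeros_like(t.data)
        full[start:stop] = g
        eg._accum(t, full)

    return Tensor(out_data, (t,), backward)


def train(network: SegmentationNetwork,
          train_studies: list[tuple[CineSequence, MaskSequence]],
          val_studies: list[tuple[CineSequence, MaskSequence]],
          config: TrainConfig | None = None,
          energy_tracker=None) -> tuple[list[np.ndarray], list[EpochRecord]]:
    """Optimise the network; returns (best-validation weights, history).

    Model selection uses the validation Dice at threshold 0.5.  The network
    is left loaded with the best weights.  ``energy_tracker`` is an
    optional object with ``epoch_start()``/``epoch_end()`` hooks (e.g. a
    carbontracker instance); nothing is asserted on it.
    """
    config = config or TrainConfig()
    if not train_studies or not val_studies:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    loss_fn = make_loss(config.loss_kind, config.loss)
    optimizer = Adam(network.parameters(), lr=config.learning_rate)

    history: list[EpochRecord] = []
    best_dice = -1.0
    best_state = network.state_dict()
    for epoch in range(config.epochs):
        if energy_tracker is not None:
            energy_tracker.epoch_start()
        order = rng.permutation(len(train_studies))
        epoch_losses = []
        for start in range(0, len(order), config.batch_sequences):
            batch = [train_studies[i] for i in order[start:start + config.batch_sequences]]
            frames_list, fg_list = [], []
            for cine, masks in batch:
                img, msk = augment(cine.frames, masks.labels, rng, config.aug)
                frames_list.append(img)
                fg_list.append((msk > 0).astype(np.float64))
            loss, _ = _forward_batch(network, frames_list, fg_list, loss_fn,
                                     training=True)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: {loss.data}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))

        val_loss, val_dice = _validate(network, val_studies, loss_fn)
        history.append(EpochRecord(epoch=epoch,
                                   train_loss=float(np.mean(epoch_losses)),
                                   val_loss=val_loss, val_dice=val_dice))
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = network.state_dict()
        if energy_tracker is not None:
            energy_tracker.epoch_end()
    network.load_state_dict(best_state)
    return best_state, history


def _validate(network: SegmentationNetwork, studies, loss_fn) -> tuple[float, float]:
    dtype = np.dtype(network.config.dtype).type
    losses, dices = [], []
    for cine, masks in studies:
        t_n = cine.frames.shape[0]
        x = Tensor(cine.frames[:, None].astype(dtype))
        probs = network.forward(x, n_frames=t_n, training=False)
        fg = (masks.labels > 0)
        loss = loss_fn(Tensor(probs.data), Tensor(fg[:, None].astype(dtype)))
        losses.append(float(loss.data))
        dices.append(dice(probs.data[:, 0] >= 0.5, fg))
    return float(np.mean(losses)), float(np.mean(dices))
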