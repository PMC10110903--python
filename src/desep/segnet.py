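"""3D segmentation U-Net with bottleneck feature extraction.

The network follows the classic hourglass design: four encoder blocks
(3x3x3 convolution + ReLU + 2x2x2 max pooling), a symmetric decoder
(2x2x2 stride-2 transposed convolution, skip concatenation from the
matching encoder resolution, 3x3x3 convolution + ReLU) and a final 1x1x1
convolution with a two-channel softmax head; the foreground channel is
thresholded at 0.5 (ties assigned to foreground). Training minimizes
per-voxel binary cross-entropy with Adam at learning rate 1e-4.

The pooled output of the deepest encoder block is the "central latent
vector": with the full-scale preset (96x96x48 input, 64/128/256/512
encoder channels) it has shape 6x6x3x512 = 55296 features per volume.
A ``desk`` preset (32x32x16, 8/16/32/64 channels) keeps the same
architecture at a size trainable in minutes on one CPU.

Intensities enter the network on their native calibrated scale by default
(absolute lesion density carries prognostic information); per-volume
z-scoring is available as a config option for uncalibrated inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import DTYPE


@dataclass
class UNetConfig:
    input_shape: tuple[int, int, int] = (96, 96, 48)
    encoder_channels: tuple[int, ...] = (64, 128, 256, 512)
    learning_rate: float = 1e-4
    batch_size: int = 4
    epochs: int = 30
    seed: int = 0
    # "none": intensities enter as-is (CT-like units are calibrated, and
    # absolute lesion density is informative); "zscore": per-volume z-score
    normalization: str = "none"

    @classmethod
    def preset(cls, name: str, **kw) -> "UNetConfig":
        if name == "paper":
            return cls(**kw)
        if name == "desk":
            kw.setdefault("input_shape", (32, 32, 16))
            kw.setdefault("encoder_channels", (8, 16, 32, 64))
            # a desk run makes ~150 optimizer steps; the full-scale rate of
            # 1e-4 would leave it far from converged
            kw.setdefault("learning_rate", 3e-3)
            return cls(**kw)
        raise ValueError(f"unknown preset {name!r}")

    def __post_init__(self):
        n_blocks = len(self.encoder_channels)
        f = 2 ** n_blocks
        if any(s % f != 0 for s in self.input_shape):
            raise ValueError(
                f"input_shape {self.input_shape} not divisible by {f} "
                f"(2^{n_blocks} encoder blocks)")

    @property
    def decoder_deconv_channels(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_channels))

    @property
    def decoder_conv_channels(self) -> tuple[int, ...]:
        return tuple(c // 2 for c in reversed(self.encoder_channels))

    @property
    def bottleneck_shape(self) -> tuple[int, int, int, int]:
        f = 2 ** len(self.encoder_channels)
        x, y, z = (s // f for s in self.input_shape)
        return (x, y, z, self.encoder_channels[-1])

    @property
    def latent_length(self) -> int:
        return int(np.prod(self.bottleneck_shape))


def _normalize(volume: np.ndarray, mode: str = "none") -> np.ndarray:
    v = np.asarray(volume, dtype=DTYPE)
    if mode == "none":
        return v
    if mode == "zscore":
        sd = float(v.std())
        if sd == 0:
            return v - float(v.mean())
        return (v - float(v.mean())) / sd
    raise ValueError(f"unknown normalization {mode!r}")


class SegNetModel:
    """The U-Net: layers, weights, and the training history."""

    def __init__(self, config: UNetConfig, seed: int | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed if seed is None else seed)
        enc = config.encoder_channels
        self.enc_convs, self.enc_relus, self.pools = [], [], []
        c_prev = 1
        for c in enc:
            self.enc_convs.append(_nn.Conv3x3(c_prev, c, rng))
            self.enc_relus.append(_nn.ReLU())
            self.pools.append(_nn.MaxPool2())
            c_prev = c
        self.dec_deconvs, self.dec_convs, self.dec_relus = [], [], []
        c_prev = enc[-1]
        for cd, cc, skip in zip(config.decoder_deconv_channels,
                                config.decoder_conv_channels,
                                reversed(enc)):
            self.dec_deconvs.append(_nn.Deconv2(c_prev, cd, rng))
            self.dec_convs.append(_nn.Conv3x3(cd + skip, cc, rng))
            self.dec_relus.append(_nn.ReLU())
            c_prev = cc
        self.head = _nn.Conv1x1(c_prev, 2, rng)
        self.training_history: list[float] = []

    @property
    def bottleneck_shape(self):
        return self.config.bottleneck_shape

    def _layers(self):
        yield from self.enc_convs
        yield from self.dec_deconvs
        yield from self.dec_convs
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params]

    def zero_grads(self):
        for layer in self._layers():
            for g in layer.grads:
                g[...] = 0

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads]

    def _encode(self, volume: np.ndarray, retain: bool = True
                ) -> tuple[list, np.ndarray]:
        """Encoder pass: returns (pre-pool skip activations, bottleneck)."""
        x = _normalize(volume, self.config.normalization)[..., None]
        skips = []
        for conv, relu, pool in zip(self.enc_convs, self.enc_relus, self.pools):
            a = relu.forward(conv.forward(x, retain=retain))
            skips.append(a)
            x = pool.forward(a)
        return skips, x

    def _forward(self, volume: np.ndarray, retain: bool = True
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Returns (logits (X,Y,Z,2), bottleneck (x,y,z,C))."""
        skips, x = self._encode(volume, retain=retain)
        bottleneck = x
        for deconv, conv, relu, skip in zip(self.dec_deconvs, self.dec_convs,
                                            self.dec_relus, reversed(skips)):
            up = deconv.forward(x)
            x = np.concatenate([up, skip], axis=-1)
            x = relu.forward(conv.forward(x, retain=retain))
        return self.head.forward(x), bottleneck

    def _backward(self, dlogits: np.ndarray):
        dx = self.head.backward(dlogits)
        dskips = []
        for deconv, conv, relu in zip(reversed(self.dec_deconvs),
                                      reversed(self.dec_convs),
                                      reversed(self.dec_relus)):
            dx = conv.backward(relu.backward(dx))
            c_up = deconv.w.shape[-1]
            dup, dskip = dx[..., :c_up], dx[..., c_up:]
            dskips.append(dskip)
            dx = deconv.backward(dup)
        # dskips was filled shallowest-first; the encoder unwinds deepest-first
        for conv, relu, pool, dskip in zip(reversed(self.enc_convs),
                                           reversed(self.enc_relus),
                                           reversed(self.pools),
                                           reversed(dskips)):
            dx = pool.backward(dx) + dskip
            dx = conv.backward(relu.backward(dx))


def build_model(config: UNetConfig, seed: int | None = None) -> SegNetModel:
    """Construct the U-Net with He-style fan-in initialization, seeded."""
    return SegNetModel(config, seed=seed)


def train(model: SegNetModel, dataset, config: UNetConfig | None = None,
          verbose: bool = False) -> SegNetModel:
    """Train in place on (volume, binary mask) pairs; returns the model.

    Per-epoch mean loss is appended to ``model.training_history``. Batches
    accumulate per-sample mean-loss gradients; the epoch ordering is drawn
    from the config seed, so a run is reproducible end to end.
    """
    cfg = config or model.config
    dataset = list(dataset)
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    for vol, mask in dataset:
        if tuple(vol.shape) != tuple(cfg.input_shape):
            raise ValueError(f"volume shape {vol.shape} != {cfg.input_shape}")
        if tuple(mask.shape) != tuple(cfg.input_shape):
            raise ValueError("mask shape mismatch")
    opt = _nn.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grads()
            for i in idx:
                vol, mask = dataset[i]
                logits, _ = model._forward(vol)
                loss, _, dlogits = _nn.softmax_cross_entropy(
                    logits, np.asarray(mask, dtype=DTYPE))
                model._backward(dlogits / len(idx))
                losses.append(loss)
            opt.step(model.grads())
        model.training_history.append(float(np.mean(losses)))
        if verbose:  # pragma: no cover
            print(f"epoch {epoch + 1}/{cfg.epochs} loss {model.training_history[-1]:.4f}")
    return model


def predict_probability(model: SegNetModel, volume: np.ndarray) -> np.ndarray:
    """Foreground probability map."""
    if tuple(volume.shape) != tuple(model.config.input_shape):
        raise ValueError(f"volume shape {volume.shape} != {model.config.input_shape}")
    logits, _ = model._forward(volume, retain=False)
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return (ez / ez.sum(axis=-1, keepdims=True))[..., 1]


def segment(model: SegNetModel, volume: np.ndarray) -> np.ndarray:
    """Binary mask: foreground probability >= 0.5 (ties -> foreground)."""
    return (predict_probability(model, volume) >= 0.5).astype(np.uint8)


def extract_latent(model: SegNetModel, volume: np.ndarray) -> np.ndarray:
    """Flattened bottleneck activations for one volume.

    Flattening is Fortran order over (x, y, z, channel): x varies fastest,
    then y, then z, then channel — stable across calls and versions.
    """
    if tuple(volume.shape) != tuple(model.config.input_shape):
        raise ValueError(f"volume shape {volume.shape} != {model.config.input_shape}")
    _, bottleneck = model._encode(volume, retain=False)
    return np.asarray(bottleneck, dtype=np.float64).flatten(order="F")


# ---------------------------------------------------------------------------
# segmentation quality metrics


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); two empty masks -> 1."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one face-adjacent background
    neighbor (the array edge counts as background). Returns (n, 3) indices."""
    m = np.asarray(mask).astype(bool)
    padded = np.pad(m, 1)
    interior = np.ones_like(m)
    for ax in range(3):
        for sh in (1, -1):
            interior &= np.roll(padded, sh, axis=ax)[1:-1, 1:-1, 1:-1]
    return np.argwhere(m & ~interior)


def assd(mask_a: np.ndarray, mask_b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance between two masks, in mm.

    Mean of the two directed average boundary distances, where distances
    are Euclidean between boundary voxel centers scaled by ``spacing``.
    """
    from scipy.spatial import cKDTree

    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not a.any() or not b.any():
        raise ValueError("ASSD undefined for empty mask")
    sp = np.asarray(spacing, dtype=float)
    pa = boundary_voxels(a) * sp
    pb = boundary_voxels(b) * sp
    d_ab = cKDTree(pb).query(pa)[0].mean()
    d_ba = cKDTree(pa).query(pb)[0].mean()
    return float((d_ab + d_ba) / 2.0)


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: SegNetModel, path):
    """Single-file npz checkpoint: config fields + flat parameter list."""
    cfg = model.config
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters())}
    np.savez_compressed(
        path,
        input_shape=np.asarray(cfg.input_shape),
        encoder_channels=np.asarray(cfg.encoder_channels),
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        seed=cfg.seed,
        normalization=cfg.normalization,
        history=np.asarray(model.training_history),
        **arrays,
    )


def load_model(path) -> SegNetModel:
    with np.load(path) as z:
        cfg = UNetConfig(
            input_shape=tuple(int(v) for v in z["input_shape"]),
            encoder_channels=tuple(int(v) for v in z["encoder_channels"]),
            learning_rate=float(z["learning_rate"]),
            batch_size=int(z["batch_size"]),
            epochs=int(z["epochs"]),
            seed=int(z["seed"]),
            normalization=str(z["normalization"]),
        )
        model = SegNetModel(cfg)
        for i, p in enumerate(model.parameters()):
            p[...] = z[f"p{i}"]
        model.training_history = [float(v) for v in z["history"]]
    return model
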