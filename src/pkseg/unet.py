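"""Anisotropic 3D U-Net for whole-body mouse PET/CT organ segmentation.

The network follows the encoder/decoder design standard for anisotropic
medical volumes: six downsampling steps from a ``(64, 160, 160)`` patch,
where the first two strides act only on the two fine in-plane axes (the
axial axis is sampled ~5x coarser, 0.80 mm vs 0.15 mm) and the last stride
acts only on the axial axis. Channel width starts at 32 and doubles with
each downsampling up to a cap of 320, giving a ``(4, 5, 5)`` x 320
bottleneck. Each resolution holds two conv + instance-norm + leaky-ReLU
blocks; downsampling is a strided convolution, upsampling a transposed
convolution, and skip connections concatenate encoder features into the
decoder at equal resolution.

Stages whose incoming stride is ``(1, 2, 2)`` use ``(1, 3, 3)`` kernels so
the receptive field grows isotropically in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

#: stride entering each level below the input resolution (6 downsamplings)
DEFAULT_STRIDES: tuple[tuple[int, int, int], ...] = (
    (1, 2, 2), (1, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2), (2, 1, 1),
)


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``strides`` lists the downsampling stride entering each level after the
    first; the network has ``len(strides) + 1`` resolutions. When ``strides``
    is None an isotropic schedule with ``n_resolutions`` levels (all-axes
    stride 2) is generated, which is what the small test configurations use.
    """

    in_channels: int = 2
    n_classes: int = 7
    patch_size: tuple[int, int, int] = (64, 160, 160)
    strides: tuple[tuple[int, int, int], ...] | None = DEFAULT_STRIDES
    n_resolutions: int | None = None
    base_kernels: int = 32
    max_kernels: int = 320
    blocks_per_resolution: int = 2

    def __post_init__(self):
        self.patch_size = tuple(int(p) for p in self.patch_size)
        if self.strides is None:
            if self.n_resolutions is None or self.n_resolutions < 2:
                raise ValueError("need strides or n_resolutions >= 2")
            self.strides = tuple((2, 2, 2) for _ in range(self.n_resolutions - 1))
        else:
            self.strides = tuple(tuple(int(x) for x in s) for s in self.strides)
        if self.base_kernels > self.max_kernels:
            raise ValueError("base_kernels exceeds max_kernels")
        cum = np.prod(np.asarray(self.strides), axis=0)
        if any(p % c for p, c in zip(self.patch_size, cum)):
            raise ValueError(
                f"patch {self.patch_size} not divisible by cumulative "
                f"strides {tuple(int(c) for c in cum)}")

    @property
    def n_levels(self) -> int:
        return len(self.strides) + 1

    def channels(self) -> list[int]:
        return [min(self.base_kernels * 2 ** i, self.max_kernels)
                for i in range(self.n_levels)]

    def kernels(self) -> list[tuple[int, int, int]]:
        """Per-level conv kernel; (1,3,3) where the entering stride is (1,2,2)."""
        ks = []
        for i in range(self.n_levels):
            entering = self.strides[i - 1] if i > 0 else self.strides[0]
            ks.append((1, 3, 3) if tuple(entering) == (1, 2, 2) else (3, 3, 3))
        return ks


@dataclass
class ShapeSchedule:
    """Spatial shape and channel count at every encoder level (top to bottleneck)."""

    shapes: list[tuple[int, int, int]] = field(default_factory=list)
    channels: list[int] = field(default_factory=list)

    def __iter__(self):
        return iter(zip(self.shapes, self.channels))


def compute_shape_schedule(cfg: NetConfig) -> ShapeSchedule:
    shapes = [cfg.patch_size]
    for s in cfg.strides:
        prev = shapes[-1]
        shapes.append(tuple(p // st for p, st in zip(prev, s)))
    return ShapeSchedule(shapes=shapes, channels=cfg.channels())


class UNet3D:
    """Encoder-decoder segmentation network on single-sample float32 tensors.

    ``forward`` records the post-activation shape of every encoder level in
    ``last_encoder_shapes`` so the architecture can be audited against
    :func:`compute_shape_schedule` on a live forward pass.
    """

    def __init__(self, cfg: NetConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        ch = cfg.channels()
        ks = cfg.kernels()
        nb = cfg.blocks_per_resolution

        self.enc: list[list[nn.ConvBlock]] = []
        for i in range(cfg.n_levels):
            c_in = cfg.in_channels if i == 0 else ch[i - 1]
            stride = (1, 1, 1) if i == 0 else cfg.strides[i - 1]
            blocks = [nn.ConvBlock(c_in, ch[i], ks[i], stride, rng)]
            for _ in range(nb - 1):
                blocks.append(nn.ConvBlock(ch[i], ch[i], ks[i], 1, rng))
            self.enc.append(blocks)

        self.up: list[nn.ConvTranspose3d] = []
        self.dec: list[list[nn.ConvBlock]] = []
        for i in range(cfg.n_levels - 2, -1, -1):
            self.up.append(nn.ConvTranspose3d(ch[i + 1], ch[i], cfg.strides[i], rng))
            blocks = [nn.ConvBlock(2 * ch[i], ch[i], ks[i], 1, rng)]
            for _ in range(nb - 1):
                blocks.append(nn.ConvBlock(ch[i], ch[i], ks[i], 1, rng))
            self.dec.append(blocks)

        self.head = nn.Conv3d(ch[0], cfg.n_classes, 1, 1, rng)
        self.last_encoder_shapes: list[tuple[int, ...]] = []
        self._acts: dict[str, np.ndarray] = {}

    # ---- parameter plumbing -------------------------------------------------
    def modules(self):
        out = []
        for i, blocks in enumerate(self.enc):
            for j, b in enumerate(blocks):
                out.append((f"enc{i}.block{j}", b))
        for i, u in enumerate(self.up):
            out.append((f"up{i}", u))
        for i, blocks in enumerate(self.dec):
            for j, b in enumerate(blocks):
                out.append((f"dec{i}.block{j}", b))
        out.append(("head", self.head))
        return out

    def params(self):
        p = []
        for _, m in self.modules():
            p.extend(m.params())
        return p

    def n_parameters(self) -> int:
        return sum(int(p.size) for p, _ in self.params())

    @property
    def last_feature_layer(self) -> str:
        """Name of the final decoder conv block (Grad-CAM default target)."""
        return f"dec{len(self.dec) - 1}.block{self.cfg.blocks_per_resolution - 1}"

    # ---- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                record: tuple[str, ...] = ()) -> np.ndarray:
        if x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[0]}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        self.last_encoder_shapes = []
        self._acts = {}
        skips = []
        for i, blocks in enumerate(self.enc):
            for j, b in enumerate(blocks):
                x = b.forward(x, train)
                name = f"enc{i}.block{j}"
                if name in record:
                    self._acts[name] = x
            self.last_encoder_shapes.append(x.shape)
            if i < self.cfg.n_levels - 1:
                skips.append(x)
        for i, (u, blocks) in enumerate(zip(self.up, self.dec)):
            x = u.forward(x, train)
            skip = skips.pop()
            x = np.concatenate([skip, x], axis=0)
            self._skip_ch = skip.shape[0]
            for j, b in enumerate(blocks):
                x = b.forward(x, train)
                name = f"dec{i}.block{j}"
                if name in record:
                    self._acts[name] = x
        return self.head.forward(x, train)

    def backward(self, glogits: np.ndarray,
                 capture: str | None = None) -> np.ndarray | None:
        """Backpropagate; optionally return the gradient at a named activation."""
        captured = None
        g = self.head.backward(glogits)
        skip_grads = []
        for i in range(len(self.dec) - 1, -1, -1):
            for j in range(len(self.dec[i]) - 1, -1, -1):
                if capture == f"dec{i}.block{j}":
                    captured = g
                g = self.dec[i][j].backward(g)
            ch = self.enc[len(self.enc) - 2 - i][0].conv.w.shape[0]
            skip_grads.append(g[:ch])
            g = self.up[i].backward(g[ch:])
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.enc) - 1:
                g = g + skip_grads[i]
            for j in range(len(self.enc[i]) - 1, -1, -1):
                if capture == f"enc{i}.block{j}":
                    captured = g
                g = self.enc[i][j].backward(g)
        return captured if capture else g

    def activation(self, name: str) -> np.ndarray:
        return self._acts[name]

    # ---- checkpointing ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, m in self.modules():
            if isinstance(m, nn.ConvBlock):
                state[f"{name}.w"] = m.conv.w
                state[f"{name}.b"] = m.conv.b
                state[f"{name}.gamma"] = m.norm.gamma
                state[f"{name}.beta"] = m.norm.beta
            else:
                state[f"{name}.w"] = m.w
                state[f"{name}.b"] = m.b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, m in self.modules():
            if isinstance(m, nn.ConvBlock):
                m.conv.w[...] = state[f"{name}.w"]
                m.conv.b[...] = state[f"{name}.b"]
                m.norm.gamma[...] = state[f"{name}.gamma"]
                m.norm.beta[...] = state[f"{name}.beta"]
            else:
                m.w[...] = state[f"{name}.w"]
                m.b[...] = state[f"{name}.b"]


def build_network(cfg: NetConfig, seed: int | None = None) -> UNet3D:
    return UNet3D(cfg, np.random.default_rng(seed))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=0, keepdims=True)


def dice_ce_loss(logits: np.ndarray, target: np.ndarray,
                 eps: float = 1e-5) -> tuple[float, np.ndarray]:
    """Soft Dice + cross-entropy loss and its gradient w.r.t. the logits.

    ``target`` holds integer class indices on the logits' spatial grid.
    """
    n_classes = logits.shape[0]
    p = softmax(logits)
    nvox = target.size
    flat_t = target.ravel()
    onehot = np.zeros_like(p)
    idx = np.unravel_index(np.arange(nvox), target.shape)
    onehot[(flat_t,) + idx] = 1.0

    ce = -np.log(np.clip(p[(flat_t,) + idx], 1e-12, None)).mean()
    gce = (p - onehot) / nvox

    inter = (p * onehot).sum(axis=(1, 2, 3))
    denom = p.sum(axis=(1, 2, 3)) + onehot.sum(axis=(1, 2, 3))
    dice = (2 * inter + eps) / (denom + eps)
    dice_loss = 1.0 - dice.mean()
    # d(dice_c)/dp_c = (2*g - dice_c*... ) via quotient rule, then softmax jac
    gp = -(2 * onehot * (denom + eps)[:, None, None, None]
           - (2 * inter + eps)[:, None, None, None]) \
        / ((denom + eps) ** 2)[:, None, None, None] / n_classes
    dot = (gp * p).sum(axis=0, keepdims=True)
    gdice = p * (gp - dot)

    return float(ce + dice_loss), (gce + gdice).astype(np.float32)
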