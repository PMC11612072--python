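"""Residual segmentation backbone and siamese patch encoder.

The backbone is an encoder–decoder built from the layers in
:mod:`segpretext.nn.layers`: a stem convolution, a stride-2 downsampling
convolution, residual blocks at half resolution, nearest-neighbor upsampling
back to full resolution and a 1×1 head convolution with either a sigmoid
(regression, one channel) or per-pixel softmax (classification) output.  The
``layers`` parameter counts convolutional layers, head included, so the
default ``layers=20`` yields a twenty-convolution residual network.

The encoder half doubles as the trunk of the siamese patch encoder used for
contrastive pretraining: global-average pooling plus a linear projection turn
its feature maps into a fixed-size embedding regardless of input size.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    ChannelSoftmax,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    Param,
    ReLU,
    ResBlock,
    Sequential,
    Sigmoid,
    Upsample2x,
)

__all__ = ["SegmentationNet", "ContrastiveEncoder", "copy_weights", "conv_layer_count", "Adam"]


def _build_trunk(layers: int, width: int, in_ch: int, rng: np.random.Generator
                 ) -> tuple[Sequential, Sequential, int]:
    """Return (encoder, decoder) layer stacks; decoder may be empty.

    Conv budget: encoder stem (1) + downsample (1) + middle (layers-4) and
    decoder post-upsample conv (1); the 1×1 head conv supplies the last one.
    """
    if layers < 2:
        raise ValueError(f"need at least 2 layers, got {layers}")
    enc: list[Layer] = [Conv2d(in_ch, width, rng=rng), ReLU()]
    if layers >= 6:
        enc += [Conv2d(width, width, stride=2, rng=rng), ReLU()]
        mid = layers - 4
        for _ in range(mid // 2):
            enc.append(ResBlock(width, rng=rng))
        if mid % 2:
            enc += [Conv2d(width, width, rng=rng), ReLU()]
        # decoder conv runs at half resolution, before upsampling
        dec: list[Layer] = [Conv2d(width, width, rng=rng), ReLU()]
        used = 2 + mid + 1
    else:
        for _ in range(layers - 2):
            enc += [Conv2d(width, width, rng=rng), ReLU()]
        dec = []
        used = layers - 1
    return Sequential(enc), Sequential(dec), used


class SegmentationNet(Layer):
    """Residual encoder–decoder producing per-pixel outputs at input size."""

    def __init__(self, layers: int = 20, width: int = 16, in_ch: int = 1,
                 out_ch: int = 1, head: str = "sigmoid",
                 rng: np.random.Generator | None = None):
        if head not in ("sigmoid", "softmax"):
            raise ValueError(f"head must be 'sigmoid' or 'softmax', got {head!r}")
        if head == "softmax" and out_ch < 2:
            raise ValueError("softmax head needs out_ch >= 2")
        rng = rng or np.random.default_rng()
        self.layers_spec = layers
        self.width = width
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.head_kind = head
        self.encoder, self.decoder, _ = _build_trunk(layers, width, in_ch, rng)
        self.downsampled = layers >= 6
        self.upsample = Upsample2x() if self.downsampled else None
        self.head_conv = Conv2d(width, out_ch, ksize=1, rng=rng)
        self.head_act: Layer = Sigmoid() if head == "sigmoid" else ChannelSoftmax()

    # -- parameter access -------------------------------------------------
    def params(self) -> list[Param]:
        return self.encoder.params() + self.decoder.params() + self.head_params()

    def trunk_params(self) -> list[Param]:
        return self.encoder.params() + self.decoder.params()

    def encoder_params(self) -> list[Param]:
        return self.encoder.params()

    def head_params(self) -> list[Param]:
        return self.head_conv.params()

    # -- computation -------------------------------------------------------
    def forward(self, x):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        hw = x.shape[2:]
        h, ce = self.encoder.forward(x)
        h, cd = self.decoder.forward(h)
        if self.downsampled:
            h, cu = self.upsample.forward(h, out_hw=hw)
        else:
            cu = None
        h, ch = self.head_conv.forward(h)
        y, ca = self.head_act.forward(h)
        return y, (ce, cd, cu, ch, ca)

    def backward(self, gy, cache):
        ce, cd, cu, ch, ca = cache
        g = self.head_act.backward(gy, ca)
        g = self.head_conv.backward(g, ch)
        if self.downsampled:
            g = self.upsample.backward(g, cu)
        g = self.decoder.backward(g, cd)
        return self.encoder.backward(g, ce)

    def predict(self, x) -> np.ndarray:
        """Forward pass only; for a softmax head, returns per-class scores."""
        y, _ = self.forward(x)
        return y


class ContrastiveEncoder(Layer):
    """Siamese branch: segmentation encoder + GAP + linear embedding head.

    Both branches of the siamese pair are this one object — the weights are
    shared by construction and gradients from the two branches accumulate in
    the same parameters.
    """

    def __init__(self, layers: int = 20, width: int = 16, in_ch: int = 1,
                 embed_dim: int = 64, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.layers_spec = layers
        self.width = width
        self.in_ch = in_ch
        self.embed_dim = embed_dim
        self.encoder, _, _ = _build_trunk(layers, width, in_ch, rng)
        self.pool = GlobalAvgPool()
        self.proj = Linear(width, embed_dim, rng=rng)

    def params(self) -> list[Param]:
        return self.encoder.params() + self.proj.params()

    def forward(self, x):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        h, ce = self.encoder.forward(x)
        h, cp = self.pool.forward(h)
        z, cl = self.proj.forward(h)
        return z, (ce, cp, cl)

    def backward(self, gz, cache):
        ce, cp, cl = cache
        g = self.proj.backward(gz, cl)
        g = self.pool.backward(g, cp)
        return self.encoder.backward(g, ce)

    def embed(self, x) -> np.ndarray:
        z, _ = self.forward(x)
        return z


def copy_weights(src_params: list[Param], dst_params: list[Param]) -> None:
    """Copy parameter values positionally; shapes must match exactly."""
    if len(src_params) != len(dst_params):
        raise ValueError(f"parameter count mismatch: {len(src_params)} vs {len(dst_params)}")
    for s, d in zip(src_params, dst_params):
        if s.value.shape != d.value.shape:
            raise ValueError(f"shape mismatch: {s.value.shape} vs {d.value.shape}")
        d.value[...] = s.value


def conv_layer_count(model: Layer) -> int:
    """Number of convolutional layers in a model, head included."""
    count = 0
    stack = [model]
    seen: set[int] = set()
    while stack:
        obj = stack.pop()
        if id(obj) in seen:
            continue
        seen.add(id(obj))
        if isinstance(obj, Conv2d):
            count += 1
        for attr in vars(obj).values():
            if isinstance(attr, Layer):
                stack.append(attr)
            elif isinstance(attr, list):
                stack.extend(a for a in attr if isinstance(a, Layer))
    return count


class Adam:
    """Adam optimizer over a parameter list; learning rate settable per step."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        # dedupe shared params so one step applies one update
        seen: set[int] = set()
        self.params = []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                self.params.append(p)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float | None = None) -> None:
        if lr is not None:
            self.lr = lr
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def lr_schedule(lr_start: float, lr_end: float, total_steps: int) -> list[float]:
    """Geometric decay from lr_start to lr_end over total_steps steps."""
    if total_steps <= 1:
        return [lr_start] * max(total_steps, 0)
    ratio = lr_end / lr_start
    return [lr_start * ratio ** (t / (total_steps - 1)) for t in range(total_steps)]
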