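"""Generic 2D/3D U-Net with optional residual encoder and deep supervision.

The network is assembled from the explicit layers in
:mod:`caroseg.nn.layers`; forward passes cache the activations that the
hand-written backward pass needs.  Spatial sizes must be divisible by
``2**(encoder_stages - 1)``; :meth:`UNet.pad_input` provides the padding and
bookkeeping to lift that restriction at inference time.

Downsampling is by strided convolution, except for encoder stages listed in
``avgpool_stages`` of a residual encoder, which pool their input with
average pooling before a stride-1 residual block.  Upsampling is by
transposed convolution; skip connections concatenate encoder features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import AvgPool, ConvND, InstanceNorm, Layer, LeakyReLU, TransposedConvND

__all__ = ["UNetSpec", "UNet"]


@dataclass(frozen=True)
class UNetSpec:
    ndim: int = 2
    encoder_stages: int = 8
    base_channels: int = 32
    max_channels: int = 320
    in_channels: int = 1
    out_channels: int = 1
    residual: bool = False
    avgpool_stages: tuple[int, ...] = ()  # 0-based encoder stage indices
    deep_supervision: bool = True
    slope: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        if self.encoder_stages < 2:
            raise ValueError("need at least 2 encoder stages")

    @property
    def decoder_stages(self) -> int:
        return self.encoder_stages - 1

    @property
    def divisor(self) -> int:
        return 2 ** (self.encoder_stages - 1)

    def channels(self, stage: int) -> int:
        return min(self.base_channels * 2**stage, self.max_channels)


class _ConvNormAct:
    def __init__(self, cin, cout, ndim, stride, slope, rng):
        self.conv = ConvND(cin, cout, ndim, kernel=3, stride=stride, rng=rng)
        self.norm = InstanceNorm(cout, ndim)
        self.act = LeakyReLU(slope)

    def forward(self, x, train=True):
        return self.act.forward(self.norm.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.norm.backward(self.act.backward(dy)))

    def layers(self):
        return [self.conv, self.norm]


class _EncoderStage:
    """Two conv(+norm+act) blocks, optional residual shortcut and downsampling."""

    def __init__(self, cin, cout, ndim, downsample, residual, slope, rng):
        self.residual = residual
        self.pool = AvgPool(ndim) if downsample == "avgpool" else None
        stride = 2 if downsample == "stride" else 1
        self.cna1 = _ConvNormAct(cin, cout, ndim, stride, slope, rng)
        self.conv2 = ConvND(cout, cout, ndim, kernel=3, stride=1, rng=rng)
        self.norm2 = InstanceNorm(cout, ndim)
        self.act2 = LeakyReLU(slope)
        self.shortcut = None
        if residual and (cin != cout or stride != 1):
            self.shortcut = ConvND(cin, cout, ndim, kernel=1, stride=stride, rng=rng)

    def forward(self, x, train=True):
        if self.pool is not None:
            x = self.pool.forward(x, train)
        h = self.cna1.forward(x, train)
        h = self.norm2.forward(self.conv2.forward(h, train), train)
        if self.residual:
            sc = x if self.shortcut is None else self.shortcut.forward(x, train)
            h = h + sc
        return self.act2.forward(h, train)

    def backward(self, dy):
        d = self.act2.backward(dy)
        dx = self.cna1.backward(self.conv2.backward(self.norm2.backward(d)))
        if self.residual:
            dx = dx + (d if self.shortcut is None else self.shortcut.backward(d))
        if self.pool is not None:
            dx = self.pool.backward(dx)
        return dx

    def layers(self):
        out = self.cna1.layers() + [self.conv2, self.norm2]
        if self.shortcut is not None:
            out.append(self.shortcut)
        return out


class _DecoderStage:
    def __init__(self, cin_deep, c_skip, ndim, slope, rng):
        self.c_up = c_skip
        self.up = TransposedConvND(cin_deep, c_skip, ndim, rng=rng)
        self.cna1 = _ConvNormAct(2 * c_skip, c_skip, ndim, 1, slope, rng)
        self.cna2 = _ConvNormAct(c_skip, c_skip, ndim, 1, slope, rng)

    def forward(self, deep, skip, train=True):
        u = self.up.forward(deep, train)
        cat = np.concatenate([u, skip], axis=1)
        return self.cna2.forward(self.cna1.forward(cat, train), train)

    def backward(self, dy):
        dcat = self.cna1.backward(self.cna2.backward(dy))
        du = np.ascontiguousarray(dcat[:, : self.c_up])
        dskip = np.ascontiguousarray(dcat[:, self.c_up :])
        return self.up.backward(du), dskip

    def layers(self):
        return [self.up] + self.cna1.layers() + self.cna2.layers()


class UNet:
    """Encoder-decoder segmentation network over 2D or 3D inputs."""

    def __init__(self, spec: UNetSpec) -> None:
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        E, nd = spec.encoder_stages, spec.ndim
        self.encoder: list[_EncoderStage] = []
        for i in range(E):
            cin = spec.in_channels if i == 0 else spec.channels(i - 1)
            if i == 0:
                down = None
            elif spec.residual and i in spec.avgpool_stages:
                down = "avgpool"
            else:
                down = "stride"
            self.encoder.append(
                _EncoderStage(cin, spec.channels(i), nd, down, spec.residual, spec.slope, rng)
            )
        self.decoder: list[_DecoderStage] = []
        for r in range(E - 2, -1, -1):  # built deepest-first
            self.decoder.append(
                _DecoderStage(spec.channels(r + 1), spec.channels(r), nd, spec.slope, rng)
            )
        self.n_heads = min(3, spec.decoder_stages) if spec.deep_supervision else 1
        self.heads = [
            ConvND(spec.channels(r), spec.out_channels, nd, kernel=1, rng=rng)
            for r in range(self.n_heads)
        ]

    # -- plumbing ----------------------------------------------------------
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for st in self.encoder:
            out += st.layers()
        for st in self.decoder:
            out += st.layers()
        out += self.heads
        return out

    @property
    def num_params(self) -> int:
        return sum(p.size for layer in self.layers() for p in layer.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers()):
            for k, v in layer.params.items():
                out[f"layer{i:03d}.{k}"] = v.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers()):
            for k in layer.params:
                layer.params[k] = np.array(state[f"layer{i:03d}.{k}"], dtype=np.float32)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> list[np.ndarray]:
        """Return logits per head, finest resolution first."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        div = self.spec.divisor
        if any(s % div for s in x.shape[2:]):
            raise ValueError(
                f"spatial sizes {x.shape[2:]} must be divisible by {div}; use pad_input"
            )
        enc = []
        h = x
        for st in self.encoder:
            h = st.forward(h, train)
            enc.append(h)
        E = self.spec.encoder_stages
        dec_out: dict[int, np.ndarray] = {}
        h = enc[-1]
        for idx, st in enumerate(self.decoder):
            r = E - 2 - idx
            h = st.forward(h, enc[r], train)
            dec_out[r] = h
        logits = [
            head.forward(dec_out[r], train) for r, head in enumerate(self.heads)
        ]
        if train:
            self._E = E
        return logits

    def backward(self, dlogits: list[np.ndarray]) -> None:
        E = self._E
        d_dec: dict[int, np.ndarray | None] = {r: None for r in range(E - 1)}
        for r, (head, dl) in enumerate(zip(self.heads, dlogits)):
            if dl is None:
                continue
            g = head.backward(np.ascontiguousarray(dl, dtype=np.float32))
            d_dec[r] = g if d_dec[r] is None else d_dec[r] + g
        d_enc: dict[int, np.ndarray | None] = {i: None for i in range(E)}
        for r in range(E - 1):  # finest decoder stage first
            st = self.decoder[E - 2 - r]
            dy = d_dec[r]
            if dy is None:
                dy = np.zeros(0)  # unreachable in practice: head 0 always exists
            ddeep, dskip = st.backward(dy)
            d_enc[r] = dskip if d_enc[r] is None else d_enc[r] + dskip
            if r + 1 <= E - 2:
                d_dec[r + 1] = ddeep if d_dec[r + 1] is None else d_dec[r + 1] + ddeep
            else:
                d_enc[E - 1] = ddeep if d_enc[E - 1] is None else d_enc[E - 1] + ddeep
        d = None
        for i in range(E - 1, 0, -1):
            dy = d_enc[i] if d is None else d_enc[i] + d
            d = self.encoder[i].backward(dy)
        # stage 0 gradient w.r.t. the input is not needed
        self.encoder[0].backward(d_enc[0] + d if d is not None else d_enc[0])

    # -- inference helpers -------------------------------------------------
    def pad_input(self, x: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
        """Zero-pad trailing spatial edges to the net's divisibility."""
        div = self.spec.divisor
        pads = [(0, 0), (0, 0)]
        for s in x.shape[2:]:
            extra = (-s) % div
            pads.append((0, extra))
        return np.pad(x, pads), pads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Foreground probability at input resolution (handles padding)."""
        from .losses import sigmoid

        xp, pads = self.pad_input(np.ascontiguousarray(x, dtype=np.float32))
        logits = self.forward(xp, train=False)[0]
        sl = tuple(slice(0, s) for s in x.shape[2:])
        return sigmoid(logits)[(slice(None), slice(None)) + sl]
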