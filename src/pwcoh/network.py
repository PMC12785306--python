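"""Five-level encoder–decoder enhancer for 2-channel I/Q images, in numpy.

The network maps an I/Q frame packed as ``(2, H, W)`` (channel 0 =
in-phase, channel 1 = quadrature) to an enhanced frame of identical shape:
an encoder of convolutional blocks (default widths 32→64→128→256→512,
each block two 3×3 convolutions with LeakyReLU, negative slope 0.2)
separated by 2×2 max pooling, a mirrored decoder with ×2 upsampling and
skip concatenation, and a final 1×1 convolution with tanh for bounded
output. Weights use Kaiming-normal initialization. The deep stack gives a
receptive field large enough to span the long-range reverberation
structures the coherence loss must learn to remove.

Forward *and* backward passes are implemented here directly on numpy
arrays (every layer caches what its gradient needs), so the enhancer can
be trained without an autodiff framework; gradient correctness is checked
against finite differences in the test suite. Convolutions are evaluated
as nine shifted channel-mixing matmuls, which keeps both directions
vectorized.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkSpec",
    "UNet",
    "build_enhancer",
    "enhance",
    "complex_to_channels",
    "channels_to_complex",
    "receptive_field",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description; the parameter count is a pure function of it."""

    channel_widths: tuple[int, ...] = (32, 64, 128, 256, 512)
    negative_slope: float = 0.2
    upsample: str = "nearest"  # 'nearest' (resize + 3x3 conv) or 'transposed'
    in_channels: int = 2
    out_channels: int = 2
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if len(self.channel_widths) < 2:
            raise ValueError("need at least two levels")
        if self.upsample not in ("nearest", "transposed"):
            raise ValueError("upsample must be 'nearest' or 'transposed'")

    @property
    def depth(self) -> int:
        return len(self.channel_widths)

    @property
    def divisor(self) -> int:
        """Spatial dims must divide by this (one 2×2 pooling between levels)."""
        return 2 ** (self.depth - 1)


def _kaiming_std(fan_in: int, negative_slope: float) -> float:
    return float(np.sqrt(2.0 / ((1.0 + negative_slope**2) * fan_in)))


class _Conv2d:
    """k×k 'same' convolution (k in {1, 3}), stride 1, zero padding."""

    def __init__(self, name, c_in, c_out, k, rng, negative_slope, dtype):
        self.name = name
        self.k = k
        std = _kaiming_std(c_in * k * k, negative_slope)
        self.W = rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp = None

    def forward(self, x):
        k = self.k
        pad = k // 2
        c_in, H, W_ = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad))) if pad else x
        self._xp = xp
        out = np.empty((self.W.shape[0], H, W_), dtype=x.dtype)
        out[:] = self.b[:, None, None]
        for di in range(k):
            for dj in range(k):
                out += np.tensordot(
                    self.W[:, :, di, dj], xp[:, di : di + H, dj : dj + W_], axes=(1, 0)
                )
        return out

    def backward(self, dy):
        k = self.k
        pad = k // 2
        _, H, W_ = dy.shape
        xp = self._xp
        self.db += dy.sum(axis=(1, 2))
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                sl = xp[:, di : di + H, dj : dj + W_]
                self.dW[:, :, di, dj] += np.tensordot(dy, sl, axes=((1, 2), (1, 2)))
                dxp[:, di : di + H, dj : dj + W_] += np.tensordot(
                    self.W[:, :, di, dj], dy, axes=(0, 0)
                )
        return dxp[:, pad : pad + H, pad : pad + W_] if pad else dxp

    def params(self):
        return [(f"{self.name}.W", self), (f"{self.name}.b", self)]


class _ConvTranspose2x2:
    """2×2 stride-2 transposed convolution (flagged upsampling variant)."""

    def __init__(self, name, c_in, c_out, rng, negative_slope, dtype):
        self.name = name
        self.k = 2
        std = _kaiming_std(c_in, negative_slope)
        self.W = rng.normal(0.0, std, size=(c_in, c_out, 2, 2)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x):
        self._x = x
        c_in, H, W_ = x.shape
        out = np.empty((self.W.shape[1], 2 * H, 2 * W_), dtype=x.dtype)
        out[:] = self.b[:, None, None]
        for di in range(2):
            for dj in range(2):
                out[:, di::2, dj::2] += np.tensordot(self.W[:, :, di, dj], x, axes=(0, 0))
        return out

    def backward(self, dy):
        x = self._x
        self.db += dy.sum(axis=(1, 2))
        dx = np.zeros_like(x)
        for di in range(2):
            for dj in range(2):
                d = dy[:, di::2, dj::2]
                self.dW[:, :, di, dj] += np.tensordot(x, d, axes=((1, 2), (1, 2)))
                dx += np.tensordot(self.W[:, :, di, dj], d, axes=(1, 0))
        return dx


class _LeakyReLU:
    def __init__(self, slope):
        self.slope = slope
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class _MaxPool2:
    def __init__(self):
        self._arg = None
        self._shape = None

    def forward(self, x):
        C, H, W_ = x.shape
        self._shape = x.shape
        xr = x.reshape(C, H // 2, 2, W_ // 2, 2).transpose(0, 1, 3, 2, 4).reshape(C, H // 2, W_ // 2, 4)
        self._arg = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        C, H, W_ = self._shape
        dxr = np.zeros((C, H // 2, W_ // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        return dxr.reshape(C, H // 2, W_ // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(C, H, W_)


class _UpsampleNearest2:
    def forward(self, x):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        C, H, W_ = dy.shape
        return dy.reshape(C, H // 2, 2, W_ // 2, 2).sum(axis=(2, 4))


class _Tanh:
    def __init__(self):
        self._y = None

    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class _Block:
    """Two 3×3 convolutions, each followed by LeakyReLU."""

    def __init__(self, name, c_in, c_out, rng, slope, dtype):
        self.conv1 = _Conv2d(f"{name}.conv1", c_in, c_out, 3, rng, slope, dtype)
        self.act1 = _LeakyReLU(slope)
        self.conv2 = _Conv2d(f"{name}.conv2", c_out, c_out, 3, rng, slope, dtype)
        self.act2 = _LeakyReLU(slope)

    def forward(self, x):
        return self.act2.forward(self.conv2.forward(self.act1.forward(self.conv1.forward(x))))

    def backward(self, dy):
        return self.conv1.backward(self.act1.backward(self.conv2.backward(self.act2.backward(dy))))

    def convs(self):
        return [self.conv1, self.conv2]


class UNet:
    """The enhancer network; build via :func:`build_enhancer`."""

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(seed)
        dtype = np.dtype(spec.dtype).type
        w = spec.channel_widths
        slope = spec.negative_slope
        self.enc = []
        c_prev = spec.in_channels
        for level, c in enumerate(w[:-1]):
            self.enc.append(_Block(f"enc{level}", c_prev, c, rng, slope, dtype))
            c_prev = c
        self.pools = [_MaxPool2() for _ in w[:-1]]
        self.bottleneck = _Block("bottleneck", w[-2], w[-1], rng, slope, dtype)
        self.ups = []
        self.up_convs = []
        self.up_acts = []
        self.dec = []
        c_prev = w[-1]
        for level in reversed(range(len(w) - 1)):
            c = w[level]
            if spec.upsample == "nearest":
                self.ups.append(_UpsampleNearest2())
                self.up_convs.append(_Conv2d(f"up{level}", c_prev, c, 3, rng, slope, dtype))
            else:
                self.ups.append(None)
                self.up_convs.append(
                    _ConvTranspose2x2(f"up{level}", c_prev, c, rng, slope, dtype)
                )
            self.up_acts.append(_LeakyReLU(slope))
            self.dec.append(_Block(f"dec{level}", 2 * c, c, rng, slope, dtype))
            c_prev = c
        self.head = _Conv2d("head", w[0], spec.out_channels, 1, rng, slope, dtype)
        self.out_act = _Tanh()

    # -- parameter plumbing ------------------------------------------------
    def _conv_layers(self):
        layers = []
        for b in self.enc:
            layers += b.convs()
        layers += self.bottleneck.convs()
        for up_conv, block in zip(self.up_convs, self.dec):
            layers.append(up_conv)
            layers += block.convs()
        layers.append(self.head)
        return layers

    def parameters(self):
        """Yield (name, layer, attr) triples for every trainable array."""
        for layer in self._conv_layers():
            yield f"{layer.name}.W", layer, "W"
            yield f"{layer.name}.b", layer, "b"

    def zero_grad(self):
        for layer in self._conv_layers():
            layer.dW[...] = 0.0
            layer.db[...] = 0.0

    @property
    def n_parameters(self) -> int:
        return sum(getattr(layer, attr).size for _, layer, attr in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(layer, attr).copy() for name, layer, attr in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, attr in self.parameters():
            current = getattr(layer, attr)
            new = np.asarray(state[name], dtype=current.dtype)
            if new.shape != current.shape:
                raise ValueError(f"shape mismatch for {name}: {new.shape} vs {current.shape}")
            setattr(layer, attr, new.copy())

    def parameter_hash(self) -> str:
        h = hashlib.sha256()
        for name, layer, attr in self.parameters():
            h.update(name.encode())
            h.update(np.ascontiguousarray(getattr(layer, attr)).tobytes())
        return h.hexdigest()

    # -- forward / backward ------------------------------------------------
    def _check_shape(self, x):
        if x.ndim != 3 or x.shape[0] != self.spec.in_channels:
            raise ValueError(f"expected ({self.spec.in_channels}, H, W) input, got {x.shape}")
        d = self.spec.divisor
        if x.shape[1] % d or x.shape[2] % d:
            raise ValueError(
                f"spatial dims {x.shape[1]}x{x.shape[2]} must be divisible by {d} "
                f"({self.spec.depth - 1} pooling stages)"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_shape(x)
        x = np.asarray(x, dtype=self.spec.dtype)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        for up, up_conv, up_act, block, skip in zip(
            self.ups, self.up_convs, self.up_acts, self.dec, reversed(skips)
        ):
            x = up.forward(x) if up is not None else x
            x = up_act.forward(up_conv.forward(x))
            x = np.concatenate([skip, x], axis=0)
            x = block.forward(x)
        self._n_skip_channels = [s.shape[0] for s in skips]
        return self.out_act.forward(self.head.forward(x))

    __call__ = forward

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(output); accumulates parameter grads."""
        g = self.head.backward(self.out_act.backward(dy))
        skip_grads = []
        for up, up_conv, up_act, block, c_skip in zip(
            reversed(self.ups),
            reversed(self.up_convs),
            reversed(self.up_acts),
            reversed(self.dec),
            self._n_skip_channels,
        ):
            g = block.backward(g)
            skip_grads.append(g[:c_skip])
            g = up_conv.backward(up_act.backward(g[c_skip:]))
            g = up.backward(g) if up is not None else g
        g = self.bottleneck.backward(g)
        for block, pool, sg in zip(reversed(self.enc), reversed(self.pools), reversed(skip_grads)):
            g = pool.backward(g)
            g = block.backward(g + sg)
        return g


def build_enhancer(spec: NetworkSpec = NetworkSpec(), seed: int = 0) -> UNet:
    """Construct a seeded enhancer; identical seeds give identical weights."""
    return UNet(spec, seed)


def complex_to_channels(frame: np.ndarray) -> np.ndarray:
    """Pack a complex image into the (I, Q) channel layout."""
    frame = np.asarray(frame)
    return np.stack([frame.real, frame.imag]).astype(np.float64)


def channels_to_complex(channels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`complex_to_channels` (lossless round trip)."""
    return np.asarray(channels[0], dtype=np.float64) + 1j * np.asarray(
        channels[1], dtype=np.float64
    )


def enhance(net: UNet, frame: np.ndarray, check_normalized: bool = True) -> np.ndarray:
    """Run the enhancer on one complex I/Q frame; returns a complex image."""
    m = float(np.max(np.abs(frame))) if frame.size else 0.0
    if check_normalized and m > 1.0 + 1e-6:
        warnings.warn(
            f"input max modulus {m:.3g} > 1; the enhancer expects max-abs-normalized frames",
            stacklevel=2,
        )
    out = net.forward(complex_to_channels(frame))
    return channels_to_complex(out)


def receptive_field(spec: NetworkSpec) -> int:
    """Analytic receptive field (pixels) of one output pixel at full resolution."""
    rf, jump = 1, 1
    n_levels = spec.depth - 1
    for _ in range(n_levels):
        rf += 2 * 2 * jump  # two 3x3 convs
        rf += jump  # 2x2 pool
        jump *= 2
    rf += 2 * 2 * jump  # bottleneck block
    for _ in range(n_levels):
        jump //= 2
        rf += 2 * jump  # up conv
        rf += 2 * 2 * jump  # decoder block
    return rf


def save_checkpoint(net: UNet, path) -> Path:
    """Single-file archive: weight arrays + the NetworkSpec as JSON metadata."""
    path = Path(path)
    spec_json = json.dumps(
        {
            "channel_widths": list(net.spec.channel_widths),
            "negative_slope": net.spec.negative_slope,
            "upsample": net.spec.upsample,
            "in_channels": net.spec.in_channels,
            "out_channels": net.spec.out_channels,
            "dtype": net.spec.dtype,
        }
    )
    with open(path, "wb") as fh:
        np.savez(
            fh, __spec__=np.frombuffer(spec_json.encode(), dtype=np.uint8), **net.state_dict()
        )
    return path


def load_checkpoint(path) -> UNet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__spec__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__spec__"}
    spec = NetworkSpec(
        channel_widths=tuple(meta["channel_widths"]),
        negative_slope=meta["negative_slope"],
        upsample=meta["upsample"],
        in_channels=meta["in_channels"],
        out_channels=meta["out_channels"],
        dtype=meta["dtype"],
    )
    net = UNet(spec, seed=0)
    net.load_state_dict(state)
    return net
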