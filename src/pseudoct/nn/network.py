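"""The convolutional encoder-decoder with symmetric additive shortcuts.

Topology
--------
The encoder is a VGG-style stack: each stage is ``n_conv`` unit layers
(convolution → batch-norm → ReLU) followed by 2×2 stride-2 max pooling,
with the filter count growing stage by stage.  The decoder mirrors the
stages in reverse, replacing every pool by ×2 bilinear un-pooling, and
ends in a single-filter convolution that synthesises the output image.

Shortcut connections are additive and parameter-free.  The feature map
tapped just before each encoder pool is added elementwise into the
decoder at the matched resolution, inserted after the first decoder
convolution of the mirror stage and *before* that unit's batch-norm and
ReLU (the full pre-activation residual insertion).  A final shortcut
adds the input image directly to the single-channel output; both live
in the normalised Softsign domain, where the addition is well defined.

The full-scale configuration uses the 13-convolution VGG16 encoder
(stages (2,64),(2,128),(3,256),(3,512),(3,512)) with four encoder→
decoder shortcuts; reduced desk-scale instances share the same code
path.  Input sides must be divisible by ``2^n_stages`` so pooling and
un-pooling round-trip exactly; ``predict`` pads other sizes (e.g.
200×180 → 224×192) with the normalised-air constant and crops back.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field

import numpy as np

from pseudoct._seeding import rng_for
from pseudoct.nn.layers import BatchNorm2d, BilinearUp2x, Conv2d, MaxPool2x2, ReLU

__all__ = ["NetworkSpec", "EncoderDecoder", "build_network",
           "save_checkpoint", "load_checkpoint"]

VGG16_STAGES = ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative encoder-decoder topology.

    ``shortcut_stages=None`` selects every inter-stage boundary, i.e.
    stages 0..n_stages−2 (four shortcuts for the five-stage full
    configuration).
    """

    stages: tuple[tuple[int, int], ...] = VGG16_STAGES
    kernel_size: int = 3
    shortcut_stages: tuple[int, ...] | None = None
    input_output_shortcut: bool = True
    init: str = "he_normal"

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("at least one stage required")
        filters = [f for _, f in self.stages]
        if any(f2 < f1 for f1, f2 in zip(filters, filters[1:])):
            raise ValueError("filter counts must be non-decreasing across stages")
        if self.init != "he_normal":
            raise ValueError(f"unknown init {self.init!r}")
        for s in self.resolved_shortcuts():
            if not 0 <= s < len(self.stages):
                raise ValueError(f"shortcut stage {s} out of range")

    def resolved_shortcuts(self) -> tuple[int, ...]:
        if self.shortcut_stages is None:
            return tuple(range(len(self.stages) - 1))
        return tuple(sorted(set(self.shortcut_stages)))

    @property
    def n_conv_layers(self) -> int:
        return sum(n for n, _ in self.stages)

    @property
    def is_full_scale(self) -> bool:
        """True for the 13-conv VGG16 ladder with all four shortcuts."""
        return (self.stages == VGG16_STAGES and self.n_conv_layers == 13
                and len(self.resolved_shortcuts()) == 4
                and self.input_output_shortcut)

    @classmethod
    def reduced(cls, stages=((1, 16), (1, 32), (2, 64)), **kw) -> "NetworkSpec":
        return cls(stages=tuple(tuple(s) for s in stages), **kw)

    def to_dict(self) -> dict:
        return {
            "stages": [list(s) for s in self.stages],
            "kernel_size": self.kernel_size,
            "shortcut_stages": (None if self.shortcut_stages is None
                                else list(self.shortcut_stages)),
            "input_output_shortcut": self.input_output_shortcut,
            "init": self.init,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            stages=tuple(tuple(s) for s in d["stages"]),
            kernel_size=d.get("kernel_size", 3),
            shortcut_stages=(None if d.get("shortcut_stages") is None
                             else tuple(d["shortcut_stages"])),
            input_output_shortcut=d.get("input_output_shortcut", True),
            init=d.get("init", "he_normal"),
        )


class EncoderDecoder:
    """Stateful numpy implementation of the encoder-decoder.

    ``dtype`` defaults to float32 (the working precision for training);
    float64 instances are used where exact gradient checks matter.
    """

    def __init__(self, spec: NetworkSpec, input_shape: tuple[int, int],
                 dtype=np.float32):
        self.spec = spec
        self.dtype = np.dtype(dtype)
        self.input_shape = tuple(input_shape)
        S = len(spec.stages)
        div = 2 ** S
        if any(s % div for s in self.input_shape):
            valid = ", ".join(str(div * m) for m in range(max(1, self.input_shape[0] // div - 1),
                                                          self.input_shape[0] // div + 3))
            raise ValueError(
                f"input shape {self.input_shape} not divisible by 2^{S}={div}; "
                f"valid sides include {valid} (predict() pads automatically)")
        self.shortcuts = spec.resolved_shortcuts()
        k = spec.kernel_size

        # encoder: per stage, list of (conv, bn, relu); pool after each stage
        self.enc: list[list[tuple[Conv2d, BatchNorm2d, ReLU]]] = []
        self.pools: list[MaxPool2x2] = []
        in_ch = 1
        for (n_conv, f) in spec.stages:
            units = []
            for _ in range(n_conv):
                units.append((Conv2d(in_ch, f, k, dtype=self.dtype),
                              BatchNorm2d(f, dtype=self.dtype), ReLU()))
                in_ch = f
            self.enc.append(units)
            self.pools.append(MaxPool2x2())

        # decoder: per stage (deep→shallow): up, first unit (+shortcut), rest
        self.ups: list[BilinearUp2x] = []
        self.dec: list[list[tuple[Conv2d, BatchNorm2d, ReLU]]] = []
        in_ch = spec.stages[-1][1]
        for s in range(S - 1, -1, -1):
            n_conv, f = spec.stages[s]
            self.ups.append(BilinearUp2x())
            units = [(Conv2d(in_ch, f, k, dtype=self.dtype),
                      BatchNorm2d(f, dtype=self.dtype), ReLU())]
            for _ in range(n_conv - 1):
                units.append((Conv2d(f, f, k, dtype=self.dtype),
                              BatchNorm2d(f, dtype=self.dtype), ReLU()))
            self.dec.append(units)
            in_ch = f
        self.final_conv = Conv2d(spec.stages[0][1], 1, k, dtype=self.dtype)
        self._taps: dict[int, np.ndarray] | None = None

    # -- parameter plumbing -------------------------------------------------

    def _layers(self):
        for s, units in enumerate(self.enc):
            for u, (conv, bn, _) in enumerate(units):
                yield f"enc{s}_{u}_conv", conv
                yield f"enc{s}_{u}_bn", bn
        for d, units in enumerate(self.dec):
            for u, (conv, bn, _) in enumerate(units):
                yield f"dec{d}_{u}_conv", conv
                yield f"dec{d}_{u}_bn", bn
        yield "final_conv", self.final_conv

    def parameters(self):
        """Yields (name, param array, grad array) triples."""
        for lname, layer in self._layers():
            for pname in layer.params:
                yield f"{lname}.{pname}", layer.params[pname], layer.grads[pname]

    def set_param(self, name: str, value: np.ndarray) -> None:
        lname, pname = name.rsplit(".", 1)
        dict(self._layers())[lname].params[pname] = value

    def param_count(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    def zero_grad(self) -> None:
        for _, layer in self._layers():
            for g in layer.grads.values():
                g[...] = 0.0

    def initialize_weights(self, seed: int) -> "EncoderDecoder":
        """He-normal conv kernels (std √(2/fan_in)), zero biases,
        batch-norm scale 1 / shift 0; deterministic given the seed."""
        rng = rng_for(seed, "weight-init")
        for _, layer in self._layers():
            if isinstance(layer, Conv2d):
                layer.init_he(rng)
            elif isinstance(layer, BatchNorm2d):
                layer.params["gamma"] = np.ones(layer.n_ch, dtype=layer.dtype)
                layer.params["beta"] = np.zeros(layer.n_ch, dtype=layer.dtype)
                layer.running_mean = np.zeros(layer.n_ch, dtype=layer.dtype)
                layer.running_var = np.ones(layer.n_ch, dtype=layer.dtype)
        return self

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, 1, H, W) in the Softsign domain; returns (N, 1, H, W)."""
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != self.input_shape:
            raise ValueError(
                f"expected (N, 1, {self.input_shape[0]}, {self.input_shape[1]}), "
                f"got {x.shape}")
        taps: dict[int, np.ndarray] = {}
        x = np.ascontiguousarray(x, dtype=self.dtype)
        h = x
        for s, units in enumerate(self.enc):
            for conv, bn, relu in units:
                h = relu.forward(bn.forward(conv.forward(h, train), train), train)
            taps[s] = h
            h = self.pools[s].forward(h, train)
        S = len(self.enc)
        for d, units in enumerate(self.dec):
            s = S - 1 - d  # mirrored encoder stage
            h = self.ups[d].forward(h, train)
            conv, bn, relu = units[0]
            h = conv.forward(h, train)
            if s in self.shortcuts:
                h = h + taps[s]  # full pre-activation insertion
            h = relu.forward(bn.forward(h, train), train)
            for conv, bn, relu in units[1:]:
                h = relu.forward(bn.forward(conv.forward(h, train), train), train)
        y = self.final_conv.forward(h, train)
        if self.spec.input_output_shortcut:
            y = y + x
        if train:
            self._taps = taps
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Accumulates parameter gradients; returns gradient w.r.t. input."""
        dy = np.ascontiguousarray(dy, dtype=self.dtype)
        dx_direct = dy if self.spec.input_output_shortcut else 0.0
        g = self.final_conv.backward(dy)
        S = len(self.enc)
        tap_grads: dict[int, np.ndarray] = {}
        for d in range(len(self.dec) - 1, -1, -1):
            s = S - 1 - d
            units = self.dec[d]
            for conv, bn, relu in reversed(units[1:]):
                g = conv.backward(bn.backward(relu.backward(g)))
            conv, bn, relu = units[0]
            g = bn.backward(relu.backward(g))
            if s in self.shortcuts:
                tap_grads[s] = g  # additive branch: same gradient flows to the tap
            g = conv.backward(g)
            g = self.ups[d].backward(g)
        for s in range(S - 1, -1, -1):
            g = self.pools[s].backward(g)
            if s in tap_grads:
                g = g + tap_grads[s]
            for conv, bn, relu in reversed(self.enc[s]):
                g = conv.backward(bn.backward(relu.backward(g)))
        return g + dx_direct

    # -- inference ----------------------------------------------------------

    def predict(self, x: np.ndarray, pad_value: float = 0.0) -> np.ndarray:
        """Deterministic inference (running batch-norm statistics).

        Accepts a single 2D slice or an (N, H, W) stack of any size;
        sides not divisible by ``2^n_stages`` are padded with
        ``pad_value`` (the normalised-air constant) and the output is
        cropped back.
        """
        single = x.ndim == 2
        batch = x[None] if single else x
        n, h, w = batch.shape
        hp, wp = self.input_shape
        if h > hp or w > wp:
            raise ValueError(
                f"slice {h}x{w} exceeds the network input {hp}x{wp}")
        padded = np.full((n, 1, hp, wp), float(pad_value), dtype=self.dtype)
        padded[:, 0, :h, :w] = batch
        out = self.forward(padded, train=False)[:, 0, :h, :w]
        return out[0] if single else out


def build_network(spec: NetworkSpec, input_shape: tuple[int, int],
                  seed: int | None = None, dtype=np.float32) -> EncoderDecoder:
    """Construct the encoder-decoder; initialise weights when a seed is given.

    For the 200×180 interface matrix, build with ``input_shape=(224, 192)``
    (the next multiple of 2⁵); ``predict`` handles the padding.
    """
    net = EncoderDecoder(spec, input_shape, dtype=dtype)
    if seed is not None:
        net.initialize_weights(seed)
    return net


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(net: EncoderDecoder, path) -> None:
    """Single-file .npz checkpoint with the spec embedded (self-describing)."""
    arrays = {name.replace(".", "__"): p for name, p, _ in net.parameters()}
    for lname, layer in net._layers():
        if isinstance(layer, BatchNorm2d):
            arrays[f"{lname}__running_mean"] = layer.running_mean
            arrays[f"{lname}__running_var"] = layer.running_var
    meta = json.dumps({"spec": net.spec.to_dict(), "input_shape": list(net.input_shape)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> EncoderDecoder:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        dtype = data[[k for k in data.files if k != "__meta__"][0]].dtype
        net = EncoderDecoder(NetworkSpec.from_dict(meta["spec"]),
                             tuple(meta["input_shape"]), dtype=dtype)
        layers = dict(net._layers())
        for key in data.files:
            if key == "__meta__":
                continue
            if key.endswith("__running_mean"):
                layers[key[: -len("__running_mean")]].running_mean = data[key].copy()
            elif key.endswith("__running_var"):
                layers[key[: -len("__running_var")]].running_var = data[key].copy()
            else:
                lname, pname = key.rsplit("__", 1)
                layer = layers[lname]
                layer.params[pname] = data[key].copy()
                layer.grads[pname] = np.zeros_like(layer.params[pname])
    return net


def checkpoint_bytes(net: EncoderDecoder) -> bytes:
    """In-memory checkpoint (used for per-epoch snapshots during training)."""
    buf = _io.BytesIO()
    save_checkpoint(net, buf)
    return buf.getvalue()


def network_from_bytes(blob: bytes) -> EncoderDecoder:
    return load_checkpoint(_io.BytesIO(blob))
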