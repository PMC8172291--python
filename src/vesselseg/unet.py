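"""The encoder-decoder segmentation network and its parameter ledger.

The architecture is a U-Net with five encoder DoubleConv blocks (widths
64, 128, 256, 512, 512 at full size), 2×2 max pooling between them,
bilinear 2× upsampling in the decoder with skip concatenation, four
decoder DoubleConv blocks (256, 128, 64, 64), and a 1×1 output
convolution followed by a sigmoid so each pixel carries a vessel
probability.  Every convolution is 3×3 with padding 1, bias, batch
normalization and leaky ReLU, so spatial dimensions are preserved
end-to-end; any input side divisible by 16 is accepted.

A DoubleConv block C₁→C₂ therefore carries

    (9·C₁ + 1)·C₂ + 2·C₂ + (9·C₂ + 1)·C₂ + 2·C₂  =  9·(C₁ + C₂)·C₂ + 6·C₂

learnable terms (conv weights + biases, batch-norm scale + shift), and the
full-width network totals 13,394,177 (≈ 13.39 M).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._engine import BatchNorm2d, BilinearUp2d, Conv2d, LeakyReLU, MaxPool2d, Param, Sigmoid

__all__ = [
    "UNetSpec",
    "ParamLedger",
    "DoubleConv",
    "UNet",
    "build_unet",
    "count_parameters",
    "double_conv_param_count",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass(frozen=True)
class UNetSpec:
    """Channel widths and wiring of the network.

    ``base`` scales every width: base 64 is the full-size network; smaller
    bases keep the identical topology for fast experiments.
    """

    input_side: int = 576
    base: int = 64
    negative_slope: float = 0.01
    seed: int = 0

    @property
    def encoder_widths(self) -> tuple[int, ...]:
        b = self.base
        return (b, 2 * b, 4 * b, 8 * b, 8 * b)

    @property
    def decoder_widths(self) -> tuple[int, ...]:
        b = self.base
        return (4 * b, 2 * b, b, b)

    def __post_init__(self) -> None:
        if self.base < 1:
            raise ValueError("base width must be >= 1")
        if self.input_side % 16:
            raise ValueError("input side must be divisible by 16 (four pooling stages)")


@dataclasses.dataclass(frozen=True)
class ParamLedger:
    """Ordered (block name, learnable-term count) pairs with their total."""

    entries: tuple[tuple[str, int], ...]

    @property
    def total(self) -> int:
        return sum(n for _, n in self.entries)

    def as_dict(self) -> dict[str, int]:
        return dict(self.entries)

    def format_table(self) -> str:
        width = max(len(name) for name, _ in self.entries)
        lines = [f"{name:<{width}}  {count:>10,}" for name, count in self.entries]
        lines.append(f"{'Total':<{width}}  {self.total:>10,}")
        return "\n".join(lines)


def double_conv_param_count(c_in: int, c_out: int) -> int:
    """Closed-form learnable-term count of one DoubleConv block."""
    return 9 * (c_in + c_out) * c_out + 6 * c_out


class DoubleConv:
    """Conv(3×3) → BN → LeakyReLU, twice."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32, negative_slope: float = 0.01):
        self.layers = [
            Conv2d(c_in, c_out, 3, rng, dtype, negative_slope),
            BatchNorm2d(c_out, dtype),
            LeakyReLU(negative_slope),
            Conv2d(c_out, c_out, 3, rng, dtype, negative_slope),
            BatchNorm2d(c_out, dtype),
            LeakyReLU(negative_slope),
        ]

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class UNet:
    """Fully-convolutional encoder-decoder with skip concatenation."""

    def __init__(self, spec: UNetSpec, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(spec.seed)
        enc = spec.encoder_widths
        dec = spec.decoder_widths
        ns = spec.negative_slope

        self.encoders = []
        c_prev = 1
        for c in enc:
            self.encoders.append(DoubleConv(c_prev, c, rng, dtype, ns))
            c_prev = c
        self.pools = [MaxPool2d() for _ in range(4)]
        self.ups = [BilinearUp2d(dtype) for _ in range(4)]
        self.decoders = []
        skip_widths = enc[3::-1]  # enc4, enc3, enc2, enc1 feed the decoder
        c_prev = enc[-1]
        for c, skip in zip(dec, skip_widths):
            self.decoders.append(DoubleConv(c_prev + skip, c, rng, dtype, ns))
            c_prev = c
        self.out_conv = Conv2d(dec[-1], 1, 1, rng, dtype, ns)
        self.out_act = Sigmoid()

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        for block in self.encoders + self.decoders:
            out.extend(block.params())
        out.extend(self.out_conv.params())
        return out

    def block_names(self) -> list[str]:
        return [f"DoubleConv_{i}" for i in range(1, 10)] + ["Output"]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W) input, got {x.shape}")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("input dims must be divisible by 16")
        skips = []
        for i, block in enumerate(self.encoders):
            x = block.forward(x, train)
            if i < 4:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        self._skip_widths = [s.shape[1] for s in skips]
        for i, block in enumerate(self.decoders):
            x = self.ups[i].forward(x, train)
            x = np.concatenate([skips[3 - i], x], axis=1)
            x = block.forward(x, train)
        x = self.out_conv.forward(x, train)
        return self.out_act.forward(x, train)

    def backward(self, grad: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/d(output probability)."""
        grad = np.asarray(grad, dtype=self.dtype)
        grad = self.out_act.backward(grad)
        grad = self.out_conv.backward(grad)
        skip_grads: list[np.ndarray | None] = [None] * 4
        for i in reversed(range(4)):
            grad = self.decoders[i].backward(grad)
            w = self._skip_widths[3 - i]
            skip_grads[3 - i], grad = grad[:, :w], grad[:, w:]
            grad = self.ups[i].backward(grad)
        for i in reversed(range(5)):
            if i < 4:
                grad = self.pools[i].backward(grad)
                grad = grad + skip_grads[i]
            grad = self.encoders[i].backward(grad)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass (running batch-norm statistics)."""
        return self.forward(x, train=False)

    # -- (de)serialization --------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.params()]
        for block in self.encoders + self.decoders:
            for layer in block.layers:
                if isinstance(layer, BatchNorm2d):
                    arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("checkpoint does not match this architecture")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src


def build_unet(spec: UNetSpec, dtype=np.float32) -> UNet:
    return UNet(spec, dtype)


def count_parameters(model: UNet) -> ParamLedger:
    """Per-block learnable-term counts from the model's actual arrays."""
    entries = []
    for name, block in zip(model.block_names(), model.encoders + model.decoders):
        entries.append((name, sum(p.size for p in block.params())))
    entries.append(("Output", sum(p.size for p in model.out_conv.params())))
    return ParamLedger(tuple(entries))


def save_checkpoint(path: str | Path, model: UNet) -> None:
    path = Path(path)
    spec_json = json.dumps(dataclasses.asdict(model.spec), sort_keys=True)
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez_compressed(path, spec=np.frombuffer(spec_json.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path, dtype=np.float32) -> UNet:
    with np.load(Path(path)) as data:
        spec = UNetSpec(**json.loads(bytes(data["spec"]).decode()))
        model = UNet(spec, dtype)
        arrays = [data[f"arr_{i}"] for i in range(len(model.state_arrays()))]
    model.load_state_arrays(arrays)
    return model
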