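"""Adaptive-threshold binarization, OR fusion, and small-component pruning.

The per-channel probability maps are scaled to 0–255 and binarized
against a local-mean threshold ``T = −b + mean(window)``; a pixel is
vessel iff its value exceeds T.  The three channel masks are fused with a
pixelwise OR — so any vessel found by any channel survives — and
8-connected components smaller than 25 pixels are then removed as noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from .enhancement import ChannelSpec, enhance_channel
from .imaging_io import from_network_frame, to_network_frame
from .preprocess import PreprocessConfig, preprocess_pipeline
from .training import predict_channel
from .unet import UNet

__all__ = [
    "ThresholdConfig",
    "adaptive_threshold",
    "fuse_or",
    "remove_small_components",
    "segment",
]

MIN_COMPONENT = 25


@dataclasses.dataclass(frozen=True)
class ThresholdConfig:
    """Local threshold ``T = −b + window mean`` over a (2w_m+1)×(2w_n+1) window.

    A negative ``b`` demands the pixel exceed its local mean by |b| gray
    levels — the appropriate direction for bright foreground on a smooth
    dark background, and the default here (b = −15, 31×31 window) for the
    network's probability maps.
    """

    b: float = -15.0
    w_m: int = 15
    w_n: int = 15

    def __post_init__(self) -> None:
        if self.w_m < 1 or self.w_n < 1:
            raise ValueError("window half-sizes must be >= 1 (window >= 3x3)")


def adaptive_threshold(g: np.ndarray, cfg: ThresholdConfig = ThresholdConfig()) -> np.ndarray:
    """Binarize against the local-mean threshold (reflect borders)."""
    g = np.asarray(g, dtype=np.float64)
    wh, ww = 2 * cfg.w_m + 1, 2 * cfg.w_n + 1
    if wh > g.shape[0] or ww > g.shape[1]:
        raise ValueError(f"window {wh}x{ww} larger than image {g.shape}")
    local_mean = ndi.uniform_filter(g, size=(wh, ww), mode="reflect")
    return g > (local_mean - cfg.b)


def fuse_or(*masks: np.ndarray) -> np.ndarray:
    """Pixelwise logical OR of any number of same-shaped masks."""
    if not masks:
        raise ValueError("need at least one mask")
    out = np.asarray(masks[0], dtype=bool)
    for m in masks[1:]:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ValueError(f"mask dim mismatch: {m.shape} vs {out.shape}")
        out = out | m
    return out


def remove_small_components(mask: np.ndarray, min_size: int = MIN_COMPONENT,
                            connectivity: int = 8) -> np.ndarray:
    """Drop connected components with fewer than ``min_size`` pixels.

    "Fewer than" is strict: a component of exactly ``min_size`` survives.
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = ndi.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndi.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def segment(
    image: np.ndarray,
    models: dict[int, UNet],
    *,
    channel_specs: dict[int, ChannelSpec] | None = None,
    pre_cfg: PreprocessConfig = PreprocessConfig(),
    thr_cfg: ThresholdConfig = ThresholdConfig(),
    fov: np.ndarray | None = None,
    network_side: int | None = None,
    min_component: int = MIN_COMPONENT,
    return_intermediates: bool = False,
):
    """Full pipeline on one fundus image with three trained channel models.

    preprocess → per-channel enhancement → network probability map →
    adaptive threshold → OR fusion → FOV masking → restore native dims →
    prune sub-25-pixel components.  Component pruning runs at native
    resolution so the 25-pixel rule applies on the original pixel grid.
    """
    from .enhancement import CHANNEL2_DEFAULTS, CHANNEL3_DEFAULTS

    if channel_specs is None:
        channel_specs = {1: ChannelSpec(channel=1), 2: CHANNEL2_DEFAULTS, 3: CHANNEL3_DEFAULTS}
    missing = set(models) ^ set(channel_specs)
    if missing:
        raise ValueError(f"models/channel specs mismatch on channels {sorted(missing)}")

    side = network_side or next(iter(models.values())).spec.input_side
    native_shape = image.shape[:2]
    g_pre = preprocess_pipeline(image, pre_cfg)

    channel_masks = {}
    for ch, model in sorted(models.items()):
        enhanced = enhance_channel(g_pre, channel_specs[ch])
        framed = to_network_frame(enhanced, side)
        prob = predict_channel(model, framed)
        channel_masks[ch] = adaptive_threshold(prob * 255.0, thr_cfg)

    fused = fuse_or(*channel_masks.values())
    if fov is not None:
        fused_frame_fov = to_network_frame(np.asarray(fov, dtype=np.float64), side) > 0.5
        fused &= fused_frame_fov
    native = from_network_frame(fused, native_shape, binary=True)
    if fov is not None:
        native &= np.asarray(fov, dtype=bool)
    final = remove_small_components(native, min_component)
    if return_intermediates:
        return final, {"channel_masks": channel_masks, "fused_frame": fused}
    return final
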