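"""The three channel-specific vessel-enhancement pipelines.

Channel 1 removes the slowly-varying background (optic disc, illumination
artifacts) with a morphological closing and an intensity remap.  Channels 2
and 3 run a rotated Gaussian matched-filter bank — a large scale tuned to
thick vessels and a small scale tuned to capillaries — and then a modified
black-hat transform ("black hat2") that subtracts the residual background
and doubles the dark-structure term.

A matched-filter template models the vessel cross-section as an inverted
Gaussian: intensity dips at the centerline and recovers at the edges.  Each
template is mean-subtracted so it gives zero response on flat background,
and the bank covers ``n_dirs`` orientations uniformly spaced on [0, π);
the per-pixel response is the maximum over orientations.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

logger = logging.getLogger(__name__)

__all__ = [
    "KernelBank",
    "BlackHatConfig",
    "ChannelSpec",
    "CHANNEL2_DEFAULTS",
    "CHANNEL3_DEFAULTS",
    "build_kernel_bank",
    "remove_background_close",
    "matched_filter_response",
    "matched_filter_argmax",
    "black_hat2",
    "enhance_channel",
    "rescale_to_255",
]


@dataclasses.dataclass(frozen=True)
class KernelBank:
    """Rotated, mean-subtracted matched-filter templates at one scale.

    ``s`` is the Gaussian cross-section width (pixels), ``l`` the template
    length along the vessel, and ``angles[i]`` the orientation of kernel
    ``i``.  Every kernel sums to zero by construction.
    """

    s: float
    l: float
    n_dirs: int
    angles: tuple[float, ...]
    kernels: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.kernels) != self.n_dirs:
            raise ValueError("kernel count must equal n_dirs")


@dataclasses.dataclass(frozen=True)
class BlackHatConfig:
    radius: int = 11

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("structuring-element radius must be >= 1")


@dataclasses.dataclass(frozen=True)
class ChannelSpec:
    """Parameters of one enhancement channel.

    Channel 1: closing-based background removal (``closing_radius``).
    Channels 2/3: matched-filter bank ``(l, s, n_dirs)`` + black hat2.
    """

    channel: int
    l: float = 0.0
    s: float = 0.0
    n_dirs: int = 0
    closing_radius: int = 11
    blackhat_radius: int = 11

    def __post_init__(self) -> None:
        if self.channel not in (1, 2, 3):
            raise ValueError(f"unknown channel id {self.channel}")
        if self.channel in (2, 3) and (self.l <= 0 or self.s <= 0 or self.n_dirs < 1):
            raise ValueError("channels 2/3 need positive l, s and n_dirs >= 1")


#: Large-scale bank for thick vessels.
CHANNEL2_DEFAULTS = ChannelSpec(channel=2, l=10.8, s=1.9, n_dirs=8)
#: Small-scale bank for capillaries.
CHANNEL3_DEFAULTS = ChannelSpec(channel=3, l=5.0, s=0.1, n_dirs=18)


def rescale_to_255(g: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 255]; a constant image maps to all zeros."""
    g = np.asarray(g, dtype=np.float64)
    lo, hi = g.min(), g.max()
    if hi <= lo:
        logger.warning("degenerate (constant) image in min-max rescale; returning zeros")
        return np.zeros_like(g)
    return 255.0 * (g - lo) / (hi - lo)


def _disk(radius: int) -> np.ndarray:
    return morphology.disk(radius)


def _closing(g: np.ndarray, radius: int) -> np.ndarray:
    # grey closing with reflect borders: dilation (max) then erosion (min)
    footprint = _disk(radius)
    dil = ndi.grey_dilation(g, footprint=footprint, mode="reflect")
    return ndi.grey_erosion(dil, footprint=footprint, mode="reflect")


def remove_background_close(g: np.ndarray, disc_radius: int = 11) -> np.ndarray:
    """Channel-1 enhancement: closing-based background estimate and remap.

    The closing fills dark structures (vessels) so its output estimates the
    background; ``closing − image`` isolates the vessels, and the remap
    ``255 − (closing − image) + mean(closing)`` followed by a min-max
    rescale yields a 0–255 image with dark vessels and flattened
    illumination.
    """
    g = np.asarray(g, dtype=np.float64)
    closed = _closing(g, disc_radius)
    raw = 255.0 - (closed - g) + closed.mean()
    return rescale_to_255(raw)


def build_kernel_bank(l: float, s: float, n_dirs: int) -> KernelBank:
    """Construct the rotated matched-filter bank for one scale.

    The canonical template is a discrete point set: integer lattice points
    (u, v) with |u| ≤ max(3s, 1) across the vessel and |v| ≤ l/2 along it,
    each carrying weight −exp(−u²/2s²); the mean over the set is
    subtracted so the template has exactly zero total weight.  A rotated
    kernel forward-rotates every point and deposits its weight onto the
    four surrounding pixels with bilinear splatting, which preserves the
    total (zero) mass and the sub-pixel geometry of the centerline ridge —
    at very narrow scales (3s < 1, where the one-pixel half-width floor
    activates) a continuous resampling of the Gaussian would lose the
    ridge entirely at oblique angles.  Each rotated kernel is finally
    scaled back to the canonical template's L2 energy so the orientations
    compete on equal footing in the per-pixel maximum.
    """
    if n_dirs < 1:
        raise ValueError("n_dirs must be >= 1")
    if not (math.isfinite(l) and math.isfinite(s)) or l <= 0 or s <= 0:
        raise ValueError("l and s must be positive and finite")
    u_half = max(3.0 * s, 1.0)
    if 3.0 * s < 1.0:
        logger.info("kernel half-width floor active for s=%g (3s=%g < 1 px)", s, 3 * s)
    v_half = l / 2.0
    uu = np.arange(-int(u_half), int(u_half) + 1)
    vv = np.arange(-int(math.floor(v_half)), int(math.floor(v_half)) + 1)
    grid_u, grid_v = np.meshgrid(uu, vv, indexing="xy")
    weights = -np.exp(-(grid_u.astype(np.float64) ** 2) / (2.0 * s * s))
    weights = weights - weights.mean()
    ref_energy = float(np.linalg.norm(weights))
    if ref_energy == 0.0:
        raise ValueError(f"degenerate template for l={l}, s={s}")

    half = int(math.ceil(math.hypot(u_half, v_half))) + 2
    size = 2 * half + 1
    angles = tuple((i * math.pi / n_dirs) for i in range(n_dirs))
    kernels = []
    for theta in angles:
        c, si = math.cos(theta), math.sin(theta)
        # forward-rotate (u, v) -> (x, y) = (col, row) and splat bilinearly
        x = c * grid_u - si * grid_v + half
        y = si * grid_u + c * grid_v + half
        x0 = np.floor(x).astype(int)
        y0 = np.floor(y).astype(int)
        fx, fy = x - x0, y - y0
        k = np.zeros((size, size))
        np.add.at(k, (y0, x0), weights * (1 - fx) * (1 - fy))
        np.add.at(k, (y0, x0 + 1), weights * fx * (1 - fy))
        np.add.at(k, (y0 + 1, x0), weights * (1 - fx) * fy)
        np.add.at(k, (y0 + 1, x0 + 1), weights * fx * fy)
        k *= ref_energy / np.linalg.norm(k)
        kernels.append(k)
    return KernelBank(s=s, l=l, n_dirs=n_dirs, angles=angles, kernels=tuple(kernels))


def _responses(g: np.ndarray, bank: KernelBank) -> np.ndarray:
    g = np.asarray(g, dtype=np.float64)
    k0 = bank.kernels[0]
    if g.shape[0] < k0.shape[0] or g.shape[1] < k0.shape[1]:
        raise ValueError(f"image {g.shape} smaller than kernel support {k0.shape}")
    return np.stack([ndi.correlate(g, k, mode="reflect") for k in bank.kernels])


def matched_filter_response(g: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Per-pixel maximum correlation over the bank, min-max rescaled to [0, 255].

    Vessels (dark lines at some orientation) give high response; flat
    background gives zero response before rescaling.
    """
    return rescale_to_255(_responses(g, bank).max(axis=0))


def matched_filter_argmax(g: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Index of the winning orientation at each pixel (for diagnostics/tests)."""
    return _responses(g, bank).argmax(axis=0)


def black_hat2(f: np.ndarray, cfg: BlackHatConfig = BlackHatConfig()) -> np.ndarray:
    """Modified black-hat background removal.

    ``B = closing(f) − f`` highlights dark structures; the output
    ``255 − (f − 2B)`` inverts the image while counting the dark-structure
    term twice, which suppresses background and deepens vessel contrast.
    Clipped to [0, 255].
    """
    f = np.asarray(f, dtype=np.float64)
    bhat = _closing(f, cfg.radius) - f
    out = 255.0 - (f - 2.0 * bhat)
    return np.clip(out, 0.0, 255.0)


def enhance_channel(g_pre: np.ndarray, spec: ChannelSpec) -> np.ndarray:
    """Run one channel's enhancement on a preprocessed gray image."""
    if spec.channel == 1:
        return remove_background_close(g_pre, spec.closing_radius)
    bank = build_kernel_bank(spec.l, spec.s, spec.n_dirs)
    resp = matched_filter_response(g_pre, bank)
    return black_hat2(resp, BlackHatConfig(radius=spec.blackhat_radius))
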