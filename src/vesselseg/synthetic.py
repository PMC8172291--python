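"""Seed-reproducible fundus phantoms with exact vessel ground truth.

A phantom emulates the features of a fundus photograph that the pipeline
depends on: a bright background (green-plane base ≈ 200) with a smooth
low-frequency illumination field, dark curvilinear vessels whose
cross-section is an inverted Gaussian (deepest at the centerline), an
optional bright optic-disc blob, additive Gaussian noise, and a circular
field of view outside which the frame is dark.  The green plane carries
the strongest vessel contrast, as in real fundus photographs.

Ground truth comes from the analytic distance to each vessel centerline
(a pixel is vessel iff it lies within width/2), not from re-thresholding
the rendered image, so labels are exact.  It does not attempt
photorealism: no lesions, no central light reflex, no branching trees —
just enough structure to exercise enhancement, training, fusion and the
connectivity metrics.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .imaging_io import DatasetSplit, save_manifest, write_image, write_mask

__all__ = ["PhantomConfig", "generate_phantom", "generate_suite"]


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; every default is chosen to mimic fundus statistics.

    ``depth_range`` is the centerline intensity dip on the 0–255 green
    scale; ``width_range`` the vessel diameter in pixels (real vasculature
    spans capillaries of ~1 px to trunks of ~6 px at DRIVE resolution).
    """

    side: int = 256
    n_vessels: int = 6
    width_range: tuple[float, float] = (1.0, 6.0)
    depth_range: tuple[float, float] = (40.0, 80.0)
    background: float = 200.0
    illumination_amplitude: float = 12.0
    noise_sigma: float = 5.0
    fov_radius_fraction: float = 0.48
    optic_disc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_range[0] < 1:
            raise ValueError("vessel widths must be >= 1 px")
        if self.depth_range[1] >= self.background:
            raise ValueError("vessel dip depth must stay below the background base")
        if self.side < 8 * self.width_range[1]:
            raise ValueError(f"frame side {self.side} too small for widths {self.width_range}")


def _smooth_field(rng: np.random.Generator, side: int, amplitude: float) -> np.ndarray:
    """Low-frequency illumination field with zero mean and given amplitude."""
    coarse = rng.standard_normal((4, 4))
    field = ndi.zoom(coarse, side / 4.0, order=3, mode="nearest")[:side, :side]
    span = np.abs(field).max()
    return amplitude * field / span if span > 0 else np.zeros((side, side))


def _vessel_centerline(rng: np.random.Generator, side: int, radius: float,
                       center: tuple[float, float]) -> np.ndarray:
    """Quadratic Bézier from near the disc center to near the FOV rim."""
    cy, cx = center
    a0 = rng.uniform(0, 2 * np.pi)
    r0 = rng.uniform(0.05, 0.25) * radius
    p0 = np.array([cy + r0 * np.sin(a0), cx + r0 * np.cos(a0)])
    a2 = a0 + rng.uniform(-0.9, 0.9)
    r2 = rng.uniform(0.85, 0.98) * radius
    p2 = np.array([cy + r2 * np.sin(a2), cx + r2 * np.cos(a2)])
    mid = 0.5 * (p0 + p2)
    perp = np.array([-(p2 - p0)[1], (p2 - p0)[0]])
    norm = np.linalg.norm(perp)
    perp = perp / norm if norm > 0 else perp
    p1 = mid + perp * rng.uniform(-0.25, 0.25) * np.linalg.norm(p2 - p0)
    t = np.linspace(0.0, 1.0, 6 * side)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
    return pts


def generate_phantom(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one phantom: (RGB uint8 image, vessel ground truth, FOV mask)."""
    rng = np.random.default_rng(cfg.seed)
    side = cfg.side
    yy, xx = np.mgrid[0:side, 0:side]
    center = ((side - 1) / 2.0, (side - 1) / 2.0)
    radius = cfg.fov_radius_fraction * side
    fov = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2

    dip = np.zeros((side, side))
    gt = np.zeros((side, side), dtype=bool)
    for _ in range(cfg.n_vessels):
        width = rng.uniform(*cfg.width_range)
        depth = rng.uniform(*cfg.depth_range)
        pts = _vessel_centerline(rng, side, radius, center)
        line = np.zeros((side, side), dtype=bool)
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, side - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, side - 1)
        line[rr, cc] = True
        d = ndi.distance_transform_edt(~line)
        sigma_w = max(width / 2.0, 0.5)
        dip = np.maximum(dip, depth * np.exp(-(d**2) / (2.0 * sigma_w**2)))
        gt |= d <= width / 2.0

    gt &= fov
    illum = _smooth_field(rng, side, cfg.illumination_amplitude)
    green = cfg.background + illum - dip
    if cfg.optic_disc:
        a = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(0.4, 0.7) * radius
        dy, dx = center[0] + r * np.sin(a), center[1] + r * np.cos(a)
        disc = 35.0 * np.exp(-(((yy - dy) ** 2 + (xx - dx) ** 2) / (2.0 * (0.08 * side) ** 2)))
        green = green + disc

    red = 0.85 * cfg.background + illum - 0.5 * dip + 15.0
    blue = 0.45 * cfg.background + illum - 0.25 * dip
    planes = []
    for plane in (red, green, blue):
        plane = np.where(fov, plane, 4.0)
        plane = plane + rng.normal(0.0, cfg.noise_sigma, size=plane.shape)
        planes.append(np.clip(plane, 0, 255))
    img = np.stack(planes, axis=-1).round().astype(np.uint8)
    return img, gt, fov


def _item_seed(seed: int, index: int) -> int:
    return zlib.crc32(f"phantom:{seed}:{index}".encode()) & 0x7FFFFFFF


def generate_suite(
    n: int,
    cfg: PhantomConfig = PhantomConfig(),
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_test: int = 0,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Generate ``n`` phantoms with disjoint derived seeds.

    With ``out_dir`` set, images/labels/FOVs are written as PNG and a YAML
    manifest (last ``n_test`` items as the test split) is placed alongside,
    in the layout the dataset reader and the training CLI consume.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    phantoms = [
        generate_phantom(dataclasses.replace(cfg, seed=_item_seed(seed, i)))
        for i in range(n)
    ]
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "labels").mkdir(exist_ok=True)
        (out / "fov").mkdir(exist_ok=True)
        items = {}
        ids = [f"phantom_{i:03d}" for i in range(n)]
        for pid, (img, gt, fov) in zip(ids, phantoms):
            write_image(out / "images" / f"{pid}.png", img)
            write_mask(out / "labels" / f"{pid}.png", gt)
            write_mask(out / "fov" / f"{pid}.png", fov)
            items[pid] = {
                "image": str(out / "images" / f"{pid}.png"),
                "label": str(out / "labels" / f"{pid}.png"),
                "fov": str(out / "fov" / f"{pid}.png"),
            }
        split = DatasetSplit(
            "synthetic",
            tuple(ids[: n - n_test]) if n_test else tuple(ids),
            tuple(ids[n - n_test:]) if n_test else (),
        )
        save_manifest(out / "manifest.yaml", split, items)
    return phantoms
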