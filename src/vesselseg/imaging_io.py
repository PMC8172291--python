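"""Image and mask I/O, FOV-mask construction, dataset splits, network-frame mapping.

Conventions used throughout the package:

* a *fundus image* is an ``(H, W, 3)`` uint8 array (RGB, values 0–255);
* a *gray image* is an ``(H, W)`` float64 array on the 0–255 scale;
* a *binary mask* is an ``(H, W)`` bool array, written to disk as a
  single-channel PNG with 0 = background and 255 = foreground;
* coordinates are row-major, 0-based ``(row, col)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage import filters, morphology, transform

NETWORK_SIDE = 576

__all__ = [
    "NETWORK_SIDE",
    "DatasetSplit",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "extract_green",
    "make_fov_mask",
    "to_network_frame",
    "from_network_frame",
    "drive_split",
    "stare_split",
    "chase_split",
    "load_manifest",
    "save_manifest",
]


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    """Ordered train/test identifiers for one dataset."""

    name: str
    train: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.train) & set(self.test)
        if overlap:
            raise ValueError(f"train/test overlap in split {self.name!r}: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# reading / writing


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit image as an (H, W, 3) uint8 RGB array.

    Grayscale sources are replicated onto three planes; an alpha plane, if
    present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise OSError(f"could not decode image file {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise ValueError(f"unsupported bit depth {arr.dtype} in {path}; only 8-bit images are supported")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")
    return arr


def write_image(path: str | Path, img: np.ndarray) -> None:
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError("write_image expects a uint8 array")
    iio.imwrite(Path(path), img)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG/GIF as a bool array (any nonzero pixel is foreground)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    return np.asarray(arr) > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError("write_mask expects a bool array")
    iio.imwrite(Path(path), (mask.astype(np.uint8)) * 255)


# ---------------------------------------------------------------------------
# channels and FOV


def extract_green(img: np.ndarray) -> np.ndarray:
    """Return the green plane as a float gray image on the 0–255 scale.

    The green channel carries the strongest vessel/background contrast in
    fundus photographs, so the whole pipeline works from it.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got {img.shape}")
    return img[:, :, 1].astype(np.float64)


def make_fov_mask(
    img: np.ndarray,
    *,
    blur_sigma: float = 3.0,
    erosion_radius: int = 3,
) -> np.ndarray:
    """Estimate the circular field-of-view aperture of a fundus photograph.

    Recipe: green plane → Gaussian blur → Otsu threshold → fill holes →
    keep the largest 8-connected component → erode by a disc so the mask
    sits strictly inside the aperture rim.
    """
    g = extract_green(img)
    blurred = ndi.gaussian_filter(g, sigma=blur_sigma)
    if blurred.max() <= blurred.min():
        raise ValueError("cannot build a FOV mask: the image has no intensity variation")
    thr = filters.threshold_otsu(blurred)
    fg = blurred > thr
    if not fg.any():
        raise ValueError("cannot build a FOV mask: no pixel exceeds the threshold")
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndi.sum(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    if erosion_radius > 0:
        # border_value=0 so the margin is eroded at the frame edge too
        fg = ndi.binary_erosion(fg, structure=morphology.disk(erosion_radius),
                                border_value=0)
    if not fg.any():
        raise ValueError("FOV mask empty after erosion")
    return fg


# ---------------------------------------------------------------------------
# network frame


def to_network_frame(g: np.ndarray, side: int = NETWORK_SIDE) -> np.ndarray:
    """Bilinearly resize a gray image to the square frame the network consumes."""
    g = np.asarray(g, dtype=np.float64)
    if g.ndim != 2 or min(g.shape) < 1:
        raise ValueError(f"expected a non-empty 2-D image, got shape {g.shape}")
    if g.shape == (side, side):
        return g.copy()
    return transform.resize(g, (side, side), order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True)


def from_network_frame(g: np.ndarray, shape: tuple[int, int], *, binary: bool = False) -> np.ndarray:
    """Map a network-frame image back to native dimensions.

    Binary predictions are resized nearest-neighbour so they stay two-valued.
    """
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError(f"non-positive target dims {shape}")
    arr = np.asarray(g)
    if arr.shape == (h, w):
        return arr.astype(bool) if binary else arr.astype(np.float64)
    if binary:
        out = transform.resize(arr.astype(np.float64), (h, w), order=0,
                               mode="edge", anti_aliasing=False, preserve_range=True)
        return out > 0.5
    return transform.resize(arr.astype(np.float64), (h, w), order=1,
                            mode="edge", anti_aliasing=False, preserve_range=True)


# ---------------------------------------------------------------------------
# published dataset splits

STARE_TEST_IDS = ("im0002", "im0077", "im0163", "im0255", "im0291")


def drive_split(train_ids: list[str], test_ids: list[str]) -> DatasetSplit:
    """DRIVE ships pre-divided 20 training / 20 test images."""
    if len(train_ids) != 20 or len(test_ids) != 20:
        raise ValueError("DRIVE uses its published 20/20 split")
    return DatasetSplit("DRIVE", tuple(train_ids), tuple(test_ids))


def stare_split(all_ids: list[str]) -> DatasetSplit:
    """STARE: the five published held-out images test, the rest train."""
    test = tuple(i for i in all_ids if i in STARE_TEST_IDS)
    train = tuple(i for i in all_ids if i not in STARE_TEST_IDS)
    return DatasetSplit("STARE", train, test)


def chase_split(all_ids: list[str]) -> DatasetSplit:
    """CHASE_DB1: last 8 images test, first 20 train (by sorted id order)."""
    ids = sorted(all_ids)
    return DatasetSplit("CHASE_DB1", tuple(ids[:-8]), tuple(ids[-8:]))


# ---------------------------------------------------------------------------
# manifests


def save_manifest(path: str | Path, split: DatasetSplit, items: dict[str, dict[str, str]]) -> None:
    """Write a YAML manifest mapping ids to image/label/fov paths plus the split."""
    doc = {
        "dataset": split.name,
        "train": list(split.train),
        "test": list(split.test),
        "items": {k: dict(v) for k, v in items.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_manifest(path: str | Path) -> tuple[DatasetSplit, dict[str, dict[str, str]]]:
    doc = yaml.safe_load(Path(path).read_text())
    for key in ("dataset", "train", "test", "items"):
        if key not in doc:
            raise KeyError(f"manifest {path} is missing key {key!r}")
    split = DatasetSplit(doc["dataset"], tuple(doc["train"]), tuple(doc["test"]))
    return split, doc["items"]
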