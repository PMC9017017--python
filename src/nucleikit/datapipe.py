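"""Dataset mechanics: patches, grayscale conversion, point ground truth.

Conventions: pixel coordinates are 0-based ``(row, col)`` and windows are
half-open.  Nucleus annotations are center points, optionally labelled with
one of the four phenotype classes; detection ground truth is derived from
them either as a dilated binary mask or as a Gaussian density surface.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

CLASS_NAMES = ("epithelial", "fibroblast", "inflammatory", "miscellaneous")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PointSet:
    """Nucleus center annotations: integer (row, col) pairs, optional labels."""

    coords: np.ndarray                    # (n, 2) int
    labels: list | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)
        if self.labels is not None and len(self.labels) != len(self.coords):
            raise ValueError("labels and coords must have equal length")
        if len(self.coords) and len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("duplicate (row, col) annotations")

    def __len__(self):
        return len(self.coords)

    def __iter__(self):
        labels = self.labels or [None] * len(self)
        yield from zip(self.coords[:, 0], self.coords[:, 1], labels)

    def check_bounds(self, shape) -> "PointSet":
        h, w = shape[:2]
        if len(self) and (self.coords.min() < 0 or self.coords[:, 0].max() >= h
                          or self.coords[:, 1].max() >= w):
            raise ValueError("points outside image bounds")
        return self

    @classmethod
    def empty(cls) -> "PointSet":
        return cls(np.empty((0, 2), dtype=int), [])

    @classmethod
    def from_csv(cls, path) -> "PointSet":
        df = pd.read_csv(path)
        labels = df["label"].tolist() if "label" in df else None
        return cls(df[["row", "col"]].to_numpy(), labels)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"row": self.coords[:, 0], "col": self.coords[:, 1]})
        if self.labels is not None:
            df["label"] = self.labels
        df.to_csv(path, index=False)


@dataclass
class AnnotatedImage:
    pixels: np.ndarray                    # (h, w) or (h, w, 3), 0..255
    points: PointSet = field(default_factory=PointSet.empty)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.points.check_bounds(self.pixels.shape)
        if self.mask is not None and self.mask.shape[:2] != self.pixels.shape[:2]:
            raise ValueError("mask shape does not match image")


@dataclass
class DensityTarget:
    """Non-negative detection surface; in ``max`` mode values lie in [0, 1]."""

    surface: np.ndarray
    sigma: float
    combine_mode: str = "max"

    def __post_init__(self):
        self.surface = np.asarray(self.surface, dtype=np.float32)
        if (self.surface < 0).any():
            raise ValueError("density surface must be non-negative")


@dataclass
class PatchGrid:
    patches: list
    origins: list                         # (row, col) top-left anchors
    patch_size: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_class_patches(img: AnnotatedImage, size: int = 32):
    """One ``size``-square patch per annotated point, reflect-padded at borders.

    The window for a point ``(r, c)`` is rows ``[r - size//2, r + size//2)``
    and likewise for columns.  Returns ``[(patch, label), ...]``.
    """
    if size % 2:
        raise ValueError("patch size must be even")
    half = size // 2
    pixels = img.pixels
    pad = ((size, size), (size, size)) + ((0, 0),) * (pixels.ndim - 2)
    padded = np.pad(pixels, pad, mode="reflect")
    out = []
    labels = img.points.labels or [None] * len(img.points)
    for (r, c), label in zip(img.points.coords, labels):
        rr, cc = r + size, c + size  # offset into the padded frame
        out.append((padded[rr - half:rr + half, cc - half:cc + half].copy(), label))
    return out


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luminosity grayscale (0.299 R + 0.587 G + 0.114 B), range preserved."""
    img = np.asarray(img)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[-1] == 1:
        return img[..., 0]
    if img.ndim == 3 and img.shape[-1] == 3:
        return img.astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"expected 1 or 3 channels, got shape {img.shape}")


def tile_patches(img: np.ndarray, patch_size: int = 96) -> PatchGrid:
    """Non-overlapping tiling of the largest top-left multiple-of-size region.

    A 500x500 image with 96-pixel patches is cropped to 480x480 and the
    remaining border is discarded.
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError("image smaller than one patch")
    nh, nw = h // patch_size, w // patch_size
    patches, origins = [], []
    for i in range(nh):
        for j in range(nw):
            r, c = i * patch_size, j * patch_size
            patches.append(img[r:r + patch_size, c:c + patch_size].copy())
            origins.append((r, c))
    return PatchGrid(patches, origins, patch_size)


def merge_patches(grid: PatchGrid) -> np.ndarray:
    """Inverse of :func:`tile_patches`; rejects incomplete grids."""
    if not grid.patches:
        raise ValueError("empty patch grid")
    s = grid.patch_size
    rows = max(r for r, _ in grid.origins) + s
    cols = max(c for _, c in grid.origins) + s
    if len(grid.origins) != (rows // s) * (cols // s) or \
            len(set(grid.origins)) != len(grid.origins):
        raise ValueError("patch grid does not tile a full rectangle")
    first = np.asarray(grid.patches[0])
    out = np.zeros((rows, cols) + first.shape[2:], dtype=first.dtype)
    for patch, (r, c) in zip(grid.patches, grid.origins):
        out[r:r + s, c:c + s] = patch
    return out


def dilate_points(points: PointSet, shape, kernel_size: int = 5) -> np.ndarray:
    """Binary mask with a square ``kernel_size`` neighborhood set per point."""
    if kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd")
    points.check_bounds(shape)
    h, w = shape[:2]
    half = kernel_size // 2
    mask = np.zeros((h, w), dtype=np.uint8)
    for r, c in points.coords:
        mask[max(0, r - half):r + half + 1, max(0, c - half):c + half + 1] = 1
    return mask


def make_density_target(points: PointSet, shape, sigma: float = 2.0,
                        combine_mode: str = "max") -> DensityTarget:
    """Superpose an isotropic Gaussian bump (peak 1, truncated at 3 sigma)
    at every annotated center; bumps combine by pixelwise max or by sum."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if combine_mode not in ("max", "sum"):
        raise ValueError("combine_mode must be 'max' or 'sum'")
    points.check_bounds(shape)
    h, w = shape[:2]
    surface = np.zeros((h, w), dtype=np.float32)
    radius = int(np.ceil(3 * sigma))
    ax = np.arange(-radius, radius + 1)
    bump = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma ** 2))
    bump = bump.astype(np.float32)
    for r, c in points.coords:
        r0, r1 = max(0, r - radius), min(h, r + radius + 1)
        c0, c1 = max(0, c - radius), min(w, c + radius + 1)
        piece = bump[r0 - r + radius:r1 - r + radius, c0 - c + radius:c1 - c + radius]
        if combine_mode == "max":
            np.maximum(surface[r0:r1, c0:c1], piece, out=surface[r0:r1, c0:c1])
        else:
            surface[r0:r1, c0:c1] += piece
    return DensityTarget(surface, sigma, combine_mode)


# ---------------------------------------------------------------------------
# file I/O in the tool's on-disk formats
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def write_image(path, array) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(array))
    else:
        iio.imwrite(path, np.asarray(array))


def read_mask(path) -> np.ndarray:
    """Single-channel {0, 255} PNG to a {0, 1} uint8 mask."""
    m = np.asarray(iio.imread(path))
    if m.ndim == 3:
        m = m[..., 0]
    return (m > 127).astype(np.uint8)


def write_mask(path, mask) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def write_density(path, target: DensityTarget) -> None:
    tifffile.imwrite(path, target.surface.astype(np.float32))


def read_density(path, sigma: float = 2.0, combine_mode: str = "max") -> DensityTarget:
    return DensityTarget(tifffile.imread(path), sigma, combine_mode)
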