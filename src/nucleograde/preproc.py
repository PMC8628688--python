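"""Desk-scale slide pre-processing: tissue masking, tiling, stain normalization.

The tumor-bed classifier that assigns tiles a tumor-bed probability is an
injected interface (a CSV column or a callable); this module only prepares its
inputs and turns its outputs into per-section tumor-bed areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_objects


def tissue_mask(rgb: np.ndarray, closing_radius: int = 2,
                min_object_area: int = 64) -> np.ndarray:
    """Foreground (tissue) mask by Otsu thresholding + morphology.

    Tissue is darker than the bright slide background, so foreground =
    grayscale below the Otsu threshold, then binary closing and small-object
    removal. A degenerate (uniform) histogram yields an empty mask with a
    warning.
    """
    img = np.asarray(rgb)
    gray = rgb2gray(img) if img.ndim == 3 else img.astype(float)
    if gray.max() == gray.min():
        warnings.warn("uniform image: degenerate histogram, returning empty mask",
                      stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    t = threshold_otsu(gray)
    mask = gray < t
    mask = closing(mask, disk(closing_radius))
    mask = remove_small_objects(mask, max_size=min_object_area - 1)
    return mask


@dataclass
class TileGrid:
    """Non-overlapping tile grid with per-tile background fractions."""

    tile_size: int
    origins: list[tuple[int, int]]                 # (row, col) of every grid tile
    background_fraction: list[float]
    retained: list[bool]
    tumor_bed_probability: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def retained_origins(self) -> list[tuple[int, int]]:
        return [o for o, r in zip(self.origins, self.retained) if r]

    def tumor_bed_area(self, probability_threshold: float = 0.5) -> int:
        """Pixel area of retained tiles whose tumor-bed probability passes."""
        n = sum(
            1 for o in self.retained_origins
            if self.tumor_bed_probability.get(o, 0.0) >= probability_threshold
        )
        return n * self.tile_size**2


def tile_image(image: np.ndarray, mask: np.ndarray, size: int = 750,
               max_background: float = 0.10,
               allow_clipped: bool = False) -> TileGrid:
    """Grid tiling anchored at (0, 0); tiles above the background cap are
    discarded but stay in the grid accounting (retained + discarded = grid)."""
    if mask.shape[:2] != image.shape[:2]:
        raise ValueError("mask extent differs from image extent")
    h, w = mask.shape[:2]
    if (h < size or w < size) and not allow_clipped:
        raise ValueError(
            f"image {w}x{h} smaller than one {size}px tile "
            "(pass allow_clipped=True for a single clipped tile)")
    rows = max(1, h // size) if allow_clipped else h // size
    cols = max(1, w // size) if allow_clipped else w // size
    origins, bg, retained = [], [], []
    for r in range(rows):
        for c in range(cols):
            y0, x0 = r * size, c * size
            tile_mask = mask[y0:min(y0 + size, h), x0:min(x0 + size, w)]
            frac_bg = 1.0 - float(tile_mask.mean())
            origins.append((y0, x0))
            bg.append(frac_bg)
            retained.append(frac_bg <= max_background)
    return TileGrid(size, origins, bg, retained)


# ---------------------------------------------------------- stain normalization

@dataclass(frozen=True)
class StainReference:
    """Target H&E stain matrix (3 x 2, columns = hematoxylin, eosin OD unit
    vectors) and the reference 99th-percentile stain concentrations."""

    stain_matrix: tuple = (
        (0.5626, 0.2159),
        (0.7201, 0.8012),
        (0.4062, 0.5581),
    )
    max_concentration: tuple = (1.9705, 1.0308)


def _optical_density(tile: np.ndarray, i0: float = 255.0) -> np.ndarray:
    arr = tile.reshape(-1, 3).astype(float)
    return -np.log((arr + 1.0) / (i0 + 1.0))


def macenko_stain_matrix(tile: np.ndarray, beta: float = 0.15,
                         alpha: float = 1.0) -> np.ndarray | None:
    """Estimate the 3x2 H&E stain matrix of a tile (Macenko-style SVD on
    optical densities); returns None when the tile carries no stain signal."""
    od = _optical_density(np.asarray(tile))
    od = od[np.all(od > beta, axis=1)]
    if len(od) < 20:
        return None
    _, eigvecs = np.linalg.eigh(np.cov(od.T))
    basis = eigvecs[:, [2, 1]]          # two largest eigenvalues
    if basis[0, 0] < 0:
        basis[:, 0] *= -1
    if basis[0, 1] < 0:
        basis[:, 1] *= -1
    proj = od @ basis
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100 - alpha])
    v1 = basis @ np.array([np.cos(lo), np.sin(lo)])
    v2 = basis @ np.array([np.cos(hi), np.sin(hi)])
    # hematoxylin first (larger red-channel OD than eosin)
    he = np.column_stack([v1, v2] if v1[0] > v2[0] else [v2, v1])
    he = np.abs(he)
    return he / np.linalg.norm(he, axis=0)


def stain_normalize(tile: np.ndarray,
                    reference: StainReference | None = None,
                    beta: float = 0.15) -> tuple[np.ndarray, bool]:
    """Macenko-style normalization of an RGB tile to a reference stain basis.

    Returns (normalized tile, flagged) where flagged=True marks the no-stain
    path (near-white tiles are returned unchanged).
    """
    reference = reference or StainReference()
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("expected an 8-bit RGB tile")
    he = macenko_stain_matrix(tile, beta=beta)
    if he is None:
        return tile.copy(), True
    od = _optical_density(tile)
    conc, *_ = np.linalg.lstsq(he, od.T, rcond=None)
    max_c = np.percentile(conc, 99, axis=1)
    max_c[max_c == 0] = 1.0
    ref_m = np.asarray(reference.stain_matrix, float)
    ref_c = np.asarray(reference.max_concentration, float)
    conc_norm = conc * (ref_c / max_c)[:, None]
    od_norm = ref_m @ conc_norm
    rgb = (255.0 + 1.0) * np.exp(-od_norm.T) - 1.0
    out = np.clip(rgb, 0, 255).reshape(tile.shape).astype(np.uint8)
    return out, False
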