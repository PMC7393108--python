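"""Leaf morphological traits from measurement tables and binary scan masks.

Specific leaf area SLA = LA / dry weight (cm^2/g) and leaf tissue density
LTD = dry weight / (LA * thickness) (g/cm^3); any consistent record
therefore satisfies SLA * LTD * thickness = 1.  Leaf area LA comes from a
binary scan mask as filled foreground area; the main-vein length LV is
approximated by the longest geodesic path through the mask's
morphological skeleton (a surrogate for tracing the midrib on the scan).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

__all__ = [
    "LeafRecord",
    "LeafMask",
    "sla",
    "ltd",
    "leaf_area_from_mask",
    "vein_length_from_mask",
    "read_mask",
]


def sla(la: float, dry_weight: float) -> float:
    """Specific leaf area, cm^2 of lamina per gram of dry mass."""
    if dry_weight <= 0:
        raise ValueError(f"dry_weight must be positive, got {dry_weight}")
    if la < 0:
        raise ValueError(f"leaf area must be >= 0, got {la}")
    return la / dry_weight


def ltd(dry_weight: float, la: float, thickness: float) -> float:
    """Leaf tissue density, g of dry mass per cm^3 of lamina volume."""
    if la <= 0 or thickness <= 0:
        raise ValueError(
            f"leaf area and thickness must be positive, got la={la}, thickness={thickness}"
        )
    if dry_weight < 0:
        raise ValueError(f"dry_weight must be >= 0, got {dry_weight}")
    return dry_weight / (la * thickness)


@dataclass
class LeafRecord:
    """One measured leaf; lengths in cm, mass in g, derived traits attached."""

    la: float
    thickness: float  # cm (caliper mm are converted at ingestion)
    dry_weight: float
    lv: float = float("nan")

    @property
    def sla(self) -> float:
        return sla(self.la, self.dry_weight)

    @property
    def ltd(self) -> float:
        return ltd(self.dry_weight, self.la, self.thickness)


@dataclass
class LeafMask:
    """Binary leaf scan raster with its physical resolution in cm/pixel."""

    pixels: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2D raster")
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if not self.pixels.any():
            raise ValueError("mask has no foreground pixels")


def read_mask(path: str | Path, resolution: float) -> LeafMask:
    """Load a binary mask from any raster format imageio understands."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return LeafMask(pixels=img > img.max() / 2.0, resolution=resolution)


def leaf_area_from_mask(mask: LeafMask) -> float:
    """Leaf area in cm^2: filled foreground pixel count times pixel area.

    Interior holes (scan artifacts, bright vein pixels) are filled before
    counting, so the area follows the outer leaf outline.
    """
    filled = ndimage.binary_fill_holes(mask.pixels)
    return float(filled.sum()) * mask.resolution ** 2


def _skeleton_graph(skel: np.ndarray) -> tuple[coo_matrix, np.ndarray]:
    ij = np.argwhere(skel)
    index = -np.ones(skel.shape, dtype=np.int64)
    index[skel] = np.arange(len(ij))
    rows, cols, weights = [], [], []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    h, w = skel.shape
    for di, dj in offsets:
        src = ij
        dst = ij + (di, dj)
        ok = (dst[:, 0] >= 0) & (dst[:, 0] < h) & (dst[:, 1] >= 0) & (dst[:, 1] < w)
        dst = dst[ok]
        neighbor = index[dst[:, 0], dst[:, 1]]
        has = neighbor >= 0
        rows.append(index[src[ok][has][:, 0], src[ok][has][:, 1]])
        cols.append(neighbor[has])
        weights.append(np.full(has.sum(), np.hypot(di, dj)))
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(ij), len(ij)),
    )
    return graph.tocsr(), ij


def vein_length_from_mask(mask: LeafMask, n_sweeps: int = 4) -> float:
    """Main-vein length in cm: longest geodesic through the mask skeleton.

    The mask is hole-filled and skeletonized; skeleton pixels form a graph
    with 8-connectivity (diagonal steps weigh sqrt(2) pixels).  The graph
    diameter is found by repeated farthest-point sweeps (exact on
    tree-shaped skeletons, which leaf midrib skeletons are).
    """
    filled = ndimage.binary_fill_holes(mask.pixels)
    skel = skeletonize(filled)
    if not skel.any():
        raise ValueError("skeleton is empty")
    if skel.sum() == 1:
        return 0.0
    graph, _ = _skeleton_graph(skel)
    start = 0
    best = 0.0
    for _ in range(n_sweeps):
        dist = dijkstra(graph, indices=start, directed=False)
        dist[~np.isfinite(dist)] = -1.0
        far = int(np.argmax(dist))
        if dist[far] <= best:
            break
        best = float(dist[far])
        start = far
    return best * mask.resolution
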