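"""Point-cloud containers and I/O.

Single-tree clouds are plain ``n x 3`` coordinate arrays in meters, z-up.
Two text formats are supported: whitespace-separated XYZ (one point per
line, ``#`` comments allowed) and ASCII PLY 1.0 with float vertex
properties ``x y z``.  Binary PLY is deliberately rejected.

Also provides the two preprocessing steps applied to segmented trees
before trait extraction: ground normalization (grid-minimum detrending)
and statistical outlier removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TreeCloud",
    "CloudParseError",
    "read_cloud",
    "write_cloud",
    "normalize_ground",
    "denoise_sor",
]


class CloudParseError(ValueError):
    """Raised when a cloud file does not parse under the declared dialect."""


@dataclass
class TreeCloud:
    """A segmented single-tree point set, coordinates in meters, z-up."""

    points: np.ndarray
    tree_id: str = ""
    plot_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be n x 3, got shape {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("cloud must contain at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("cloud contains non-finite coordinates")
        if self.normalized and pts[:, 2].min() < -1e-9:
            raise ValueError("normalized cloud has min z below zero")
        self.points = pts

    @property
    def n(self) -> int:
        return self.points.shape[0]


def _read_xyz(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 3:
                raise CloudParseError(
                    f"{path}: line {lineno}: expected 3 coordinates, got {len(tokens)} tokens"
                )
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise CloudParseError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise CloudParseError(f"{path}: no points found")
    return np.asarray(rows, dtype=float)


def _read_ply(path: Path) -> np.ndarray:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise CloudParseError(f"{path}: missing 'ply' magic line")
    n_vertex = None
    props: list[str] = []
    i = 1
    while i < len(lines):
        tokens = lines[i].split()
        i += 1
        if not tokens:
            continue
        if tokens[0] == "format":
            if tokens[1] != "ascii":
                raise CloudParseError(
                    f"{path}: binary PLY ({tokens[1]}) is not supported; use ASCII 1.0"
                )
        elif tokens[0] == "element":
            if tokens[1] != "vertex":
                raise CloudParseError(f"{path}: unsupported element '{tokens[1]}'")
            n_vertex = int(tokens[2])
        elif tokens[0] == "property":
            props.append(tokens[-1])
        elif tokens[0] == "end_header":
            break
    else:
        raise CloudParseError(f"{path}: end_header not found")
    if n_vertex is None:
        raise CloudParseError(f"{path}: no vertex element declared")
    for axis in ("x", "y", "z"):
        if axis not in props:
            raise CloudParseError(f"{path}: vertex property '{axis}' missing")
    cols = [props.index(a) for a in ("x", "y", "z")]
    data = lines[i : i + n_vertex]
    if len(data) < n_vertex:
        raise CloudParseError(
            f"{path}: header declares {n_vertex} vertices, found {len(data)}"
        )
    rows = np.empty((n_vertex, 3), dtype=float)
    for j, line in enumerate(data):
        tokens = line.split()
        if len(tokens) != len(props):
            raise CloudParseError(
                f"{path}: vertex line {j + 1}: expected {len(props)} values, got {len(tokens)}"
            )
        rows[j] = [float(tokens[c]) for c in cols]
    if n_vertex == 0:
        raise CloudParseError(f"{path}: no points found")
    return rows


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix == ".ply":
        return "ply"
    return "xyz"


def read_cloud(
    path: str | Path,
    format: str | None = None,
    tree_id: str = "",
    plot_id: str = "",
) -> TreeCloud:
    """Read a point cloud from XYZ text or ASCII PLY.

    Every input point appears exactly once, in file order.  Malformed
    lines raise :class:`CloudParseError` naming the offending line.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        pts = _read_xyz(path)
    elif fmt == "ply":
        pts = _read_ply(path)
    else:
        raise ValueError(f"unknown cloud format {fmt!r} (expected 'xyz' or 'ply')")
    if not tree_id:
        tree_id = path.stem
    return TreeCloud(points=pts, tree_id=tree_id, plot_id=plot_id)


def write_cloud(cloud: TreeCloud, path: str | Path, format: str | None = None) -> Path:
    """Write a cloud as XYZ text (full precision) or ASCII PLY (float32)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        with open(path, "w") as fh:
            fh.write("# x y z (m)\n")
            for x, y, z in cloud.points:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
    elif fmt == "ply":
        pts32 = cloud.points.astype(np.float32)
        with open(path, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(pts32)}\n"
                "property float x\nproperty float y\nproperty float z\n"
                "end_header\n"
            )
            for x, y, z in pts32:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
    else:
        raise ValueError(f"unknown cloud format {fmt!r} (expected 'xyz' or 'ply')")
    return path


def normalize_ground(
    cloud: TreeCloud, cell: float = 0.5, method: str = "global"
) -> TreeCloud:
    """Shift heights so the ground sits at z = 0.

    ``method='global'`` (default, appropriate for segmented single trees)
    subtracts the global minimum z.  ``method='grid'`` detrends sloping
    ground by subtracting, within each ``cell`` x ``cell`` meter column,
    that column's minimum z.  Both are idempotent and equivariant under
    z-translation.
    """
    pts = cloud.points.copy()
    if method == "global":
        pts[:, 2] -= pts[:, 2].min()
    elif method == "grid":
        if cell <= 0:
            raise ValueError("cell size must be positive")
        ij = np.floor(pts[:, :2] / cell).astype(np.int64)
        _, inverse = np.unique(ij, axis=0, return_inverse=True)
        cell_min = np.full(inverse.max() + 1, np.inf)
        np.minimum.at(cell_min, inverse, pts[:, 2])
        pts[:, 2] -= cell_min[inverse]
    else:
        raise ValueError(f"unknown method {method!r} (expected 'global' or 'grid')")
    return replace(cloud, points=pts, normalized=True)


def denoise_sor(
    cloud: TreeCloud, k: int = 8, m: float = 3.0, max_removal: float = 0.2
) -> TreeCloud:
    """Statistical outlier removal.

    Computes each point's mean distance to its ``k`` nearest neighbors and
    drops points whose statistic exceeds the global mean plus ``m`` standard
    deviations.  As a guard against destroying sparse crowns, never removes
    more than ``max_removal`` of the points (the worst offenders go first).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if cloud.n <= k:
        raise ValueError(f"cloud has {cloud.n} points, need more than k={k}")
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_knn = dists[:, 1:].mean(axis=1)
    threshold = mean_knn.mean() + m * mean_knn.std()
    keep = mean_knn <= threshold
    n_drop = int((~keep).sum())
    max_drop = int(max_removal * cloud.n)
    if n_drop > max_drop:
        warnings.warn(
            f"SOR would remove {n_drop}/{cloud.n} points; capping at {max_drop}",
            stacklevel=2,
        )
        order = np.argsort(mean_knn)[::-1]
        keep = np.ones(cloud.n, dtype=bool)
        keep[order[:max_drop]] = False
    return replace(cloud, points=cloud.points[keep])
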