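"""Stem morphometrics from segmented single-tree point clouds.

Height is the z-extent of the cloud; DBH comes from Taubin algebraic
circle fits to a thin slice at breast height (1.3 m), with single-linkage
clustering splitting multi-stem slices; the crown base is found from the
vertical profile of convex-hull cross-section areas; the canopy area CA
is the maximum convex-hull cross-section over horizontal layers (Graham
scan); LAI is inverted from ray-cast gap fractions via the Beer-Lambert
law with a Lang-Xiang clumping correction; the trunk dominance ratio
TDR = num * (sum d_i / d_max) summarizes single-trunk versus shrub-like
multi-stem architecture from the stem diameters at 1 m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io import TreeCloud

__all__ = [
    "TreeTraits",
    "StemInventory",
    "Hull2D",
    "GapProfile",
    "tree_height",
    "fit_circle_taubin",
    "dbh",
    "crown_base",
    "graham_hull",
    "polygon_area",
    "canopy_area",
    "gap_profile",
    "lai_from_profile",
    "lai",
    "tdr",
    "branch_ratios",
    "percent_cover",
    "extract_traits",
    "traits_table",
]


@dataclass
class TreeTraits:
    """Per-tree stem morphological record (meters, m^2, dimensionless)."""

    height: float
    crown_base: float
    clr: float
    dbh: float
    ca: float
    lai: float = float("nan")
    tdr: float = float("nan")
    sl_fl: float = float("nan")
    sc_fc: float = float("nan")
    tree_id: str = ""
    plot_id: str = ""


@dataclass
class StemInventory:
    """Stem diameters measured at 1 m aboveground (one entry per stem)."""

    diameters_1m: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.diameters_1m) == 0:
            raise ValueError("stem inventory must contain at least one diameter")
        if any(d <= 0 for d in self.diameters_1m):
            raise ValueError(f"stem diameters must be positive, got {self.diameters_1m}")


@dataclass
class Hull2D:
    """Convex hull: CCW vertices, no collinear boundary points retained."""

    vertices: np.ndarray  # (k, 2)


@dataclass
class GapProfile:
    """Per-zenith-bin gap fractions from ray casting plus clumping index."""

    zenith_bins: list[tuple[float, float, int]]  # (theta_center rad, P, ray_count)
    clumping: float
    g_function: float = 0.5


def tree_height(cloud: TreeCloud) -> float:
    """Tree height = difference between the highest and lowest points."""
    if cloud.n < 2:
        raise ValueError("height requires at least 2 points")
    z = cloud.points[:, 2]
    return float(z.max() - z.min())


def fit_circle_taubin(points2d: np.ndarray) -> tuple[float, float, float]:
    """Taubin algebraic circle fit.

    Minimizes the algebraic distance sum((x^2 + y^2) + D x + E y + F)^2
    under Taubin's gradient-norm normalization, solved as a (generalized)
    eigenproblem.  Nearly unbiased for partial arcs; exact on noiseless
    circles.  Returns (cx, cy, r).
    """
    pts = np.asarray(points2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("circle fit requires >= 3 points in 2D")
    centroid = pts.mean(axis=0)
    x = pts[:, 0] - centroid[0]
    y = pts[:, 1] - centroid[1]
    z = x * x + y * y
    zm, xm2 = z.mean(), (x * x).mean()
    ym2, xym = (y * y).mean(), (x * y).mean()
    if xm2 * ym2 - xym * xym < 1e-12 * max(xm2 + ym2, 1e-30) ** 2:
        raise ValueError("degenerate slice: points are collinear")
    # Taubin's characteristic polynomial in the centered moments
    # (Chernov's formulation); the smallest non-negative root gives the fit.
    mz = zm
    mxz, myz = (x * z).mean(), (y * z).mean()
    mzz = (z * z).mean()
    cov_xy = xm2 * ym2 - xym * xym
    var_z = mzz - mz * mz
    a3 = 4.0 * mz
    a2 = -3.0 * mz * mz - mzz
    a1 = var_z * mz + 4.0 * cov_xy * mz - mxz * mxz - myz * myz
    a0 = mxz * (mxz * ym2 - myz * xym) + myz * (myz * xm2 - mxz * xym) - var_z * cov_xy
    # Newton iteration from 0 converges to the smallest positive root
    t = 0.0
    for _ in range(50):
        f = a0 + t * (a1 + t * (a2 + t * a3))
        fp = a1 + t * (2.0 * a2 + 3.0 * a3 * t)
        step = f / fp
        t_new = t - step
        if not np.isfinite(t_new) or t_new < 0:
            break
        if abs(step) < 1e-14 * max(abs(t), 1.0):
            t = t_new
            break
        t = t_new
    det = (t - xm2) * (t - ym2) - xym * xym
    cx = (mxz * (ym2 - t) - myz * xym) / det / 2.0
    cy = (myz * (xm2 - t) - mxz * xym) / det / 2.0
    r = np.sqrt(cx * cx + cy * cy + mz)
    return float(cx + centroid[0]), float(cy + centroid[1]), float(r)


def _split_stems(xy: np.ndarray, linkage_dist: float) -> list[np.ndarray]:
    if len(xy) == 1:
        return [np.array([0])]
    merges = linkage(xy, method="single")
    labels = fcluster(merges, t=linkage_dist, criterion="distance")
    return [np.flatnonzero(labels == lab) for lab in np.unique(labels)]


def dbh(
    cloud: TreeCloud,
    slice_center: float = 1.3,
    slice_halfwidth: float = 0.05,
    stem_linkage: float = 0.1,
) -> tuple[float, list[float]]:
    """Diameter at breast height from Taubin circle fits at 1.3 m.

    The slice is projected to XY and split into stems by single-linkage
    connected components (0.1 m default linkage); each stem gets its own
    circle fit.  Returns (DBH of the largest stem, per-stem diameters).
    """
    z = cloud.points[:, 2]
    mask = np.abs(z - slice_center) <= slice_halfwidth
    if not mask.any():
        raise ValueError(f"no points at breast height ({slice_center} m)")
    xy = cloud.points[mask, :2]
    diameters = []
    for idx in _split_stems(xy, stem_linkage):
        if len(idx) < 3:
            continue
        _, _, r = fit_circle_taubin(xy[idx])
        diameters.append(2.0 * r)
    if not diameters:
        raise ValueError("no stem cluster in the breast-height slice has >= 3 points")
    diameters.sort(reverse=True)
    return diameters[0], diameters


def graham_hull(points2d: np.ndarray) -> Hull2D:
    """Convex hull by Graham scan.

    Sorts by polar angle around the lowest point (ties broken by
    distance) and retains only strict left turns, so collinear boundary
    points are dropped.  Vertices come back counter-clockwise.
    """
    pts = np.unique(np.asarray(points2d, dtype=float), axis=0)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("hull requires >= 3 distinct points in 2D")
    # pivot: lowest y, then lowest x
    pivot_idx = np.lexsort((pts[:, 0], pts[:, 1]))[0]
    pivot = pts[pivot_idx]
    rest = np.delete(pts, pivot_idx, axis=0)
    delta = rest - pivot
    angles = np.arctan2(delta[:, 1], delta[:, 0])
    dist2 = (delta ** 2).sum(axis=1)
    order = np.lexsort((dist2, angles))
    rest = rest[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    stack: list[np.ndarray] = [pivot]
    for p in rest:
        while len(stack) >= 2 and cross(stack[-2], stack[-1], p) <= 1e-12 * max(
            1.0, float(np.abs(p).max())
        ):
            stack.pop()
        stack.append(p)
    if len(stack) < 3:
        raise ValueError("degenerate geometry: all points are collinear")
    return Hull2D(vertices=np.asarray(stack))


def polygon_area(hull: Hull2D | np.ndarray) -> float:
    """Polygon area by the shoelace formula (absolute value)."""
    verts = hull.vertices if isinstance(hull, Hull2D) else np.asarray(hull, dtype=float)
    if verts.shape[0] < 3:
        raise ValueError("polygon area requires >= 3 vertices")
    x, y = verts[:, 0], verts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _layer_hull_area(xy: np.ndarray) -> float:
    if len(xy) < 3:
        return 0.0
    try:
        return polygon_area(graham_hull(xy))
    except ValueError:  # collinear layer
        return 0.0


def crown_base(
    cloud: TreeCloud, layer: float = 0.25, alpha: float = 0.15, persistence: int = 2
) -> float:
    """Crown base height from the vertical profile of hull areas.

    Splits the cloud into horizontal layers, computes each layer's convex
    hull area A(z), and locates the lowest layer with A >= alpha * max A
    that is followed by at least ``persistence`` consecutive qualifying
    layers.  Because the area threshold is only reached once the crown has
    accumulated some depth, the reported base sits half a layer below that
    layer's lower edge, centering the quantization error; a profile that
    never qualifies (pure trunk, shrub-like form) returns 0 with a warning.
    """
    z = cloud.points[:, 2]
    z0 = z.min()
    n_layers = int(np.ceil((z.max() - z0) / layer))
    if n_layers < 4:
        raise ValueError("cloud must span at least 4 layers for crown-base detection")
    idx = np.minimum(((z - z0) / layer).astype(int), n_layers - 1)
    areas = np.array(
        [_layer_hull_area(cloud.points[idx == i, :2]) for i in range(n_layers)]
    )
    if areas.max() <= 0:
        warnings.warn("no layer has a positive hull area; returning 0", stacklevel=2)
        return 0.0
    qualifies = areas >= alpha * areas.max()
    if qualifies.all():
        # flat area profile: a bare trunk or ground-hugging shrub, no
        # detectable trunk/canopy transition
        warnings.warn("flat area profile (trunk-only or shrub-like form); returning 0",
                      stacklevel=2)
        return 0.0
    for i in range(n_layers - persistence):
        if qualifies[i : i + persistence + 1].all():
            return float(max(z0 + i * layer - layer / 2.0, z0))
    warnings.warn(
        "area profile never qualifies persistently (shrub-like form); returning 0",
        stacklevel=2,
    )
    return 0.0


def canopy_area(cloud: TreeCloud, crown_base: float, layer: float = 0.5) -> float:
    """Canopy area CA: maximum hull cross-section over horizontal layers.

    Canopy points (z >= crown base) are partitioned into layers of the
    given thickness; CA is the largest convex-hull area among layers with
    at least 3 points.
    """
    canopy = cloud.points[cloud.points[:, 2] >= crown_base]
    if len(canopy) < 3:
        raise ValueError("fewer than 3 points above the crown base")
    z = canopy[:, 2]
    n_layers = max(1, int(np.ceil((z.max() - crown_base) / layer)))
    idx = np.minimum(((z - crown_base) / layer).astype(int), n_layers - 1)
    areas = [_layer_hull_area(canopy[idx == i, :2]) for i in range(n_layers)]
    best = max(areas)
    if best <= 0:
        raise ValueError("no canopy layer has >= 3 non-collinear points")
    return float(best)


def gap_profile(
    cloud: TreeCloud,
    scanner_pos: tuple[float, float, float],
    zenith_edges: np.ndarray | list[float] | None = None,
    n_zenith_steps: int = 4,
    n_azimuth: int = 48,
    n_sectors: int = 4,
    beam_radius: float = 0.02,
    crown_base_z: float | None = None,
    g: float = 0.5,
) -> GapProfile:
    """Cast a regular angular ray grid through the canopy and bin gap fractions.

    A ray is intercepted when it passes within ``beam_radius`` of any
    canopy point (z above ``crown_base_z`` when given).  Gap fraction
    P(theta) is the non-intercepted fraction per zenith bin; the clumping
    index uses Lang-Xiang log-averaging over azimuth sectors,
    Omega = ln(mean P) / mean(ln P).
    """
    if zenith_edges is None:
        zenith_edges = np.radians([0.0, 10.0, 20.0, 30.0])
    edges = np.asarray(zenith_edges, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least one zenith bin")
    pts = cloud.points
    if crown_base_z is not None:
        pts = pts[pts[:, 2] >= crown_base_z]
    origin = np.asarray(scanner_pos, dtype=float)
    rel = pts - origin

    bins: list[tuple[float, float, int]] = []
    sector_gaps: list[float] = []
    azimuths = 2.0 * np.pi * (np.arange(n_azimuth) + 0.5) / n_azimuth
    sector_of = (azimuths / (2.0 * np.pi) * n_sectors).astype(int) % n_sectors
    for lo, hi in zip(edges[:-1], edges[1:]):
        thetas = lo + (hi - lo) * (np.arange(n_zenith_steps) + 0.5) / n_zenith_steps
        hits = np.zeros((n_zenith_steps, n_azimuth), dtype=bool)
        for i, theta in enumerate(thetas):
            for j, phi in enumerate(azimuths):
                u = np.array(
                    [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
                )
                t = rel @ u
                forward = t > 0
                if not forward.any():
                    continue
                d2 = (rel[forward] ** 2).sum(axis=1) - t[forward] ** 2
                hits[i, j] = bool((d2 < beam_radius ** 2).any())
        p_bin = 1.0 - hits.mean()
        bins.append((float((lo + hi) / 2.0), float(p_bin), int(hits.size)))
        for s in range(n_sectors):
            cols = sector_of == s
            if cols.any():
                sector_gaps.append(1.0 - hits[:, cols].mean())

    p_sectors = np.array([p for p in sector_gaps if p > 0.0])
    if len(p_sectors) == 0 or np.all(p_sectors >= 1.0):
        omega = 1.0
    else:
        mean_log = np.mean(np.log(p_sectors))
        omega = 1.0 if mean_log == 0.0 else float(np.log(p_sectors.mean()) / mean_log)
    return GapProfile(zenith_bins=bins, clumping=omega, g_function=g)


def lai_from_profile(profile: GapProfile) -> float:
    """Invert a gap profile to LAI via Beer-Lambert.

    Per usable bin L_e(theta) = -cos(theta) ln P(theta) / G; saturated
    bins (P = 0) are excluded with a warning; LAI = mean L_e / Omega.
    """
    usable = [(theta, p) for theta, p, _ in profile.zenith_bins if p > 0.0]
    n_saturated = len(profile.zenith_bins) - len(usable)
    if n_saturated:
        warnings.warn(f"{n_saturated} zenith bin(s) saturated (P = 0); excluded", stacklevel=2)
    if not usable:
        raise ValueError("all zenith bins saturated; cannot invert gap fractions")
    le = [-np.cos(theta) * np.log(p) / profile.g_function for theta, p in usable]
    return float(np.mean(le) / profile.clumping)


def lai(
    cloud: TreeCloud,
    scanner_pos: tuple[float, float, float],
    zenith_edges: np.ndarray | list[float] | None = None,
    g: float = 0.5,
    **kwargs,
) -> tuple[float, GapProfile]:
    """Leaf area index from ray-cast gap fractions (Beer-Lambert inversion)."""
    profile = gap_profile(cloud, scanner_pos, zenith_edges, g=g, **kwargs)
    return lai_from_profile(profile), profile


def tdr(inv: StemInventory) -> float:
    """Trunk dominance ratio: num * (sum of stem diameters / largest diameter).

    Equals 1 for a single dominant trunk and grows with the number and
    relative size of extra basal stems (n equal stems give n^2).
    """
    d = np.asarray(inv.diameters_1m, dtype=float)
    return float(len(d) * d.sum() / d.max())


def branch_ratios(table: pd.DataFrame) -> tuple[float, float]:
    """Second-order/first-order branch ratios of summed lengths and counts.

    ``table`` needs columns branch_id, order (1 or 2), length_m; order-2
    rows may carry a parent_id referencing an order-1 branch.  Returns
    (Sl/Fl, Sc/Fc) computed from totals.
    """
    if table["branch_id"].duplicated().any():
        dupes = table.loc[table["branch_id"].duplicated(), "branch_id"].tolist()
        raise ValueError(f"duplicate branch_id rows: {dupes}")
    if not set(table["order"].unique()) <= {1, 2}:
        raise ValueError("branch order must be 1 or 2")
    if (table["length_m"] <= 0).any():
        raise ValueError("branch lengths must be positive")
    first = table[table["order"] == 1]
    second = table[table["order"] == 2]
    if len(first) == 0 or first["length_m"].sum() <= 0:
        raise ValueError("no first-order branches (zero total length)")
    sl_fl = second["length_m"].sum() / first["length_m"].sum()
    sc_fc = len(second) / len(first)
    return float(sl_fl), float(sc_fc)


def percent_cover(
    clouds: list[TreeCloud],
    plot_side: float = 25.0,
    cell: float = 0.5,
    min_h: float = 2.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Percentage tree cover: share of plot grid cells with canopy returns.

    A cell counts as covered when it contains at least one point with
    z >= ``min_h``.  The plot is a ``plot_side`` square gridded at
    ``cell`` resolution starting at ``origin``.
    """
    n_cells = int(round(plot_side / cell))
    covered = np.zeros((n_cells, n_cells), dtype=bool)
    for cloud in clouds:
        pts = cloud.points[cloud.points[:, 2] >= min_h]
        if len(pts) == 0:
            continue
        ix = np.floor((pts[:, 0] - origin[0]) / cell).astype(int)
        iy = np.floor((pts[:, 1] - origin[1]) / cell).astype(int)
        inside = (ix >= 0) & (ix < n_cells) & (iy >= 0) & (iy < n_cells)
        covered[ix[inside], iy[inside]] = True
    return float(covered.sum() / covered.size * 100.0)


def extract_traits(
    cloud: TreeCloud,
    stems: StemInventory | None = None,
    branches: pd.DataFrame | None = None,
    crown_layer: float = 0.25,
    ca_layer: float = 0.5,
    compute_lai: bool = False,
    scanner_pos: tuple[float, float, float] | None = None,
) -> TreeTraits:
    """Run the full stem-trait extraction on one segmented tree."""
    height = tree_height(cloud)
    cb = crown_base(cloud, layer=crown_layer)
    d, _ = dbh(cloud)
    ca = canopy_area(cloud, cb, layer=ca_layer)
    traits = TreeTraits(
        height=height,
        crown_base=cb,
        clr=cb / height if height > 0 else 0.0,
        dbh=d,
        ca=ca,
        tree_id=cloud.tree_id,
        plot_id=cloud.plot_id,
    )
    if stems is not None:
        traits.tdr = tdr(stems)
    if branches is not None:
        traits.sl_fl, traits.sc_fc = branch_ratios(branches)
    if compute_lai:
        if scanner_pos is None:
            xy = cloud.points[:, :2].mean(axis=0)
            scanner_pos = (float(xy[0]), float(xy[1]), 0.0)
        traits.lai, _ = lai(cloud, scanner_pos, crown_base_z=cb)
    return traits


def traits_table(records: list[TreeTraits]) -> pd.DataFrame:
    """Assemble per-tree records into the standard traits table (meters)."""
    cols = [
        "tree_id", "plot_id", "height", "crown_base", "clr", "dbh", "ca",
        "lai", "tdr", "sl_fl", "sc_fc",
    ]
    return pd.DataFrame([{c: getattr(t, c) for c in cols} for t in records], columns=cols)
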