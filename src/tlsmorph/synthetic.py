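"""Synthetic single-tree clouds, allometry tables and plot tables with known truth.

Every downstream stage of the pipeline is testable against this module:

* :func:`make_tree` builds a segmented single-tree cloud — a vertical
  cylinder-surface trunk (one cylinder per stem for shrub-like multi-stem
  forms) plus leaf points drawn uniformly inside an ellipsoidal crown —
  together with the analytically implied trait values (``GroundTruth``).
* :func:`make_envelope_table` draws (x, y) samples whose conditional 5% and
  95% quantiles of y given x are *exactly* two prescribed power laws, so
  quantile-envelope fitting can be checked against known truth.
* :func:`make_plot_table` draws plot-level trait/environment records from a
  multivariate Gaussian with a requested correlation structure, so the
  trait-environment correlation machinery can be calibrated.

All randomness flows through explicit integer seeds; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TreeCloud

__all__ = [
    "TreeParams",
    "GroundTruth",
    "EnvelopeSimParams",
    "make_tree",
    "make_envelope_table",
    "make_plot_table",
    "correlation_matrix",
    "TRAIT_COLUMNS",
    "ENV_COLUMNS",
]

#: the 12 plot-mean morphological trait columns, stem traits then leaf traits
TRAIT_COLUMNS = (
    "height", "clr", "dbh", "tdr", "ca", "lai", "sl_fl", "sc_fc",
    "la", "sla", "ltd", "lv",
)

#: the 13 environment columns (climate, topography, soil, stand)
ENV_COLUMNS = (
    "map", "cvp", "radiation", "mat", "pdsi", "pet", "aet",
    "bd", "altitude", "slope", "aspect", "age", "cover",
)


@dataclass
class TreeParams:
    """Geometric parameters of one synthetic tree.

    Lengths in meters.  ``stem_diameters_1m`` lists the stem diameters at
    1 m aboveground (one entry per stem); when omitted the tree has a
    single stem of diameter ``dbh``.  ``crown_semi_axes`` are the (rx, ry,
    rz) semi-axes of the ellipsoidal leaf crown, whose base sits at
    ``crown_base``.  ``noise_sigma`` adds isotropic Gaussian ranging
    jitter; it defaults to 0 so exactness tests see ideal geometry.
    """

    height: float = 8.0
    crown_base: float = 3.0
    dbh: float = 0.2
    stem_diameters_1m: tuple[float, ...] | None = None
    crown_semi_axes: tuple[float, float, float] = (2.0, 2.0, 2.5)
    leaf_area_density: float = 0.5
    trunk_point_spacing: float = 0.02
    leaf_point_count: int = 4000
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crown_base < 0:
            raise ValueError(f"crown_base must be >= 0, got {self.crown_base}")
        if self.height <= self.crown_base:
            raise ValueError(
                f"height must exceed crown_base, got height={self.height}, "
                f"crown_base={self.crown_base}"
            )
        if self.dbh <= 0:
            raise ValueError(f"dbh must be positive, got {self.dbh}")
        if any(a <= 0 for a in self.crown_semi_axes):
            raise ValueError(f"crown_semi_axes must be positive, got {self.crown_semi_axes}")
        if self.stem_diameters_1m is not None:
            if len(self.stem_diameters_1m) == 0 or any(d <= 0 for d in self.stem_diameters_1m):
                raise ValueError(
                    f"stem_diameters_1m must be non-empty and positive, got {self.stem_diameters_1m}"
                )
        if self.trunk_point_spacing <= 0:
            raise ValueError(f"trunk_point_spacing must be positive, got {self.trunk_point_spacing}")
        if self.leaf_point_count < 0:
            raise ValueError(f"leaf_point_count must be >= 0, got {self.leaf_point_count}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")

    @property
    def stems(self) -> tuple[float, ...]:
        return self.stem_diameters_1m if self.stem_diameters_1m is not None else (self.dbh,)


@dataclass
class GroundTruth:
    """Trait values implied analytically by :class:`TreeParams`.

    Branch ratios (sl_fl, sc_fc) are not encoded in the cloud geometry and
    are reported as NaN; they come from branch tables instead.
    """

    height: float
    crown_base: float
    clr: float
    dbh: float
    ca: float
    lai: float
    tdr: float
    sl_fl: float = float("nan")
    sc_fc: float = float("nan")


def _trunk_truth_height(params: TreeParams) -> float:
    rx, ry, rz = params.crown_semi_axes
    return max(params.height, params.crown_base + 2.0 * rz)


def _stem_centers(params: TreeParams) -> np.ndarray:
    diams = params.stems
    if len(diams) == 1:
        return np.zeros((1, 2))
    # minimal circle keeping adjacent stem surfaces > 0.1 m apart, so the
    # 1.3 m slices are disjoint and cleanly separable by single linkage
    radii = sorted((d / 2.0 for d in diams), reverse=True)
    radius = (radii[0] + radii[1] + 0.15) / (2.0 * np.sin(np.pi / len(diams)))
    angles = 2.0 * np.pi * np.arange(len(diams)) / len(diams)
    return radius * np.column_stack([np.cos(angles), np.sin(angles)])


def _cylinder_surface(
    center: np.ndarray, diameter: float, z_top: float, spacing: float
) -> np.ndarray:
    radius = diameter / 2.0
    n_ring = max(8, int(round(2.0 * np.pi * radius / spacing)))
    n_z = max(2, int(round(z_top / spacing)) + 1)
    zs = np.linspace(0.0, z_top, n_z)
    angles = 2.0 * np.pi * np.arange(n_ring) / n_ring
    ring = np.column_stack([radius * np.cos(angles), radius * np.sin(angles)])
    pts = np.empty((n_z * n_ring, 3))
    pts[:, 0] = np.tile(ring[:, 0] + center[0], n_z)
    pts[:, 1] = np.tile(ring[:, 1] + center[1], n_z)
    pts[:, 2] = np.repeat(zs, n_ring)
    return pts


def _ellipsoid_interior(
    rng: np.random.Generator, n: int, semi_axes: tuple[float, float, float],
    center_z: float,
) -> np.ndarray:
    if n == 0:
        return np.empty((0, 3))
    # uniform in the unit ball: isotropic direction, radius ~ U^(1/3)
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    pts = directions * radii * np.asarray(semi_axes)
    pts[:, 2] += center_z
    return pts


def make_tree(params: TreeParams) -> tuple[TreeCloud, GroundTruth]:
    """Sample a single-tree cloud and its analytically known traits.

    The trunk is a cylinder *surface* sampling (mimicking laser returns
    from the bark, with full 360 degree station coverage) from the ground
    to the crown base; the tallest stem continues through the crown up to
    the true tree top.  Leaf points are uniform inside the crown
    ellipsoid.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    rx, ry, rz = params.crown_semi_axes
    truth_height = _trunk_truth_height(params)
    diams = params.stems
    centers = _stem_centers(params)

    parts = []
    for i, (diam, center) in enumerate(zip(diams, centers)):
        z_top = truth_height if i == int(np.argmax(diams)) else params.crown_base
        parts.append(_cylinder_surface(center, diam, z_top, params.trunk_point_spacing))
    parts.append(
        _ellipsoid_interior(
            rng, params.leaf_point_count, params.crown_semi_axes,
            params.crown_base + rz,
        )
    )
    pts = np.vstack(parts)
    if params.noise_sigma > 0:
        pts = pts + rng.normal(scale=params.noise_sigma, size=pts.shape)

    crown_volume = 4.0 / 3.0 * np.pi * rx * ry * rz
    truth = GroundTruth(
        height=truth_height,
        crown_base=params.crown_base,
        clr=params.crown_base / truth_height,
        dbh=max(diams),
        ca=np.pi * rx * ry,
        # one-sided leaf area per unit crown ground area; the mean vertical
        # chord of an ellipsoid over its footprint is V / (pi rx ry) = 4 rz / 3
        lai=params.leaf_area_density * crown_volume / (np.pi * rx * ry),
        tdr=len(diams) * (sum(diams) / max(diams)),
    )
    cloud = TreeCloud(points=pts, tree_id=f"synthetic-{params.seed}", normalized=True)
    return cloud, truth


def random_tree_params(
    rng: np.random.Generator,
    seed: int,
    leaf_point_count: int = 20000,
    trunk_point_spacing: float = 0.02,
    multi_stem_prob: float = 0.3,
) -> TreeParams:
    """Draw one plausible semi-arid oak geometry.

    Emulates the short, wide-crowned growth form of drought-limited oak
    stands: crown base 1.6-3 m (above breast height, so the DBH slice is
    clean), crown depth 2-5 m and crown width 1.6-6 m (crowns at least as
    wide as deep), stem diameter 8-35 cm, and a 30% chance of a
    shrub-like multi-stem base.  The default point budget reflects a
    multi-station terrestrial-laser scan of a single tree.
    """
    crown_base = float(rng.uniform(1.6, 3.0))
    rz = float(rng.uniform(1.0, 2.5))
    dbh = float(rng.uniform(0.08, 0.35))
    stems = None
    multi = rng.uniform() < multi_stem_prob
    if multi:
        extra = int(rng.integers(1, 4))
        stems = tuple([dbh] + [float(dbh * rng.uniform(0.3, 0.9)) for _ in range(extra)])
    # shrub-like multi-stem forms carry the wide crowns that define the
    # semi-arid growth type (and keep the basal cluster well below the
    # crown's cross-section in the area profile)
    rx = float(rng.uniform(max(rz * 0.8, 1.8 if multi else 0.8), 3.0))
    ry = rx * float(rng.uniform(0.8, 1.2))
    return TreeParams(
        height=crown_base + 2.0 * rz,
        crown_base=crown_base,
        dbh=dbh,
        stem_diameters_1m=stems,
        crown_semi_axes=(rx, ry, rz),
        trunk_point_spacing=trunk_point_spacing,
        leaf_point_count=leaf_point_count,
        seed=seed,
    )


@dataclass
class EnvelopeSimParams:
    """Parameters for the power-law quantile-envelope sampler."""

    n: int = 2000
    x_range: tuple[float, float] = (2.0, 14.0)
    lower_curve: tuple[float, float] = (3.73e-5, 4.62)
    upper_curve: tuple[float, float] = (11.48, 0.546)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValueError(f"n must be >= 20, got {self.n}")
        lo, hi = self.x_range
        if not (0 < lo < hi):
            raise ValueError(f"x_range must satisfy 0 < min < max, got {self.x_range}")
        a5, _ = self.lower_curve
        a95, _ = self.upper_curve
        if a5 <= 0 or a95 <= 0:
            raise ValueError("power-law coefficients must be positive")
        xs = np.linspace(lo, hi, 101)
        lower = a5 * xs ** self.lower_curve[1]
        upper = a95 * xs ** self.upper_curve[1]
        if np.any(lower > upper * (1 + 1e-12)):
            raise ValueError("lower_curve exceeds upper_curve inside x_range (curves cross)")


def envelope_quantile_curve(params: EnvelopeSimParams, u: float) -> tuple[float, float]:
    """The (a, b) of the exact conditional u-quantile curve of the sampler."""
    a5, b5 = params.lower_curve
    a95, b95 = params.upper_curve
    s = (u - 0.05) / 0.90
    log_a = math.log(a5) + s * (math.log(a95) - math.log(a5))
    b = b5 + s * (b95 - b5)
    return math.exp(log_a), b


def make_envelope_table(params: EnvelopeSimParams) -> pd.DataFrame:
    """Sample (x, y) whose conditional quantiles of y|x are exact power laws.

    x is uniform on ``x_range``; a latent U ~ Uniform(0, 1) indexes a family
    of power laws whose (log a, b) interpolate linearly between the lower
    curve at U = 0.05 and the upper curve at U = 0.95, so the conditional
    5% and 95% quantiles of y given x equal the two stated curves exactly.
    """
    rng = np.random.default_rng(params.seed)
    x = rng.uniform(*params.x_range, size=params.n)
    u = rng.uniform(size=params.n)
    a5, b5 = params.lower_curve
    a95, b95 = params.upper_curve
    s = (u - 0.05) / 0.90
    log_a = np.log(a5) + s * (np.log(a95) - np.log(a5))
    b = b5 + s * (b95 - b5)
    y = np.exp(log_a + b * np.log(x))
    return pd.DataFrame({"x": x, "y": y})


def correlation_matrix(pairs: dict[tuple[str, str], float] | None = None) -> pd.DataFrame:
    """Identity trait-environment correlation matrix with requested entries set.

    ``pairs`` maps column-name pairs (any of the 12 traits and 13
    environment variables) to correlation coefficients.
    """
    cols = list(TRAIT_COLUMNS) + list(ENV_COLUMNS)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for (c1, c2), r in (pairs or {}).items():
        if c1 not in cols or c2 not in cols:
            raise KeyError(f"unknown column in pair ({c1}, {c2})")
        mat.loc[c1, c2] = r
        mat.loc[c2, c1] = r
    return mat


def make_plot_table(
    n_plots: int,
    effect_matrix: pd.DataFrame | np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw plot records from a Gaussian with the requested correlations.

    Columns are ``plot_id`` plus the 12 trait and 13 environment columns;
    marginals are standard normal (correlation structure is all the
    downstream statistics consume).
    """
    cols = list(TRAIT_COLUMNS) + list(ENV_COLUMNS)
    if effect_matrix is None:
        effect_matrix = np.eye(len(cols))
    if isinstance(effect_matrix, pd.DataFrame):
        effect_matrix = effect_matrix.loc[cols, cols].to_numpy()
    mat = np.asarray(effect_matrix, dtype=float)
    if mat.shape != (len(cols), len(cols)):
        raise ValueError(f"effect_matrix must be {len(cols)} x {len(cols)}, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("effect_matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValueError("effect_matrix must have unit diagonal")
    eigvals, eigvecs = np.linalg.eigh(mat)
    if eigvals.min() < -1e-8:
        raise ValueError(
            f"effect_matrix is not positive semi-definite (min eigenvalue {eigvals.min():.3g})"
        )
    factor = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n_plots, len(cols))) @ factor.T
    table = pd.DataFrame(z, columns=cols)
    table.insert(0, "plot_id", [f"P{i + 1:03d}" for i in range(n_plots)])
    return table
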