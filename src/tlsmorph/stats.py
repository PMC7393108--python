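"""Trait-trait and trait-environment statistics at the plot level.

Pearson and partial correlations (two-tailed, with the 0.1/0.05/0.01
significance stars used in the trait-environment matrix), standardized
PCA of the 12 morphological traits (LTD and TDR sign-flipped so that
all loadings read in the direction of "taller, single-trunk, thin-leaf"
tree form), and agglomerative clustering of trait profiles with
Euclidean centroid linkage (inversions are possible under centroid
linkage and are flagged rather than hidden).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage

from .synthetic import ENV_COLUMNS, TRAIT_COLUMNS

__all__ = [
    "CorrelationResult",
    "PCAResult",
    "pearson",
    "partial_correlation",
    "pca_traits",
    "cluster_traits",
    "env_trait_matrix",
    "plot_env_trait_matrix",
]

_STAR_LEVELS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


def _stars(p: float) -> str:
    for level, mark in _STAR_LEVELS:
        if p < level:
            return mark
    return ""


@dataclass
class CorrelationResult:
    """A correlation with its two-tailed p-value and significance stars."""

    r: float
    p: float
    n: int
    controls: tuple[str, ...] = ()

    @property
    def stars(self) -> str:
        return _stars(self.p)


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Two-tailed Pearson product-moment correlation.

    The p-value comes from t = r * sqrt((n - 2) / (1 - r^2)) on n - 2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the arguments")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def _residuals(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), controls])
    coef, _, rank, _ = np.linalg.lstsq(design, v, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient control matrix")
    return v - design @ coef


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    controls: np.ndarray | None = None,
    control_names: tuple[str, ...] = (),
) -> CorrelationResult:
    """Partial correlation of x and y given a set of control variables.

    Both variables are regressed (ordinary least squares, with intercept)
    on the controls; the Pearson correlation of the residuals is tested on
    n - 2 - k degrees of freedom for k controls.  With no controls this
    reduces exactly to :func:`pearson`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or (hasattr(controls, "size") and controls.size == 0):
        return pearson(x, y)
    c = np.asarray(controls, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    k = c.shape[1]
    n = len(x)
    if n < k + 3:
        raise ValueError(f"need n >= {k + 3} observations for {k} controls, got {n}")
    rx = _residuals(x, c)
    ry = _residuals(y, c)
    # a variable (numerically) fully explained by the controls
    if np.ptp(rx) <= 1e-10 * max(np.ptp(x), 1e-300) or np.ptp(ry) <= 1e-10 * max(
        np.ptp(y), 1e-300
    ):
        # a variable fully explained by the controls has partial r = 0
        return CorrelationResult(r=0.0, p=1.0, n=n, controls=control_names or ("?",) * k)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, p=p, n=n, controls=control_names or ("?",) * k)


@dataclass
class PCAResult:
    """Standardized PCA: loadings, scores and explained variance fractions."""

    loadings: pd.DataFrame  # variables x axes
    scores: pd.DataFrame  # observations x axes
    explained_fraction: np.ndarray


def pca_traits(
    table: pd.DataFrame,
    flip: tuple[str, ...] = ("ltd", "tdr"),
    columns: tuple[str, ...] = TRAIT_COLUMNS,
) -> PCAResult:
    """PCA of the trait columns on the correlation matrix.

    Columns named in ``flip`` are multiplied by -1 before standardization
    (they load opposite to the rest of the tree-form axis, so flipping
    makes the biplot read uniformly); each column is then centered and
    scaled to unit variance (n - 1 denominator) and the correlation
    matrix eigendecomposed.  Loading signs are fixed so each axis's
    largest-magnitude loading is positive.
    """
    if len(table) < 3:
        raise ValueError("PCA requires at least 3 rows")
    data = table.loc[:, list(columns)].astype(float).copy()
    for col in flip:
        if col in data:
            data[col] = -data[col]
    std = data.std(ddof=1)
    constant = std.index[std == 0].tolist()
    if constant:
        raise ValueError(f"constant column(s) in PCA input: {constant}")
    z = (data - data.mean()) / std
    corr = np.cov(z.to_numpy(), rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        lead = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[lead, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    axes = [f"PC{j + 1}" for j in range(len(eigvals))]
    loadings = pd.DataFrame(eigvecs, index=list(columns), columns=axes)
    scores = pd.DataFrame(
        z.to_numpy() @ eigvecs, index=table.index, columns=axes
    )
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_fraction=eigvals / eigvals.sum(),
    )


def cluster_traits(
    table: pd.DataFrame,
    columns: tuple[str, ...] = TRAIT_COLUMNS,
    standardize: bool = True,
) -> pd.DataFrame:
    """Agglomerative centroid-linkage clustering of trait profiles.

    Each trait is represented by its standardized vector of plot values;
    merges use Euclidean distance between cluster centroids.  Returns the
    merge table (item indices, height, cluster size) with an ``inversion``
    flag on merges whose height drops below the previous one — centroid
    linkage permits such inversions and they are reported, not hidden.
    """
    names = list(columns)
    if len(names) != len(set(names)):
        raise ValueError("duplicate trait names")
    if len(names) < 2:
        raise ValueError("need at least 2 items to cluster")
    profiles = table.loc[:, names].astype(float).to_numpy().T  # traits x plots
    if standardize:
        mean = profiles.mean(axis=1, keepdims=True)
        sd = profiles.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant trait profile cannot be standardized")
        profiles = (profiles - mean) / sd
    merges = linkage(profiles, method="centroid")
    out = pd.DataFrame(merges, columns=["left", "right", "height", "size"])
    out["left"] = out["left"].astype(int)
    out["right"] = out["right"].astype(int)
    out["size"] = out["size"].astype(int)
    out["inversion"] = np.concatenate(
        [[False], np.diff(out["height"].to_numpy()) < -1e-12]
    )
    if out["inversion"].any():
        warnings.warn(
            "centroid linkage produced dendrogram inversions", stacklevel=2
        )
    out.attrs["labels"] = names
    return out


def env_trait_matrix(
    table: pd.DataFrame,
    env_columns: tuple[str, ...] = ENV_COLUMNS,
    trait_columns: tuple[str, ...] = TRAIT_COLUMNS,
) -> pd.DataFrame:
    """Pairwise Pearson tests between environment and trait columns.

    Returns a long-form frame (env, trait, r, p, n, stars); pivot on
    (env, trait) for the matrix layout.  Constant columns raise an error
    naming the column.
    """
    for col in list(env_columns) + list(trait_columns):
        if col not in table.columns:
            raise KeyError(f"column {col!r} missing from table")
        if np.ptp(table[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"column {col!r} is constant")
    rows = []
    for env in env_columns:
        for trait in trait_columns:
            res = pearson(table[env].to_numpy(float), table[trait].to_numpy(float))
            rows.append(
                {"env": env, "trait": trait, "r": res.r, "p": res.p,
                 "n": res.n, "stars": res.stars}
            )
    return pd.DataFrame(rows)


def plot_env_trait_matrix(matrix: pd.DataFrame, path: str | None = None):
    """Render the correlation matrix as a dot-matrix figure (size = |r|)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    envs = matrix["env"].unique()
    traits = matrix["trait"].unique()
    fig, ax = plt.subplots(figsize=(0.55 * len(traits) + 2, 0.55 * len(envs) + 1.5))
    for _, row in matrix.iterrows():
        i = np.where(envs == row["env"])[0][0]
        j = np.where(traits == row["trait"])[0][0]
        ax.scatter(
            j, i, s=400 * abs(row["r"]) + 5, c=[row["r"]],
            cmap="RdBu_r", vmin=-1, vmax=1, edgecolors="k", linewidths=0.3,
        )
        if row["stars"]:
            ax.text(j, i, row["stars"], ha="center", va="center", fontsize=7)
    ax.set_xticks(range(len(traits)), traits, rotation=90)
    ax.set_yticks(range(len(envs)), envs)
    ax.invert_yaxis()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
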