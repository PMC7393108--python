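"""End-to-end orchestration: simulate -> extract -> allometry -> stats.

Each stage reads and writes plain-text artifacts (XYZ clouds, CSV tables,
JSON fits) under an output directory and is independently skippable; a
manifest with SHA-256 content hashes records every file written, so a
rerun with the same seeds is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allometry, stats, synthetic, traits
from .io import read_cloud, write_cloud
from .synthetic import ENV_COLUMNS, TRAIT_COLUMNS

__all__ = ["PipelineConfig", "run"]

log = logging.getLogger("tlsmorph")


@dataclass
class PipelineConfig:
    """Configuration for the full pipeline (paths, stage parameters, seeds)."""

    out_dir: str = "tlsmorph_out"
    clouds_dir: str | None = None  # None: simulate clouds under out_dir
    seed: int = 0
    n_trees: int = 25
    n_plots: int = 36
    tau: tuple[float, ...] = (0.05, 0.95)
    crown_layer: float = 0.25
    ca_layer: float = 0.5
    slice_halfwidth: float = 0.05
    pca_flip: tuple[str, ...] = ("ltd", "tdr")
    stages: tuple[str, ...] = ("simulate", "extract", "allometry", "stats")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tau", "pca_flip", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if any(not 0 < t < 1 for t in self.tau):
            raise ValueError(f"tau values must lie in (0, 1), got {self.tau}")
        if self.clouds_dir is not None and not Path(self.clouds_dir).is_dir():
            raise FileNotFoundError(f"clouds directory does not exist: {self.clouds_dir}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate(cfg: PipelineConfig, out: Path, manifest: list[Path]) -> Path:
    clouds_dir = out / "clouds"
    clouds_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    truth_rows = []
    for i in range(cfg.n_trees):
        # lighter point budget than the full-density default keeps the
        # demonstration pipeline quick; traits remain recoverable
        params = synthetic.random_tree_params(
            rng, seed=cfg.seed + 1000 + i,
            leaf_point_count=3000, trunk_point_spacing=0.03,
        )
        cloud, truth = synthetic.make_tree(params)
        cloud.tree_id = f"T{i + 1:03d}"
        path = write_cloud(cloud, clouds_dir / f"{cloud.tree_id}.xyz")
        manifest.append(path)
        truth_rows.append({"tree_id": cloud.tree_id, **dataclasses.asdict(truth)})
        with open(clouds_dir / f"{cloud.tree_id}.json", "w") as fh:
            json.dump(dataclasses.asdict(params), fh, indent=1)
        manifest.append(clouds_dir / f"{cloud.tree_id}.json")
    truth_path = out / "ground_truth.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    manifest.append(truth_path)
    plot_table = synthetic.make_plot_table(cfg.n_plots, seed=cfg.seed + 77)
    plots_path = out / "plots.csv"
    plot_table.to_csv(plots_path, index=False)
    manifest.append(plots_path)
    log.info("simulate: %d clouds and a %d-plot table under %s", cfg.n_trees, cfg.n_plots, out)
    return clouds_dir


def _stage_extract(cfg: PipelineConfig, clouds_dir: Path, out: Path, manifest: list[Path]) -> Path:
    records = []
    for path in sorted(clouds_dir.glob("*.xyz")) + sorted(clouds_dir.glob("*.ply")):
        cloud = read_cloud(path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = traits.extract_traits(
                cloud, crown_layer=cfg.crown_layer, ca_layer=cfg.ca_layer
            )
        records.append(rec)
        log.debug("extract: %s height=%.2f dbh=%.3f ca=%.2f", cloud.tree_id, rec.height, rec.dbh, rec.ca)
    if not records:
        raise FileNotFoundError(f"no .xyz or .ply clouds found under {clouds_dir}")
    table = traits.traits_table(records)
    path = out / "traits.csv"
    table.to_csv(path, index=False)
    manifest.append(path)
    log.info("extract: wrote %d rows to %s", len(table), path)
    return path


def _stage_allometry(cfg: PipelineConfig, traits_path: Path, out: Path, manifest: list[Path]) -> Path:
    table = pd.read_csv(traits_path)
    x = table["height"].to_numpy(float)
    y = table["ca"].to_numpy(float)
    theory = allometry.LPJ
    fits: dict[str, dict] = {}
    for tau in cfg.tau:
        fit = allometry.fit_power_quantile(x, y, tau)
        fits[f"ca_height_q{int(round(tau * 100))}"] = {
            "a": fit.a, "b": fit.b, "tau": tau, "loss": fit.loss,
            "n": fit.n, "coverage": fit.coverage(x, y),
        }
    prop = allometry.fit_proportional(x, y)
    fits["ca_height_origin"] = {"a": prop.a, "b": 1.0, "p_value": prop.p_value, "n": prop.n}
    k_c, p_c = theory.combined
    fits["theory_ca_height"] = {"a": k_c, "b": p_c}
    fits_path = out / "fits.json"
    with open(fits_path, "w") as fh:
        json.dump(fits, fh, indent=1)
    manifest.append(fits_path)
    grid = np.linspace(max(x.min(), 0.5), x.max(), 50)
    first_fit = allometry.fit_power_quantile(x, y, cfg.tau[0])
    comp = allometry.compare_envelopes(first_fit, (k_c, p_c), grid)
    comp_path = out / "envelope_comparison.csv"
    comp.to_csv(comp_path, index=False)
    manifest.append(comp_path)
    log.info("allometry: fitted %s; wrote %s", list(fits), fits_path)
    return fits_path


def _stage_stats(cfg: PipelineConfig, plots_path: Path, out: Path, manifest: list[Path]) -> None:
    table = pd.read_csv(plots_path)
    matrix = stats.env_trait_matrix(table)
    matrix_path = out / "corr_matrix.csv"
    matrix.to_csv(matrix_path, index=False)
    manifest.append(matrix_path)
    pca = stats.pca_traits(table, flip=cfg.pca_flip)
    pca.loadings.to_csv(out / "pca_loadings.csv")
    pca.scores.to_csv(out / "pca_scores.csv", index=False)
    manifest.extend([out / "pca_loadings.csv", out / "pca_scores.csv"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        merges = stats.cluster_traits(table)
    merges.to_csv(out / "cluster_merges.csv", index=False)
    manifest.append(out / "cluster_merges.csv")
    stats.plot_env_trait_matrix(matrix, str(out / "env_trait_matrix.png"))
    manifest.append(out / "env_trait_matrix.png")
    log.info(
        "stats: PCA axes explain %s; outputs under %s",
        np.round(pca.explained_fraction[:2], 3), out,
    )


def run(config: PipelineConfig) -> dict:
    """Run the configured stages in order; returns the artifact manifest."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    log.info("pipeline config: %s", dataclasses.asdict(config))

    clouds_dir = Path(config.clouds_dir) if config.clouds_dir else out / "clouds"
    if "simulate" in config.stages and config.clouds_dir is None:
        clouds_dir = _stage_simulate(config, out, manifest)
    traits_path = out / "traits.csv"
    if "extract" in config.stages:
        traits_path = _stage_extract(config, clouds_dir, out, manifest)
    if "allometry" in config.stages:
        _stage_allometry(config, traits_path, out, manifest)
    if "stats" in config.stages:
        plots_path = out / "plots.csv"
        if not plots_path.exists():
            raise FileNotFoundError(f"plot table not found: {plots_path}")
        _stage_stats(config, plots_path, out, manifest)

    entries = {str(p.relative_to(out)): _sha256(p) for p in manifest}
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(entries, fh, indent=1, sort_keys=True)
    log.info("manifest: %d artifacts hashed into %s", len(entries), manifest_path)
    return entries
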