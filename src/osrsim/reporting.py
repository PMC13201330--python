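"""Reproducible runs: YAML configs, TSV/JSON outputs, run manifests.

Every pipeline run resolves its configuration, derives all randomness
from a single mandatory base seed, writes tidy TSV tables plus a JSON
manifest (resolved config, seed, package version, output checksums).
Re-running the same config and seed reproduces the TSV outputs byte for
byte, and the manifest alone suffices to re-run.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .evolution import (
    ClassificationConfig,
    EvolutionConfig,
    evolve,
    fisher_optimum,
    run_condition_grid,
)
from .family import FamilyStructureConfig, zietsch_like_config
from .power import PowerGridSpec, run_power_grid
from .sex_models import sigma_variants

__all__ = [
    "ConfigError",
    "write_table",
    "read_table",
    "run_from_config",
    "export_figure_tables",
]

PIPELINES = ("power-locus", "power-latent", "power-grid", "evolve", "evolve-grid")


class ConfigError(ValueError):
    """Configuration schema violation; message names the field path."""


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _require(cfg: dict, key: str, ctx: str = ""):
    if key not in cfg:
        raise ConfigError(f"missing required field {ctx + key!r}")
    return cfg[key]


def _family_from_config(cfg: dict) -> FamilyStructureConfig:
    if cfg.get("preset") == "zietsch-like":
        fam = zietsch_like_config(
            n_sibling_pairs=cfg.get("n_sibling_pairs", 539_731),
            one_offspring_per_father=cfg.get("one_offspring_per_father", False),
        )
        return fam
    return FamilyStructureConfig(
        n_sibling_pairs=_require(cfg, "n_sibling_pairs", "family."),
        offspring_count_model=cfg.get("offspring_count_model", "fixed"),
        k=cfg.get("k", 1),
        lam=cfg.get("lam"),
        count_table=cfg.get("count_table"),
        one_offspring_per_father=cfg.get("one_offspring_per_father", False),
        parent_sex_mode=cfg.get("parent_sex_mode", "fixed_male_male"),
    )


def _run_power_locus(cfg: dict, seed: int) -> pd.DataFrame:
    spec = PowerGridSpec(
        model="single_locus",
        mafs=tuple(_as_list(_require(cfg, "maf"))),
        betas=tuple(_as_list(_require(cfg, "beta"))),
        n_pairs=int(_require(cfg, "n_pairs")),
        alpha=float(cfg.get("alpha", 0.05)),
        n_replicates=int(cfg.get("n_replicates", 200)),
        base_seed=seed,
        parent_sex_mode=cfg.get("parent_sex_mode", "random"),
        p0=float(cfg.get("p0", 0.5)),
    )
    return run_power_grid(spec)


def _run_power_latent(cfg: dict, seed: int) -> pd.DataFrame:
    family = _family_from_config(cfg.get("family", {"preset": "zietsch-like"}))
    sigmas = cfg.get("sigma")
    if sigmas is None:
        base = float(cfg.get("base_sigma", 0.025))
        mult = _as_list(cfg.get("sigma_mult", 1.0))
        sigmas = [base * m for m in mult]
    spec = PowerGridSpec(
        model="latent_propensity",
        h2s=tuple(_as_list(_require(cfg, "h2"))),
        sigmas=tuple(_as_list(sigmas)),
        family=family,
        alpha=float(cfg.get("alpha", 0.05)),
        n_replicates=int(cfg.get("n_replicates", 50)),
        base_seed=seed,
        mu=float(cfg.get("mu", 0.514)),
    )
    return run_power_grid(spec)


def _as_list(value):
    if isinstance(value, (list, tuple)):
        return list(value)
    return [value]


def _evolution_config(cfg: dict, seed: int) -> EvolutionConfig:
    return EvolutionConfig(
        pop_size=int(cfg.get("pop_size", 10_000)),
        n_generations=int(cfg.get("n_generations", 2_000)),
        mutation_rate=float(cfg.get("mutation_rate", 0.0)),
        mutation_size=float(cfg.get("mutation_size", 0.0)),
        cost_son=float(cfg.get("cost_son", 1.0)),
        cost_daughter=float(cfg.get("cost_daughter", 1.0)),
        family_budget=float(cfg.get("family_budget", 4.0)),
        segregation_sd=float(cfg.get("segregation_sd", 0.0)),
        initial_propensity=float(cfg.get("initial_propensity", 0.5)),
        initial_propensity_sd=float(cfg.get("initial_propensity_sd", 0.0)),
        seed=seed,
    )


def _run_evolve(cfg: dict, seed: int) -> pd.DataFrame:
    traj = evolve(_evolution_config(cfg, seed))
    return traj.to_frame()


def _run_evolve_grid(cfg: dict, seed: int) -> pd.DataFrame:
    template = _evolution_config(cfg, seed=0)
    class_cfg = ClassificationConfig(
        h2_ci_low=float(cfg.get("h2_ci_low", -0.00147)),
        h2_ci_high=float(cfg.get("h2_ci_high", 0.00038)),
        optimum=float(
            cfg.get(
                "optimum", fisher_optimum(template.cost_son, template.cost_daughter)
            )
        ),
        white_band=float(cfg.get("white_band", 0.05)),
        window_frac=float(cfg.get("window_frac", 0.1)),
    )
    return run_condition_grid(
        _as_list(_require(cfg, "mutation_rates")),
        _as_list(_require(cfg, "mutation_sizes")),
        reps=int(cfg.get("reps", 1)),
        template=template,
        cfg=class_cfg,
        base_seed=seed,
    )


def run_from_config(
    config, outdir, overrides: dict | None = None, seed: int | None = None
) -> dict:
    """Execute the named pipeline; returns the manifest dict.

    ``config`` is a mapping or a YAML file path with at least
    ``pipeline`` and ``seed`` keys (seed may instead come from the
    ``seed`` argument / CLI flag).  Outputs: ``<pipeline>.tsv`` and
    ``manifest.json`` under ``outdir``.  Partial outputs are removed on
    failure.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    cfg.update(overrides or {})
    pipeline = _require(cfg, "pipeline")
    if pipeline not in PIPELINES:
        raise ConfigError(f"pipeline must be one of {PIPELINES}, got {pipeline!r}")
    if seed is None:
        seed = cfg.get("seed")
    if seed is None:
        raise ConfigError("missing required field 'seed' (config or CLI flag)")
    seed = int(seed)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_path = outdir / f"{pipeline}.tsv"
    manifest_path = outdir / "manifest.json"
    started = datetime.now(timezone.utc).isoformat()
    runners = {
        "power-locus": _run_power_locus,
        "power-latent": _run_power_latent,
        "power-grid": _run_power_grid_cfg,
        "evolve": _run_evolve,
        "evolve-grid": _run_evolve_grid,
    }
    try:
        frame = runners[pipeline](cfg, seed)
        write_table(frame, table_path)
    except Exception:
        table_path.unlink(missing_ok=True)
        manifest_path.unlink(missing_ok=True)
        raise
    manifest = {
        "command": pipeline,
        "config": {k: v for k, v in cfg.items() if k != "seed"},
        "base_seed": seed,
        "seed_derivation": "SeedSequence(base_seed, spawn_key=(cell, replicate))",
        "package_version": __version__,
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "outputs": {table_path.name: _sha256(table_path)},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_power_grid_cfg(cfg: dict, seed: int) -> pd.DataFrame:
    model = _require(cfg, "model")
    if model == "single_locus":
        return _run_power_locus(cfg, seed)
    if model == "latent_propensity":
        return _run_power_latent(cfg, seed)
    raise ConfigError(f"model must be single_locus or latent_propensity, got {model!r}")


# ---------------------------------------------------------------------------
# figure-style exports
# ---------------------------------------------------------------------------

FIG1_COLUMNS = ["maf", "beta", "n_pairs", "alpha", "power", "ci_low", "ci_high"]
TABLE1_COLUMNS = ["sd_label", "sigma", "h2", "power"]
FIG2_COLUMNS = [
    "mutation_rate",
    "mutation_size",
    "mean_progress",
    "mean_h2",
    "colour",
    "within_ci",
    "asterisk",
]


def export_figure_tables(results: pd.DataFrame, figure: str) -> pd.DataFrame:
    """Long-format tables with frozen column vocabularies.

    ``fig1_style``: single-locus power conditions; ``table1_style``:
    latent power grid labelled by the standard-deviation multipliers
    (-20% ... +100%) and heritability percents; ``fig2_style``:
    evolution-grid classification with colour and asterisk columns.
    """
    if figure == "fig1_style":
        _check_columns(results, ["maf", "beta", "power"], figure)
        out = results.reindex(columns=FIG1_COLUMNS)
        return out
    if figure == "table1_style":
        _check_columns(results, ["sigma", "h2", "power"], figure)
        out = results.copy()
        labels = {round(v, 10): k for k, v in sigma_variants().items()}
        out["sd_label"] = [
            labels.get(round(s, 10), f"{s:g}") for s in out["sigma"]
        ]
        out["h2"] = (out["h2"] * 100).round().astype(int).astype(str) + "%"
        return out.reindex(columns=TABLE1_COLUMNS)
    if figure == "fig2_style":
        _check_columns(results, ["mutation_rate", "mutation_size", "colour"], figure)
        return results.reindex(columns=FIG2_COLUMNS)
    raise ValueError(f"unknown figure style {figure!r}")


def _check_columns(frame: pd.DataFrame, needed, figure: str) -> None:
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"results lack columns {missing} required for {figure}")
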