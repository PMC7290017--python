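"""Reproducible simulate -> analyze -> report runs.

A run directory contains the generated data files, per-observer results,
a run-level summary, a manifest with every parameter and seed (sufficient
to reproduce bit-identical outputs), a log, and a markdown report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias import (
    Mode,
    bias_table,
    estimate_pull_weight,
    exact_chance,
    memory_consistency,
    monte_carlo_chance,
    pull_magnitude,
    pull_model_chance,
    single_item_null,
    trial_table,
)
from .datamodel import ObserverDataset, read_dataset, write_dataset
from .inference import one_sample_t
from .synthetic import GenerativeParams, generate_observers

__all__ = ["RunConfig", "load_config", "run_experiment", "analyze", "report"]

logger = logging.getLogger("ensemblepull")

_STAGE_FILES = {
    "simulate": ["ratings.csv", "trials.csv"],
    "analyze": ["summary.csv"],
}


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration of one experiment run."""

    n_observers: int = 50
    n_images: int = 190
    n_trials: int = 200
    pull_weight: float = 0.16
    noise_sd: float = 0.75
    seed: int = 0
    condition: str = "upright"
    modes: tuple[str, ...] = ("full", "restricted")
    n_sim: int = 10_000
    single_item_iterations: int = 0  # 0 disables the (slow) resampling null
    out_dir: str = "run"

    def generative_params(self) -> GenerativeParams:
        return GenerativeParams(
            n_observers=self.n_observers,
            n_images=self.n_images,
            n_trials=self.n_trials,
            pull_weight=self.pull_weight,
            response_noise_sd=self.noise_sd,
            seed=self.seed,
        )


_FIELD_TYPES = {f.name: f for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a flat ``key = value`` config file; keyword overrides win."""
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}, line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in _FIELD_TYPES:
            raise ValueError(f"{path}, line {lineno}: unknown key {key!r}")
        values[key] = _coerce(key, value)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def _coerce(key: str, value: str):
    kind = _FIELD_TYPES[key].type
    if key == "modes":
        return tuple(v.strip() for v in value.split(","))
    if "int" in str(kind):
        return int(value)
    if "float" in str(kind):
        return float(value)
    return value


def _setup_logging(out: Path) -> None:
    logger.setLevel(logging.INFO)
    have_file = any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (out / "run.log").resolve()
        for h in logger.handlers
    )
    if not have_file:
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())


def run_experiment(config: RunConfig) -> Path:
    """Simulate a full experiment, analyze it, and write the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    logger.info("run config: %s", dataclasses.asdict(config))

    try:
        params = config.generative_params()
        observers = generate_observers(params, condition=config.condition)
        write_dataset(observers, out / "ratings.csv", out / "trials.csv")
        logger.info(
            "simulate: %d observers x %d images x %d trials (seed=%d)",
            config.n_observers, config.n_images, config.n_trials, config.seed,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        summary = analyze(observers, config, out)
    except Exception as exc:
        raise RuntimeError(f"stage 'analyze' failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "seeds": {
            "generator": config.seed,
            "monte_carlo_chance": config.seed + 1,
            "single_item_null": config.seed + 2,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out / "report.md").write_text(report(out))
    logger.info("summary:\n%s", summary.to_string(index=False))
    return out


def analyze(
    observers: list[ObserverDataset], config: RunConfig, out: Path
) -> pd.DataFrame:
    """Bias, chance, magnitude and test statistics for every analysis mode.

    Writes ``bias_<mode>.csv`` per mode and a run-level ``summary.csv``;
    returns the summary frame.  The bias proportions are tested against
    two references: the uniform-random-responder Monte-Carlo chance level
    (the classical no-bias benchmark for human data) and the pull-model
    chance level matched to the generator's w = 0 null.
    """
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    skeleton_designs = [
        [(row.r1, row.m) for row in trial_table(obs).itertuples()]
        for obs in observers
    ]
    for mode in config.modes:
        table, flagged = bias_table(observers, mode)  # type: ignore[arg-type]
        table.to_csv(out / f"bias_{mode}.csv", index=False)
        if flagged:
            logger.info("%s mode: flagged observers with no included trials: %s",
                        mode, flagged)
        if table.empty:
            raise ValueError(f"no observer has included trials in {mode} mode")
        chance = monte_carlo_chance(
            skeleton_designs, mode, n_sim=config.n_sim, seed=config.seed + 1
        )
        matched = pull_model_chance(
            config.noise_sd, mode,
            skeletons=None if mode == "restricted" else [s for d in skeleton_designs for s in d],
        )
        props = table["proportion"].to_numpy()
        test_uniform = one_sample_t(props, chance.level)
        test_matched = one_sample_t(props, matched.level)
        magnitude = pull_magnitude(observers, mode)  # type: ignore[arg-type]
        row = {
            "condition": config.condition,
            "mode": mode,
            "n_observers": len(table),
            "mean_bias": props.mean(),
            "sd_bias": props.std(ddof=1),
            "chance_uniform": chance.level,
            "chance_exact": exact_chance(skeleton_designs, mode).level,
            "chance_pull_model_w0": matched.level,
            "t_vs_uniform_chance": test_uniform.statistic,
            "p_vs_uniform_chance": test_uniform.p_value,
            "t_vs_w0_chance": test_matched.statistic,
            "p_vs_w0_chance": test_matched.p_value,
            "df": test_uniform.df,
            "mean_available_diff": magnitude.mean_available_diff,
            "mean_shift": magnitude.mean_shift,
            "pct_of_max": magnitude.pct_of_max,
            "pull_weight_hat": estimate_pull_weight(observers, mode),  # type: ignore[arg-type]
            "memory_consistency": memory_consistency(observers),
        }
        if config.single_item_iterations > 0:
            nulls = [
                single_item_null(
                    obs, config.single_item_iterations,
                    np.random.SeedSequence(config.seed + 2, spawn_key=(i,)),
                    mode=mode,  # type: ignore[arg-type]
                ).mean_proportion
                for i, obs in enumerate(observers)
            ]
            row["single_item_mean"] = float(np.mean(nulls))
        rows.append(row)
        logger.info(
            "%s mode: M_bias=%.3f vs uniform chance %.3f (t=%.2f) "
            "vs w0 chance %.3f (t=%.2f)",
            mode, row["mean_bias"], chance.level,
            row["t_vs_uniform_chance"], matched.level, row["t_vs_w0_chance"],
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.csv", index=False)
    return summary


def report(run_dir: str | Path) -> str:
    """Render a completed run directory as a markdown summary."""
    run_dir = Path(run_dir)
    for stage, files in _STAGE_FILES.items():
        for name in files:
            if not (run_dir / name).exists():
                raise FileNotFoundError(
                    f"stage '{stage}' output missing: {run_dir / name}"
                )
    summary = pd.read_csv(run_dir / "summary.csv")
    lines = ["# Ensemble-pull bias report", ""]
    for row in summary.itertuples():
        lines += [
            f"## Condition: {row.condition} — {row.mode} analysis",
            "",
            f"- observers analyzed: {row.n_observers}",
            f"- mean bias proportion: {row.mean_bias:.3f} (SD {row.sd_bias:.3f})",
            f"- chance level, uniform random responder: {row.chance_uniform:.3f}"
            f" (exact {row.chance_exact:.3f})",
            f"- chance level, matched no-pull responder: {row.chance_pull_model_w0:.3f}",
            f"- t vs uniform chance: t({row.df:.0f}) = {row.t_vs_uniform_chance:.2f},"
            f" p = {row.p_vs_uniform_chance:.3g}",
            f"- t vs no-pull chance: t({row.df:.0f}) = {row.t_vs_w0_chance:.2f},"
            f" p = {row.p_vs_w0_chance:.3g}",
            f"- pull magnitude: shift {row.mean_shift:.3f} of available"
            f" {row.mean_available_diff:.3f} -> {row.pct_of_max:.1f}% of maximum",
            f"- recovered pull weight: {row.pull_weight_hat:.3f}",
            f"- memory consistency (mean |r2 - r1|): {row.memory_consistency:.3f}",
        ]
        if hasattr(row, "single_item_mean") and not pd.isna(
            getattr(row, "single_item_mean", float("nan"))
        ):
            lines.append(
                f"- single-item sampling null: {row.single_item_mean:.3f}"
            )
        lines.append("")
    return "\n".join(lines)


def analyze_files(
    ratings_path: str | Path, trials_path: str | Path, config: RunConfig, out: Path
) -> pd.DataFrame:
    """Run the analysis stage on data files already on disk."""
    observers = read_dataset(ratings_path, trials_path)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    return analyze(observers, config, out)
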