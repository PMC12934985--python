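"""File formats, run configuration and the end-to-end pipeline.

Formats: long CSV for data, chains and trajectories; JSON for topologies,
ground truths, scores and run manifests; YAML or JSON for run configs.
Every file written here is re-readable by the package's own readers, and a
run manifest records enough (package version, config hash, seed) to
reproduce a run bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import COLUMNS, LayerTimeSeries
from .inference import (
    ParameterSpace,
    PriorBounds,
    default_bounds,
    fit_model,
)
from .models import SolverConfig, Trajectory, predict_observables
from .synthetic import GroundTruth

logger = logging.getLogger("microdev")

__all__ = [
    "RunConfig",
    "load_timeseries",
    "save_timeseries",
    "trajectory_to_frame",
    "save_trajectory",
    "chains_to_csv",
    "run_pipeline",
    "PipelineError",
]

MODEL_KINDS = ("logistic", "linear", "two_pop")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def load_timeseries(path: str | Path) -> LayerTimeSeries:
    """Read a long-format data CSV, validating schema and invariants."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.index[df["value"].isna()]
    if len(bad):
        raise ValueError(f"{path}: missing values at CSV lines {[i + 2 for i in bad[:5]]}")
    neg = df.index[df["value"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative values at CSV lines {[i + 2 for i in neg[:5]]}")
    region = str(df["region"].iloc[0]) if len(df) else "unknown"
    return LayerTimeSeries(region, df)


def save_timeseries(data: LayerTimeSeries, path: str | Path) -> None:
    data.to_csv(path)


def trajectory_to_frame(traj: Trajectory, tau_k: float = 0.25) -> pd.DataFrame:
    """Flatten a trajectory to (layer, age_days, A, B, density, volume, pct_ki67)."""
    obs = predict_observables(traj, tau_k=tau_k)
    rows = []
    for li, layer in enumerate(traj.topo.layers):
        for ti, t in enumerate(traj.times):
            rows.append(
                {
                    "layer": layer,
                    "age_days": t,
                    "A": traj.A[li, ti] if traj.A is not None else np.nan,
                    "B": traj.B[li, ti] if traj.B is not None else np.nan,
                    "density": traj.M[li, ti],
                    "volume": traj.V[li, ti],
                    "pct_ki67": obs.pct_ki67[li, ti],
                }
            )
    return pd.DataFrame(rows)


def save_trajectory(traj: Trajectory, path: str | Path, tau_k: float = 0.25) -> None:
    trajectory_to_frame(traj, tau_k).to_csv(path, index=False)


def chains_to_csv(chains, outdir: str | Path) -> list[Path]:
    """One CSV per chain (iteration, log_posterior, loglik, parameters)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in range(chains.n_chains):
        df = pd.DataFrame(chains.draws[c], columns=list(chains.param_names))
        df.insert(0, "iteration", np.arange(chains.draws.shape[1]))
        df["log_posterior"] = chains.log_posterior[c]
        df["loglik"] = chains.loglik[c]
        p = outdir / f"chain_{c}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one calibration run.

    ``truth_path`` points at a ground-truth JSON (model kind, parameters and
    topology); ``free_names`` selects the sampled coordinates; bounds not
    listed in ``prior_bounds`` fall back to the shipped defaults.
    """

    model_kind: str
    data_path: str
    truth_path: str
    seed: int
    output_dir: str
    free_names: tuple[str, ...] = ()
    prior_bounds: dict = field(default_factory=dict)
    n_chains: int = 3
    n_iter: int = 2000
    burn_in_frac: float = 0.5
    solver_method: str = "RK4"
    switch_layer: str | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(
                f"unknown model kind {self.model_kind!r}; expected one of {MODEL_KINDS}"
            )
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.free_names = tuple(self.free_names)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = (
            yaml.safe_load(path.read_text())
            if path.suffix in (".yaml", ".yml")
            else json.loads(path.read_text())
        )
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Load data, calibrate, score, derive milestones, write everything.

    Returns the result bundle: fit result, scores, switch-time posterior and
    the manifest. Deterministic for a fixed config (the config seed drives
    every random draw). Partial outputs are kept on stage failure.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    try:

        stage = "load"
        try:
            data = load_timeseries(config.data_path)
            truth = GroundTruth.from_json(config.truth_path)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        stage = "setup"
        try:
            free = config.free_names or _default_free_names(config.model_kind, truth)
            space = ParameterSpace(
                config.model_kind, truth.topo, truth.params, free,
                base_tau_k=truth.tau_k, base_sigmas=truth.sigmas,
            )
            bounds_map = dict(default_bounds(space, data).bounds)
            bounds_map.update(
                {k: tuple(v) for k, v in config.prior_bounds.items() if k in free}
            )
            bounds = PriorBounds(bounds_map)
            solver_cfg = SolverConfig(method=config.solver_method)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        stage = "fit"
        try:
            logger.info("fitting %s with %d free parameters", config.model_kind, len(free))
            fit = fit_model(
                data, space, bounds,
                n_chains=config.n_chains, n_iter=config.n_iter, seed=config.seed,
                burn_in_frac=config.burn_in_frac, solver_cfg=solver_cfg,
            )
            chains_to_csv(fit.chains, outdir / "chains")
            fit.summary.to_csv(outdir / "posterior_summary.csv")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        stage = "milestones"
        try:
            milestones = {}
            if config.model_kind == "two_pop":
                layers = [config.switch_layer] if config.switch_layer else list(truth.topo.layers)
                grid = np.linspace(data.ages()[0], data.ages()[-1], 105)
                for layer in layers:
                    mean, sd = fit.switch_time_posterior(
                        layer, grid, n_draws=60, solver_cfg=solver_cfg
                    )
                    milestones[layer] = {"switch_mean_days": mean, "switch_sd_days": sd}
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        stage = "write"
        try:
            score = dataclasses.asdict(fit.score)
            (outdir / "scores.json").write_text(json.dumps(score, indent=2))
            manifest = {
                "package_version": __version__,
                "config": config.to_dict(),
                "config_hash": config.digest(),
                "seed": config.seed,
                "iterations": config.n_iter,
                "prior_bounds": {k: list(v) for k, v in bounds.bounds.items()},
                "acceptance_rates": fit.chains.acceptance_rate.tolist(),
                "max_rhat": float(fit.summary["rhat"].max()),
                "criteria": {k: score[k] for k in ("aic", "bic", "waic")},
                "switch_times": milestones,
            }
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        return {"fit": fit, "score": score, "switch_times": milestones, "manifest": manifest}
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _default_free_names(model_kind: str, truth: GroundTruth) -> tuple[str, ...]:
    """A modest default sampling set: kinetic rates plus the two cell-level
    noise scales; volumes and initial densities stay at their configured
    values."""
    if model_kind == "logistic":
        names = ("r", "kappa", "c")
    elif model_kind == "linear":
        names = ("p", "c", "lam") + tuple(f"s0.{l}" for l in truth.topo.layers)
    else:
        names = ("a1_int_A", "a1_int_B", "a2_ext_AB", "c_A", "c_B")
    return names + ("sigma_density", "sigma_pct_ki67")
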