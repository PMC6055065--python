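"""Run configuration: loading, validation, and seeded orchestration.

A run is fully determined by its configuration and seed. ``load_config``
resolves a YAML/JSON file (or plain dict) against the published defaults and
rejects out-of-range values with messages naming the offending field;
``run`` executes a command (train / test / batch / inspect-weights) and
writes CSV/JSON artifacts plus a manifest (config hash, seed, version) that
suffices to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .network import HyperParams
from .tasks import SequencePredictionTask, TwelveAXTask
from . import experiments as ex

__all__ = ["RunConfig", "ConfigError", "load_config", "build_task",
           "default_criterion", "run"]


class ConfigError(ValueError):
    """A configuration value is missing, malformed or out of range."""


_TASKS = ("12ax", "seqpred")
_VARIANTS = ("standard", "leaky", "hybrid", "custom")


@dataclass
class RunConfig:
    """Fully resolved run configuration (defaults reproduce the published
    hyperparameter and architecture tables when nothing is overridden)."""

    task: str = "12ax"
    task_params: dict = field(default_factory=dict)
    variant: str = "hybrid"
    phi: Optional[list] = None          # required for variant='custom'
    phi_leak: float = 0.7
    hyperparams: HyperParams = field(default_factory=HyperParams)
    arch_overrides: dict = field(default_factory=dict)
    seed: int = 0
    max_trials: Optional[int] = None    # None -> task default budget
    n_consecutive: Optional[int] = None
    n_sims: int = 1
    n_test: int = 1000
    test_policy: str = "greedy"
    out_dir: str = "runs"
    init_scale: float = 0.25

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        hp = d.pop("hyperparams", {})
        if isinstance(hp, dict):
            try:
                hp = HyperParams(**hp)
            except (TypeError, ValueError) as err:
                raise ConfigError(f"hyperparams: {err}") from err
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(hyperparams=hp, **d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.task not in _TASKS:
            raise ConfigError(f"task must be one of {_TASKS}, "
                              f"got {self.task!r}")
        if self.variant not in _VARIANTS:
            raise ConfigError(f"variant must be one of {_VARIANTS}, "
                              f"got {self.variant!r}")
        if self.variant == "custom":
            if self.phi is None:
                raise ConfigError(
                    "phi: custom variant requires an explicit phi vector")
        if self.phi is not None:
            phi = np.asarray(self.phi, dtype=float)
            if np.any(phi < 0.0) or np.any(phi > 1.0):
                raise ConfigError("phi: all leak coefficients must be "
                                  "in [0, 1]")
        if not 0.0 <= self.phi_leak <= 1.0:
            raise ConfigError(f"phi_leak must be in [0, 1], "
                              f"got {self.phi_leak}")
        for name in ("n_sims", "n_test"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("max_trials", "n_consecutive"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name, v in self.arch_overrides.items():
            if name not in ("n_regular", "n_memory", "n_actions",
                            "n_sensory"):
                raise ConfigError(f"arch_overrides: unknown field {name!r}")
            if v < 1:
                raise ConfigError(f"arch_overrides.{name} must be >= 1")
        if self.test_policy not in ("greedy", "eps_greedy"):
            raise ConfigError("test_policy must be 'greedy' or 'eps_greedy'")


def load_config(source) -> RunConfig:
    """Resolve a config from a dict, a YAML/JSON path, or None (defaults)."""
    if source is None:
        return RunConfig.from_dict({})
    if isinstance(source, RunConfig):
        source.validate()
        return source
    if isinstance(source, dict):
        return RunConfig.from_dict(source)
    path = Path(source)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"could not parse {path}: {err}") from err
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must contain a mapping")
    return RunConfig.from_dict(data)


def build_task(cfg: RunConfig):
    if cfg.task == "12ax":
        return TwelveAXTask(**cfg.task_params)
    return SequencePredictionTask(**cfg.task_params)


def default_criterion(cfg: RunConfig) -> ex.ConvergenceCriterion:
    base = (ex.TWELVEAX_CRITERION if cfg.task == "12ax"
            else ex.SEQPRED_CRITERION)
    return ex.ConvergenceCriterion(
        cfg.n_consecutive or base.n_consecutive,
        cfg.max_trials or base.max_trials,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _manifest(cfg: RunConfig, command: str) -> dict:
    blob = json.dumps(cfg.to_dict(), sort_keys=True)
    return {
        "command": command,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": cfg.seed,
        "version": __version__,
    }


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _export_weights(net, task, out: Path) -> None:
    w = net.weights
    np.savez(out / "weights.npz", **{
        "V_R": w.V_R, "V_M": w.V_M, "W_R": w.W_R, "W_M": w.W_M,
        "Wp_R": w.Wp_R, "Wp_M": w.Wp_M, "phi": net.arch.phi,
    })
    vm, wm = ex.export_memory_weights(net, task)
    vm.to_csv(out / "memory_weights_VM.csv")
    wm.to_csv(out / "memory_weights_WM.csv")


def run(cfg: RunConfig, command: str = "train",
        weights_npz: Optional[str] = None) -> dict:
    """Execute a command and write its artifacts under ``cfg.out_dir``.

    Returns the summary dict that was written to disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(out / "manifest.json", _manifest(cfg, command))
    task = build_task(cfg)
    criterion = default_criterion(cfg)

    if command == "train":
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        net = ex.make_network(task, cfg.variant, rng, hp=cfg.hyperparams,
                              phi=cfg.phi, phi_leak=cfg.phi_leak,
                              **cfg.arch_overrides)
        stats = ex.train_until_convergence(net, task, criterion, rng,
                                           record=True)
        curves = ex.td_loss_curves(stats.deltas, stats.stimuli)
        for name, df in curves.items():
            df.to_csv(out / f"td_loss_{name}.csv", index=False)
        _export_weights(net, task, out)
        summary = {
            "converged": stats.converged,
            "trials_to_criterion": stats.trials_to_criterion,
            "n_trials": stats.n_trials,
            "n_predictions": int(stats.deltas.shape[0]),
        }
    elif command == "test":
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        net = ex.make_network(task, cfg.variant, rng, hp=cfg.hyperparams,
                              phi=cfg.phi, phi_leak=cfg.phi_leak,
                              **cfg.arch_overrides)
        stats = ex.train_until_convergence(net, task, criterion, rng)
        test_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 1]))
        if cfg.task == "12ax":
            score = ex.twelveax_test(net, task, n_trials=cfg.n_test,
                                     policy=cfg.test_policy, rng=test_rng)
            metric = "trial_success_fraction"
        else:
            score = ex.seqpred_generalization_test(net, task,
                                                   n_test=cfg.n_test,
                                                   rng=test_rng)
            metric = "final_prediction_accuracy"
        _export_weights(net, task, out)
        summary = {
            "converged": stats.converged,
            "trials_to_criterion": stats.trials_to_criterion,
            "policy": cfg.test_policy,
            "n_test": cfg.n_test,
            metric: score,
        }
    elif command == "batch":
        result = ex.run_batch(cfg.variant, task, cfg.n_sims, criterion,
                              cfg.seed, hp=cfg.hyperparams, phi=cfg.phi,
                              phi_leak=cfg.phi_leak, **cfg.arch_overrides)
        rows = pd.DataFrame({
            "sim": np.arange(cfg.n_sims),
            "converged": [t is not None for t in result.trials_to_criterion],
            "trials_to_criterion": result.trials_to_criterion,
        })
        rows.to_csv(out / "batch_runs.csv", index=False)
        summary = {
            "n_sims": result.n_sims,
            "success_fraction": result.success_fraction,
            "learning_time_mean": result.time_mean,
            "learning_time_sd": result.time_sd,
        }
    elif command == "inspect-weights":
        if weights_npz is None:
            raise ConfigError("inspect-weights requires a weights .npz path")
        data = np.load(weights_npz)
        from .network import Architecture, Network, NetworkWeights
        arch = Architecture(
            n_sensory=data["V_R"].shape[1],
            n_regular=data["V_R"].shape[0],
            n_memory=data["V_M"].shape[0],
            n_actions=data["W_R"].shape[0],
            phi=data["phi"],
        )
        w = NetworkWeights(data["V_R"], data["V_M"], data["W_R"],
                           data["W_M"], data["Wp_R"], data["Wp_M"])
        net = Network(arch, hp=cfg.hyperparams, weights=w)
        vm, wm = ex.export_memory_weights(net, task)
        vm.to_csv(out / "memory_weights_VM.csv")
        wm.to_csv(out / "memory_weights_WM.csv")
        summary = {"n_memory": arch.n_memory,
                   "max_abs_VM": float(np.abs(w.V_M).max())}
    else:
        raise ConfigError(f"unknown command {command!r}")

    _write_json(out / "summary.json", summary)
    return summary
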