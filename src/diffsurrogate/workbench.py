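"""Experiment orchestration: YAML configs, presets, seeds and the
generate -> train -> evaluate pipeline with reproducibility manifests.

A single experiment seed is expanded through ``numpy.random.SeedSequence``
into named substreams (sampling, weight init, training), so each stage can
be reproduced independently. Datasets are cached by a content hash of the
grid + sampling section of the config: re-running an experiment with an
unchanged data section reuses the dataset on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data import load_dataset, save_dataset
from .loss import LossConfig
from .metrics import evaluate_model
from .model import PRESETS, SurrogateModel, SurrogateSpec
from .solver import DatasetSplit, GridSpec, generate_dataset
from .train import TrainConfig, TrainState, train

__all__ = ["ExperimentConfig", "load_config", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    radius: float = 5.0
    n_disks: int = 2
    n_samples: int = 20_000
    split_fraction: float = 0.8
    surrogate: SurrogateSpec = field(default_factory=SurrogateSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    relative_floor: float = 1e-3
    n_slices: int = 10
    pdf_bins: int = 100
    eval_batch_size: int = 32
    seed: int = 0
    dataset_path: str | None = None

    def data_hash(self) -> str:
        """Content hash of everything that determines the dataset."""
        payload = {
            "grid": dataclasses.asdict(self.grid),
            "radius": self.radius,
            "n_disks": self.n_disks,
            "n_samples": self.n_samples,
            "split_fraction": self.split_fraction,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    def config_hash(self) -> str:
        blob = json.dumps(_config_to_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTIONS = {"grid", "sampling", "surrogate", "loss", "training", "evaluation", "paths", "seed"}


def _take(d: dict, allowed: dict, section: str) -> dict:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section {section!r}")
    return {k: type_(d[k]) for k, type_ in allowed.items() if k in d}


def load_config(path: str | Path | None = None, text: str | None = None) -> ExperimentConfig:
    """Load and validate a YAML experiment file; unknown keys are rejected.

    An empty file yields the reference defaults (100x100 grid, D=1,
    gamma=1/400, radius-5 disks). A ``surrogate.preset`` name (model1 ..
    model14) binds mixing weights, dropout rates, loss kind and w together;
    explicit keys may override everything but the preset's loss binding.
    """
    if text is None:
        text = Path(path).read_text() if path is not None else ""
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")

    grid = GridSpec(**_take(raw.get("grid", {}), {"L": int, "D": float, "gamma": float}, "grid"))
    sampling = _take(
        raw.get("sampling", {}),
        {"radius": float, "n_disks": int, "n_samples": int, "split_fraction": float},
        "sampling",
    )

    sur_raw = dict(raw.get("surrogate", {}))
    preset_name = sur_raw.pop("preset", None)
    loss_raw = dict(raw.get("loss", {}))
    preset = {}
    if preset_name is not None:
        if preset_name not in PRESETS:
            raise ValueError(f"unknown preset {preset_name!r}")
        preset = dict(PRESETS[preset_name])
        loss_raw.setdefault("kind", preset["loss"])
        loss_raw.setdefault("w", preset["w"])
    sur_kw = _take(
        sur_raw,
        {
            "grid_size": int,
            "p1": float,
            "p2": float,
            "dropout": tuple,
            "nn2_base_channels": int,
            "leaky_slope": float,
        },
        "surrogate",
    )
    if preset:
        sur_kw.setdefault("p1", float(preset["p1"]))
        sur_kw.setdefault("p2", float(preset["p2"]))
        sur_kw.setdefault("dropout", tuple(preset["dropout"]))
    sur_kw.setdefault("grid_size", grid.L)
    surrogate = SurrogateSpec(**sur_kw)
    if surrogate.grid_size != grid.L:
        raise ValueError(
            f"surrogate grid_size {surrogate.grid_size} != lattice size {grid.L}"
        )

    loss_kw = _take(loss_raw, {"kind": str, "alpha": int, "w": float}, "loss")
    if "kind" in loss_kw:
        loss_cfg = LossConfig.from_name(loss_kw["kind"], loss_kw.get("w", LossConfig().w))
        if "alpha" in loss_kw and loss_kw["alpha"] != loss_cfg.alpha:
            raise ValueError("loss.kind and loss.alpha disagree")
    else:
        loss_cfg = LossConfig(**loss_kw)

    seed = int(raw.get("seed", 0))
    tr_kw = _take(
        raw.get("training", {}),
        {
            "epochs": int,
            "lr": float,
            "batch_size": int,
            "rollback_C": float,
            "rollback_m": int,
            "rollback_s": int,
            "max_rollbacks": int,
        },
        "training",
    )
    ev_kw = _take(
        raw.get("evaluation", {}),
        {"relative_floor": float, "n_slices": int, "pdf_bins": int, "batch_size": int},
        "evaluation",
    )
    paths = _take(raw.get("paths", {}), {"dataset": str}, "paths")

    seeds = _stage_seeds(seed)
    training = TrainConfig(loss=loss_cfg, seed=seeds["training"], **tr_kw)
    return ExperimentConfig(
        grid=grid,
        surrogate=surrogate,
        loss=loss_cfg,
        training=training,
        seed=seed,
        relative_floor=ev_kw.get("relative_floor", 1e-3),
        n_slices=ev_kw.get("n_slices", 10),
        pdf_bins=ev_kw.get("pdf_bins", 100),
        eval_batch_size=ev_kw.get("batch_size", 32),
        dataset_path=paths.get("dataset"),
        **sampling,
    )


def _stage_seeds(seed: int) -> dict[str, int]:
    """Named per-stage substreams derived from the experiment seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("sampling", "init", "training")
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF
        for name, child in zip(names, children)
    }


def _config_to_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["surrogate"]["dropout"] = list(cfg.surrogate.dropout)
    d["surrogate"]["nn1_channels"] = list(cfg.surrogate.nn1_channels)
    return d


def run_experiment(
    cfg: ExperimentConfig, workdir: str | Path, progress: bool = False
) -> dict:
    """Execute generate -> train -> evaluate, writing all artifacts to workdir.

    Artifacts: ``data-<hash>.h5`` (reused if already present), ``model.npz``
    + YAML sidecar, ``training_log.csv`` (epoch, loss, rolled_back,
    rollback_count), ``report.json`` and ``manifest.json``. Returns the
    manifest as a dict.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {
        "config": _config_to_dict(cfg),
        "config_hash": cfg.config_hash(),
        "data_hash": cfg.data_hash(),
        "stage_seeds": seeds,
        "stages": {},
    }

    # -- stage 1: dataset (cached by content hash) --------------------------
    data_path = (
        Path(cfg.dataset_path)
        if cfg.dataset_path
        else workdir / f"data-{cfg.data_hash()}.h5"
    )
    if data_path.exists():
        ds = load_dataset(data_path)
        manifest["stages"]["generate"] = {"reused": True, "path": str(data_path)}
    else:
        try:
            ds = generate_dataset(
                cfg.n_samples,
                seeds["sampling"],
                grid=cfg.grid,
                radius=cfg.radius,
                n_disks=cfg.n_disks,
                split_fraction=cfg.split_fraction,
                progress=progress,
            )
        except Exception as exc:
            raise RuntimeError("stage 'generate' failed") from exc
        save_dataset(data_path, ds)
        manifest["stages"]["generate"] = {"reused": False, "path": str(data_path)}

    # -- stage 2: training ---------------------------------------------------
    try:
        model = SurrogateModel(cfg.surrogate, rng=seeds["init"])
        xtr, ytr = ds.train
        state = train(model, xtr, ytr, cfg.training, progress=progress)
    except Exception as exc:
        raise RuntimeError("stage 'train' failed") from exc
    ckpt = workdir / "model.npz"
    model.save(
        ckpt,
        provenance={
            "seed": cfg.seed,
            "stage_seeds": seeds,
            "epochs": cfg.training.epochs,
            "loss": {"alpha": cfg.loss.alpha, "w": cfg.loss.w},
            "config_hash": cfg.config_hash(),
        },
    )
    log_path = workdir / "training_log.csv"
    _write_log(log_path, state)
    manifest["stages"]["train"] = {
        "checkpoint": str(ckpt),
        "log": str(log_path),
        "best_epoch": state.best_epoch,
        "best_loss": state.best_loss,
        "rollback_count": state.rollback_count,
    }

    # -- stage 3: evaluation -------------------------------------------------
    try:
        xte, yte = ds.test
        report = evaluate_model(
            model,
            xte,
            yte,
            batch_size=cfg.eval_batch_size,
            relative_floor=cfg.relative_floor,
            n_slices=cfg.n_slices,
            pdf_bins=cfg.pdf_bins,
        )
    except Exception as exc:
        raise RuntimeError("stage 'evaluate' failed") from exc
    report_path = workdir / "report.json"
    report.save(report_path)
    manifest["stages"]["evaluate"] = {
        "report": str(report_path),
        "mean_residual": report.mean_residual,
        "p99_residual": report.p99_residual,
        "max_residual": report.max_residual,
    }

    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _write_log(path: Path, state: TrainState) -> None:
    lines = ["epoch,loss,rolled_back,rollback_count"]
    lines += [
        f"{row.epoch},{row.loss:.10e},{int(row.rolled_back)},{row.rollback_count}"
        for row in state.log
    ]
    path.write_text("\n".join(lines) + "\n")
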