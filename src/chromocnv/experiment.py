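"""Declarative experiment runner: one flat config file -> one output dir.

Configs are plain ``key = value`` text (``#`` comments allowed).  Every key
is validated against the schema below before any compute starts; unknown
keys are rejected.  Runs are deterministic under the config's seed, and
every artifact is stamped with the config hash and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .gcn import TrainConfig
from .hic_io import write_contact_matrix, write_labels
from .linear import SplitSpec, fit_linear_model
from .perturb import KINDS, apply_perturbation
from .pipeline import run_gcn_pipeline
from .synthetic import simulate_chromosome

log = logging.getLogger("chromocnv")

# key -> (parser, default)
_SCHEMA: dict[str, tuple] = {
    "task": (str, "gcn"),  # gcn | linear | perturbation_suite
    "n_bins": (int, 1000),
    "n_segments": (int, 12),
    "copy_pool": (lambda s: tuple(int(x) for x in str(s).split(",")), (1, 3, 4)),
    "min_len": (int, 25),
    "max_len": (int, 50),
    "noise": (str, "poisson"),
    "decay_exponent": (float, 1.0),
    "base_depth": (float, 100.0),
    "diagonal_boost": (float, 5.0),
    "bin_size": (int, 40_000),
    "train_fraction": (float, 0.6),
    "embed_dim": (int, 64),
    "walk_length": (int, 100),
    "num_walks": (int, 10),
    "window": (int, 10),
    "p": (float, 1.0),
    "q": (float, 1.0),
    "embed_epochs": (int, 3),
    "hidden_dim": (int, 64),
    "dropout": (float, 0.5),
    "epochs": (int, 200),
    "lr": (float, 0.01),
    "perturbation": (str, "none"),
    "seed": (int, 0),
}

_TASKS = ("gcn", "linear", "perturbation_suite")


@dataclass
class ExperimentConfig:
    """Validated flat key-value experiment description."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        parsed = {}
        for key, (parse, default) in _SCHEMA.items():
            raw = self.values.get(key, default)
            parsed[key] = parse(raw) if isinstance(raw, str) else raw
        if parsed["task"] not in _TASKS:
            raise ValueError(f"task must be one of {_TASKS}")
        if parsed["perturbation"] not in ("none",) + KINDS:
            raise ValueError(f"perturbation must be 'none' or one of {KINDS}")
        self.values = parsed

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        values: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in values:
                raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
            values[key] = value
        return cls(values=values)

    def canonical_text(self) -> str:
        lines = []
        for key in sorted(self.values):
            v = self.values[key]
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{key} = {v}")
        return "\n".join(lines) + "\n"

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_text().encode()).hexdigest()[:16]


def _simulate(config: ExperimentConfig, seed_offset: int = 0):
    return simulate_chromosome(
        n_bins=config["n_bins"],
        n_segments=config["n_segments"],
        copy_number_pool=config["copy_pool"],
        min_len=config["min_len"],
        max_len=config["max_len"],
        noise_model=config["noise"],
        decay_exponent=config["decay_exponent"],
        base_depth=config["base_depth"],
        diagonal_boost=config["diagonal_boost"],
        bin_size=config["bin_size"],
        seed=config["seed"] + seed_offset,
    )


def _stamp(config: ExperimentConfig, extra: dict) -> dict:
    return {"config_hash": config.hash(), "version": __version__, **extra}


def _run_one_gcn(config, matrix, labels, out_dir: Path, tag: str, embeddings=None):
    seed = config["seed"]
    result = run_gcn_pipeline(
        matrix,
        labels,
        d=config["embed_dim"],
        walk_length=config["walk_length"],
        num_walks=config["num_walks"],
        window=config["window"],
        p=config["p"],
        q=config["q"],
        embed_epochs=config["embed_epochs"],
        train_config=TrainConfig(
            split=SplitSpec(config["train_fraction"], seed),
            epochs=config["epochs"],
            lr=config["lr"],
            seed=seed,
            hidden_dim=config["hidden_dim"],
            dropout_rate=config["dropout"],
        ),
        embeddings=embeddings,
        seed=seed,
    )
    (out_dir / f"metrics_{tag}.json").write_text(
        json.dumps(_stamp(config, result.report.to_dict()), indent=1)
    )
    np.savetxt(out_dir / f"loss_{tag}.txt", np.asarray(result.losses), fmt="%.8g")
    result.params.save(out_dir / f"model_{tag}.npz")
    log.info("stage %s: accuracy %.4f", tag, result.report.accuracy)
    return result


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Execute a config end to end; returns the output directory.

    Artifacts: simulated matrix and labels, per-stage metrics JSON (stamped
    with config hash and version), loss curves, trained models, and — for
    the perturbation suite — one perturbation report per operator.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("experiment %s -> %s", config.hash(), out_dir)
    (out_dir / "config.txt").write_text(config.canonical_text())

    try:
        sim = _simulate(config)
        write_contact_matrix(out_dir / "matrix.tsv", sim.matrix)
        write_labels(out_dir / "labels.bed", sim.labels, sim.copy_numbers,
                     chrom=sim.matrix.chrom, bin_size=sim.matrix.bin_size)
        task = config["task"]
        if task == "linear":
            params, report = fit_linear_model(
                sim.matrix, sim.labels,
                SplitSpec(config["train_fraction"], config["seed"]),
            )
            params.save(out_dir / "model_linear.json")
            (out_dir / "metrics_linear.json").write_text(
                json.dumps(_stamp(config, report.to_dict()), indent=1)
            )
            log.info("linear accuracy %.4f", report.accuracy)
        elif task == "gcn":
            matrix, labels = sim.matrix, sim.labels
            if config["perturbation"] != "none":
                matrix, labels, report = apply_perturbation(
                    config["perturbation"], matrix, labels, seed=config["seed"]
                )
                (out_dir / f"perturbation_{config['perturbation']}.json").write_text(
                    json.dumps(report.__dict__, indent=1)
                )
            _run_one_gcn(config, matrix, labels, out_dir, tag="gcn")
        else:  # perturbation_suite
            baseline = _run_one_gcn(config, sim.matrix, sim.labels, out_dir, tag="baseline")
            for kind in KINDS:
                matrix, labels, report = apply_perturbation(
                    kind, sim.matrix, sim.labels, seed=config["seed"]
                )
                (out_dir / f"perturbation_{kind}.json").write_text(
                    json.dumps(report.__dict__, indent=1)
                )
                emb = baseline.embeddings if kind in ("label_reconstruction", "label_shuffle") else None
                _run_one_gcn(config, matrix, labels, out_dir, tag=kind, embeddings=emb)
    except Exception as exc:  # re-raise with experiment context
        raise RuntimeError(
            f"experiment {config.hash()} failed (task={config['task']}): {exc}"
        ) from exc
    return out_dir
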