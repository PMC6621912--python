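"""Experiment orchestration: staged pipeline with on-disk artifacts.

Each stage reads the artifacts of the previous one from the run
directory and writes its own, plus a run manifest (config hash, seed,
metrics) so every artifact traces back to a configuration.  Stages:

    synth         -> data/ (CSV sequences + manifest)
    train-wta     -> topology.h5 (STDP-trained encoders)
    simulate      -> snapshots.h5 (final trace states of every sequence)
    train-readout -> readout.h5 + loss curve
    evaluate      -> metrics.json (accuracy, confusion matrix)
    resources     -> resources.json (cost-model report)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as dio
from .attention_readout import predict, train_readout
from .config import ExperimentConfig, config_hash
from .network import DeepLSM, derive_seed
from .resource_model import full_report, sec41_spec
from .synthetic_data import generate_sequences, write_dataset

__all__ = ["run_experiment", "DependencyError", "COMMANDS"]

COMMANDS = ("synth", "train-wta", "simulate", "train-readout", "evaluate",
            "resources")


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing artifact {path.name}; run the {producer!r} stage first"
        )
    return path


def _load_dataset(run_dir: Path, split: str):
    manifest = _require(run_dir / "data" / f"{split}_manifest.csv", "synth")
    seqs, labels = [], []
    for line in manifest.read_text().splitlines()[1:]:
        name, label, _ = line.split(",")
        seqs.append(np.loadtxt(run_dir / "data" / name, delimiter=","))
        labels.append(int(label))
    return seqs, np.array(labels)


def _build_network(config: ExperimentConfig, run_dir: Path,
                   train_seqs) -> DeepLSM:
    net = DeepLSM(config.network)
    net.encoder.fit(train_seqs)
    topo = run_dir / "topology.h5"
    if topo.exists():
        saved = dio.load_topology(topo)
        for wta, data in zip(net.wtas, saved["wtas"]):
            wta.weights = data["weights"]
            wta.intrinsic.theta = data["theta"]
    return net


def _write_manifest(run_dir: Path, config: ExperimentConfig, command: str,
                    metrics: dict) -> dict:
    manifest = {
        "command": command,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "metrics": metrics,
    }
    path = run_dir / f"manifest_{command.replace('-', '_')}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_experiment(config: ExperimentConfig, command: str,
                   run_dir: str | Path | None = None) -> dict:
    """Execute one pipeline stage; returns its manifest (with metrics)."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; choose from {COMMANDS}")
    run_dir = Path(run_dir or config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    metrics: dict = {}

    if command == "synth":
        tr_s, tr_y, te_s, te_y = generate_sequences(config.task)
        data_dir = run_dir / "data"
        write_dataset(data_dir, tr_s, tr_y)
        (data_dir / "manifest.csv").rename(data_dir / "train_manifest.csv")
        # test sequences share the directory under distinct names
        rows = []
        for i, (seq, lab) in enumerate(zip(te_s, te_y)):
            name = f"test_{i:04d}.csv"
            np.savetxt(data_dir / name, seq, delimiter=",")
            rows.append(f"{name},{int(lab)},{seq.shape[0]}")
        (data_dir / "test_manifest.csv").write_text(
            "path,label,length\n" + "\n".join(rows) + "\n"
        )
        metrics = {"n_train": len(tr_s), "n_test": len(te_s)}

    elif command == "train-wta":
        tr_s, _ = _load_dataset(run_dir, "train")
        net = DeepLSM(config.network)
        net.encoder.fit(tr_s)
        net.train_wta_layers(tr_s, epochs_per_layer=config.wta_epochs,
                             seed=derive_seed(config.seed, "wta"))
        dio.save_topology(run_dir / "topology.h5", net)
        metrics = {"wta_layers": len(net.wtas)}

    elif command == "simulate":
        for split in ("train", "test"):
            seqs, labels = _load_dataset(run_dir, split)
            if split == "train":
                net = _build_network(config, run_dir, seqs)
            snaps = net.run_dataset(seqs, seed=derive_seed(config.seed, split))
            dio.save_snapshots(run_dir / f"snapshots_{split}.h5", snaps,
                               labels, config.network.n_layers)
        metrics = {"snapshot_dim": int(snaps.shape[1])}

    elif command == "train-readout":
        X, y, n_layers = dio.load_snapshots(
            _require(run_dir / "snapshots_train.h5", "simulate")
        )
        params, losses = train_readout(
            X, y, n_layers,
            lr=config.readout.lr, epochs=config.readout.epochs,
            seed=derive_seed(config.seed, "readout"),
            standardize=config.readout.standardize,
        )
        dio.save_readout(run_dir / "readout.h5", params)
        np.savetxt(run_dir / "loss_curve.csv", losses, delimiter=",")
        metrics = {"final_loss": float(losses[-1])}

    elif command == "evaluate":
        X, y, _ = dio.load_snapshots(
            _require(run_dir / "snapshots_test.h5", "simulate")
        )
        params = dio.load_readout(_require(run_dir / "readout.h5",
                                           "train-readout"))
        pred = predict(X, params)
        n_classes = params.n_classes
        confusion = np.zeros((n_classes, n_classes), dtype=int)
        for t, p in zip(y, pred):
            confusion[t, p] += 1
        np.savetxt(run_dir / "confusion.csv", confusion, fmt="%d", delimiter=",")
        per_class = [
            float(confusion[c, c] / max(confusion[c].sum(), 1))
            for c in range(n_classes)
        ]
        metrics = {
            "accuracy": float(np.mean(pred == y)),
            "per_class_accuracy": per_class,
        }

    elif command == "resources":
        report = {}
        for kind in ("deep-lsm", "lsm", "lstm"):
            for attention in (False, True):
                if kind == "lstm" and attention:
                    continue
                key = kind + ("+attention" if attention else "")
                report[key] = full_report(sec41_spec(kind, attention)).as_dict()
        (run_dir / "resources.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        metrics = {"models": sorted(report)}

    return _write_manifest(run_dir, config, command, metrics)
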