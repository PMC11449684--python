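"""Reproducible experiment runner: one activation, or the nine-way sweep.

A run is described by a small config mapping (usually loaded from
YAML)::

    data:
      source: phantom            # or "folder"
      root: path/to/classes      # folder source
      phantom: {n_per_class: 100, image_size: [224, 224], noise_sd: 0.05, seed: 0}
      target_size: [224, 224]    # folder preprocessing
    split: {train: 0.7, val: 0.1, test: 0.2, seed: 0, stratified: true}
    activation: {name: rectified_softsign}     # plus optional hyperparameters
    network: {num_classes: 4}                  # input shape follows the data
    training: {learning_rate: 1.0e-4, batch_size: 64, max_epochs: 64, seed: 0}

The sweep holds the dataset, the split, the initialization seed and the
training budget fixed across all nine activations, so metric
differences are attributable to the activation alone.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .activations import ACTIVATION_NAMES, ActivationSpec
from .architecture import default_network, build_network, NetworkSpec
from .data_io import (LabeledImageSet, PhantomSpec, SplitSpec,
                      generate_phantoms, load_image_folder, split_dataset)
from .metrics import (confusion, macro_f1, metrics_table, accuracy as cm_accuracy,
                      multiclass_roc)
from .training import TrainConfig, train, predict

__all__ = ["RunResult", "ExperimentError", "load_config", "run_experiment",
           "run_sweep", "save_checkpoint", "load_checkpoint"]


class ExperimentError(ValueError):
    pass


@dataclass
class RunResult:
    """Summary of one train/evaluate cycle."""

    activation: str
    test_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: object = field(repr=False)          # DataFrame
    seed: int = 0
    config_digest: str = ""
    run_dir: str | None = None
    history: object = field(default=None, repr=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ExperimentError(f"config {path} is not a mapping")
    return cfg


def config_digest(cfg: dict) -> str:
    """Stable hash of the canonicalized config."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _activation_from_config(cfg: dict) -> ActivationSpec:
    act = dict(cfg.get("activation") or {})
    name = act.pop("name", None)
    if name is None:
        raise ExperimentError("config must name an activation")
    return ActivationSpec(name=name, **act)


def _dataset_from_config(cfg: dict) -> LabeledImageSet:
    data = cfg.get("data") or {}
    source = data.get("source", "phantom")
    if source == "phantom":
        ph = dict(data.get("phantom") or {})
        if "image_size" in ph:
            ph["image_size"] = tuple(ph["image_size"])
        return generate_phantoms(PhantomSpec(**ph))
    if source == "folder":
        if "root" not in data:
            raise ExperimentError("folder source requires data.root")
        target = tuple(data.get("target_size", (224, 224)))
        return load_image_folder(data["root"], target_size=target)
    raise ExperimentError(f"unknown data source {source!r}")


def _prepare(cfg: dict):
    dataset = _dataset_from_config(cfg)
    split = SplitSpec(**(cfg.get("split") or {}))
    train_set, val_set, test_set = split_dataset(dataset, split)
    h, w = dataset.images.shape[1:3]
    net_cfg = cfg.get("network") or {}
    num_classes = int(net_cfg.get("num_classes", dataset.num_classes))
    net = default_network(input_shape=(h, w, dataset.images.shape[3]),
                          num_classes=num_classes)
    return train_set, val_set, test_set, net


def _evaluate(model, test_set) -> dict:
    probs, y_pred = predict(model, test_set.images)
    cm = confusion(test_set.labels, y_pred, test_set.num_classes,
                   test_set.class_names)
    table = metrics_table(cm, probs, test_set.labels)
    defined = table.dropna(subset=["precision", "recall"])
    return {
        "cm": cm,
        "probs": probs,
        "table": table,
        "accuracy": cm_accuracy(cm),
        "macro_precision": float(defined["precision"].mean()),
        "macro_recall": float(defined["recall"].mean()),
        "macro_f1": macro_f1(cm),
    }


def run_experiment(cfg: dict, out_dir=None) -> RunResult:
    """Execute load → split → build → train → evaluate for one config.

    When ``out_dir`` is given, the run artifacts are persisted there:
    the resolved config, per-epoch history, per-class metrics, the
    confusion matrix, one-vs-rest ROC points, and a checkpoint.
    """
    act = _activation_from_config(cfg)   # validate before any compute
    train_cfg = TrainConfig(**(cfg.get("training") or {}))
    train_set, val_set, test_set, net = _prepare(cfg)
    model = build_network(net, act, seed=train_cfg.seed)
    model, history = train(model, train_set, val_set, train_cfg)
    ev = _evaluate(model, test_set)
    digest = config_digest(cfg)
    result = RunResult(
        activation=act.name,
        test_accuracy=ev["accuracy"],
        macro_precision=ev["macro_precision"],
        macro_recall=ev["macro_recall"],
        macro_f1=ev["macro_f1"],
        per_class=ev["table"],
        seed=train_cfg.seed,
        config_digest=digest,
        history=history,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        history.to_frame().to_csv(out / "history.csv", index=False)
        ev["table"].to_csv(out / "metrics.csv", index=False)
        np.savetxt(out / "confusion_matrix.csv", ev["cm"].counts,
                   fmt="%d", delimiter=",",
                   header=",".join(ev["cm"].class_names), comments="")
        roc_rows = []
        for curve, auc in multiclass_roc(ev["probs"], test_set.labels):
            for fpr, tpr in zip(curve.fpr, curve.tpr):
                roc_rows.append((curve.positive_class, fpr, tpr, auc))
        np.savetxt(out / "roc.csv", np.array(roc_rows),
                   delimiter=",", header="class,fpr,tpr,auc", comments="")
        save_checkpoint(model, net, act, out / "checkpoint.npz")
        result.run_dir = str(out)
    return result


def run_sweep(cfg: dict, out_dir=None):
    """Run all nine activations on one shared dataset/split/seed.

    Returns (DataFrame sorted by descending test accuracy, results
    dict).  A failing activation is recorded with its error and the
    sweep continues.
    """
    import pandas as pd

    train_cfg = TrainConfig(**(cfg.get("training") or {}))
    train_set, val_set, test_set, net = _prepare(cfg)
    rows, results = [], {}
    for name in ACTIVATION_NAMES:
        sub = copy.deepcopy(cfg)
        sub.setdefault("activation", {})
        sub["activation"]["name"] = name
        try:
            act = _activation_from_config(sub)
            model = build_network(net, act, seed=train_cfg.seed)
            model, history = train(model, train_set, val_set, train_cfg)
            ev = _evaluate(model, test_set)
            result = RunResult(name, ev["accuracy"], ev["macro_precision"],
                               ev["macro_recall"], ev["macro_f1"], ev["table"],
                               train_cfg.seed, config_digest(sub), history=history)
            results[name] = result
            rows.append({"activation": name, "test_accuracy": result.test_accuracy,
                         "macro_precision": result.macro_precision,
                         "macro_recall": result.macro_recall,
                         "macro_f1": result.macro_f1, "error": ""})
            if out_dir is not None:
                sub_out = Path(out_dir) / name
                sub_out.mkdir(parents=True, exist_ok=True)
                ev["table"].to_csv(sub_out / "metrics.csv", index=False)
                history.to_frame().to_csv(sub_out / "history.csv", index=False)
        except Exception as exc:  # keep sweeping; record the failure
            results[name] = exc
            rows.append({"activation": name, "test_accuracy": np.nan,
                         "macro_precision": np.nan, "macro_recall": np.nan,
                         "macro_f1": np.nan, "error": str(exc)})
    frame = pd.DataFrame(rows).sort_values(
        "test_accuracy", ascending=False, na_position="last").reset_index(drop=True)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        frame.to_csv(Path(out_dir) / "sweep.csv", index=False)
    return frame, results


# -- checkpoints ------------------------------------------------------------

def save_checkpoint(model, net: NetworkSpec, act: ActivationSpec, path) -> None:
    """Persist parameters + batchnorm state + enough spec to rebuild."""
    arrays = {}
    for i, layer in enumerate(model.layers):
        for k, v in layer.params.items():
            arrays[f"layer{i}:{k}"] = v
        if hasattr(layer, "running_mean"):
            arrays[f"layer{i}:_running_mean"] = layer.running_mean
            arrays[f"layer{i}:_running_var"] = layer.running_var
    meta = {
        "input_shape": list(net.input_shape),
        "num_classes": net.num_classes,
        "activation": {"name": act.name, "slope": act.slope,
                       "ceiling": act.ceiling, "alpha": act.alpha,
                       "gelu_constant": act.gelu_constant},
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Rebuild the default-architecture model stored by ``save_checkpoint``."""
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    act = ActivationSpec(**meta["activation"])
    net = default_network(input_shape=tuple(meta["input_shape"]),
                          num_classes=meta["num_classes"])
    model = build_network(net, act, seed=0)
    for i, layer in enumerate(model.layers):
        for k in list(layer.params):
            layer.params[k] = data[f"layer{i}:{k}"]
        if hasattr(layer, "running_mean"):
            layer.running_mean = data[f"layer{i}:_running_mean"]
            layer.running_var = data[f"layer{i}:_running_var"]
    return model, net, act
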