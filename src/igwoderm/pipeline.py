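"""End-to-end orchestration: synth -> preprocess -> segment -> train -> evaluate.

A run is described by a nested key-value config (YAML on disk).  Two
profiles exist: ``desk`` (the default; small images, short optimizer budgets
and few epochs so a full run finishes in minutes on one CPU) and ``full``
(the full-scale protocol: 225x225 inputs, 50 epochs, N=30, T=200 optimizer
iterations, 25 threshold repeats).  Every run directory contains the resolved
config, the seeds and library versions needed to reproduce it exactly.
"""
from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import CNNClassifier, cnn_error, split_dataset
from .metrics import full_report
from .optimizer import IgwoConfig, optimize, SearchSpace
from .preprocess import DermoscopyPreprocessor
from .segmentation import SegmentationConfig, segment_lesion
from .synthetic import (BENIGN_PARAMS, MALIGNANT_PARAMS, LesionParams,
                        benchmark_function, make_classification_arrays)

__all__ = ["DEFAULT_CONFIG", "FULL_OVERRIDES", "load_config", "resolve_config",
           "run_pipeline", "iou"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "profile": "desk",
    "synth": {
        "enabled": True,
        "n_images": 200,
        "imbalance": 0.1,
        "n_patients": 40,
        "image_size": 32,
        "hair": False,
    },
    "preprocess": {
        "enabled": False,  # generator images are hairless by default
        "denoise_sigma": 0.5,
        "hair_element": 7,
        "hair_threshold": 10,
        "contrast": True,
    },
    "segment": {
        "enabled": True,
        "n_images": 4,
        "classes": 2,
        "repeats": 3,
        "variant": "igwo",
        "pop_size": 20,
        "max_iter": 40,
    },
    "split": {"ratios": [0.70, 0.15, 0.15]},
    "train": {
        "filters": [32, 64, 128],
        "dropout": 0.5,
        "learning_rate": 1.0e-3,
        "batch_size": 16,
        "epochs": 8,
        "patience": 10,
        "class_weighted": True,
    },
    "benchmark": {
        "enabled": False,
        "functions": ["sphere"],
        "dim": 10,
        "n_seeds": 5,
        "pop_size": 30,
        "max_iter": 200,
    },
}

#: Full-scale protocol values layered on top of the defaults.
FULL_OVERRIDES: dict = {
    "synth": {"n_images": 33126, "image_size": 225, "n_patients": 2000},
    "segment": {"repeats": 25, "pop_size": 30, "max_iter": 200},
    "train": {"epochs": 50, "batch_size": 32},
}


def _deep_update(base: dict, extra: dict, path: str = "") -> dict:
    for key, value in extra.items():
        if key not in base:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"section {path + key!r} must be a mapping")
            _deep_update(base[key], value, path + key + ".")
        else:
            base[key] = value
    return base


def resolve_config(user: dict | None = None) -> dict:
    """Merge user settings over the defaults; unknown keys are rejected."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    user = dict(user or {})
    if user.get("profile", cfg["profile"]) == "full":
        _deep_update(cfg, copy.deepcopy(FULL_OVERRIDES))
        cfg["profile"] = "full"
    _deep_update(cfg, user)
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return resolve_config(yaml.safe_load(fh) or {})


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(cfg: dict | None = None, out_dir=None) -> dict:
    """Execute the configured stages in order and return the run report.

    The report contains the per-stage summaries and the full metrics report
    of the trained classifier on the held-out test split.  When ``out_dir``
    is given, per-stage artifacts (manifest, history, metrics, reproducibility
    manifest) are written there.
    """
    cfg = resolve_config(cfg if isinstance(cfg, dict) else None) \
        if not _is_resolved(cfg) else cfg
    seed = int(cfg["seed"])
    report: dict = {"config_hash": _config_hash(cfg), "seed": seed,
                    "profile": cfg["profile"]}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)

    stage = "synth"
    try:
        sc = cfg["synth"]
        if not sc["enabled"]:
            raise ValueError("pipeline currently requires the synth stage")
        size = int(sc["image_size"])
        pb = _sized(BENIGN_PARAMS, size)
        pm = _sized(MALIGNANT_PARAMS, size)
        data = make_classification_arrays(
            int(sc["n_images"]), float(sc["imbalance"]), int(sc["n_patients"]),
            pb, pm, seed=seed, hair=bool(sc["hair"]))
        report["synth"] = {"n_images": int(sc["n_images"]),
                           "n_malignant": int((data["labels"] == "malignant").sum())}

        stage = "preprocess"
        images = data["images"]
        pc = cfg["preprocess"]
        if pc["enabled"]:
            pre = DermoscopyPreprocessor(
                denoise_sigma=pc["denoise_sigma"], hair_element=pc["hair_element"],
                hair_threshold=pc["hair_threshold"], contrast=pc["contrast"])
            images = pre.fit(images).transform(images)
            report["preprocess"] = {"applied": True}

        stage = "split"
        records = pd.DataFrame({"label": data["labels"],
                                "patient_id": data["patient_id"],
                                "index": np.arange(len(data["labels"]))})
        tagged = split_dataset(records, tuple(cfg["split"]["ratios"]), seed=seed)
        idx = {name: tagged.loc[tagged["split"] == name, "index"].to_numpy()
               for name in ("train", "val", "test")}
        report["split"] = {name: int(v.size) for name, v in idx.items()}
        if out is not None:
            tagged.to_csv(out / "manifest.csv", index=False)

        stage = "segment"
        gc = cfg["segment"]
        if gc["enabled"]:
            seg_cfg = SegmentationConfig(
                m=int(gc["classes"]), repeats=int(gc["repeats"]),
                variant=gc["variant"],
                optimizer=IgwoConfig(pop_size=int(gc["pop_size"]),
                                     max_iter=int(gc["max_iter"])),
                seed=seed)
            n_seg = min(int(gc["n_images"]), idx["test"].size)
            ious = [iou(segment_lesion(images[i], seg_cfg), data["masks"][i])
                    for i in idx["test"][:n_seg]]
            report["segment"] = {"n_images": n_seg,
                                 "mean_iou": float(np.mean(ious)) if ious else None}

        stage = "train"
        tc = cfg["train"]
        clf = CNNClassifier(
            filters=tuple(tc["filters"]), dropout=float(tc["dropout"]),
            learning_rate=float(tc["learning_rate"]),
            batch_size=int(tc["batch_size"]), epochs=int(tc["epochs"]),
            patience=int(tc["patience"]), class_weighted=bool(tc["class_weighted"]),
            random_state=seed)
        clf.fit(images[idx["train"]], data["labels"][idx["train"]],
                validation_data=(images[idx["val"]], data["labels"][idx["val"]]))
        report["train"] = {"epochs_run": len(clf.history_["train_loss"]),
                           "best_epoch": clf.best_epoch_,
                           "n_params": clf.n_params_}
        if out is not None:
            hist = pd.DataFrame({k: pd.Series(v) for k, v in clf.history_.items()})
            hist.to_csv(out / "history.csv", index_label="epoch")

        stage = "evaluate"
        x_test, y_test = images[idx["test"]], data["labels"][idx["test"]]
        probs = clf.predict_proba(x_test)
        pred = clf.predict(x_test)
        mal_col = int(np.argmax(clf.classes_ == "malignant"))
        rep = full_report(pred, y_test, scores=probs[:, mal_col])
        report["metrics"] = rep.to_dict()
        report["metrics"]["cnn_error"] = cnn_error(
            probs, np.searchsorted(clf.classes_, y_test))

        stage = "benchmark"
        bc = cfg["benchmark"]
        if bc["enabled"]:
            report["benchmark"] = _run_benchmark(bc, seed, out)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed "
            f"(completed artifacts, if any, are in {out})") from exc

    report["versions"] = _versions()
    if out is not None:
        with open(out / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        with open(out / "run_manifest.json", "w") as fh:
            json.dump({"config_hash": report["config_hash"], "seed": seed,
                       "versions": report["versions"]}, fh, indent=2)
    return report


def _is_resolved(cfg) -> bool:
    return isinstance(cfg, dict) and set(cfg) == set(DEFAULT_CONFIG)


def _sized(p: LesionParams, size: int) -> LesionParams:
    return replace(p, size=size)


def _run_benchmark(bc: dict, seed: int, out) -> dict:
    rows = []
    cfg0 = IgwoConfig(pop_size=int(bc["pop_size"]), max_iter=int(bc["max_iter"]))
    ss = np.random.SeedSequence(seed).generate_state(int(bc["n_seeds"]))
    for name in bc["functions"]:
        bench = benchmark_function(name, int(bc["dim"]))
        space = SearchSpace(lower=np.full(bench.optimum.size, bench.bounds[0]),
                            upper=np.full(bench.optimum.size, bench.bounds[1]))
        for s in ss:
            cfg = replace(cfg0, seed=int(s) & 0x7FFFFFFF)
            for variant in ("gwo", "igwo"):
                res = optimize(bench.fn, space, cfg, variant=variant,
                               vectorized=True)
                rows.append({"function": name, "seed": int(s) & 0x7FFFFFFF,
                             "variant": variant,
                             "best_fitness": res.best_fitness})
    df = pd.DataFrame(rows)
    if out is not None:
        df.to_csv(Path(out) / "benchmark.csv", index=False)
    summary: dict = {}
    for (fn_name, variant), grp in df.groupby(["function", "variant"]):
        summary.setdefault(fn_name, {})[variant] = float(grp["best_fitness"].mean())
    return {"mean_best_fitness": summary}


def _versions() -> dict:
    import scipy
    import sklearn
    return {"igwoderm": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__}
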