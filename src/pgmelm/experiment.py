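"""End-to-end experiment driver: preprocess -> balance -> fit -> evaluate,
averaged over independent Monte-Carlo trials.

Each trial re-splits the data, refits the standardize+PCA front end and the
GAN on that trial's training split only (no leakage into the test split),
trains the requested methods and scores them on the held-out split.  Every
number in the report is a deterministic function of (config, master_seed):
trial seeds are derived by an explicit integer hash so reports are stable
across runs and platforms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import Dataset
from .elm import (adaptive_structure, elm_fit, helm_fit, pgmelm_fit, predict,
                  welm_fit)
from .ganbalance import GANConfig, balance_dataset, smote_oversample
from .metrics import classification_report, confusion, roc_auc
from .preprocess import Preprocessor
from .stats import RankSummary, ScoreTable, compare_classifiers
from .synthdata import SynthSpec, make_imbalanced, split

METHODS = ("pgm-elm", "w-elm", "smote-elm", "h-elm")


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage, method and trial."""

    def __init__(self, stage: str, trial: int, cause: Exception):
        super().__init__(f"stage {stage!r} failed in trial {trial}: {cause}")
        self.stage = stage
        self.trial = trial


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    synth: SynthSpec | None = None
    data_path: str | None = None
    label_column: str = "label"
    n_train: int | None = None          # default: half the samples
    methods: tuple[str, ...] = METHODS
    gan: GANConfig = field(default_factory=GANConfig)
    C: float = 1.0
    pca_threshold: float = 0.85
    trials: int = 20
    master_seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}; choose from {METHODS}")

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["methods"] = list(self.methods)
        return doc


def trial_seed(master_seed: int, trial: int) -> int:
    """Deterministic per-trial seed: a fixed-multiplier integer hash of
    (master_seed, trial), stable across versions and platforms."""
    h = (master_seed * 2654435761 + trial * 40503 + 12345) % (2**31 - 1)
    return int(h)


def _default_nodes(n: int, m: int) -> int:
    # single-layer baseline width: the dIR = 0 limit of the adaptive rule
    return max(1, math.ceil(n / m - 1e-9))


def run_single_trial(train: Dataset, test: Dataset, cfg: ExperimentConfig,
                     seed: int, trial: int = 0) -> dict[str, dict]:
    """Fit and score every requested method on one train/test split."""
    results: dict[str, dict] = {}
    n, m = train.n, train.n_features
    nodes = _default_nodes(n, m)

    # standardized view (training statistics) for the single-layer baselines
    mu = train.X.mean(axis=0)
    delta = train.X.std(axis=0, ddof=1)
    delta = np.where(delta < 1e-12, 1.0, delta)
    Xtr_std = (train.X - mu) / delta
    Xte_std = (test.X - mu) / delta

    for method in cfg.methods:
        try:
            if method == "pgm-elm":
                pre = Preprocessor(threshold=cfg.pca_threshold)
                Z_tr = pre.fit_transform(train.X)
                Z_te = pre.transform(test.X)
                gan_cfg = GANConfig(**{**asdict(cfg.gan), "seed": seed})
                bal = balance_dataset(Z_tr, train.y, gan_cfg)
                P, Q = adaptive_structure(n, m, bal.n, pre.n_components,
                                          bal.delta_ir)
                model = pgmelm_fit(bal.Z, bal.y, P=P, Q=Q, C=cfg.C, seed=seed)
                scores, y_hat = predict(model, Z_te)
                extra = {"P": P, "Q": Q, "n_components": pre.n_components,
                         "num": bal.num, "delta_ir": bal.delta_ir}
            elif method == "w-elm":
                model = welm_fit(Xtr_std, train.y, nodes=nodes, C=cfg.C,
                                 seed=seed)
                scores, y_hat = predict(model, Xte_std)
                extra = {"nodes": nodes}
            elif method == "smote-elm":
                bal = smote_oversample(Xtr_std, train.y, k=min(5, train.n_minority - 1),
                                       seed=seed)
                model = elm_fit(bal.Z, bal.y, nodes=nodes, C=cfg.C, seed=seed)
                scores, y_hat = predict(model, Xte_std)
                extra = {"nodes": nodes}
            elif method == "h-elm":
                model = helm_fit(Xtr_std, train.y, P=nodes, Q=2, C=cfg.C,
                                 seed=seed)
                scores, y_hat = predict(model, Xte_std)
                extra = {"nodes": nodes, "layers": 2}
            else:  # pragma: no cover - guarded by config validation
                raise ValueError(method)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise StageError(f"fit/{method}", trial, exc) from exc

        cm = confusion(test.y, y_hat)
        rep = classification_report(cm)
        _, auc = roc_auc(scores, test.y)
        rep.auc = auc
        results[method] = {
            "tpr": rep.tpr, "tnr": rep.tnr, "precision": rep.precision,
            "g_mean": rep.g_mean, "f_measure": rep.f_measure, "auc": auc,
            "confusion": asdict(cm), **extra,
        }
    return results


def run_experiment(cfg: ExperimentConfig, dataset: Dataset | None = None) -> dict:
    """Run the full Monte-Carlo experiment and return the report dict.

    The report carries the full config, one metric row per (trial, method),
    and trial-averaged G-mean / F-measure / AUC per method (undefined
    per-trial metrics are excluded from the average and counted).
    """
    if dataset is None:
        if cfg.synth is not None:
            dataset = make_imbalanced(cfg.synth)
        elif cfg.data_path is not None:
            from .data import read_table
            dataset = read_table(cfg.data_path, cfg.label_column)
        else:
            raise ValueError("config needs synth spec, data_path, or a dataset")
    n_train = cfg.n_train or dataset.n // 2

    rows = []
    for t in range(cfg.trials):
        seed = trial_seed(cfg.master_seed, t)
        try:
            train, test = split(dataset, n_train, seed=seed,
                                stratified=cfg.stratified)
        except Exception as exc:
            raise StageError("split", t, exc) from exc
        res = run_single_trial(train, test, cfg, seed, trial=t)
        for method, metrics_row in res.items():
            rows.append({"trial": t, "seed": seed, "method": method,
                         **metrics_row})

    averages: dict[str, dict] = {}
    for method in cfg.methods:
        sub = [r for r in rows if r["method"] == method]
        averages[method] = {}
        for key in ("g_mean", "f_measure", "auc", "tpr", "tnr"):
            vals = [r[key] for r in sub if r[key] is not None]
            averages[method][key] = float(np.mean(vals)) if vals else None
            averages[method][f"{key}_defined"] = len(vals)
    return {"config": cfg.to_dict(), "n_train": n_train,
            "dataset": {"n": dataset.n, "n_minority": dataset.n_minority,
                        "n_majority": dataset.n_majority,
                        "imbalance_ratio": dataset.imbalance_ratio},
            "trials": rows, "averages": averages}


def report_to_frame(report: dict) -> pd.DataFrame:
    """Per-trial rows of a report as a tidy DataFrame."""
    drop = ("confusion",)
    return pd.DataFrame([{k: v for k, v in r.items() if k not in drop}
                         for r in report["trials"]])


def compare_methods(reports: dict[str, dict], metric: str = "g_mean",
                    alpha: float = 0.05) -> RankSummary:
    """Rank methods across several experiment reports (one per dataset).

    ``reports`` maps dataset name -> report from :func:`run_experiment`;
    all reports must share the same method set.
    """
    names = list(reports)
    if len(names) < 2:
        raise ValueError("need reports for >= 2 datasets")
    method_sets = [tuple(sorted(r["averages"])) for r in reports.values()]
    if len(set(method_sets)) != 1:
        raise ValueError(f"method sets differ across reports: {method_sets}")
    methods = list(reports[names[0]]["averages"])
    scores = np.array([[reports[d]["averages"][m][metric] for m in methods]
                       for d in names], dtype=float)
    table = ScoreTable(scores, methods, names)
    return compare_classifiers(table, alpha=alpha)


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
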