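"""Metrics, model selection, significance testing, and experiment runs.

Implements the standard binary-classification report (ACC, PPV, SEN, F1
from the confusion counts; AUC by the Mann-Whitney rank statistic with
tie correction), stratified grid-search cross-validation with
simplest-model tie-breaking, paired two-sided t-tests across seeds, and
a config-driven experiment harness that compares the no-transfer and
transfer classifiers across calibration sizes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace, asdict
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import StratifiedKFold

from . import baselines
from .smm import Hyperparams, MatrixDataset, fit, predict, decision_function
from .transfer import TransferTask, fit_transfer, lambda_sensitivity

__all__ = [
    "MetricsReport",
    "GridSpec",
    "confusion_metrics",
    "auc_score",
    "cross_validate_grid",
    "paired_ttest",
    "run_experiment",
    "DEFAULT_C_GRID",
    "DEFAULT_TAU_GRID",
    "DEFAULT_LAMBDA_GRID",
]

logger = logging.getLogger("smmtransfer")

# hyperparameter grids used throughout the experiments
DEFAULT_C_GRID = [1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1e0, 1e1]
DEFAULT_TAU_GRID = [1e-5, 2e-5, 5e-5, 1e-4, 2e-4, 5e-4, 1e-3, 2e-3,
                    5e-3, 1e-2, 2e-2, 5e-2, 1e-1, 2e-1, 5e-1, 1e0]
DEFAULT_LAMBDA_GRID = [1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2, 1e-1, 5e-1, 1e0]


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    PPV: float
    SEN: float
    F1: float
    AUC: float | None = None
    f1_undefined: bool = False

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _check_signed(y: np.ndarray, name: str) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.abs(y) == 1.0):
        raise ValueError(f"{name} must contain only +1/-1 labels")
    return y


def confusion_metrics(y_true, y_pred, decision_values=None) -> MetricsReport:
    """Confusion counts and ACC/PPV/SEN/F1 (+AUC when decisions are given).

    ACC = (TP+TN)/(TP+FN+FP+TN); PPV = TP/(TP+FP); SEN = TP/(TP+FN);
    F1 = 2*PPV*SEN/(PPV+SEN), reported as 0 with a flag when PPV+SEN = 0.
    """
    y_true = _check_signed(y_true, "y_true")
    y_pred = _check_signed(y_pred, "y_pred")
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("y_true and y_pred must have equal nonzero length")
    TP = int(np.sum((y_true > 0) & (y_pred > 0)))
    TN = int(np.sum((y_true < 0) & (y_pred < 0)))
    FP = int(np.sum((y_true < 0) & (y_pred > 0)))
    FN = int(np.sum((y_true > 0) & (y_pred < 0)))
    acc = (TP + TN) / (TP + FN + FP + TN)
    ppv = TP / (TP + FP) if TP + FP else 0.0
    sen = TP / (TP + FN) if TP + FN else 0.0
    undefined = (ppv + sen) == 0.0
    f1 = 0.0 if undefined else 2 * ppv * sen / (ppv + sen)
    auc = None
    if decision_values is not None:
        auc = auc_score(y_true, decision_values)
    return MetricsReport(TP, TN, FP, FN, acc, ppv, sen, f1, auc, undefined)


def auc_score(y_true, decision_values) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic (ties count 1/2)."""
    y_true = _check_signed(y_true, "y_true")
    d = np.asarray(decision_values, dtype=float).ravel()
    if d.shape != y_true.shape:
        raise ValueError("decision_values must match y_true in length")
    n_pos = int(np.sum(y_true > 0))
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = scipy.stats.rankdata(d)  # average ranks handle ties
    r_pos = ranks[y_true > 0].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ----------------------------------------------------------------------
# cross-validated grid search
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    C_grid: tuple = tuple(DEFAULT_C_GRID)
    tau_grid: tuple = tuple(DEFAULT_TAU_GRID)
    lambda_grid: tuple = tuple(DEFAULT_LAMBDA_GRID)
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (self.C_grid and self.tau_grid and self.lambda_grid):
            raise ValueError("grids must be non-empty")


def _fold_indices(y: np.ndarray, n_folds: int, seed: int):
    """Stratified folds, auto-reduced to the smallest class count.

    Tiny calibration sets degrade gracefully: when a class has a single
    trial, folds become leave-one-out; folds whose training part is
    single-class are dropped (the caller records them as skipped).
    """
    classes, counts = np.unique(y, return_counts=True)
    k = min(n_folds, int(counts.min()))
    if k >= 2:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(skf.split(np.zeros_like(y), y))
    n = y.size
    folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    return [(tr, te) for tr, te in folds if np.unique(y[tr]).size == 2]


def cross_validate_grid(
    data: MatrixDataset,
    grid: GridSpec,
    estimator: str = "smm",
    W_source: np.ndarray | None = None,
    hyper_base: Hyperparams | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Select (C, tau[, lambda]) by stratified CV mean accuracy.

    ``estimator``: "svm" tunes C only; "smm" tunes (C, tau); "klsmm"
    tunes (C, tau, lambda) and requires ``W_source``.  Ties break toward
    smaller C, then smaller tau, then smaller lambda (simplest model).
    Returns the winning parameter dict and the full CV table.
    """
    if estimator not in ("svm", "smm", "klsmm"):
        raise ValueError(f"unknown estimator '{estimator}'")
    if estimator == "klsmm" and W_source is None:
        raise ValueError("klsmm estimator requires W_source")
    base = hyper_base or Hyperparams()
    X, y = data.labeled()
    folds = _fold_indices(y, grid.n_folds, grid.seed)

    if estimator == "svm":
        combos = [(c, None, None) for c in sorted(grid.C_grid)]
    elif estimator == "smm":
        combos = [(c, t, None) for c in sorted(grid.C_grid) for t in sorted(grid.tau_grid)]
    else:
        combos = [(c, t, l) for c in sorted(grid.C_grid)
                  for t in sorted(grid.tau_grid) for l in sorted(grid.lambda_grid)]

    rows = []
    best: dict | None = None
    best_acc = -np.inf
    for c, t, l in combos:
        fold_accs = []
        for fi, (tr, te) in enumerate(folds):
            try:
                sub = data.subset(tr)
                if estimator == "svm":
                    m = baselines.fit_linear_svm(sub, C=c)
                    yhat = m.predict(X[te].reshape(len(te), -1)).ravel()
                else:
                    hy = replace(base, C=c, tau=t, lam=0.0 if l is None else l)
                    model = fit(sub, hy, W_source if l is not None else None)
                    yhat = predict(model, X[te])
                fold_accs.append(float(np.mean(yhat == y[te])))
            except Exception as exc:  # noqa: BLE001 - fold failures are recorded
                logger.warning("fold %d failed at C=%g tau=%s lam=%s: %s", fi, c, t, l, exc)
        if not fold_accs:
            continue
        mean_acc = float(np.mean(fold_accs))
        rows.append({"C": c, "tau": t, "lambda": l, "mean_acc": mean_acc,
                     "fold_accs": fold_accs})
        if mean_acc > best_acc + 1e-12:  # strict improvement keeps simplest tie-winner
            best_acc = mean_acc
            best = {"C": c, **({"tau": t} if t is not None else {}),
                    **({"lambda": l} if l is not None else {})}
    if best is None:
        raise RuntimeError("every CV fold failed")
    return best, pd.DataFrame(rows)


# ----------------------------------------------------------------------
# significance
# ----------------------------------------------------------------------

def paired_ttest(scores_a, scores_b) -> tuple[float, float, bool]:
    """Two-sided paired t-test; returns (t, p, degenerate_flag).

    ``degenerate`` is set (with p = nan) when the per-unit differences
    have zero variance, where the statistic is undefined.
    """
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired scores must have equal length >= 2")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        return 0.0, float("nan"), True
    res = scipy.stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), False


# ----------------------------------------------------------------------
# experiment harness
# ----------------------------------------------------------------------

def _method_fit_predict(method: str, task: TransferTask, grid: GridSpec,
                        hyper_base: Hyperparams):
    """CV-tune a method on the labeled target prefix, return test metrics."""
    train = task.labeled_train()
    Xte, yte = task.target_test.labeled()
    Ws = task.source_model.W

    if method == "SVM":
        best, _ = cross_validate_grid(train, grid, "svm")
        m = baselines.fit_linear_svm(train, C=best["C"])
        dec = m.decision_function(Xte.reshape(len(yte), -1)).ravel()
    elif method == "SMM":
        best, _ = cross_validate_grid(train, grid, "smm", hyper_base=hyper_base)
        model = fit(train, replace(hyper_base, C=best["C"], tau=best["tau"], lam=0.0))
        dec = decision_function(model, Xte)
    elif method == "ASVM":
        src = task.source_model
        fsrc = lambda v: np.einsum("ij,j->i", np.atleast_2d(v), src.W.ravel()) + src.b
        best_acc, best_m = -np.inf, None
        vtrain = baselines.vectorize(train)
        folds = _fold_indices(vtrain.labels, grid.n_folds, grid.seed)
        for c, la in product(sorted(grid.C_grid), sorted(grid.lambda_grid)):
            accs = []
            for tr, te in folds:
                sub = baselines.VectorDataset(
                    vtrain.vectors[tr], vtrain.labels[tr], vtrain.p, vtrain.q)
                m = baselines.fit_asvm(fsrc, sub, C=c, lam_A=la)
                accs.append(np.mean(m.predict(vtrain.vectors[te]) == vtrain.labels[te]))
            if np.mean(accs) > best_acc + 1e-12:
                best_acc, best_m = float(np.mean(accs)), (c, la)
        m = baselines.fit_asvm(fsrc, vtrain, C=best_m[0], lam_A=best_m[1])
        dec = m.decision_function(Xte.reshape(len(yte), -1)).ravel()
    elif method == "KL-SMM":
        best, _ = cross_validate_grid(train, grid, "klsmm", W_source=Ws,
                                      hyper_base=hyper_base)
        model = fit_transfer(task, replace(hyper_base, C=best["C"], tau=best["tau"],
                                           lam=best["lambda"]))
        dec = decision_function(model, Xte)
    else:
        raise ValueError(f"unknown method '{method}'")

    yhat = np.where(np.asarray(dec) >= 0, 1.0, -1.0)
    return confusion_metrics(yte, yhat, dec)


def run_experiment(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Config-driven comparison across methods, seeds, and calibration sizes.

    The config (YAML path or dict) specifies the synthetic task spec,
    methods, n_labeled list, seeds, and reduced hyperparameter grids.
    Emits per-metric CSV tables (rows = methods, columns = seeds + Avg),
    a t-test table of KL-SMM against each other method, a
    lambda-sensitivity table, and a JSON run manifest.
    """
    import yaml

    from .synthetic import SyntheticTaskSpec, make_transfer_task

    if not isinstance(config, dict):
        config_path = Path(config)
        config = yaml.safe_load(config_path.read_text())
    cfg = dict(config)
    out = Path(out_dir or cfg.get("out", "smmtransfer_report"))
    out.mkdir(parents=True, exist_ok=True)

    task_cfg = cfg.get("task", {})
    methods = cfg.get("methods", ["SVM", "SMM", "ASVM", "KL-SMM"])
    n_labeled_list = cfg.get("n_labeled", [8, 14, 20])
    seeds = cfg.get("seeds", list(range(5)))
    grid = GridSpec(
        C_grid=tuple(cfg.get("C_grid", [1e-2, 1e0])),
        tau_grid=tuple(cfg.get("tau_grid", [1e-3, 1e-1])),
        lambda_grid=tuple(cfg.get("lambda_grid", DEFAULT_LAMBDA_GRID)),
        n_folds=int(cfg.get("n_folds", 5)),
        seed=int(cfg.get("cv_seed", 0)),
    )
    hyper_base = Hyperparams(**cfg.get("hyper", {}))

    records = []
    for seed in seeds:
        spec = SyntheticTaskSpec(**{**task_cfg, "seed": int(seed)})
        task_full = make_transfer_task(spec)
        for n_lab in n_labeled_list:
            task = TransferTask(task_full.source_model, task_full.target_train,
                                task_full.target_test, n_labeled=int(n_lab))
            for method in methods:
                rep = _method_fit_predict(method, task, grid, hyper_base)
                records.append({"seed": seed, "n_labeled": n_lab, "method": method,
                                "ACC": rep.ACC, "AUC": rep.AUC, "F1": rep.F1})
    long = pd.DataFrame(records)
    long.to_csv(out / "metrics_long.csv", index=False)

    for metric in ("ACC", "AUC", "F1"):
        for n_lab in n_labeled_list:
            sub = long[long.n_labeled == n_lab].pivot(index="method", columns="seed",
                                                      values=metric)
            sub["Avg."] = sub.mean(axis=1)
            sub.to_csv(out / f"{metric.lower()}_n{n_lab}.csv")

    if "KL-SMM" in methods and len(seeds) >= 2:
        rows = []
        for n_lab in n_labeled_list:
            sub = long[long.n_labeled == n_lab].pivot(index="method", columns="seed",
                                                      values="ACC")
            for other in methods:
                if other == "KL-SMM":
                    continue
                t, p, degen = paired_ttest(sub.loc["KL-SMM"].values, sub.loc[other].values)
                rows.append({"n_labeled": n_lab, "comparison": f"KL-SMM vs. {other}",
                             "t": t, "p": p, "degenerate": degen})
        pd.DataFrame(rows).to_csv(out / "ttest_acc.csv", index=False)

    sens_cfg = cfg.get("lambda_sensitivity", {})
    if sens_cfg.get("enabled", True):
        spec = SyntheticTaskSpec(**{**task_cfg, "seed": int(seeds[0])})
        task = make_transfer_task(spec, n_labeled=int(n_labeled_list[0]))
        table = lambda_sensitivity(task, hyper_base, list(grid.lambda_grid))
        table.to_csv(out / "lambda_sensitivity.csv", index=False)

    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "seeds": list(seeds),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("experiment report written to %s", out)
    return out
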