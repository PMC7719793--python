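"""Cross-subject model-parameter transfer workflow.

Fit a plain SMM on the source subject, then fit the knowledge-leverage
SMM on a handful of labeled target trials, regularizing toward the
source regression matrix W_s.  Only W_s crosses the subject boundary —
never the source recordings — which is what affords privacy protection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .smm import (FittedMatrixModel, Hyperparams, MatrixDataset, decision_function,
                  fit, predict)

__all__ = ["TransferTask", "fit_source", "fit_transfer", "select_lambda_cv",
           "lambda_sensitivity"]


@dataclass
class TransferTask:
    """A source model plus target train/test splits.

    ``n_labeled`` selects the first-k prefix of ``target_train`` used for
    fitting (emulating a short calibration session); it must leave at
    least two trials with both classes present.
    """

    source_model: FittedMatrixModel
    target_train: MatrixDataset
    target_test: MatrixDataset
    n_labeled: int

    def __post_init__(self):
        if self.source_model.W.shape != (self.target_train.p, self.target_train.q):
            raise ValueError("source model shape does not match target trials")
        if self.n_labeled < 2 or self.n_labeled > len(self.target_train):
            raise ValueError("n_labeled must be in [2, len(target_train)]")
        labels = {self.target_train.trials[i].label for i in range(self.n_labeled)}
        if len(labels - {None}) < 2:
            raise ValueError("the first n_labeled target trials must contain both classes")

    def labeled_train(self) -> MatrixDataset:
        return self.target_train.subset(range(self.n_labeled))


def fit_source(source_data: MatrixDataset, hyper: Hyperparams) -> FittedMatrixModel:
    """Fit the source-subject SMM (plain, lam = 0)."""
    if hyper.lam != 0:
        hyper = replace(hyper, lam=0.0)
    return fit(source_data, hyper, W_source=None)


def fit_transfer(task: TransferTask, hyper: Hyperparams) -> FittedMatrixModel:
    """Fit the target classifier leveraging only the source matrix W_s."""
    return fit(task.labeled_train(), hyper, W_source=task.source_model.W)


def select_lambda_cv(
    task: TransferTask,
    hyper_base: Hyperparams,
    lambda_grid: list[float],
    seed: int = 0,
) -> float:
    """Pick the transfer weight by CV accuracy on the labeled target prefix.

    Folds are stratified 5-fold, reduced to the smallest class count and
    ultimately to leave-one-out when the calibration set is tiny; ties
    break toward the smallest lambda (least reliance on the source).
    """
    from .evaluation import _fold_indices  # shared fold policy

    train = task.labeled_train()
    X, y = train.labeled()
    folds = _fold_indices(y, 5, seed)
    best, best_acc = None, -np.inf
    for lam in sorted(lambda_grid):
        accs = []
        for tr, te in folds:
            try:
                model = fit(train.subset(tr), replace(hyper_base, lam=float(lam)),
                            task.source_model.W)
            except ValueError:
                continue
            accs.append(float(np.mean(predict(model, X[te]) == y[te])))
        if accs and np.mean(accs) > best_acc + 1e-12:
            best_acc, best = float(np.mean(accs)), float(lam)
    if best is None:
        raise RuntimeError("every cross-validation fold failed")
    return best


def lambda_sensitivity(
    task: TransferTask,
    hyper_base: Hyperparams,
    lambda_grid: list[float],
) -> pd.DataFrame:
    """One transfer fit per lambda; report test accuracy and ||W_t - W_s||_F.

    Columns: ``lambda``, ``acc``, ``w_dist``.  Data and splits are fixed,
    so the profile isolates the effect of the transfer weight.
    """
    if not lambda_grid:
        raise ValueError("lambda grid must be non-empty")
    Xte, yte = task.target_test.labeled()
    Ws = task.source_model.W
    rows = []
    for lam in lambda_grid:
        model = fit_transfer(task, replace(hyper_base, lam=float(lam)))
        yhat = predict(model, Xte)
        rows.append({
            "lambda": float(lam),
            "acc": float(np.mean(yhat == yte)),
            "w_dist": float(np.linalg.norm(model.W - Ws, "fro")),
        })
    return pd.DataFrame(rows)
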