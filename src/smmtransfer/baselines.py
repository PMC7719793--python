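"""Vector-space reference classifiers.

A soft-margin linear SVM on row-major-vectorized trials (the no-transfer
baseline and the tau=0, lam=0 oracle of the matrix machine) and an
ASVM-style adaptive SVM that learns a perturbation on top of a frozen
source decision function.  Both run on the shared box-constraint dual QP
solver.

The adaptive SVM here uses the classical perturbation form

    f(x) = lam_A * f_s(x) + w_delta . x + b,
    min  1/2 ||w_delta||^2 + C * sum_i hinge(y_i * f(x_i)),

where ``lam_A`` scales how much of the source decision is trusted; the
exact placement of the transfer knob varies across the ASVM literature,
and this choice (scaling the source decision) is the one implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .qp import DualQP, solve_box_eq_qp
from .smm import MatrixDataset, _encode_labels

__all__ = [
    "VectorDataset",
    "vectorize",
    "LinearSVMModel",
    "fit_linear_svm",
    "ASVMModel",
    "fit_asvm",
]


@dataclass(frozen=True)
class VectorDataset:
    """Row-major flattening of a matrix dataset: vectors (N, p*q), labels +/-1."""

    vectors: np.ndarray
    labels: np.ndarray
    p: int
    q: int

    def __post_init__(self):
        if self.vectors.ndim != 2 or self.labels.shape != (self.vectors.shape[0],):
            raise ValueError("vectors must be (N, d) with matching labels")


def vectorize(data: MatrixDataset) -> VectorDataset:
    """Flatten each p x q trial row-major; tr(W^T X) = vec(W) . vec(X)."""
    X, y_raw = data.labeled()
    if set(np.unique(y_raw)) <= {-1.0, 1.0}:
        y = y_raw
    else:
        y, _ = _encode_labels(y_raw)
    return VectorDataset(X.reshape(X.shape[0], -1), y, data.p, data.q)


@dataclass
class LinearSVMModel:
    w: np.ndarray
    b: float
    alpha: np.ndarray
    kkt_residual: float

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return x @ self.w + self.b

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(x) >= 0, 1.0, -1.0)


def _bias_from_margin(alpha: np.ndarray, y: np.ndarray, raw_dec: np.ndarray, C: float) -> float:
    """Average b over on-margin support vectors, with fallbacks."""
    eps = 1e-8 * C
    margin = np.where((alpha > eps) & (alpha < C - eps))[0]
    active = np.where(alpha > eps)[0]
    idx = margin if margin.size else (active if active.size else np.arange(len(y)))
    return float(np.mean(y[idx] - raw_dec[idx]))


def fit_linear_svm(data: VectorDataset | MatrixDataset, C: float) -> LinearSVMModel:
    """Soft-margin linear SVM: min 1/2||w||^2 + C sum ξ via the shared dual QP."""
    if isinstance(data, MatrixDataset):
        data = vectorize(data)
    x, y = data.vectors, data.labels
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    K = np.outer(y, y) * (x @ x.T)
    H = np.ones(len(y))
    sol = solve_box_eq_qp(DualQP(K=K, H=H, Y=y, C=C), raise_on_failure=False)
    w = x.T @ (sol.alpha * y)
    b = _bias_from_margin(sol.alpha, y, x @ w, C)
    return LinearSVMModel(w=w, b=b, alpha=sol.alpha, kkt_residual=sol.kkt_residual)


@dataclass
class ASVMModel:
    w_delta: np.ndarray
    b: float
    lam_A: float
    source_decision: Callable[[np.ndarray], np.ndarray]
    alpha: np.ndarray
    kkt_residual: float

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        fs = np.asarray(self.source_decision(x), dtype=float).ravel()
        return self.lam_A * fs + x @ self.w_delta + self.b

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(x) >= 0, 1.0, -1.0)


def fit_asvm(
    source_decision: Callable[[np.ndarray], np.ndarray],
    data: VectorDataset | MatrixDataset,
    C: float,
    lam_A: float,
) -> ASVMModel:
    """Adaptive SVM: perturb a frozen source decision function.

    Dual of the perturbation problem: K_ij = y_i y_j x_i.x_j and
    h_i = 1 - lam_A * y_i * f_s(x_i); lam_A = 0 reduces exactly to the
    plain linear SVM.
    """
    if isinstance(data, MatrixDataset):
        data = vectorize(data)
    x, y = data.vectors, data.labels
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    fs = np.asarray(source_decision(x), dtype=float).ravel()
    K = np.outer(y, y) * (x @ x.T)
    H = 1.0 - lam_A * y * fs
    sol = solve_box_eq_qp(DualQP(K=K, H=H, Y=y, C=C), raise_on_failure=False)
    w = x.T @ (sol.alpha * y)
    b = _bias_from_margin(sol.alpha, y, lam_A * fs + x @ w, C)
    return ASVMModel(w_delta=w, b=b, lam_A=lam_A, source_decision=source_decision,
                     alpha=sol.alpha, kkt_residual=sol.kkt_residual)
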