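"""Support matrix machine (SMM) and its knowledge-leverage transfer variant.

The classifier on a p-by-q trial matrix X is f(X) = tr(W^T X) + b with a
matrix of regression coefficients W regularized by the spectral elastic
net (squared Frobenius norm + tau * nuclear norm) and fit with the hinge
loss.  A transfer term ``lam * ||W_s - W||_F^2`` pulls W toward a source
subject's fitted matrix W_s, using only the source *model* — never the
source data — so cross-subject knowledge is leveraged without exposing
raw recordings.

Training splits the objective with an auxiliary matrix S constrained to
equal W and runs ADMM:

* (W, b) step — a box-constrained dual QP over the hinge multipliers,
  after which ``W = (Lambda + rho*S + 2*lam*W_s + sum_i alpha_i y_i X_i)
  / (2*lam + rho + 1)`` and b is averaged over the on-margin support set;
* S step — singular value thresholding, ``S = (1/rho) * svt(rho*W -
  Lambda, tau)``;
* multiplier step — ``Lambda += rho * (S - W)``.

Setting ``lam = 0`` recovers the plain SMM; ``tau = 0`` makes the model a
linear SVM on vectorized trials (the Frobenius inner product equals the
dot product of the flattened matrices).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .linalg import svt
from .qp import DualQP, DualSolution, solve_box_eq_qp

__all__ = [
    "TrialMatrix",
    "MatrixDataset",
    "Hyperparams",
    "FittedMatrixModel",
    "ADMMState",
    "build_dual_coefficients",
    "update_W_b",
    "update_S",
    "update_multiplier",
    "fit",
    "objective",
    "decision_function",
    "predict",
    "save_model",
    "load_model",
]

logger = logging.getLogger("smmtransfer")


# ----------------------------------------------------------------------
# data containers
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TrialMatrix:
    """One labeled (or unlabeled) p-by-q trial feature matrix."""

    values: np.ndarray
    label: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("trial values must be a p x q matrix with p, q >= 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("trial values contain non-finite entries")
        object.__setattr__(self, "values", v)


class MatrixDataset:
    """Ordered collection of trial matrices sharing a common (p, q) shape."""

    def __init__(self, trials: list[TrialMatrix]):
        if not trials:
            raise ValueError("dataset must contain at least one trial")
        shapes = {t.values.shape for t in trials}
        if len(shapes) != 1:
            raise ValueError(f"all trials must share one shape, got {sorted(shapes)}")
        self.trials = list(trials)
        self.p, self.q = trials[0].values.shape

    @classmethod
    def from_arrays(cls, X: np.ndarray, y: np.ndarray | None = None) -> "MatrixDataset":
        """Build from a stacked (N, p, q) array and optional labels."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must have shape (N, p, q)")
        if y is None:
            return cls([TrialMatrix(x) for x in X])
        y = np.asarray(y).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        return cls([TrialMatrix(x, float(lab)) for x, lab in zip(X, y)])

    @property
    def N(self) -> int:
        """Number of labeled trials."""
        return sum(1 for t in self.trials if t.label is not None)

    def __len__(self) -> int:
        return len(self.trials)

    def labeled(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (N, p, q) labeled values and their raw labels."""
        lab = [t for t in self.trials if t.label is not None]
        if not lab:
            raise ValueError("dataset has no labeled trials")
        X = np.stack([t.values for t in lab])
        y = np.array([t.label for t in lab], dtype=float)
        return X, y

    def subset(self, idx) -> "MatrixDataset":
        idx = np.asarray(idx)
        return MatrixDataset([self.trials[int(i)] for i in idx])


@dataclass(frozen=True)
class Hyperparams:
    """Training knobs.

    C : hinge weight (misfit vs. model complexity); tau : nuclear-norm
    weight encouraging low rank; lam : transfer weight pulling W toward
    the source matrix; rho : ADMM penalty (kept fixed over iterations);
    eta : restart threshold of the accelerated solver, in (0, 1).
    """

    C: float = 1.0
    tau: float = 0.0
    lam: float = 0.0
    rho: float = 1.0
    max_iter: int = 500
    tol_primal: float = 1e-4
    tol_obj: float = 1e-6
    accelerated: bool = False
    eta: float = 0.999

    def __post_init__(self):
        if self.C <= 0 or self.rho <= 0:
            raise ValueError("C and rho must be positive")
        if self.tau < 0 or self.lam < 0:
            raise ValueError("tau and lam must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.tol_primal <= 0 or self.tol_obj <= 0:
            raise ValueError("tolerances must be positive")
        if not (0.0 < self.eta < 1.0):
            raise ValueError("eta must lie in (0, 1)")


@dataclass
class ADMMState:
    """Iterates of the ADMM split; primal_residual = ||S - W||_F."""

    W: np.ndarray
    b: float
    S: np.ndarray
    Lambda: np.ndarray
    k: int = 0
    v: float = 1.0
    S_hat: np.ndarray | None = None
    Lambda_hat: np.ndarray | None = None
    primal_residual: float = np.inf


@dataclass
class FittedMatrixModel:
    """Fitted classifier: decision f(X) = tr(W^T X) + b."""

    W: np.ndarray
    b: float
    hyper: Hyperparams
    converged: bool = True
    n_iter: int = 0
    support_set: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    objective_trace: list[float] = field(default_factory=list)
    classes: tuple[float, float] = (1.0, -1.0)  # (mapped +1, mapped -1)
    W_source: np.ndarray | None = None
    kkt_residual: float = 0.0
    stationarity_residual: float = 0.0
    primal_residual: float = 0.0
    source_distance: float | None = None  # ||W - W_s||_F when transferring


# ----------------------------------------------------------------------
# label handling
# ----------------------------------------------------------------------

def _encode_labels(y: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Map two arbitrary label values onto {+1, -1} (first-seen order).

    Native {-1, +1} labels keep their sign.  Returns the signed labels and
    the (positive, negative) original values for decoding predictions.
    """
    vals = list(dict.fromkeys(y.tolist()))  # first-seen unique order
    if len(vals) == 1:
        raise ValueError("training data contains a single class")
    if len(vals) > 2:
        raise ValueError(f"expected binary labels, got {len(vals)} classes")
    if set(vals) == {-1.0, 1.0}:
        pos, neg = 1.0, -1.0
    else:
        pos, neg = vals[0], vals[1]
    signed = np.where(y == pos, 1.0, -1.0)
    return signed, (pos, neg)


# ----------------------------------------------------------------------
# ADMM building blocks
# ----------------------------------------------------------------------

def build_dual_coefficients(
    X: "np.ndarray | MatrixDataset",
    y: np.ndarray | None,
    Lambda: np.ndarray,
    S: np.ndarray,
    W_source: np.ndarray | None,
    lam: float,
    rho: float,
    C: float,
) -> DualQP:
    """Assemble the dual QP of the (W, b) subproblem.

    K_ij = y_i y_j tr(X_i^T X_j) / (2*lam + rho + 1)
    h_i  = 1 - y_i tr[(Lambda + rho*S + 2*lam*W_s)^T X_i] / (2*lam + rho + 1)

    ``X`` may be a stacked (N, p, q) array with signed labels ``y``, or a
    labeled MatrixDataset (then ``y`` is ignored).
    """
    if isinstance(X, MatrixDataset):
        X, y_raw = X.labeled()
        y, _ = _encode_labels(y_raw)
    if lam > 0:
        if W_source is None:
            raise ValueError("lam > 0 requires a source matrix W_source")
        if W_source.shape != X.shape[1:]:
            raise ValueError(
                f"source matrix shape {W_source.shape} does not match trials {X.shape[1:]}"
            )
    denom = 2.0 * lam + rho + 1.0
    Xv = X.reshape(X.shape[0], -1)
    G = Xv @ Xv.T  # Gram matrix of vectorized trials: tr(X_i^T X_j)
    K = (np.outer(y, y) * G) / denom
    M = Lambda + rho * S
    if lam > 0 and W_source is not None:
        M = M + 2.0 * lam * W_source
    H = 1.0 - y * (Xv @ M.ravel()) / denom
    return DualQP(K=K, H=H, Y=y, C=C)


def update_W_b(
    X: np.ndarray,
    y: np.ndarray,
    state: ADMMState,
    hyper: Hyperparams,
    W_source: np.ndarray | None,
    alpha0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, DualSolution]:
    """One (W, b) step: solve the dual QP, rebuild W, average b over the margin set."""
    lam, rho, C = hyper.lam, hyper.rho, hyper.C
    S = state.S_hat if state.S_hat is not None else state.S
    Lam = state.Lambda_hat if state.Lambda_hat is not None else state.Lambda
    problem = build_dual_coefficients(X, y, Lam, S, W_source, lam, rho, C)
    sol = solve_box_eq_qp(problem, tol=1e-8, max_iter=10_000, alpha0=alpha0,
                          raise_on_failure=False)
    alpha = sol.alpha

    denom = 2.0 * lam + rho + 1.0
    W = Lam + rho * S + np.einsum("i,ijk->jk", alpha * y, X)
    if lam > 0 and W_source is not None:
        W = W + 2.0 * lam * W_source
    W = W / denom

    # b averaged over on-margin vectors; printed support set {0<=a<=C} is
    # degenerate, so fall back: margin -> active -> all trials
    eps = 1e-8 * C
    margin = np.where((alpha > eps) & (alpha < C - eps))[0]
    active = np.where(alpha > eps)[0]
    if margin.size:
        delta = margin
    elif active.size:
        delta = active
        logger.warning("no on-margin support vectors; averaging b over active set")
    else:
        delta = np.arange(len(y))
        logger.warning("empty support set; averaging b over all trials")
    dec = np.einsum("jk,ijk->i", W, X)
    b = float(np.mean(y[delta] - dec[delta]))
    return W, b, delta, alpha, sol


def update_S(W: np.ndarray, Lambda: np.ndarray, tau: float, rho: float) -> np.ndarray:
    """S step: minimize tau*||S||_* + tr(Lambda^T S) + rho/2 * ||S - W||_F^2.

    Closed form (1/rho) * svt(rho*W - Lambda, tau); the 1/rho factor comes
    from the optimality condition of the proximal objective.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    return svt(rho * W - Lambda, tau) / rho


def update_multiplier(Lambda: np.ndarray, S: np.ndarray, W: np.ndarray, rho: float) -> np.ndarray:
    """Dual ascent on the consensus constraint: Lambda + rho * (S - W)."""
    return Lambda + rho * (S - W)


def objective(
    X: np.ndarray,
    y: np.ndarray,
    W: np.ndarray,
    b: float,
    hyper: Hyperparams,
    W_source: np.ndarray | None = None,
) -> float:
    """Primal objective: spectral elastic net + hinge + optional transfer term."""
    from .linalg import nuclear_norm

    dec = np.einsum("jk,ijk->i", W, X) + b
    hinge = np.maximum(0.0, 1.0 - y * dec).sum()
    val = 0.5 * float(np.sum(W * W)) + hyper.tau * nuclear_norm(W) + hyper.C * hinge
    if W_source is not None and hyper.lam > 0:
        diff = W_source - W
        val += hyper.lam * float(np.sum(diff * diff))
    return float(val)


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def fit(
    data: MatrixDataset,
    hyper: Hyperparams,
    W_source: np.ndarray | None = None,
) -> FittedMatrixModel:
    """Fit the (KL-)SMM by ADMM.

    With ``hyper.lam == 0`` this is the plain SMM; with ``lam > 0`` the
    transfer term requires ``W_source``.  Plain mode alternates the three
    updates; accelerated mode extrapolates (S, Lambda) Nesterov-style with
    an eta-triggered restart, reaching the same optimum.
    """
    X, y_raw = data.labeled()
    y, classes = _encode_labels(y_raw)
    if hyper.lam > 0 and W_source is None:
        raise ValueError("transfer weight lam > 0 requires W_source")
    if W_source is not None:
        W_source = np.asarray(W_source, dtype=float)
        if W_source.shape != (data.p, data.q):
            raise ValueError("W_source shape does not match the trials")

    p, q = data.p, data.q
    zeros = np.zeros((p, q))
    state = ADMMState(W=zeros.copy(), b=0.0, S=zeros.copy(), Lambda=zeros.copy())
    if hyper.accelerated:
        state.S_hat = zeros.copy()
        state.Lambda_hat = zeros.copy()

    trace: list[float] = []
    alpha_prev: np.ndarray | None = None
    converged = False
    stationarity = np.inf
    kkt = np.inf
    delta = np.arange(len(y))
    S_prev, Lam_prev = state.S.copy(), state.Lambda.copy()
    c_prev = np.inf
    W_s_term = W_source if hyper.lam > 0 else None

    for k in range(1, hyper.max_iter + 1):
        W, b, delta, alpha, sol = update_W_b(X, y, state, hyper, W_s_term, alpha_prev)
        alpha_prev = alpha
        kkt = sol.kkt_residual

        # stationarity of the closed-form W update against the state it used
        S_used = state.S_hat if state.S_hat is not None else state.S
        Lam_used = state.Lambda_hat if state.Lambda_hat is not None else state.Lambda
        resid = (2.0 * hyper.lam + hyper.rho + 1.0) * W - Lam_used - hyper.rho * S_used \
            - np.einsum("i,ijk->jk", alpha * y, X)
        if W_s_term is not None:
            resid = resid - 2.0 * hyper.lam * W_s_term
        stationarity = float(np.linalg.norm(resid, "fro"))

        Lam_for_S = state.Lambda_hat if state.Lambda_hat is not None else state.Lambda
        S_new = update_S(W, Lam_for_S, hyper.tau, hyper.rho)
        Lam_new = update_multiplier(Lam_for_S, S_new, W, hyper.rho)

        if hyper.accelerated:
            c_k = (np.linalg.norm(Lam_new - state.Lambda_hat, "fro") ** 2 / hyper.rho
                   + hyper.rho * np.linalg.norm(S_new - state.S_hat, "fro") ** 2)
            if c_k < hyper.eta * c_prev:
                v_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * state.v ** 2))
                w_mom = (state.v - 1.0) / v_next
                state.S_hat = S_new + w_mom * (S_new - S_prev)
                state.Lambda_hat = Lam_new + w_mom * (Lam_new - Lam_prev)
                state.v = v_next
                c_prev = c_k
                S_prev, Lam_prev = S_new, Lam_new
            else:  # restart: drop momentum, fall back to the last accepted point
                state.v = 1.0
                state.S_hat = S_prev.copy()
                state.Lambda_hat = Lam_prev.copy()
                c_prev = c_prev / hyper.eta
        else:
            S_prev, Lam_prev = S_new, Lam_new

        state.W, state.b, state.S, state.Lambda, state.k = W, b, S_new, Lam_new, k
        state.primal_residual = float(np.linalg.norm(S_new - W, "fro"))

        obj = objective(X, y, W, b, hyper, W_s_term)
        trace.append(obj)

        tol_p = hyper.tol_primal * max(1.0, float(np.linalg.norm(W, "fro")))
        rel_dobj = (abs(trace[-2] - trace[-1]) / max(1.0, abs(trace[-2]))
                    if len(trace) > 1 else np.inf)
        if state.primal_residual <= tol_p and rel_dobj <= hyper.tol_obj:
            converged = True
            break

    if not converged:
        logger.warning("ADMM did not converge within %d iterations "
                       "(primal residual %.3e)", hyper.max_iter, state.primal_residual)

    model = FittedMatrixModel(
        W=state.W, b=state.b, hyper=hyper, converged=converged, n_iter=state.k,
        support_set=delta, objective_trace=trace, classes=classes,
        W_source=W_source if hyper.lam > 0 else None,
        kkt_residual=float(kkt), stationarity_residual=stationarity,
        primal_residual=state.primal_residual,
    )
    if W_source is not None and hyper.lam > 0:
        model.source_distance = float(np.linalg.norm(state.W - W_source, "fro"))
    return model


# ----------------------------------------------------------------------
# prediction
# ----------------------------------------------------------------------

def _trial_values(X) -> np.ndarray:
    if isinstance(X, TrialMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def decision_function(model: FittedMatrixModel, X) -> float | np.ndarray:
    """f(X) = tr(W^T X) + b.  Accepts one matrix or a stacked (N, p, q) array."""
    V = _trial_values(X)
    if V.ndim == 2:
        if V.shape != model.W.shape:
            raise ValueError(f"trial shape {V.shape} does not match model {model.W.shape}")
        return float(np.sum(model.W * V) + model.b)
    if V.ndim == 3:
        if V.shape[1:] != model.W.shape:
            raise ValueError(f"trial shape {V.shape[1:]} does not match model {model.W.shape}")
        return np.einsum("jk,ijk->i", model.W, V) + model.b
    raise ValueError("expected a p x q matrix or an (N, p, q) stack")


def predict(model: FittedMatrixModel, X) -> float | np.ndarray:
    """Class label; a decision value of exactly 0 maps to the positive class."""
    dec = decision_function(model, X)
    pos, neg = model.classes
    if np.isscalar(dec):
        return pos if dec >= 0 else neg
    return np.where(np.asarray(dec) >= 0, pos, neg)


# ----------------------------------------------------------------------
# model archive (plain-text JSON)
# ----------------------------------------------------------------------

def save_model(model: FittedMatrixModel, path: str | Path) -> None:
    """Write the model as a JSON archive: named arrays + metadata record."""
    doc = {
        "format": "smmtransfer-model",
        "version": 1,
        "arrays": {
            "W": model.W.tolist(),
            **({"W_source": model.W_source.tolist()} if model.W_source is not None else {}),
        },
        "metadata": {
            "b": model.b,
            "hyper": asdict(model.hyper),
            "classes": list(model.classes),
            "converged": model.converged,
            "n_iter": model.n_iter,
            "support_set": model.support_set.tolist(),
            "objective_trace": model.objective_trace,
            "kkt_residual": model.kkt_residual,
            "stationarity_residual": model.stationarity_residual,
            "primal_residual": model.primal_residual,
            "source_distance": model.source_distance,
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> FittedMatrixModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "smmtransfer-model":
        raise ValueError(f"{path} is not a model archive")
    meta = doc["metadata"]
    ws = doc["arrays"].get("W_source")
    return FittedMatrixModel(
        W=np.array(doc["arrays"]["W"], dtype=float),
        b=float(meta["b"]),
        hyper=Hyperparams(**meta["hyper"]),
        converged=bool(meta["converged"]),
        n_iter=int(meta["n_iter"]),
        support_set=np.array(meta["support_set"], dtype=int),
        objective_trace=list(meta["objective_trace"]),
        classes=tuple(meta["classes"]),
        W_source=None if ws is None else np.array(ws, dtype=float),
        kkt_residual=float(meta["kkt_residual"]),
        stationarity_residual=float(meta["stationarity_residual"]),
        primal_residual=float(meta["primal_residual"]),
        source_distance=meta["source_distance"],
    )
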