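"""Box-constrained, single-equality-constraint dual quadratic program.

Solves  max_alpha  -1/2 a^T K a + H^T a   s.t.  0 <= a <= C,  a^T Y = 0,
the dual of the (W, b) subproblem of the support matrix machine, by
SMO-style pairwise coordinate ascent on the maximal-KKT-violating pair.
The equality constraint is preserved exactly by every pairwise step, so
alpha = 0 feasibility makes the problem always solvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DualQP", "DualSolution", "SolverFailure", "solve_box_eq_qp", "kkt_residual"]


@dataclass(frozen=True)
class DualQP:
    """Problem data: K symmetric PSD, linear term H, labels Y in {-1,+1}, box bound C."""

    K: np.ndarray
    H: np.ndarray
    Y: np.ndarray
    C: float

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        H = np.asarray(self.H, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        n = K.shape[0]
        if H.shape != (n,) or Y.shape != (n,):
            raise ValueError("H and Y must be length-N vectors matching K")
        if not np.allclose(K, K.T, atol=1e-10 * max(1.0, np.abs(K).max())):
            raise ValueError("K must be symmetric")
        if not np.all(np.abs(np.abs(Y) - 1.0) < 1e-12):
            raise ValueError("labels must be +/-1")
        if not self.C > 0:
            raise ValueError("C must be positive")
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "Y", Y)

    @property
    def n(self) -> int:
        return self.K.shape[0]


@dataclass
class DualSolution:
    alpha: np.ndarray
    objective: float
    support_set: np.ndarray  # indices with alpha_i > eps
    kkt_residual: float
    n_iter: int = 0
    converged: bool = True


class SolverFailure(RuntimeError):
    """Raised when the ascent does not reach tolerance; carries the best iterate."""

    def __init__(self, message: str, solution: DualSolution):
        super().__init__(message)
        self.solution = solution


def _objective(problem: DualQP, alpha: np.ndarray) -> float:
    return float(-0.5 * alpha @ problem.K @ alpha + problem.H @ alpha)


def kkt_residual(problem: DualQP, alpha: np.ndarray, box_tol: float = 1e-8) -> float:
    """Max stationarity violation of the KKT system at alpha.

    With gradient g = H - K alpha and multiplier mu for the equality
    constraint, optimality requires for each i (writing c_i = g_i - mu*Y_i):
    interior -> c_i = 0; alpha_i = 0 -> c_i <= 0; alpha_i = C -> c_i >= 0.
    mu is chosen to minimize the max violation (the violation is convex
    piecewise-linear in mu, minimized by ternary search).
    """
    alpha = np.asarray(alpha, dtype=float)
    C = problem.C
    if np.any(alpha < -box_tol * max(1.0, C)) or np.any(alpha > C + box_tol * max(1.0, C)):
        raise ValueError("alpha outside the box beyond tolerance")
    g = problem.H - problem.K @ alpha
    eps = 1e-10 * max(1.0, C)
    at_lo = alpha <= eps
    at_hi = alpha >= C - eps

    def viol(mu: float) -> float:
        c = g - mu * problem.Y
        v = np.abs(c.copy())
        v[at_lo] = np.maximum(c[at_lo], 0.0)
        v[at_hi] = np.maximum(-c[at_hi], 0.0)
        both = at_lo & at_hi  # degenerate C ~ 0 box
        if np.any(both):
            v[both] = 0.0
        return float(v.max()) if v.size else 0.0

    # candidate mu values where pieces break: g_i * Y_i
    cands = g * problem.Y
    lo, hi = float(cands.min()) - 1.0, float(cands.max()) + 1.0
    for _ in range(200):  # ternary search on the convex envelope
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        if viol(m1) <= viol(m2):
            hi = m2
        else:
            lo = m1
    best = min(viol(0.5 * (lo + hi)), min(viol(float(c)) for c in cands))
    return best


def solve_box_eq_qp(
    problem: DualQP,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    alpha0: np.ndarray | None = None,
    raise_on_failure: bool = True,
) -> DualSolution:
    """Maximize the dual by maximal-violating-pair coordinate ascent.

    Deterministic: pair selection and steps depend only on the problem and
    the (optional) warm start.  A pairwise step moves alpha_i by +Y_i*t and
    alpha_j by -Y_j*t, which keeps alpha^T Y invariant.
    """
    n = problem.n
    C = problem.C
    K = problem.K
    Y = problem.Y

    # guard against slightly indefinite Gram matrices of near-duplicate trials
    diag_mean = np.trace(K) / max(n, 1)
    try:
        lam_min = float(np.linalg.eigvalsh(K)[0])
    except np.linalg.LinAlgError:  # pragma: no cover
        lam_min = -1.0
    if lam_min < -1e-8 * max(diag_mean, 1e-30):
        K = K + 1e-10 * np.eye(n)

    if alpha0 is None:
        alpha = np.zeros(n)
    else:
        alpha = np.clip(np.asarray(alpha0, dtype=float).copy(), 0.0, C)
        # warm starts must stay on the equality constraint; project crudely if not
        if abs(alpha @ Y) > 1e-12 * max(1.0, C * n):
            alpha = np.zeros(n)

    if n == 1:
        # alpha^T Y = 0 pins the single variable at 0
        a = np.zeros(1)
        return DualSolution(a, _objective(problem, a), np.array([], dtype=int), 0.0, 0, True)

    g = problem.H - K @ alpha  # gradient of the (maximization) objective
    eps_box = 1e-12 * max(1.0, C)

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d = Y * g  # directional derivative of moving alpha_k by +Y_k
        up = np.where(((Y > 0) & (alpha < C - eps_box)) | ((Y < 0) & (alpha > eps_box)))[0]
        dn = np.where(((Y > 0) & (alpha > eps_box)) | ((Y < 0) & (alpha < C - eps_box)))[0]
        if up.size == 0 or dn.size == 0:
            break
        i = up[np.argmax(d[up])]
        j = dn[np.argmin(d[dn])]
        gap = d[i] - d[j]
        if gap <= tol:
            break
        # step t >= 0: alpha_i += Y_i t, alpha_j -= Y_j t
        q = K[i, i] + K[j, j] - 2.0 * Y[i] * Y[j] * K[i, j]
        t_max_i = (C - alpha[i]) if Y[i] > 0 else alpha[i]
        t_max_j = alpha[j] if Y[j] > 0 else (C - alpha[j])
        t_max = min(t_max_i, t_max_j)
        if t_max <= 0:
            break  # numerically stuck; KKT check below decides
        t = t_max if q <= 1e-300 else min(gap / q, t_max)
        alpha[i] += Y[i] * t
        alpha[j] -= Y[j] * t
        np.clip(alpha, 0.0, C, out=alpha)
        g -= t * (Y[i] * K[:, i] - Y[j] * K[:, j])

    res = kkt_residual(problem, alpha)
    support = np.where(alpha > 1e-8 * C)[0]
    sol = DualSolution(alpha, _objective(problem, alpha), support, res, n_iter, res <= max(tol, 1e-8))
    if not sol.converged:
        # refresh gradient-based residual once with exact arithmetic before failing
        if raise_on_failure:
            raise SolverFailure(
                f"pairwise ascent did not reach tol={tol} within {max_iter} sweeps "
                f"(kkt residual {res:.3e})",
                sol,
            )
    return sol
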