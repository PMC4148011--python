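"""Sparse canonical correlation analysis (sCCA) and cross-modal prediction.

The model couples two edge-variable blocks X (subjects × p) and Y
(subjects × q) by maximizing  u^T X^T Y v  subject to ||u||_2 <= 1,
||v||_2 <= 1, ||u||_1 <= c1, ||v||_1 <= c2.  The criterion is biconvex:
with v fixed, the optimal u is the L2-normalized soft-thresholding of
X^T Y v, with the threshold found by bisection so the L1 bound binds (or
zero when it is slack), and symmetrically for v.  Alternating these
closed-form updates increases the objective monotonically.  Successive
components are obtained by rank-one deflation of the cross-product matrix.

Penalty bounds are chosen by a permutation scheme: the canonical
correlation obtained on the data is compared, on the Fisher z scale, with
its distribution over row-permuted copies of X, and the grid point with
the largest standardized gap wins.

Prediction maps a held-out subject's edge vector through the canonical
space: scores = (x - x̄) U, then ŷ = scores D V⁺ + ȳ, where D holds the
in-sample canonical correlations and V⁺ is the Moore–Penrose pseudoinverse
mapping canonical scores back to edge space (and symmetrically for x̂).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import EdgeDataset

__all__ = [
    "SccaModel",
    "soft_threshold",
    "scca_fit",
    "select_penalties",
    "predict_y_from_x",
    "predict_x_from_y",
    "default_penalty_grid",
]


def soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise soft-thresholding: sign(a) * max(|a| - delta, 0)."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _l1_constrained_unit(a: np.ndarray, c: float, tol: float = 1e-9) -> np.ndarray:
    """argmax_u a^T u  s.t. ||u||_2 <= 1, ||u||_1 <= c.

    Closed form: L2-normalized soft-threshold of ``a``, with the threshold
    delta found by bisection so the L1 constraint binds (delta = 0 when the
    unconstrained optimum already satisfies it).
    """
    abs_a = np.abs(a)
    norm_a = float(np.sqrt(abs_a @ abs_a))
    if norm_a == 0.0:
        return np.zeros_like(a)
    if float(abs_a.sum()) / norm_a <= c + 1e-12:
        return a / norm_a
    lo, hi = 0.0, float(abs_a.max())
    width0 = hi
    best = None
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        s = np.maximum(abs_a - mid, 0.0)
        ns = float(np.sqrt(s @ s))
        if ns == 0.0:
            hi = mid
            continue
        l1 = float(s.sum()) / ns
        if l1 > c:
            lo = mid
        else:
            hi = mid
            best = s / ns
            if c - l1 < tol:
                break
        if hi - lo < 1e-12 * width0:
            break
    if best is None:  # only the all-zero side was reached: keep largest entry
        j = int(np.argmax(abs_a))
        best = np.zeros_like(a)
        best[j] = 1.0
    return np.sign(a) * best


@dataclass
class SccaModel:
    """Fitted sparse-CCA solution: canonical vectors, correlations, means."""

    U: np.ndarray
    V: np.ndarray
    D: np.ndarray
    c1: float
    c2: float
    x_means: np.ndarray
    y_means: np.ndarray
    K: int
    iterations: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    objective_history: list[list[float]] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.U.shape[0]

    @property
    def q(self) -> int:
        return self.V.shape[0]

    def save(self, path) -> None:
        np.savez(
            path,
            U=self.U, V=self.V, D=self.D,
            c1=self.c1, c2=self.c2,
            x_means=self.x_means, y_means=self.y_means,
            K=self.K,
            iterations=np.asarray(self.iterations),
            converged=np.asarray(self.converged),
        )

    @classmethod
    def load(cls, path) -> "SccaModel":
        z = np.load(path)
        return cls(
            U=z["U"], V=z["V"], D=z["D"],
            c1=float(z["c1"]), c2=float(z["c2"]),
            x_means=z["x_means"], y_means=z["y_means"],
            K=int(z["K"]),
            iterations=list(z["iterations"]),
            converged=list(z["converged"].astype(bool)),
        )


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, EdgeDataset):
        return X.matrix
    return np.asarray(X, dtype=float)


class _CrossProduct:
    """The (deflated) cross-product X_c^T Y_c behind matrix-free products.

    For subjects n much smaller than the edge counts, storing X_c and Y_c
    and the rank-one deflation terms makes every matvec O(n(p+q) + Kp)
    instead of O(pq).
    """

    def __init__(self, Xc: np.ndarray, Yc: np.ndarray):
        self.Xc = Xc
        self.Yc = Yc
        self._G = Xc @ Xc.T  # (n, n) Gram, reused by col_sq_norms
        self.us: list[np.ndarray] = []
        self.vs: list[np.ndarray] = []
        self.ds: list[float] = []

    def mv(self, v: np.ndarray) -> np.ndarray:
        out = self.Xc.T @ (self.Yc @ v)
        for d, u_j, v_j in zip(self.ds, self.us, self.vs):
            out -= d * (v_j @ v) * u_j
        return out

    def rmv(self, u: np.ndarray) -> np.ndarray:
        out = self.Yc.T @ (self.Xc @ u)
        for d, u_j, v_j in zip(self.ds, self.us, self.vs):
            out -= d * (u_j @ u) * v_j
        return out

    def deflate(self, d: float, u: np.ndarray, v: np.ndarray) -> None:
        self.ds.append(d)
        self.us.append(u.copy())
        self.vs.append(v.copy())

    def col_sq_norms(self) -> np.ndarray:
        # diag(M^T M) with M = X^T Y - U diag(d) V^T, without forming M
        base = np.einsum("ij,ij->j", self.Yc, self._G @ self.Yc)
        if not self.ds:
            return base
        U = np.stack(self.us, axis=1)
        V = np.stack(self.vs, axis=1)
        d = np.asarray(self.ds)
        XU = self.Xc @ U  # (n, K)
        M0tU = self.Yc.T @ XU  # (q, K)
        cross = np.einsum("jk,jk->j", M0tU * d, V)
        UtU = U.T @ U
        low = np.einsum("jk,kl,jl->j", V * d, UtU, V * d)
        return base - 2.0 * cross + low

    def is_zero(self, tol: float = 0.0) -> bool:
        return bool(np.all(self.col_sq_norms() <= tol))


def _leading_right_singular(M: _CrossProduct, n_iter: int = 40) -> np.ndarray:
    """Deterministic leading right singular vector by power iteration."""
    col_norms = M.col_sq_norms()
    v = np.zeros(col_norms.size)
    v[int(np.argmax(col_norms))] = 1.0
    for _ in range(n_iter):
        w = M.rmv(M.mv(v))
        n = np.linalg.norm(w)
        if n == 0.0:
            return v
        w /= n
        if np.abs(w @ v) > 1.0 - 1e-10:
            return w
        v = w
    return v


def _rank(M: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(M))


def scca_fit(
    X,
    Y,
    c1: float,
    c2: float,
    K: int = 1,
    tol: float = 1e-7,
    max_iter: int = 200,
    seed: int | None = None,
) -> SccaModel:
    """Fit the penalized CCA model by alternating closed-form updates.

    ``c1`` must lie in [1, sqrt(p)] and ``c2`` in [1, sqrt(q)] (the
    feasible range of an L1 bound on a unit-L2 vector).  ``K`` is capped at
    the minimum rank of the centered blocks.  Initialization is the leading
    right singular vector of the (deflated) cross-product, so the fit is
    deterministic; ``seed`` is accepted for interface symmetry.
    """
    Xm = _as_matrix(X)
    Ym = _as_matrix(Y)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("X and Y must have the same number of subjects")
    n, p = Xm.shape
    q = Ym.shape[1]
    if not (1.0 - 1e-9 <= c1 <= np.sqrt(p) + 1e-9):
        raise ValueError(f"c1={c1} outside [1, sqrt(p)={np.sqrt(p):.3f}]")
    if not (1.0 - 1e-9 <= c2 <= np.sqrt(q) + 1e-9):
        raise ValueError(f"c2={c2} outside [1, sqrt(q)={np.sqrt(q):.3f}]")

    x_means = Xm.mean(axis=0)
    y_means = Ym.mean(axis=0)
    Xc = Xm - x_means
    Yc = Ym - y_means

    max_K = min(_rank(Xc), _rank(Yc))
    if K > max_K:
        warnings.warn(f"K={K} exceeds min rank {max_K}; reducing", stacklevel=2)
        K = max_K

    M = _CrossProduct(Xc, Yc)
    U = np.zeros((p, K))
    V = np.zeros((q, K))
    D = np.zeros(K)
    iterations, converged, histories = [], [], []

    n_components = 0
    for k in range(K):
        if M.is_zero(tol=1e-24):
            warnings.warn(
                f"cross-product exhausted after {k} components", stacklevel=2
            )
            break
        v = _leading_right_singular(M)
        u = np.zeros(p)
        obj_prev = -np.inf
        history: list[float] = []
        ok = False
        it = 0
        for it in range(1, max_iter + 1):
            u = _l1_constrained_unit(M.mv(v), c1)
            a_v = M.rmv(u)
            v = _l1_constrained_unit(a_v, c2)
            obj = float(a_v @ v)
            history.append(obj)
            if obj - obj_prev < tol * max(1.0, abs(obj)):
                ok = True
                break
            obj_prev = obj
        xs = Xc @ u
        ys = Yc @ v
        if np.linalg.norm(xs) == 0.0 or np.linalg.norm(ys) == 0.0:
            d_corr = 0.0
        else:
            d_corr = float(
                (xs @ ys) / (np.linalg.norm(xs) * np.linalg.norm(ys))
            )
        U[:, k] = u
        V[:, k] = v
        D[k] = d_corr
        iterations.append(it)
        converged.append(ok)
        histories.append(history)
        M.deflate(float(u @ M.mv(v)), u, v)
        n_components += 1

    U = U[:, :n_components]
    V = V[:, :n_components]
    D = D[:n_components]
    return SccaModel(
        U=U, V=V, D=D, c1=float(c1), c2=float(c2),
        x_means=x_means, y_means=y_means, K=n_components,
        iterations=iterations, converged=converged,
        objective_history=histories,
    )


def default_penalty_grid(p: int, q: int, n_points: int = 8):
    """Grid of (c1, c2) pairs at matched fractions {0.1 … 0.8} of sqrt(p), sqrt(q)."""
    fracs = np.linspace(0.1, 0.8, n_points)
    grid = []
    for f1 in fracs:
        for f2 in fracs:
            c1 = max(1.0, f1 * np.sqrt(p))
            c2 = max(1.0, f2 * np.sqrt(q))
            grid.append((float(c1), float(c2)))
    return grid


def _fisher_z(d: float) -> float:
    return float(np.arctanh(np.clip(d, -1 + 1e-12, 1 - 1e-12)))


def select_penalties(
    X,
    Y,
    grid,
    n_perm: int = 25,
    seed: int | None = None,
):
    """Permutation-based exhaustive search over a penalty grid.

    For each grid point the first canonical correlation on the data is
    compared with its null distribution over ``n_perm`` row permutations of
    X; the score is the standardized gap on the Fisher z scale, and the
    grid point with the largest score is returned together with a
    diagnostic table.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("penalty grid is empty")
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    Xm = _as_matrix(X)
    Ym = _as_matrix(Y)
    n = Xm.shape[0]
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_perm)]

    rows = []
    best_score = -np.inf
    best = grid[0]
    for c1, c2 in grid:
        d_obs = scca_fit(Xm, Ym, c1, c2, K=1).D
        z_obs = _fisher_z(float(d_obs[0]) if d_obs.size else 0.0)
        z_perm = np.empty(n_perm)
        for i, perm in enumerate(perms):
            d_p = scca_fit(Xm[perm], Ym, c1, c2, K=1).D
            z_perm[i] = _fisher_z(float(d_p[0]) if d_p.size else 0.0)
        sd = float(np.std(z_perm, ddof=1))
        score = -np.inf if sd == 0.0 else (z_obs - float(np.mean(z_perm))) / sd
        rows.append(
            dict(c1=c1, c2=c2, z_obs=z_obs,
                 z_perm_mean=float(np.mean(z_perm)), z_perm_sd=sd, score=score)
        )
        if score > best_score:
            best_score = score
            best = (c1, c2)
    return best[0], best[1], pd.DataFrame(rows)


def _predict(scores: np.ndarray, D: np.ndarray, W: np.ndarray,
             means: np.ndarray) -> np.ndarray:
    # scores (..., K) -> edge space via D then pinv of the canonical basis
    back = np.linalg.pinv(W)  # (K, dim)
    return (scores * D) @ back + means


def predict_y_from_x(model: SccaModel, x_row: np.ndarray) -> np.ndarray:
    """Predict the Y-side edge vector of an unseen subject from its X edges."""
    x = np.asarray(x_row, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.p:
        raise ValueError(f"x_row has {x.shape[1]} features, model expects {model.p}")
    scores = (x - model.x_means) @ model.U
    out = _predict(scores, model.D, model.V, model.y_means)
    return out[0] if squeeze else out


def predict_x_from_y(model: SccaModel, y_row: np.ndarray) -> np.ndarray:
    """Predict the X-side edge vector of an unseen subject from its Y edges."""
    y = np.asarray(y_row, dtype=float)
    squeeze = y.ndim == 1
    y = np.atleast_2d(y)
    if y.shape[1] != model.q:
        raise ValueError(f"y_row has {y.shape[1]} features, model expects {model.q}")
    scores = (y - model.y_means) @ model.V
    out = _predict(scores, model.D, model.U, model.x_means)
    return out[0] if squeeze else out
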