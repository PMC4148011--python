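"""Geometry of symmetric positive-definite (SPD) matrices.

Covariance and precision matrices live on the SPD cone, where the flat
(Frobenius) distance ignores curvature.  The affine-invariant Riemannian
metric

    d_AI(P, G) = || log(G^{-1/2} P G^{-1/2}) ||_F
              = sqrt( sum_i log^2 lambda_i ),   lambda_i = eig(G^{-1} P),

is the geodesic distance under the canonical invariant metric: it is
unchanged by congruence P -> A P A^T (any invertible A) and by joint matrix
inversion, which makes it equally meaningful for covariance and precision
matrices.

Because d_AI grows with matrix order, comparing networks of different sizes
requires an order normalization.  `calibrate_order_normalization` estimates,
by simulation, the median distance between independent Wishart-distributed
matrices as a function of order and fits a line to it; `normalized_dai`
divides a distance by the fitted value at the matrices' order, which is
approximately equivalent to dividing by the number of regions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import linalg


__all__ = [
    "check_spd",
    "repair_spd",
    "dai",
    "OrderCalibration",
    "calibrate_order_normalization",
    "normalized_dai",
]


def _as_symmetric(M: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=tol, rtol=0.0):
        raise ValueError("matrix is not symmetric")
    return 0.5 * (M + M.T)


def check_spd(M: np.ndarray, tol: float = 0.0) -> tuple[bool, float]:
    """Check positive definiteness of a symmetric matrix.

    Returns ``(flag, min_eigenvalue)`` with ``flag`` true iff the smallest
    eigenvalue exceeds ``tol``.
    """
    M = _as_symmetric(M)
    min_eig = float(linalg.eigvalsh(M)[0])
    return bool(min_eig > tol), min_eig


def repair_spd(M: np.ndarray, floor: float | None = None) -> tuple[np.ndarray, bool]:
    """Clip the spectrum of a symmetric matrix from below.

    Eigenvalues below ``floor`` are raised to ``floor`` and the matrix is
    reassembled.  ``floor`` defaults to ``1e-6`` times the largest
    eigenvalue (with an absolute fallback of 1e-12 for matrices whose
    spectrum is entirely non-positive).  Returns ``(repaired, changed)``;
    inputs that are already SPD at the floor pass through unchanged.
    """
    M = _as_symmetric(M)
    w, V = linalg.eigh(M)
    if floor is None:
        floor = max(1e-6 * float(w[-1]), 1e-12)
    if w[0] > floor:
        return M, False
    w_clipped = np.maximum(w, floor)
    repaired = (V * w_clipped) @ V.T
    return 0.5 * (repaired + repaired.T), True


def _require_spd(M: np.ndarray, name: str) -> np.ndarray:
    M = _as_symmetric(M)
    ok, min_eig = check_spd(M)
    if not ok:
        raise ValueError(f"{name} is not SPD (min eigenvalue {min_eig:.3e})")
    return M


def dai(P: np.ndarray, G: np.ndarray) -> float:
    """Affine-invariant geodesic distance between two SPD matrices.

    Computed from the generalized eigenvalues of the pencil ``(P, G)``,
    which equal the eigenvalues of ``G^{-1/2} P G^{-1/2}``; this avoids
    explicit matrix square roots and logarithms.
    """
    P = _require_spd(P, "P")
    G = _require_spd(G, "G")
    if P.shape != G.shape:
        raise ValueError(f"order mismatch: {P.shape[0]} vs {G.shape[0]}")
    w = linalg.eigh(P, G, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


@dataclass
class OrderCalibration:
    """Line fit of median Wishart-pair distance against matrix order."""

    slope: float
    intercept: float
    orders: list[int] = field(default_factory=list)
    medians: list[float] = field(default_factory=list)
    fit_r2: float = float("nan")
    dof_rule: str = "2*order"
    n_pairs: int = 0
    seed: int | None = None

    def divisor(self, order: int) -> float:
        return self.slope * order + self.intercept

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "OrderCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def calibrate_order_normalization(
    orders,
    n_pairs: int = 100,
    dof_rule=None,
    seed: int | None = None,
) -> OrderCalibration:
    """Simulate how d_AI scales with matrix order and fit a line to it.

    For each order, ``n_pairs`` pairs of Wishart-distributed SPD matrices
    (identity-scale, expectation identity) are drawn and the median pairwise
    d_AI recorded; a least-squares line of median versus order is fitted.

    ``dof_rule`` maps an order to the Wishart degrees of freedom; the
    default is ``2 * order``, which keeps the matrices comfortably away from
    singularity while preserving realistic estimation noise.
    """
    from .synthetic import make_wishart_pairs

    orders = sorted(int(o) for o in set(orders))
    if len(orders) < 3:
        raise ValueError("need at least 3 distinct orders to calibrate a line fit")
    if dof_rule is None:
        rule_name = "2*order"
        dof_rule = lambda o: 2 * o  # noqa: E731
    else:
        rule_name = getattr(dof_rule, "__name__", "custom")
    rng = np.random.default_rng(seed)
    medians = []
    for order in orders:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pairs = make_wishart_pairs(order, int(dof_rule(order)), n_pairs, seed=sub_seed)
        dists = [dai(P, G) for P, G in pairs]
        medians.append(float(np.median(dists)))
    x = np.asarray(orders, dtype=float)
    y = np.asarray(medians, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return OrderCalibration(
        slope=float(slope),
        intercept=float(intercept),
        orders=orders,
        medians=medians,
        fit_r2=float(r2),
        dof_rule=rule_name,
        n_pairs=int(n_pairs),
        seed=seed,
    )


def normalized_dai(P: np.ndarray, G: np.ndarray, calibration: OrderCalibration) -> float:
    """d_AI divided by the calibrated expected scale at the matrices' order."""
    order = np.asarray(P).shape[0]
    if calibration.orders and not (
        min(calibration.orders) <= order <= max(calibration.orders)
    ):
        warnings.warn(
            f"order {order} outside the calibrated range "
            f"[{min(calibration.orders)}, {max(calibration.orders)}]; extrapolating",
            stacklevel=2,
        )
    div = calibration.divisor(order)
    if div <= 0:
        raise ValueError(f"calibration divisor non-positive at order {order}")
    return dai(P, G) / div
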