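"""Functional connectome estimation.

A connectome here is the normalized precision (inverse covariance) matrix
of region time series: its off-diagonals are, up to sign, the partial
correlations between regions conditional on all others, the simplest proxy
for direct interactions.  Because region counts approach or exceed the
number of time samples, the sample covariance is ill-conditioned; it is
regularized with the convex shrinkage estimator

    Sigma_lambda = lambda * I + (1 - lambda) * Sigma_hat,

with the intensity lambda computed analytically (Ledoit–Wolf theory for a
fixed identity target, Schaefer–Strimmer variance estimator) and clipped to
[0, 1].  The resulting matrix is always SPD and inverts stably.

EdgeDataset stacks the vectorized upper triangles of subject connectomes
into a subjects × edges matrix — the variable blocks consumed by the
sparse-CCA model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .envelope import RegionTimeSeries
from .spd import check_spd

__all__ = [
    "Connectome",
    "EdgeDataset",
    "shrinkage_covariance",
    "normalized_precision",
    "partial_correlation",
    "vectorize_edges",
    "devectorize",
    "edge_index_for",
    "build_edge_dataset",
    "threshold_top_fraction",
    "group_mean",
]


@dataclass
class Connectome:
    """Symmetric matrix over labelled regions with estimation provenance."""

    matrix: np.ndarray
    labels: list[str]
    kind: str  # covariance | precision | normalized_precision
    shrinkage_lambda: float | None = None
    subject_id: str | None = None
    modality: str | None = None
    band: str | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        R = self.matrix.shape[0]
        if self.matrix.ndim != 2 or self.matrix.shape != (R, R):
            raise ValueError("connectome matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10, rtol=0.0):
            raise ValueError("connectome matrix must be symmetric (tol 1e-10)")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)
        self.labels = list(self.labels)
        if len(self.labels) != R:
            raise ValueError(f"{len(self.labels)} labels for order-{R} matrix")
        if self.kind not in ("covariance", "precision", "normalized_precision"):
            raise ValueError(f"unknown connectome kind {self.kind!r}")
        if self.kind == "normalized_precision" and not np.allclose(
            np.diag(self.matrix), 1.0, atol=1e-8
        ):
            raise ValueError("normalized_precision must have unit diagonal")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EdgeDataset:
    """Subjects × edges matrix of vectorized connectome off-diagonals."""

    matrix: np.ndarray
    edge_index: list[tuple[str, str]]
    modality: str | None = None
    band: str | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("EdgeDataset matrix must be 2-D (subjects x edges)")
        self.edge_index = [tuple(e) for e in self.edge_index]
        if len(self.edge_index) != self.matrix.shape[1]:
            raise ValueError("edge_index length must match the number of columns")
        if self.subject_ids is not None:
            self.subject_ids = list(self.subject_ids)
            if len(self.subject_ids) != self.matrix.shape[0]:
                raise ValueError("subject_ids length must match the number of rows")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return self.matrix.shape[1]


def shrinkage_covariance(ts: RegionTimeSeries) -> Connectome:
    """Identity-target shrinkage covariance with analytic intensity.

    The sample covariance ``S`` (1/(T-1) normalization on column-centered
    data) is combined with the identity target as ``lam * I + (1-lam) * S``.
    The intensity ``lam`` minimizes the expected Frobenius loss:
    ``lam* = sum_ij Var_hat(S_ij) / sum_ij (S_ij - I_ij)^2``, with the
    entrywise variance estimated from per-sample outer products, then
    clipped to [0, 1].  Output is SPD whenever lam > 0.
    """
    X = ts.values
    T, R = X.shape
    if T < 2:
        raise ValueError("need at least 2 time samples for a covariance estimate")
    Xc = X - X.mean(axis=0, keepdims=True)
    S = (Xc.T @ Xc) / (T - 1)
    # sum of entrywise variances of S, estimated from per-sample outer
    # products w_t = x_t x_t^T (Schaefer-Strimmer):
    #   sum_ij Var_hat(S_ij) = T/(T-1)^3 * (sum_t ||x_t||^4 - T ||mean_t w_t||_F^2)
    Wbar = (Xc.T @ Xc) / T
    sq_norms = np.einsum("ti,ti->t", Xc, Xc)
    var_sum = (T / (T - 1) ** 3) * float(
        np.sum(sq_norms**2) - T * np.sum(Wbar**2)
    )
    target = np.eye(R)
    denom = float(np.sum((S - target) ** 2))
    if denom <= np.finfo(float).tiny:
        lam = 1.0
    else:
        lam = float(np.clip(var_sum / denom, 0.0, 1.0))
    # degenerate data (no sampling variability, singular S): fall back to
    # the target so the estimate stays SPD
    if var_sum == 0.0 and np.linalg.eigvalsh(S)[0] <= 0.0:
        lam = 1.0
    Sigma = lam * target + (1.0 - lam) * S
    return Connectome(
        matrix=Sigma,
        labels=ts.labels,
        kind="covariance",
        shrinkage_lambda=lam,
        subject_id=ts.subject_id,
        modality=ts.modality,
        band=ts.band,
    )


def normalized_precision(cov: Connectome) -> Connectome:
    """Invert a covariance and normalize the precision to unit diagonal.

    The unit-diagonal normalized precision is, elementwise off the
    diagonal, the negative of the partial correlation; it is invariant to
    per-region rescaling of the input series.
    """
    ok, min_eig = check_spd(cov.matrix)
    if not ok:
        raise ValueError(f"covariance not SPD (min eigenvalue {min_eig:.3e})")
    P = linalg.inv(cov.matrix)
    P = 0.5 * (P + P.T)
    d = np.sqrt(np.diag(P))
    N = P / np.outer(d, d)
    np.fill_diagonal(N, 1.0)
    return Connectome(
        matrix=N,
        labels=cov.labels,
        kind="normalized_precision",
        shrinkage_lambda=cov.shrinkage_lambda,
        subject_id=cov.subject_id,
        modality=cov.modality,
        band=cov.band,
    )


def partial_correlation(np_conn: Connectome) -> np.ndarray:
    """Partial-correlation matrix from a normalized precision.

    Off-diagonals are negated (the normalized precision's off-diagonal is
    minus the partial correlation); the diagonal is set to one.
    """
    if np_conn.kind != "normalized_precision":
        raise ValueError("partial_correlation expects a normalized_precision connectome")
    P = -np_conn.matrix.copy()
    np.fill_diagonal(P, 1.0)
    return P


def edge_index_for(labels) -> list[tuple[str, str]]:
    """Upper-triangle (i < j, row-major) region pairs for a label order."""
    labels = list(labels)
    return [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]


def vectorize_edges(conn: Connectome) -> np.ndarray:
    """Upper-triangle (i < j, row-major) off-diagonal entries as a vector."""
    R = conn.n_regions
    iu = np.triu_indices(R, k=1)
    return conn.matrix[iu].copy()


def devectorize(edges: np.ndarray, labels) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix from an edge vector."""
    labels = list(labels)
    R = len(labels)
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (R * (R - 1) // 2,):
        raise ValueError(
            f"edge vector length {edges.size} incompatible with {R} regions"
        )
    M = np.eye(R)
    iu = np.triu_indices(R, k=1)
    M[iu] = edges
    M[(iu[1], iu[0])] = edges
    return M


def build_edge_dataset(connectomes: list[Connectome]) -> EdgeDataset:
    """Stack subject connectomes (same labels, same order) into an EdgeDataset."""
    if not connectomes:
        raise ValueError("no connectomes given")
    labels = connectomes[0].labels
    for c in connectomes:
        if c.labels != labels:
            raise ValueError("all connectomes must share the same region labels")
    rows = np.stack([vectorize_edges(c) for c in connectomes], axis=0)
    return EdgeDataset(
        matrix=rows,
        edge_index=edge_index_for(labels),
        modality=connectomes[0].modality,
        band=connectomes[0].band,
        subject_ids=[c.subject_id for c in connectomes]
        if all(c.subject_id is not None for c in connectomes)
        else None,
    )


def threshold_top_fraction(
    matrix: np.ndarray, fraction: float, labels
) -> list[tuple[tuple[str, str], float, str]]:
    """Edges with the highest absolute weight.

    Edges are ranked by |weight| descending, ties broken by upper-triangle
    edge order; the top ``ceil(fraction * n_edges)`` are returned as
    ``(region pair, weight, 'positive'|'negative')`` records.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    labels = list(labels)
    R = len(labels)
    matrix = np.asarray(matrix, dtype=float)
    iu = np.triu_indices(R, k=1)
    weights = matrix[iu]
    pairs = edge_index_for(labels)
    n_keep = int(np.ceil(fraction * weights.size))
    order = np.argsort(-np.abs(weights), kind="stable")[:n_keep]
    return [
        (pairs[k], float(weights[k]), "positive" if weights[k] >= 0 else "negative")
        for k in order
    ]


def group_mean(connectomes: list[Connectome]) -> Connectome:
    """Element-wise mean of subject connectomes (group-average display)."""
    if not connectomes:
        raise ValueError("no connectomes given")
    labels = connectomes[0].labels
    kind = connectomes[0].kind
    for c in connectomes:
        if c.labels != labels or c.kind != kind:
            raise ValueError("connectomes must share labels and kind")
    M = np.mean([c.matrix for c in connectomes], axis=0)
    return Connectome(matrix=M, labels=labels, kind=kind,
                      modality=connectomes[0].modality, band=connectomes[0].band)
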