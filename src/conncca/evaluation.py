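"""Cross-validated prediction performance and distance-based statistics.

Prediction quality is judged out of sample: for each held-out subject the
sparse-CCA model (penalties re-selected on the training folds) predicts the
subject's connectome in each direction, the prediction is devectorized,
SPD-checked (spectrum-repaired and counted if needed), and compared to the
measured connectome with the affine-invariant geodesic distance.  The same
metric yields the within-subject inter-modal distance and the inter-subject
variability baselines.

Two distribution-free tests compare the resulting distance samples: a
two-sided Wilcoxon rank-sum test for independent samples (prediction
directions, bands) and a paired Wilcoxon signed-rank test for matched
per-subject comparisons.  Both use exact enumeration for small samples and
the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats as _sstats

from .connectome import Connectome, EdgeDataset, devectorize
from .scca import (
    predict_x_from_y,
    predict_y_from_x,
    scca_fit,
    select_penalties,
)
from .spd import OrderCalibration, check_spd, dai, repair_spd

__all__ = [
    "DistanceReport",
    "RankTestResult",
    "loo_predict",
    "intermodal_distance",
    "intersubject_variability",
    "ranksum_compare",
    "paired_wilcoxon",
    "boxplot_reports",
]


@dataclass
class DistanceReport:
    """Geodesic distances for one condition (a box-plot's worth of values)."""

    values: np.ndarray
    condition: str
    band: str | None = None
    region_set: str | None = None
    normalized: bool = False
    non_spd_repairs: int = 0
    subject_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def summary(self) -> dict:
        q1, med, q3 = np.percentile(self.values, [25, 50, 75])
        return dict(
            condition=self.condition, band=self.band, n=self.values.size,
            median=float(med), iqr=float(q3 - q1),
            mean=float(self.values.mean()),
            non_spd_repairs=self.non_spd_repairs,
        )

    def normalize(self, calibration: OrderCalibration, order: int) -> "DistanceReport":
        div = calibration.divisor(order)
        return DistanceReport(
            values=self.values / div, condition=self.condition, band=self.band,
            region_set=self.region_set, normalized=True,
            non_spd_repairs=self.non_spd_repairs, subject_ids=self.subject_ids,
        )


class RankTestResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str


def _labels_from_edge_index(edge_index) -> list[str]:
    labels: list[str] = []
    for i, j in edge_index:
        if i not in labels:
            labels.append(i)
        if j not in labels:
            labels.append(j)
    return labels


def _edge_to_spd(edges: np.ndarray, labels) -> tuple[np.ndarray, bool]:
    """Devectorize a predicted edge vector; repair the spectrum if needed."""
    M = devectorize(edges, labels)
    ok, _ = check_spd(M)
    if ok:
        return M, False
    repaired, _ = repair_spd(M)
    return repaired, True


def loo_predict(
    X: EdgeDataset,
    Y: EdgeDataset,
    grid,
    n_perm: int = 10,
    seed: int | None = None,
    K: int | None = None,
    strict_spd: bool = False,
) -> tuple[DistanceReport, DistanceReport]:
    """Leave-one-out cross-validated bidirectional prediction distances.

    For every held-out subject: penalties are re-selected on the training
    folds by the permutation scheme, the model is fitted with the number of
    components capped at the minimum rank of the training blocks (or ``K``
    if given), and the held-out connectome is predicted in each direction,
    devectorized and compared to the measured one with d_AI.  Non-SPD
    predictions are spectrum-repaired and counted (or recorded as missing
    in ``strict_spd`` mode).

    Returns ``(y_from_x, x_from_y)`` distance reports with one value per
    subject.
    """
    n = X.n_subjects
    if n < 4:
        raise ValueError("leave-one-out evaluation needs at least 4 subjects")
    if Y.n_subjects != n:
        raise ValueError("X and Y must cover the same subjects")
    x_labels = _labels_from_edge_index(X.edge_index)
    y_labels = _labels_from_edge_index(Y.edge_index)
    rng = np.random.default_rng(seed)

    d_yx = np.full(n, np.nan)
    d_xy = np.full(n, np.nan)
    repairs_yx = repairs_xy = 0
    for s in range(n):
        train = np.delete(np.arange(n), s)
        Xtr, Ytr = X.matrix[train], Y.matrix[train]
        fold_seed = int(rng.integers(0, 2**31 - 1))
        c1, c2, _ = select_penalties(Xtr, Ytr, grid, n_perm=n_perm, seed=fold_seed)
        k_fold = K
        if k_fold is None:
            Xtc = Xtr - Xtr.mean(axis=0)
            Ytc = Ytr - Ytr.mean(axis=0)
            k_fold = min(
                int(np.linalg.matrix_rank(Xtc)), int(np.linalg.matrix_rank(Ytc))
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = scca_fit(Xtr, Ytr, c1, c2, K=k_fold)

        y_hat = predict_y_from_x(model, X.matrix[s])
        Y_hat, rep = _edge_to_spd(y_hat, y_labels)
        if rep:
            repairs_yx += 1
        if not (rep and strict_spd):
            d_yx[s] = dai(Y_hat, devectorize(Y.matrix[s], y_labels))

        x_hat = predict_x_from_y(model, Y.matrix[s])
        X_hat, rep = _edge_to_spd(x_hat, x_labels)
        if rep:
            repairs_xy += 1
        if not (rep and strict_spd):
            d_xy[s] = dai(X_hat, devectorize(X.matrix[s], x_labels))

    ids = X.subject_ids
    rep_yx = DistanceReport(
        values=d_yx[~np.isnan(d_yx)], condition="y_from_x", band=X.band,
        non_spd_repairs=repairs_yx,
        subject_ids=ids if not np.any(np.isnan(d_yx)) else None,
    )
    rep_xy = DistanceReport(
        values=d_xy[~np.isnan(d_xy)], condition="x_from_y", band=X.band,
        non_spd_repairs=repairs_xy,
        subject_ids=ids if not np.any(np.isnan(d_xy)) else None,
    )
    return rep_yx, rep_xy


def intermodal_distance(
    A: list[Connectome], B: list[Connectome]
) -> DistanceReport:
    """Within-subject distance between two modalities' measured connectomes."""
    if len(A) != len(B):
        raise ValueError("subject lists must match")
    vals = [dai(a.matrix, b.matrix) for a, b in zip(A, B)]
    return DistanceReport(
        values=np.asarray(vals), condition="intermodal",
        band=A[0].band or B[0].band if A else None,
        subject_ids=[a.subject_id for a in A]
        if all(a.subject_id is not None for a in A) else None,
    )


def intersubject_variability(mats: list[Connectome]) -> DistanceReport:
    """Distances over all unordered subject pairs within one modality/band."""
    if len(mats) < 2:
        raise ValueError("need at least 2 subjects")
    vals = [
        dai(a.matrix, b.matrix) for a, b in itertools.combinations(mats, 2)
    ]
    return DistanceReport(
        values=np.asarray(vals), condition="intersubject",
        band=mats[0].band,
    )


def _tie_counts(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts


def ranksum_compare(a, b) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test on two independent samples.

    Exact enumeration of all rank assignments when the combined sample size
    is at most 12 (ties handled through midranks); tie-corrected normal
    approximation otherwise.  The statistic reported is the rank sum of the
    first sample.  Assumes the two samples are independent.
    """
    x = np.asarray(a.values if isinstance(a, DistanceReport) else a, dtype=float)
    y = np.asarray(b.values if isinstance(b, DistanceReport) else b, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = _sstats.rankdata(combined)
    W = float(np.sum(ranks[:n1]))
    n = n1 + n2
    if n <= 12:
        sums = np.array(
            [sum(c) for c in itertools.combinations(ranks, n1)]
        )
        eps = 1e-9
        p_le = np.mean(sums <= W + eps)
        p_ge = np.mean(sums >= W - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankTestResult(W, float(p), "exact")
    mu = n1 * (n + 1) / 2.0
    tie_term = float(np.sum(_tie_counts(combined) ** 3 - _tie_counts(combined)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        warnings.warn("degenerate rank-sum variance (all values tied)", stacklevel=2)
        return RankTestResult(W, 1.0, "approx")
    z = (W - mu) / np.sqrt(var)
    p = 2.0 * float(_sstats.norm.sf(abs(z)))
    return RankTestResult(W, min(1.0, p), "approx")


def paired_wilcoxon(a, b) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on matched samples.

    Zero differences are dropped.  Exact enumeration over sign patterns for
    at most 12 nonzero differences; tie-corrected normal approximation
    otherwise.  The statistic is the positive-rank sum W+.
    """
    x = np.asarray(a.values if isinstance(a, DistanceReport) else a, dtype=float)
    y = np.asarray(b.values if isinstance(b, DistanceReport) else b, dtype=float)
    if x.size != y.size:
        raise ValueError("paired test needs equal-length matched samples")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn(
            "all paired differences are zero; test degenerate, p = 1",
            stacklevel=2,
        )
        return RankTestResult(0.0, 1.0, "degenerate")
    ranks = _sstats.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    if n <= 12:
        sums = np.array(
            [np.sum(np.compress(mask, ranks))
             for mask in itertools.product([0, 1], repeat=n)]
        )
        eps = 1e-9
        p_le = np.mean(sums <= w_plus + eps)
        p_ge = np.mean(sums >= w_plus - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankTestResult(w_plus, float(p), "exact")
    mu = n * (n + 1) / 4.0
    tie_term = float(np.sum(_tie_counts(np.abs(d)) ** 3 - _tie_counts(np.abs(d))))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * float(_sstats.norm.sf(abs(z)))
    return RankTestResult(w_plus, min(1.0, p), "approx")


def boxplot_reports(reports: list[DistanceReport], ax=None):
    """Box plots of distance reports, one box per condition/band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(reports) + 2, 4))
    ax.boxplot(
        [r.values for r in reports],
        tick_labels=[
            f"{r.condition}\n{r.band}" if r.band else r.condition for r in reports
        ],
    )
    ax.set_ylabel("geodesic distance $d_{AI}$"
                  + (" (order-normalized)" if any(r.normalized for r in reports) else ""))
    return ax
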