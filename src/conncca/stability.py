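"""Stability selection for sparse-CCA via the randomized-Lasso principle.

The sparse-CCA support depends on the exact penalty value; randomizing the
penalty breaks that dependence.  Scaling a column by a weight in {0.5, 1}
before the L1-penalized fit is equivalent to perturbing that column's
effective penalty, so each repetition draws independent weights per column
for both variable blocks, refits the model at fixed (c1, c2), and records
which coefficients come out nonzero.  The fraction of repetitions in which
a column is selected estimates its selection probability — a principled
control on false positives.

To compare frequency bands under a single sparsity budget, the per-band
edge datasets are concatenated column-wise into one wide block before the
randomized fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import EdgeDataset
from .scca import scca_fit

__all__ = [
    "SelectionProfile",
    "concat_bands",
    "randomized_scca",
    "top_selection",
]


@dataclass
class SelectionProfile:
    """Per-column selection probabilities from randomized sparse-CCA."""

    x_probabilities: np.ndarray
    y_probabilities: np.ndarray
    n_reps: int
    c1: float
    c2: float
    seed: int | None
    band_offsets: dict[str, int] = field(default_factory=dict)
    x_edge_index: list[tuple[str, str]] | None = None
    y_edge_index: list[tuple[str, str]] | None = None
    weight_set: tuple[float, float] = (0.5, 1.0)

    def __post_init__(self):
        self.x_probabilities = np.asarray(self.x_probabilities, dtype=float)
        self.y_probabilities = np.asarray(self.y_probabilities, dtype=float)
        for pr in (self.x_probabilities, self.y_probabilities):
            if np.any((pr < 0) | (pr > 1)):
                raise ValueError("selection probabilities must lie in [0, 1]")

    def x_block(self, band: str) -> np.ndarray:
        """Selection probabilities of one band's block of the X side."""
        if band not in self.band_offsets:
            raise KeyError(f"unknown band {band!r}")
        names = sorted(self.band_offsets, key=self.band_offsets.get)
        start = self.band_offsets[band]
        i = names.index(band)
        stop = (
            self.band_offsets[names[i + 1]]
            if i + 1 < len(names)
            else self.x_probabilities.size
        )
        return self.x_probabilities[start:stop]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: block, region pair, selection probability."""
        rows = []
        names = sorted(self.band_offsets, key=self.band_offsets.get) or ["x"]
        if self.band_offsets:
            for band in names:
                probs = self.x_block(band)
                idx = self.x_edge_index or [(f"e{k}", "") for k in range(probs.size)]
                n_edges = probs.size
                for k in range(n_edges):
                    i, j = idx[k] if k < len(idx) else (f"e{k}", "")
                    rows.append(dict(block=band, region_i=i, region_j=j,
                                     probability=probs[k]))
        else:
            for k, pr in enumerate(self.x_probabilities):
                i, j = (self.x_edge_index or [])[k] if self.x_edge_index else (f"e{k}", "")
                rows.append(dict(block="x", region_i=i, region_j=j, probability=pr))
        for k, pr in enumerate(self.y_probabilities):
            i, j = (self.y_edge_index or [])[k] if self.y_edge_index else (f"e{k}", "")
            rows.append(dict(block="y", region_i=i, region_j=j, probability=pr))
        return pd.DataFrame(rows)


def concat_bands(datasets: dict[str, EdgeDataset] | list[EdgeDataset]) -> EdgeDataset:
    """Stack per-band edge datasets column-wise into one wide X block.

    All bands must cover the same subjects (in order) and the same edge
    index.  The returned dataset's ``band`` attribute records the
    band-block offsets as a dict serialized on the object.
    """
    if isinstance(datasets, dict):
        items = list(datasets.items())
    else:
        items = [(ds.band or f"band{k}", ds) for k, ds in enumerate(datasets)]
    if not items:
        raise ValueError("no datasets to concatenate")
    first = items[0][1]
    offsets: dict[str, int] = {}
    blocks = []
    edge_index: list[tuple[str, str]] = []
    col = 0
    for name, ds in items:
        if ds.n_subjects != first.n_subjects:
            raise ValueError("subject counts differ across bands")
        if first.subject_ids is not None and ds.subject_ids != first.subject_ids:
            raise ValueError("subject sets differ across bands")
        if ds.edge_index != first.edge_index:
            raise ValueError("edge indices differ across bands")
        offsets[name] = col
        col += ds.n_edges
        blocks.append(ds.matrix)
        edge_index.extend(ds.edge_index)
    out = EdgeDataset(
        matrix=np.hstack(blocks),
        edge_index=edge_index,
        modality=first.modality,
        band="+".join(n for n, _ in items),
        subject_ids=first.subject_ids,
    )
    out.band_offsets = offsets  # type: ignore[attr-defined]
    return out


def randomized_scca(
    X,
    Y,
    c1: float,
    c2: float,
    n_reps: int = 1000,
    seed: int | None = None,
    K: int = 1,
    weight_set: tuple[float, float] = (0.5, 1.0),
) -> SelectionProfile:
    """Randomized-Lasso sparse CCA: selection probabilities per column.

    Each repetition draws iid weights from ``weight_set`` per column of X
    and of Y, scales the columns, refits sCCA at the fixed penalties, and
    marks a column selected when its coefficient is nonzero in any retained
    component.  Probabilities are selection counts over ``n_reps``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    Xm = X.matrix if isinstance(X, EdgeDataset) else np.asarray(X, dtype=float)
    Ym = Y.matrix if isinstance(Y, EdgeDataset) else np.asarray(Y, dtype=float)
    p, q = Xm.shape[1], Ym.shape[1]
    rng = np.random.default_rng(seed)
    counts_x = np.zeros(p)
    counts_y = np.zeros(q)
    weights = np.asarray(weight_set, dtype=float)
    for _ in range(n_reps):
        wx = rng.choice(weights, size=p)
        wy = rng.choice(weights, size=q)
        model = scca_fit(Xm * wx, Ym * wy, c1, c2, K=K)
        if model.K > 0:
            counts_x += np.any(model.U != 0.0, axis=1)
            counts_y += np.any(model.V != 0.0, axis=1)
    offsets = getattr(X, "band_offsets", {}) if isinstance(X, EdgeDataset) else {}
    return SelectionProfile(
        x_probabilities=counts_x / n_reps,
        y_probabilities=counts_y / n_reps,
        n_reps=int(n_reps),
        c1=float(c1),
        c2=float(c2),
        seed=seed,
        band_offsets=dict(offsets),
        x_edge_index=X.edge_index if isinstance(X, EdgeDataset) else None,
        y_edge_index=Y.edge_index if isinstance(Y, EdgeDataset) else None,
        weight_set=tuple(weights),
    )


def top_selection(
    profile: SelectionProfile, fraction: float
) -> dict[str, list[tuple[int, float]]]:
    """Most frequently selected edges per band block (and the Y block).

    Within each block, edges are ranked by selection probability
    descending, ties broken by edge index; the top
    ``ceil(fraction * block_size)`` are returned as (edge position within
    block, probability) pairs.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")

    def top(probs: np.ndarray) -> list[tuple[int, float]]:
        n_keep = int(np.ceil(fraction * probs.size))
        order = np.argsort(-probs, kind="stable")[:n_keep]
        return [(int(k), float(probs[k])) for k in order]

    out: dict[str, list[tuple[int, float]]] = {}
    if profile.band_offsets:
        for band in sorted(profile.band_offsets, key=profile.band_offsets.get):
            out[band] = top(profile.x_block(band))
    else:
        out["x"] = top(profile.x_probabilities)
    out["y"] = top(profile.y_probabilities)
    return out
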