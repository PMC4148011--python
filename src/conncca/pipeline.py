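"""End-to-end orchestration of the two envelope experiments (WTS and AWE).

`run_pipeline` ties the stages together on synthetic inputs: generate
paired-modality series, extract band-limited-power envelopes (whole time
series or averaged within TR epochs), estimate normalized-precision
connectomes, build edge datasets, evaluate leave-one-out cross-modal
prediction, and run randomized-Lasso stability selection across
concatenated bands.  Every artifact is written as delimited text under a
run directory, stages are resumable from their intermediates, and the run
is deterministic given the configured seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as cio
from .connectome import build_edge_dataset, normalized_precision, shrinkage_covariance
from .envelope import (
    CANONICAL_BANDS,
    BandDefinition,
    awe_series,
    hilbert_envelope,
    wts_series,
)
from .evaluation import intermodal_distance, loo_predict
from .scca import default_penalty_grid
from .stability import concat_bands, randomized_scca, top_selection
from .synthetic import SyntheticSpec, make_coupled_timeseries

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("conncca.pipeline")

_BAND_TABLE = {b.name: b for b in CANONICAL_BANDS}


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic experiment."""

    mode: str = "AWE"  # or "WTS"
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")
    epoch_seconds: float = 2.16
    drop_first_epochs: int = 5
    n_subjects: int = 17
    n_regions: int = 30
    n_samples: int = 162_000
    sampling_rate: float = 250.0
    coupling: float = 0.8
    subject_dev: float = 0.5
    penalty_grid_points: int = 3
    n_perm: int = 10
    n_reps: int = 200
    selection_fraction: float = 0.02
    seed_generator: int = 0
    seed_permutations: int = 1
    seed_weights: int = 2
    out_dir: str = "conncca_run"

    def __post_init__(self):
        if self.mode not in ("WTS", "AWE"):
            raise ValueError(f"mode must be 'WTS' or 'AWE', got {self.mode!r}")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        unknown = [b for b in self.bands if b not in _BAND_TABLE]
        if unknown:
            raise ValueError(
                f"unknown band name(s) {unknown}; known: {sorted(_BAND_TABLE)}"
            )

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        return tuple(_BAND_TABLE[b] for b in self.bands)


def _connectome_from_series(ts):
    return normalized_precision(shrinkage_covariance(ts))


def run_pipeline(config: RunConfig, overwrite: bool = False) -> Path:
    """Run every stage and return the run directory.

    Stage outputs (edge datasets, distance reports, selection profiles) are
    written as delimited text; a manifest records the configuration and
    seeds.  Existing edge datasets are reused unless ``overwrite`` is set.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    cio.write_manifest(
        dict(config=asdict(config), package="conncca"), out / "manifest.json"
    )

    spec = SyntheticSpec(
        n_subjects=config.n_subjects,
        n_regions=config.n_regions,
        n_samples=config.n_samples,
        sampling_rate=config.sampling_rate,
        bands=config.band_definitions(),
        coupling=config.coupling,
        subject_dev=config.subject_dev,
        tr_seconds=config.epoch_seconds,
        seed=config.seed_generator,
    )

    slow_path = out / "edges_slow.tsv"
    band_paths = {b: out / f"edges_{config.mode}_{b}.tsv" for b in config.bands}
    if overwrite or not slow_path.exists() or not all(
        p.exists() for p in band_paths.values()
    ):
        logger.info("stage simulate: generating %d subjects", spec.n_subjects)
        slow, banded, _ = make_coupled_timeseries(spec)

        logger.info("stage connectome: slow modality")
        slow_conns = [_connectome_from_series(ts) for ts in slow]
        slow_edges = build_edge_dataset(slow_conns)
        cio.write_edge_dataset(slow_edges, slow_path)

        band_conns = {}
        for bname in config.bands:
            logger.info("stage envelope+connectome: band %s (%s)", bname, config.mode)
            conns = []
            for ts in banded[bname]:
                env = hilbert_envelope(ts)
                if config.mode == "AWE":
                    series = awe_series(
                        env, config.epoch_seconds, config.drop_first_epochs
                    )
                else:
                    series = wts_series(
                        env, config.epoch_seconds, config.drop_first_epochs
                    )
                conns.append(_connectome_from_series(series))
            band_conns[bname] = conns
            cio.write_edge_dataset(build_edge_dataset(conns), band_paths[bname])

        # within-subject inter-modal distances per band
        rows = []
        for bname in config.bands:
            rep = intermodal_distance(band_conns[bname], slow_conns)
            for i, v in enumerate(rep.values):
                rows.append((bname, i, v))
        with open(out / "intermodal_distances.tsv", "w") as fh:
            fh.write("band\tsubject\tdai\n")
            for bname, i, v in rows:
                fh.write(f"{bname}\t{i}\t{v:.17g}\n")

    slow_edges = cio.read_edge_dataset(slow_path, modality="slow")
    band_edges = {
        b: cio.read_edge_dataset(band_paths[b], modality="band", band=b)
        for b in config.bands
    }

    grid = default_penalty_grid(
        band_edges[config.bands[0]].n_edges,
        slow_edges.n_edges,
        n_points=config.penalty_grid_points,
    )

    logger.info("stage evaluate: leave-one-out prediction per band")
    summaries = []
    for bname in config.bands:
        rep_yx, rep_xy = loo_predict(
            band_edges[bname], slow_edges, grid,
            n_perm=config.n_perm, seed=config.seed_permutations,
        )
        summaries.append(rep_yx.summary() | {"band": bname})
        summaries.append(rep_xy.summary() | {"band": bname})
    with open(out / "loo_summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2)

    logger.info("stage stability: randomized sparse CCA across bands")
    Xall = concat_bands({b: band_edges[b] for b in config.bands})
    p, q = Xall.n_edges, slow_edges.n_edges
    c1 = 0.3 * np.sqrt(p)
    c2 = 0.3 * np.sqrt(q)
    profile = randomized_scca(
        Xall, slow_edges, c1=c1, c2=c2,
        n_reps=config.n_reps, seed=config.seed_weights,
    )
    profile.to_frame().to_csv(out / "selection_profile.tsv", sep="\t", index=False)
    tops = top_selection(profile, config.selection_fraction)
    with open(out / "top_selection.json", "w") as fh:
        json.dump({k: v for k, v in tops.items()}, fh, indent=2)

    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return out
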