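"""Synthetic paired-modality data with known covariance ground truth.

Real simultaneous dual-modality recordings are not available, so this
module generates region time series with the statistical structure the
analysis assumes, giving every downstream stage a planted truth:

* each subject owns an SPD covariance ``C_s = B + subject_dev * W_s``
  (``B`` a fixed correlation-like base, ``W_s`` Wishart with identity
  expectation), which governs the slow modality directly;
* per frequency band, the amplitude envelopes of band-limited carriers are
  lognormal with covariance ``coupling * C_s + (1 - coupling) * R_s``,
  where ``R_s`` is an independent subject- and band-specific SPD component
  — so ``coupling`` is literally the fraction of envelope covariance shared
  with the slow modality;
* carriers are band-filtered white noise, independent across bands and
  regions, normalized to unit mean envelope, so the measured Hilbert
  envelope of the emitted series has off-diagonal covariance exactly equal
  to the planted mixture, and inter-band envelope correlations stay low.

``make_linked_edge_datasets`` plants a sparse rank-one cross-modal linkage
directly in edge space for recovery tests of the sparse-CCA machinery, and
``make_wishart_pairs`` supplies the random SPD pairs behind the
order-normalization calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .envelope import BandDefinition, CANONICAL_BANDS, RegionTimeSeries

__all__ = [
    "SyntheticSpec",
    "PlantedLinkage",
    "make_coupled_timeseries",
    "make_linked_edge_datasets",
    "make_wishart_pairs",
    "region_label_fixture",
]


@dataclass
class SyntheticSpec:
    """Study-condition parameters of the paired-modality generator.

    Defaults mirror the reference study design at desk scale: 17 subjects,
    the five canonical bands, a 2.16 s repetition time at 250 Hz (540
    samples per epoch), and 300 epochs of data.
    """

    n_subjects: int = 17
    n_regions: int = 30
    n_samples: int = 162_000  # 300 epochs x 540 samples at 250 Hz / 2.16 s
    sampling_rate: float = 250.0
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
    coupling: float = 0.8
    subject_dev: float = 0.5
    tr_seconds: float = 2.16
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_regions < 2:
            raise ValueError("need at least 1 subject and 2 regions")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must lie in [0, 1]")
        if self.subject_dev < 0:
            raise ValueError("subject_dev must be non-negative")
        self.bands = tuple(
            b if isinstance(b, BandDefinition) else BandDefinition(*b)
            for b in self.bands
        )
        for b in self.bands:
            if b.high >= self.sampling_rate / 2:
                raise ValueError(
                    f"band {b.name} exceeds Nyquist at {self.sampling_rate} Hz"
                )

    @property
    def epoch_samples(self) -> int:
        return int(round(self.tr_seconds * self.sampling_rate))

    @property
    def n_epochs(self) -> int:
        return self.n_samples // self.epoch_samples


@dataclass
class PlantedLinkage:
    """Ground-truth sparse canonical vectors of a planted rank-one linkage."""

    u_star: np.ndarray
    v_star: np.ndarray
    scores: np.ndarray
    noise_sd: float

    def __post_init__(self):
        self.u_star = np.asarray(self.u_star, dtype=float)
        self.v_star = np.asarray(self.v_star, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def u_support(self) -> np.ndarray:
        return np.flatnonzero(self.u_star)

    @property
    def v_support(self) -> np.ndarray:
        return np.flatnonzero(self.v_star)


def _random_correlation(R: int, rng: np.random.Generator) -> np.ndarray:
    """Correlation matrix from a random factor model, well away from singular."""
    G = rng.standard_normal((R, 2 * R)) / np.sqrt(2 * R)
    B = G @ G.T + 0.2 * np.eye(R)
    d = np.sqrt(np.diag(B))
    return B / np.outer(d, d)


def _wishart_identity(R: int, dof: int, rng: np.random.Generator) -> np.ndarray:
    """Wishart sample with identity expectation (scale I/dof)."""
    G = rng.standard_normal((dof, R)) / np.sqrt(dof)
    return G.T @ G


def _smooth_unit_noise(
    n: int, R: int, sigma_samples: float, rng: np.random.Generator
) -> np.ndarray:
    """Temporally smoothed white noise with (asymptotically) unit variance."""
    z = rng.standard_normal((n, R))
    if sigma_samples <= 0:
        return z
    half = max(int(np.ceil(4 * sigma_samples)), 1)
    t = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (t / sigma_samples) ** 2)
    k /= np.linalg.norm(k)  # unit L2 keeps variance of white input
    return signal.fftconvolve(z, k[:, None], mode="same", axes=0)


def _lognormal_params(C_env: np.ndarray, mean_scale: float = 3.0):
    """Lognormal moment matching: Gaussian (mu, Sigma_g) whose exponential
    has covariance exactly ``C_env``.

    Envelope means are ``mean_scale * sqrt(diag(C_env))``; with
    ``mean_scale >= 2`` the implied log-scale matrix stays positive
    definite for any correlation structure of ``C_env``.
    """
    m = mean_scale * np.sqrt(np.diag(C_env))
    Sg = np.log1p(C_env / np.outer(m, m))
    mu = np.log(m) - 0.5 * np.diag(Sg)
    return mu, Sg


def _spd_cholesky_with_jitter(M: np.ndarray, what: str) -> np.ndarray:
    """Cholesky factor; escalating diagonal jitter, raise after 5 failures."""
    jitter = 0.0
    scale = float(np.trace(M)) / M.shape[0]
    for attempt in range(6):
        try:
            return np.linalg.cholesky(M + jitter * np.eye(M.shape[0]))
        except np.linalg.LinAlgError:
            jitter = scale * 10.0 ** (-10 + 2 * attempt)
    raise RuntimeError(f"{what} not SPD after 5 jitter attempts")


def _normalized_carrier(
    n: int, R: int, band: BandDefinition, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-filtered white noise per region, unit mean Hilbert envelope."""
    sos = signal.butter(2, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    w = rng.standard_normal((n, R))
    c = signal.sosfiltfilt(sos, w, axis=0)
    env_mean = np.abs(signal.hilbert(c, axis=0)).mean(axis=0)
    return c / env_mean


def make_coupled_timeseries(spec: SyntheticSpec):
    """Generate per-subject slow-modality and band-limited series.

    Returns ``(slow, banded, truth)`` where ``slow`` is a list of
    RegionTimeSeries (one per subject, sampled once per TR epoch),
    ``banded`` maps band name to a list of full-rate RegionTimeSeries, and
    ``truth`` records the planted covariances: ``truth['shared'][s]`` is
    ``C_s`` and ``truth['envelope'][band][s]`` the planted band-envelope
    covariance of subject ``s``.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.n_regions
    labels = [f"region_{i:03d}" for i in range(R)]
    B = _random_correlation(R, rng)
    B2 = _random_correlation(R, rng)
    dof = 2 * R

    n_epochs = spec.n_epochs
    if n_epochs < 2:
        raise ValueError(
            "n_samples too short: fewer than two TR epochs of slow-modality data"
        )

    slow_list: list[RegionTimeSeries] = []
    banded: dict[str, list[RegionTimeSeries]] = {b.name: [] for b in spec.bands}
    truth = {
        "base": B,
        "shared": [],
        "envelope": {b.name: [] for b in spec.bands},
    }
    env_sigma = 0.5 * spec.sampling_rate  # ~0.5 s envelope timescale

    for s in range(spec.n_subjects):
        sid = f"sub-{s:02d}"
        C_s = B + spec.subject_dev * _wishart_identity(R, dof, rng)
        C_s = 0.5 * (C_s + C_s.T)
        truth["shared"].append(C_s)

        # slow modality: low-pass correlated Gaussian, covariance C_s
        L = _spd_cholesky_with_jitter(C_s, "subject covariance")
        y = _smooth_unit_noise(n_epochs, R, 1.0, rng) @ L.T
        slow_list.append(
            RegionTimeSeries(
                values=y,
                sampling_rate=1.0 / spec.tr_seconds,
                labels=labels,
                subject_id=sid,
                modality="slow",
            )
        )

        for band in spec.bands:
            R_sb = B2 + spec.subject_dev * _wishart_identity(R, dof, rng)
            C_env = spec.coupling * C_s + (1.0 - spec.coupling) * R_sb
            C_env = 0.5 * (C_env + C_env.T)
            truth["envelope"][band.name].append(C_env)
            mu, Sg = _lognormal_params(C_env)
            Lg = _spd_cholesky_with_jitter(Sg, "log-envelope covariance")
            g = _smooth_unit_noise(spec.n_samples, R, env_sigma, rng) @ Lg.T + mu
            env = np.exp(g)
            carrier = _normalized_carrier(
                spec.n_samples, R, band, spec.sampling_rate, rng
            )
            banded[band.name].append(
                RegionTimeSeries(
                    values=env * carrier,
                    sampling_rate=spec.sampling_rate,
                    labels=labels,
                    subject_id=sid,
                    modality="band",
                    band=band.name,
                )
            )
    return slow_list, banded, truth


def make_linked_edge_datasets(
    n_subjects: int,
    p: int,
    q: int,
    support: int,
    score_sd: float,
    noise_sd: float,
    seed: int,
):
    """Edge datasets with a planted sparse rank-one cross-modal linkage.

    ``X = t u*^T + E`` and ``Y = t v*^T + F`` with per-subject scores
    ``t ~ N(0, score_sd^2)`` and iid ``N(0, noise_sd^2)`` noise; ``u*`` and
    ``v*`` are unit-norm with ``support`` nonzero entries each.  Returns
    ``(X, Y, PlantedLinkage)``.
    """
    from .connectome import EdgeDataset

    if support < 1:
        raise ValueError("support must be at least 1")
    if support > min(p, q):
        raise ValueError("support exceeds min(p, q)")
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)

    def sparse_unit(dim: int) -> np.ndarray:
        v = np.zeros(dim)
        idx = rng.choice(dim, size=support, replace=False)
        vals = rng.standard_normal(support)
        # keep entries away from zero so the support is well defined
        vals += 0.5 * np.sign(vals)
        v[idx] = vals
        return v / np.linalg.norm(v)

    u_star = sparse_unit(p)
    v_star = sparse_unit(q)
    t = rng.normal(0.0, score_sd, size=n_subjects)
    X = np.outer(t, u_star) + rng.normal(0.0, noise_sd, size=(n_subjects, p))
    Y = np.outer(t, v_star) + rng.normal(0.0, noise_sd, size=(n_subjects, q))
    subject_ids = [f"sub-{s:02d}" for s in range(n_subjects)]
    Xds = EdgeDataset(
        matrix=X,
        edge_index=[(f"x{j}", f"x{j}'") for j in range(p)],
        modality="band",
        subject_ids=subject_ids,
    )
    Yds = EdgeDataset(
        matrix=Y,
        edge_index=[(f"y{j}", f"y{j}'") for j in range(q)],
        modality="slow",
        subject_ids=subject_ids,
    )
    linkage = PlantedLinkage(u_star=u_star, v_star=v_star, scores=t, noise_sd=noise_sd)
    return Xds, Yds, linkage


def make_wishart_pairs(
    order: int, dof: int, n_pairs: int, seed: int | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pairs of independent Wishart SPD matrices with identity expectation.

    Each matrix is drawn from ``Wishart(dof, I/dof)`` so its expectation is
    the identity; ``dof >= order`` is required for almost-sure
    invertibility.
    """
    if dof < order:
        raise ValueError(f"dof ({dof}) must be >= order ({order}) for SPD samples")
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed)
    dist = stats.wishart(df=dof, scale=np.eye(order) / dof)
    draws = dist.rvs(size=2 * n_pairs, random_state=rng)
    draws = draws.reshape(2 * n_pairs, order, order)
    return [(draws[2 * k], draws[2 * k + 1]) for k in range(n_pairs)]


_CORTICAL_34 = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]

_SUBCORTICAL_7 = [
    "thalamus", "caudate", "putamen", "pallidum", "hippocampus", "amygdala",
    "accumbens",
]


def region_label_fixture(include_subcortical: bool = False) -> list[str]:
    """Ordered gray-matter region labels of the standard whole-brain atlas.

    68 cortical labels (34 per hemisphere), optionally preceded by the 14
    subcortical labels (7 per hemisphere) so subcortical regions occupy the
    top-left corner of the matrix layout.
    """
    cortical = [f"lh-{n}" for n in _CORTICAL_34] + [f"rh-{n}" for n in _CORTICAL_34]
    if not include_subcortical:
        return cortical
    subcortical = [f"Left-{n}" for n in _SUBCORTICAL_7] + [
        f"Right-{n}" for n in _SUBCORTICAL_7
    ]
    return subcortical + cortical
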