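"""Band-limited power extraction.

The slow fluctuations of a narrowband neural signal's amplitude envelope
(band-limited power, BLP) are the quantity whose covariance structure is
compared with the slow haemodynamic modality.  This module provides the
signal chain: zero-phase Butterworth band-pass filtering, the Hilbert
(analytic-signal) envelope, segmentation into repetition-time (TR) epochs,
and the two envelope summarizations used downstream:

* WTS — the envelope at the full sampling resolution of the fast modality
  (whole time series), with the first few epochs discarded;
* AWE — the envelope averaged within each TR epoch, yielding one sample per
  epoch, time-locked to the slow modality's volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


__all__ = [
    "RegionTimeSeries",
    "BandDefinition",
    "CANONICAL_BANDS",
    "bandpass",
    "hilbert_envelope",
    "segment_epochs",
    "awe_series",
    "wts_series",
]


@dataclass
class RegionTimeSeries:
    """A time × regions matrix of real-valued signals at a fixed rate."""

    values: np.ndarray
    sampling_rate: float
    labels: list[str]
    subject_id: str | None = None
    modality: str | None = None
    band: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (time x regions) array")
        if self.values.shape[0] == 0:
            raise ValueError("empty time series (zero samples)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or infinite entries")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.labels = list(self.labels)
        if len(self.labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.values.shape[1]} regions"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band {self.name}: ({self.low}, {self.high}) Hz")


#: The five canonical EEG frequency bands (Hz).
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 70.0),
)


def bandpass(
    ts: RegionTimeSeries,
    band: BandDefinition,
    pad_seconds: float = 2.16,
) -> RegionTimeSeries:
    """Zero-phase second-order Butterworth band-pass filter, per region.

    The filter is applied forward and then reverse (``filtfilt``), so the
    effective magnitude response is the square of the one-pass response and
    the phase delay is zero.  Edge transients are bounded with reflective
    padding of roughly one epoch length (``pad_seconds``); downstream
    epoch-dropping removes what remains.
    """
    nyquist = ts.sampling_rate / 2.0
    if band.high >= nyquist:
        raise ValueError(
            f"band {band.name} upper edge {band.high} Hz >= Nyquist {nyquist} Hz"
        )
    sos = signal.butter(
        2, [band.low, band.high], btype="bandpass", fs=ts.sampling_rate, output="sos"
    )
    padlen = min(int(round(pad_seconds * ts.sampling_rate)), ts.n_samples - 1)
    filtered = signal.sosfiltfilt(
        sos, ts.values, axis=0, padtype="even", padlen=padlen
    )
    return replace(ts, values=filtered, band=band.name)


def hilbert_envelope(ts: RegionTimeSeries) -> RegionTimeSeries:
    """Instantaneous amplitude: magnitude of the analytic signal, per region."""
    if ts.n_samples < 8:
        raise ValueError("need at least 8 samples for a meaningful envelope")
    env = np.abs(signal.hilbert(ts.values, axis=0))
    return replace(ts, values=env)


def segment_epochs(ts: RegionTimeSeries, epoch_seconds: float) -> np.ndarray:
    """Consecutive non-overlapping epoch boundaries, trailing partial dropped.

    Returns an ``(n_epochs, 2)`` integer array of ``[start, stop)`` sample
    indices.  Epoch length in samples is ``round(epoch_seconds *
    sampling_rate)``.
    """
    samples = int(round(epoch_seconds * ts.sampling_rate))
    if samples < 1:
        raise ValueError("epoch shorter than one sample")
    n_epochs = ts.n_samples // samples
    starts = np.arange(n_epochs) * samples
    return np.stack([starts, starts + samples], axis=1)


def _epoched_envelope(
    envelope: RegionTimeSeries, epoch_seconds: float, drop_first: int
):
    if drop_first < 0:
        raise ValueError("drop_first must be non-negative")
    bounds = segment_epochs(envelope, epoch_seconds)
    if len(bounds) < drop_first + 1:
        raise ValueError(
            f"only {len(bounds)} epochs available; need at least {drop_first + 1} "
            f"to retain any after dropping {drop_first}"
        )
    return bounds[drop_first:]


def awe_series(
    envelope: RegionTimeSeries, epoch_seconds: float, drop_first: int = 5
) -> RegionTimeSeries:
    """Average-within-epoch envelope: one sample per retained TR epoch.

    The first ``drop_first`` epochs are discarded, mirroring the removal of
    the slow modality's initial volumes, so AWE samples align one-to-one
    with retained volumes.
    """
    bounds = _epoched_envelope(envelope, epoch_seconds, drop_first)
    vals = np.stack(
        [envelope.values[a:b].mean(axis=0) for a, b in bounds], axis=0
    )
    return replace(
        envelope, values=vals, sampling_rate=1.0 / epoch_seconds
    )


def wts_series(
    envelope: RegionTimeSeries,
    epoch_seconds: float,
    drop_first: int = 5,
    include_trailing: bool = False,
) -> RegionTimeSeries:
    """Whole-time-series envelope with the first ``drop_first`` epochs removed.

    By default the trailing partial epoch is also dropped, so taking the
    per-epoch mean of the WTS output reproduces the AWE output exactly.
    With ``include_trailing=True`` the samples after the last full epoch are
    retained instead.
    """
    bounds = _epoched_envelope(envelope, epoch_seconds, drop_first)
    start = bounds[0, 0]
    stop = envelope.n_samples if include_trailing else bounds[-1, 1]
    return replace(envelope, values=envelope.values[start:stop])
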