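"""From band-limited signals to a partial-correlation connectome.

Simulates one subject's alpha-band activity, extracts the Hilbert
amplitude envelope, averages it within repetition-time epochs (AWE), and
estimates the shrinkage-regularized normalized precision matrix.
"""

import numpy as np

from conncca import (
    SyntheticSpec,
    hilbert_envelope,
    awe_series,
    make_coupled_timeseries,
    normalized_precision,
    partial_correlation,
    shrinkage_covariance,
)

spec = SyntheticSpec(
    n_subjects=1, n_regions=10, n_samples=200 * 108, sampling_rate=50.0,
    bands=(("alpha", 8.0, 13.0),), coupling=0.8, subject_dev=0.5, seed=7,
)
slow, banded, truth = make_coupled_timeseries(spec)

ts = banded["alpha"][0]
env = hilbert_envelope(ts)
awe = awe_series(env, epoch_seconds=2.16, drop_first=5)
print(f"alpha-band series: {ts.n_samples} samples at {ts.sampling_rate} Hz")
print(f"AWE envelope: {awe.n_samples} samples (one per retained TR epoch)")

cov = shrinkage_covariance(awe)
conn = normalized_precision(cov)
pc = partial_correlation(conn)
print(f"shrinkage intensity lambda = {cov.shrinkage_lambda:.3f} "
      "(0 = raw sample covariance, 1 = identity target)")

# compare the estimated partial correlations to the planted envelope
# covariance structure for the three strongest planted connections
from conncca import Connectome

C_env = truth["envelope"]["alpha"][0]
planted_pc = partial_correlation(
    normalized_precision(
        Connectome(matrix=C_env, labels=ts.labels, kind="covariance")
    )
)
iu = np.triu_indices(spec.n_regions, k=1)
order = np.argsort(-np.abs(planted_pc[iu]))[:3]
print("\nstrongest planted connections (planted vs estimated partial corr):")
for k in order:
    i, j = iu[0][k], iu[1][k]
    print(f"  {ts.labels[i]} - {ts.labels[j]}: "
          f"{planted_pc[i, j]:+.3f} vs {pc[i, j]:+.3f}")
print("\nEstimates track the planted structure; residual differences come "
      "from finite-sample noise and shrinkage bias.")
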