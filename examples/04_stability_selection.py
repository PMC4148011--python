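"""Stability selection: which connections drive the cross-modal linkage?

Runs randomized-Lasso sparse CCA on data with a planted sparse linkage:
each repetition perturbs every column's effective penalty with a random
weight in {0.5, 1} and refits; the fraction of repetitions selecting a
column estimates its selection probability.
"""

import numpy as np

from conncca import make_linked_edge_datasets, randomized_scca, top_selection

n, p, q, support = 17, 200, 200, 5
X, Y, link = make_linked_edge_datasets(
    n, p, q, support, score_sd=2.0, noise_sd=0.2, seed=11
)

c = np.sqrt(support)  # L1 bound matched to a 5-sparse unit target
profile = randomized_scca(X, Y, c, c, n_reps=200, seed=11)

on = profile.x_probabilities[link.u_support]
off = np.delete(profile.x_probabilities, link.u_support)
print(f"{profile.n_reps} randomized repetitions at c1 = c2 = {c:.2f}")
print(f"planted columns' selection probabilities: {np.round(on, 2)}")
print(f"off-support: median {np.median(off):.2f}, "
      f"95th percentile {np.percentile(off, 95):.2f}")

top = top_selection(profile, fraction=0.02)
top_cols = [k for k, _ in top["x"]]
print(f"top 2% selected columns: {sorted(top_cols)[:10]}")
print(f"planted support: {sorted(link.u_support.tolist())}")
print("\nPlanted connections are selected in (almost) every repetition "
      "while noise columns rarely survive the random down-weighting — the "
      "selection probability separates signal from noise edges.")
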