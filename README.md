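# conncca

Statistical framework for relating two sets of whole-brain functional
connectomes — the band-limited-power (BLP) envelope networks of a fast
electrophysiological modality (EEG-like) and the networks of a slow
haemodynamic modality (fMRI-like) — recorded in the same subjects.

It is written for researchers who have region-level time series (or
precomputed connectivity matrices) for two modalities per subject and want
to know (a) how similar the two sets of networks are, (b) how well one
modality's connectome predicts the other's for an unseen subject, and
(c) which connections carry that cross-modal relationship.

## The model

For each subject, modality, and frequency band, functional connectivity is
the **normalized precision matrix**: the inverse of the shrinkage
covariance estimate

&nbsp;&nbsp;&nbsp;&nbsp;Σ̂<sub>λ</sub> = λ·I + (1 − λ)·Σ̂,

with λ the analytic (Ledoit–Wolf-type) intensity for the identity target,
rescaled to unit diagonal. Its off-diagonals are (up to sign) the partial
correlations between regions conditional on all others. For the fast
modality the input series is the Hilbert amplitude envelope of the
band-passed signal, either at full resolution (WTS) or averaged within
repetition-time epochs (AWE).

Subject connectomes are vectorized (upper triangle) into two blocks
**X** (subjects × p edges) and **Y** (subjects × q edges) and coupled by
**sparse canonical correlation analysis**:

&nbsp;&nbsp;&nbsp;&nbsp;max<sub>u,v</sub> uᵀXᵀYv  s.t. ‖u‖₂ ≤ 1, ‖v‖₂ ≤ 1, ‖u‖₁ ≤ c₁, ‖v‖₁ ≤ c₂,

solved by alternating closed-form soft-threshold updates (biconvex, the
objective never decreases), with (c₁, c₂) chosen by a permutation scheme.
A held-out subject's connectome is predicted through the canonical space,
ŷ = (x − x̄)·U·D·V⁺ + ȳ, and compared to the measured one with the
**affine-invariant geodesic distance** on the SPD manifold,

&nbsp;&nbsp;&nbsp;&nbsp;d<sub>AI</sub>(P, G) = ‖log(G<sup>−1/2</sup> P G<sup>−1/2</sup>)‖<sub>F</sub>,

under leave-one-out cross-validation. Because d<sub>AI</sub> grows with
matrix order, a Wishart simulation calibrates an order normalization for
comparisons across network sizes. Finally, **randomized-Lasso stability
selection** (random per-column penalty weights in {0.5, 1}, many refits)
assigns each connection a selection probability, with all frequency bands
concatenated so one sparsity budget covers them.

No subject recordings ship with the package; `conncca.synthetic`
generates paired-modality data with planted covariance structure (a
per-subject SPD matrix shared, to a chosen degree, between modalities) so
every stage can be exercised against a known truth.

## Worked example

`python examples/04_stability_selection.py` plants a 5-edge linkage among
200 + 200 edge variables in 17 subjects and runs 200 randomized-Lasso
repetitions:

```
200 randomized repetitions at c1 = c2 = 2.24
planted columns' selection probabilities: [1. 1. 1. 1. 1.]
off-support: median 0.00, 95th percentile 0.43
```

Every planted connection is selected in all 200 repetitions while a
typical noise edge is selected in none — the selection probability cleanly
separates the connections that carry the cross-modal relationship from the
rest. The other examples walk through envelope extraction and connectome
estimation (`01`), the SPD metric and its order calibration (`02`),
sparse-CCA fitting and bidirectional prediction (`03`), and the end-to-end
pipeline (`05`).

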