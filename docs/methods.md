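# Methods

This note records the models, estimators, and design choices behind
`conncca`, in the order the pipeline applies them, together with the
numerical conventions and the limits of what the synthetic experiments can
show.

## Envelope extraction

Band-limited power is extracted per region with a second-order Butterworth
band-pass applied forward and reverse (`sosfiltfilt`), so the effective
magnitude response is the squared one-pass response and the phase delay is
zero. The five canonical bands are δ 1–4 Hz, θ 4–8 Hz, α 8–13 Hz,
β 13–30 Hz, γ 30–70 Hz; a band is rejected when its upper edge reaches the
Nyquist frequency. Edge transients are bounded by reflective padding of
roughly one epoch (2.16 s by default); padding plus the discard of the
first five epochs keeps filter transients out of every estimate.

The amplitude envelope is the magnitude of the analytic signal. Two
summarizations feed connectome estimation: **WTS** keeps the envelope at
full resolution, **AWE** averages it within repetition-time epochs
(`round(epoch_seconds × sampling_rate)` samples each; 2.16 s × 250 Hz = 540
exactly). Both drop the first `drop_first` (default 5) epochs, mirroring
the removal of the slow modality's initial volumes; by default WTS also
drops the trailing partial epoch so that per-epoch means of the WTS output
reproduce AWE exactly (a flag keeps the trailing samples instead — the two
conventions differ only in those samples). A single retained epoch is the
minimum accepted input: the epoch-mean of one epoch is still well defined.

## Connectome estimation

Covariance is estimated on column-centered data with 1/(T−1) scaling, then
shrunk toward the identity with intensity
λ* = Σ<sub>ij</sub> Var̂(Σ̂<sub>ij</sub>) / Σ<sub>ij</sub>(Σ̂<sub>ij</sub> − I<sub>ij</sub>)²,
the entrywise variance estimated from per-sample outer products
(Schäfer–Strimmer form), clipped to [0, 1]. This is the analytic optimum
for the fixed identity target; note scikit-learn's `LedoitWolf` uses the
*scaled* identity target and is therefore a different estimator. When the
data carry no sampling variability at all and the sample covariance is
singular (e.g. all-constant input), the estimator falls back to λ = 1,
returning the target. The estimate is SPD whenever λ > 0.

The connectome is the inverse covariance rescaled to unit diagonal; its
off-diagonals are minus the partial correlations, and it is invariant to
per-region rescaling of the input. Edges are stored from the upper
triangle, row-major — one convention used everywhere (the lower triangle
would carry the same information). Graphical-lasso-style sparse precision
estimation is deliberately not offered: its predictions are frequently not
positive definite in this pipeline's prediction step.

## Geometry on the SPD cone

d<sub>AI</sub>(P, G) = √Σ log²λ<sub>i</sub>, with λ<sub>i</sub> the
generalized eigenvalues of (P, G). The eigenvalue route avoids matrix
square roots and logarithms; its agreement with the explicit matrix-log
form is a test, not an assumption. (A printed variant of this metric as
tr(log ·)² appears in the literature; that expression is not a metric —
cancelling log-eigenvalues would give zero distance between distinct
matrices — so the Frobenius form is used.)

Predictions are only guaranteed symmetric with unit diagonal, not SPD.
`repair_spd` clips the spectrum at a floor (default 10⁻⁶ × the largest
eigenvalue) and reports whether it had to act; the evaluation loop counts
repairs per direction rather than hiding them, and a strict mode records
the prediction as missing instead.

Because d<sub>AI</sub> between equally-noisy estimates grows with matrix
order, `calibrate_order_normalization` draws pairs from Wishart(dof, I/dof)
(identity expectation; default dof = 2×order — the minimal dof produces
near-singular draws) at a range of orders, records the median pair
distance, and fits a line to median-versus-order. Dividing by the fitted
value at the matrices' order makes distances comparable across the 68- and
82-region configurations; over orders 10–100 the line fit achieves
R² ≳ 0.97 (the underlying trend is ∝ √order · order-free constant at fixed
dof/order, which is indistinguishable from linear over this range).

## Sparse CCA

The biconvex criterion max uᵀXᵀYv under ‖·‖₂ ≤ 1 and ‖·‖₁ bounds is solved
by alternating exact updates: the optimal u for fixed v is the
L2-normalized soft-threshold of XᵀYv, the threshold found by bisection so
the L1 bound binds (to within 10⁻⁹) or is slack at zero. The objective is
monitored every iteration and never decreases. v is initialized at the
leading right singular vector of the (deflated) cross-product, computed by
deterministic power iteration, so fits are reproducible without a seed.
Successive components deflate the cross-product by the rank-one term
(uᵀMv)·uvᵀ; the number of components is capped at the minimum rank of the
centered blocks. The per-component canonical correlation D<sub>k</sub> is
the in-sample Pearson correlation of the canonical variates.

Internally the (deflated) cross-product is held in factored form
(XᵀY = dense product is never materialized), making each update
O(n(p+q) + Kp) — the regime here is always n (≤ tens of subjects) far
below p·q (10⁴–10⁸).

Penalties are chosen by permutation: for each grid point the first
canonical correlation is compared, on the Fisher-z scale, with its
distribution over row-permuted copies of X, and the point with the largest
standardized gap wins. The default grid places matched L1 bounds at
fractions 0.1–0.8 of √p and √q. Two behaviors of this score at subject
counts far below the edge count are worth knowing: the permuted-fit spread
*shrinks* as penalties loosen (extreme singular values of permuted
cross-products concentrate), so the standardized score tends toward an
extreme of the grid even when the raw gap peaks at the true sparsity; and
with fewer than ~30 permutations the per-point spread estimate is noisy
enough to scramble the ranking — the package defaults to 25 and the
full-scale experiments use 49.

Prediction maps through the canonical space:
ŷ = (x − x̄)·U·D·V⁺ + ȳ and symmetrically for x̂, with V⁺ the
Moore–Penrose pseudoinverse returning canonical scores to edge space. This
reading of the prediction equations is forced by dimensional consistency.
One consequence: scores transfer at their X-side scale (no score-variance
renormalization), so when the two blocks share a factor with very
different loading scales the transferred deviation has the wrong
magnitude; with comparable loading scales — the situation the estimators
produce here — the formula behaves as standard reduced-rank prediction.
On a noiseless rank-one linkage it reproduces held-out rows to machine
precision.

For stability selection, each repetition scales every column of X̆ (bands
concatenated) and of Y by an independent weight drawn from {0.5, 1} —
equivalent to perturbing that column's effective penalty — refits at fixed
(c₁, c₂), and marks a column selected if its coefficient is nonzero in any
retained component (configurable; the default retains one component). The
selection probability is the count over repetitions (default 1000;
experiments here use 200). The penalty for this stage is an analysis
choice; matching the L1 bound to the expected support size k via c = √k
(the L1 norm of a balanced k-sparse unit vector) is the package's default
guidance, and the randomization makes the result insensitive to the exact
value within the sparse regime.

## Evaluation

Leave-one-out cross-validation re-selects penalties inside every training
fold (costlier than one global choice, but the fold must not see the
held-out subject), fits with K = min rank of the training blocks, predicts
the held-out connectome in both directions, devectorizes, repairs and
counts non-SPD predictions, and records d<sub>AI</sub> to the measured
connectome. Reference comparisons: the within-subject inter-modal distance
(measured vs measured across modalities) and the inter-subject variability
(all subject pairs within a modality).

Group comparisons use a two-sided Wilcoxon rank-sum test (independent
samples: directions, bands) and a paired Wilcoxon signed-rank test
(matched per-subject values; zero differences dropped). Both enumerate the
exact null for up to 12 (nonzero) observations — ties handled through
midranks — and otherwise use the tie-corrected normal approximation
without continuity correction; p-values are reported raw, with no
multiple-testing correction.

## Synthetic data

The generator plants the structure the analysis assumes. Each subject
owns C<sub>s</sub> = B + subject_dev·W<sub>s</sub>, with B a fixed random
correlation-like base (factor model plus ridge, unit diagonal) and
W<sub>s</sub> ~ Wishart(2R, I/2R) — SPD by construction, inter-subject
spread set by `subject_dev` (default 0.5, giving per-edge subject
variation comparable to the estimation noise of a few hundred samples, so
prediction is informative but not trivial). The slow modality is a
temporally smoothed Gaussian series with covariance exactly
C<sub>s</sub>, sampled once per TR.

Per band, amplitude envelopes are lognormal: a Gaussian log-envelope is
moment-matched so that the envelope covariance equals
coupling·C<sub>s</sub> + (1 − coupling)·R<sub>s,band</sub>, with
R<sub>s,band</sub> an independent subject- and band-specific SPD component
of the same construction — `coupling` (default 0.8) is thus literally the
fraction of envelope covariance shared with the slow modality.
Envelopes are smoothed on a ~0.5 s timescale, exponentiated (positivity),
and multiplied onto carriers of band-filtered white noise normalized to
unit mean envelope: the measured Hilbert envelope then has off-diagonal
covariance exactly equal to the planted mixture (diagonals are inflated by
the carrier's own Rayleigh-distributed envelope fluctuations). Carriers
and log-envelope innovations are independent across bands, so inter-band
envelope correlations are near zero even though the band covariance
*matrices* are similar. Non-SPD intermediates are retried with escalating
diagonal jitter and reported after five failures.

Defaults mirror the reference study design at desk scale: 17 subjects,
five bands, TR 2.16 s at 250 Hz (540 samples/epoch), 300 epochs, 30
regions. The full-scale statistical experiments in the test suite and the
acceptance script use one band (α) at a reduced sampling rate of 40 Hz
with AWE summarization — the arithmetic of the envelope chain is exercised
separately at the full 250 Hz — and a 2-point penalty grid with 10
permutations inside each cross-validation fold.

What the generator does **not** emulate: volume conduction and source
leakage, acquisition artifacts, nonstationarity, 1/f spectral structure
within bands, hemispheric or distance-dependent network topology, and any
nonlinear envelope–haemodynamics transfer. Passing tests therefore show
that the estimators recover planted linear-Gaussian covariance structure,
not that real cross-modal recordings satisfy these assumptions.

`make_linked_edge_datasets` bypasses the time-series layer entirely,
planting a sparse rank-one linkage directly in edge space (X = t·u*ᵀ + E);
it is the ground truth for the sparse-CCA recovery and stability-selection
experiments. `make_wishart_pairs` backs the order calibration. The region
label fixture provides the standard 68 cortical (34 per hemisphere) and 14
subcortical labels, subcortical first, matching the conventional matrix
layout.

## Numerical conventions and degenerate inputs

- Bisection for the L1 threshold: tolerance 10⁻⁹ on the bound, at most 80
  halvings; an interval collapse keeps the largest-magnitude coordinate.
- Alternating updates stop when the relative objective change falls below
  `tol` (default 10⁻⁷) or `max_iter` (200). Near-degenerate leading
  singular gaps slow convergence; the SVD-equivalence checks run at
  tol = 10⁻¹³.
- Ranking ties (edge thresholding, top selections) break by edge index
  order, making outputs deterministic.
- An all-zero cross-product ends component extraction with a warning; a
  zero canonical variate yields D<sub>k</sub> = 0.
- Degenerate rank tests (all differences zero, or all values tied) warn
  and report p = 1.
- All stochastic stages take explicit seeds; fits themselves are
  deterministic.

## Known limitations

- The permutation penalty score's drift toward loose penalties at n ≪ p
  (above) means support recovery is reliable but the *selected* penalty is
  usually not in the sparse regime; interpretable supports should come
  from the stability-selection stage, not from a single fit at selected
  penalties.
- Prediction restores the training mean, so any baseline that a
  mean predictor beats (e.g. distance to other subjects' connectomes) is
  also beaten by the full model even when no cross-modal signal exists;
  judging whether the model transfers subject-specific structure requires
  comparing against the mean predictor itself.
- In-sample canonical correlations D overestimate transferable correlation
  when subjects are few; the cross-validated distances, not D, are the
  performance measure.
- The lognormal envelope construction fixes the envelope covariance but
  not higher moments; envelope *distributions* are only qualitatively
  realistic.
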