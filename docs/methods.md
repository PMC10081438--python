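# Methods

This note documents the models, estimators and design choices behind
`metastate`, in the spirit of a package methods appendix: what is computed,
under which assumptions, with which defaults, and what the synthetic
validation does and does not establish.

## Windowing, bands and exclusion

All analyses live on a regular grid of non-overlapping 5-s windows.
Coherence is estimated within each window by Welch's method with 1-s Hann
segments at 50 % overlap (nine segments per window), giving 1-Hz bin
spacing so the 4–8 Hz theta band is resolved; band values are unweighted
means of magnitude-squared coherence over bins with center frequency in
[low, high), half-open so band edges are never double-counted. The
estimator carries the usual positive small-sample bias (~0.11 for nine
segments on independent signals), which is why the independent-noise
acceptance bound is 0.15 rather than 0. Windows overlapping a padded
exclusion interval (default one hour around ictal events) are masked and
propagate as missing values; no step, autocorrelation lag or histogram ever
spans a masked window. Re-referencing is assumed done upstream.

One practical consequence of band averaging: a *pure tone* shared at 10 dB
SNR cannot push a 4-bin band mean much above ~0.78, because bins without
signal contribute only the estimator bias. Band-level claims about a shared
"alpha rhythm" therefore use band-limited shared signals; the estimator is
verified bin-for-band against scipy's independent Welch coherence to
machine precision either way.

## Parcellation and timescales

Channels are grouped by average-linkage agglomerative clustering on
distance 1 − mean coherence. When electrode coordinates are available, a
radius graph (default 15 mm) defines spatial adjacency; channels in
different connected components never merge (each component is clustered
separately with a proportional share of the parcel budget, and sklearn's
structured agglomeration enforces contiguity within components). The number
of parcels defaults to the community count of the coherence graph
thresholded at its 90th percentile under greedy modularity maximization —
the threshold is high because for compact parcels the within-parcel pairs
are a small minority of all pairs. Undersized clusters are absorbed into
their most coherent same-component neighbor.

Each parcel/band series gets a timescale from a least-squares fit of
A·exp(−lag/τ) to the empirical autocorrelation at lags 1..50, computed only
across contiguous retained runs. The estimate is reported as identifiable
only when A > 0.1 and fit RMSE < 0.1 (white noise fails this). Network
contrasts are paired differences across recordings with Holm-corrected
two-sided t-tests; the matrix is antisymmetric by construction.

## Robust PCA and interactions

Principal component pursuit (nuclear norm + ℓ1, inexact augmented-Lagrange
iterations, λ = 1/√max(n, p), ρ = 1.5, tolerance 1e−7) splits the centered
feature matrix into low-rank and sparse parts; loadings are the top right
singular vectors of the low-rank part, with the component count defaulting
to the smallest number explaining 80 % of its variance. Activations are
computed by projecting the raw (not low-rank) centered rows — the sparse
part is treated as transient contamination of individual entries, not of
whole windows.

The pairwise interaction test builds per-day 25 × 25 joint histograms over
each component's 1st–99th percentile range, and measures (a) the mean
Jensen–Shannon distance between day joints ("cross-day") and (b) the mean
distance from each day joint to its product of marginals ("null"). The test
statistic is the gap (b) − (a): large when the joint is both far from
independence and stable across days. Significance comes from circular
shifts of the second component within each day (offsets ≥ 10 min), which
preserve autocorrelation. The flag is the calibrated permutation test
alone; the raw comparison (a) < (b) is reported but not required, because
empirical-vs-empirical distances carry more histogram-sampling bias than
empirical-vs-smooth-product distances and the gap statistic already encodes
the direction.

## Physiology links

Both links are strictly split-half in time: fit on the first half of
retained windows, frozen evaluation on the second. Time of day is encoded
circularly as (sin φ, cos φ) of the 24-h phase and linked by one-component
CCA; heart rate by lasso with the penalty chosen by blocked (contiguous,
unshuffled) cross-validation inside the training half. Significance uses
circular time shifts of the held-out target (minimum 2 h) rather than
i.i.d. shuffles, because both sides are strongly autocorrelated.

The circadian p-value is one-sided on the signed held-out correlation. With
a periodic target this matters: a two-sided |r| comparison ties with
anti-phase surrogate shifts, while excluding near-(half-)period shifts from
the surrogate pool would break exchangeability and mis-calibrate the null.
The one-sided comparison keeps the null uniform (checked by a
Kolmogorov–Smirnov test over repeated no-signal simulations) without
sacrificing power, since a genuine link evaluated with frozen CCA weights
is positive.

## Punctuated-equilibrium statistics

*Speed* is the Euclidean step length between consecutive windows'
activation vectors. *Events* are steps in the top 10 % of speed, matching a
homogeneous Poisson rate λ = 0.1/window whose expected mean inter-event gap
is 1/λ = 10 windows. The observed and expected mean gaps are reported as
such, but the p-value is computed from the **median** inter-event gap under
simulated Poisson trains of matched length and count: the mean gap
telescopes to (t_last − t_first)/(k − 1) and is therefore fixed by count
and span alone, carrying essentially no clustering information, whereas the
median collapses toward 1 for bursty trains.

*Segmentation* thresholds the speed series at a Tukey far-out fence
(Q3 + 3·IQR): burst occupancy varies strongly between recordings, so a
fixed quantile under- or over-shoots, while the quartiles are pinned by the
within-state speed mode whenever bursts are a minority. Isolated
single-step crossings are discarded before sub-threshold dips of up to 3
steps are bridged (the discard must come first, or trailing spikes extend
burst ends), and a surviving burst must contain at least one step above
twice the fence. State segments are clustered into identities by k-means on
segment-mean activations with silhouette-selected k (2–8, seeded).

*Circuitousness* is path length over displacement (≥ 1 by the triangle
inequality; segments with near-zero displacement are excluded). The
transition-vs-state comparison uses duration-matched state subsegments: raw
state segments last hundreds of windows, so their path length — and hence
their ratio — grows with duration regardless of dynamics, and an unmatched
comparison would be a duration effect, not a dynamics effect.

*Divergence profiles* resample each transition by arc length to a common
progress grid and compare the mean pairwise distance among transitions
sharing both endpoints against those sharing only the start, as a Cohen's d
per progress fraction. Analyses of heterogeneous recordings should
condition on comparable arousal (e.g. wake-to-wake transitions); mixing
regimes with different overall excursion scales inflates within-group
spread at late progress.

*Chaos* uses the Gottwald–Melbourne 0–1 test, correlation variant: K is the
median over random c ∈ (π/5, 4π/5) (restricted to avoid resonance) of the
correlation between time and the oscillation-corrected mean-square
displacement of the translation variables. Inputs longer than 5000 samples
are decimated evenly (the test is O(n²/10)); multivariate series are
reduced by the median of per-component statistics; constant series return
K = 0 with a flag. Like any 0–1 test application, diffusive stochastic
input also scores K ≈ 1 — regime contrasts are therefore made on contiguous
runs where deterministic structure can express itself, and the synthetic
validation plants quasi-periodic within-state dynamics for exactly this
reason.

*Power laws* follow Clauset–Shalizi–Newman: xmin by KS-distance scan,
exponent by MLE (closed form continuous; Hurwitz-zeta likelihood discrete),
goodness of fit by semiparametric bootstrap (p < 0.1 rejects), and
Vuong-normalized pointwise likelihood-ratio tests against exponential
(shifted-exponential / geometric) and lognormal (truncated, numerically
fitted) alternatives, positive statistics favoring the power law. Window
counts use the discrete formulation, transition sizes the continuous one.

## Koopman embedding

The latent space is a fixed nonlinear observable dictionary: the current
activations, lagged copies spread over a 24-window (2-min) context, and all
degree-2 monomials of the current activations (d = 10 components lifts to
105 observables). One-step evolution in this space is modeled as affine,
z_{t+1} ≈ K z_t + b, with K, b and the linear decoder fit by ridge least
squares on all training pairs; reconstruction, one-step and 8-step-rollout
losses are computed and logged. Because the lift is deterministic and the
fits are closed-form, training is exactly reproducible and the operator is
exactly linear — multi-step prediction is literally repeated application of
(K, b). Two whole days are held out of every operator fit (an index audit
raises if a training pair touches a held-out window) so that behavior
decoding can be trained on one unseen day and tested on the other. The
dictionary is deliberately minimal: it is the smallest lift that provably
recovers the spectrum of linear benchmark systems and of the
polynomial-embedding benchmark (x1 ← 0.9 x1, x2 ← 0.5 x2 + 0.31 x1², whose
exact lift {x1, x2, x1²} has spectrum {0.9, 0.5, 0.81}).

**Attractor.** The fixed point z* solves (I − K) z = b. Modes with
|1 − λ| < 0.05 — slow decay or slow oscillation — are "center-like": they
carry persistent structure rather than attraction, and because the solve
divides by (1 − λ) they amplify the finite-sample mismatch between the
regression's implied mean and the true long-run mean. These modes are
deflated and anchored at the mean of the analyzed lifted trajectory; the
result is flagged. The decoded pattern and its aggregation over
(network, band) feature groups give the attractor's network signature.

**Center manifold.** The axis spans the modes with |λ| closest to 1
(complex pairs contribute two real dimensions); along/off projectors are
the spectral (oblique) projectors onto that span and its complement, which
sum exactly to the identity. The axis sign is fixed so wake centroids
exceed sleep centroids (a presentation convention). The along coordinate is
the real left-eigencoordinate; the off part is summarized by its top
principal components for chaos and autocorrelation contrasts.

## Behavior

Decoding uses L2-regularized one-vs-rest logistic classifiers (blocked CV
over the penalty grid inside the training day, shared scaling pipeline and
folds for both feature sets), trained on one held-out day and tested on the
other with roles swapped and scores averaged. AUC is window-level;
accuracies are additionally reported after 5-min median smoothing of the
predicted probabilities, since natural behaviors last minutes.
Neural-behavioral coincidence is the mean distance from each behavioral
change to its nearest neural burst, against circular shifts of the burst
train (≥ 30 min). Axis orderings report per-category centroids of the
along-coordinate with across-recording CIs and Holm-corrected paired tests
between declared x-axis neighbors only; the network map is the Spearman
correlation of each (network, band) aggregate with the along coordinate,
tested across recordings with Holm correction.

## Synthetic study conditions

The generator plants, at its defaults: 8 coherent channel parcels driven by
band-limited oscillators (raw tier); 10 latent components mixed through
orthonormal loadings into 30 features labeled by (canonical network, band);
4 metastable states with discrete-power-law dwell times (exponent 1.8,
xmin 12 windows = 1 min — xmin 1 would put ~38 % of dwells at a single
window, merging adjacent bursts and contradicting minutes-to-hours states);
transition bursts of 8–24 windows whose paths interpolate between states
under a logistic-map (r = 3.99) perturbation with a sin(πu) envelope at
half the inter-state separation, so paths converge only near their
destination; mean reversion (rate 0.1/window) toward an attractor loaded on
a default-mode/theta-concentrated component; a 24-h circadian drive; a slow
sleep-wake axis whose thresholds define behavior and sleep-stage labels
(active > wakeful rest > N1 > REM > N2/N3) and gate the expression of state
offsets (0.5–1.0), giving the hourglass its narrow waist; a persistent-sign
V-shaped dependent pair; heart rate coupled to three designated components;
and a quasi-periodic within-state rhythm (amplitude 0.5, period 40 windows)
providing the deterministic structure that makes states legible as
non-chaotic to the 0–1 test. Dynamics noise is white with SD 0.1 (real
iEEG-derived features have colored noise; this is configurable and a known
simplification). Generation is bit-identical given the configuration.

Validation sizes are chosen to make each check sharp but cheap: the
reference stream spans 4 synthetic days (69 120 windows), raw-tier
demonstrations span minutes at 200 Hz, calibration checks use 100–200
simulated null instances, and chaos statistics use 5000-sample series.

## What passing tests show — and what they do not

Parameter-recovery tests show the estimators invert the generator's planted
structure under its assumptions: block-coherent parcels, low-rank linear
mixing, abrupt state switches with chaotic interpolation, sinusoidal
drives, white dynamics noise. Real recordings violate several of these
(colored noise and artifacts, non-orthonormal mixing, drifting electrode
properties, behavior-dependent spectra), so passing here demonstrates
correctness of the machinery and calibration of the tests, not performance
on patient data. Calibration checks (interaction flags, circadian and
coincidence nulls) are the strongest transferable guarantees, since they do
not depend on the planted signal model.

## Known limitations

- The observable dictionary is fixed, not learned; systems whose Koopman
  eigenfunctions are far outside the span of delays and quadratics will be
  approximated, not recovered.
- The 0–1 test cannot distinguish chaos from stochastic diffusion; regime
  comparisons are meaningful, absolute K values on noisy data are not.
- Attractor deflation (|1 − λ| < 0.05) trades bias for variance; a system
  whose genuine attraction operates slower than ~20 windows will have that
  attraction attributed to the anchor.
- The burst test's mean-gap report follows the span identity and is
  descriptive; only the median-gap p-value is inferential.
- EDF export is not provided (HDF5 only); EDF reading requires `mne`.
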