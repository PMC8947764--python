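# Methods

This note documents the models, estimators, numerical choices, and the
synthetic-data generator implemented in `interbrain`, together with what the
package's tests do and do not establish about real recordings.

## The scientific setting

During social interaction, the band-averaged neural activity (e.g. mean
normalized LFP power sampled every 2.5 s) of two subjects is often highly
correlated across brains. Writing the dyad's activity as the mean component
aM = (a1 + a2)/2 and the difference component aD = (a1 − a2)/2, the Pearson
correlation between brains can be written purely in terms of component inner
products (with hats denoting time-mean subtraction):

    corr = (ÂMᵀÂM − ÂDᵀÂD) / sqrt((ÂMᵀÂM + ÂDᵀÂD)² − 4(ÂMᵀÂD)²)

so a positive correlation is *equivalent* to the mean component having larger
variance than the difference component. Crucially, this identity constrains
magnitudes only: the *timescales* of the two components (summarized by the
power spectral centroid) are free. The package provides both the statistics
and a surrogate construction that demonstrates this freedom, plus generative
models that explain the empirically observed pattern — large/slow mean,
small/fast difference — through opposite feedback.

## The coupled linear model

Activity evolves as τ·da/dt = C a(t) + b(t) with

* C: −CS on the diagonal (functional self-coupling, a leak), CI off it
  (functional across-brain coupling — an effective, behavior-mediated
  influence, not an anatomical connection);
* b(t): behavioral modulation. Per subject and 2.5-s bin, b is the
  subject's current behavior's modulation level plus a constant offset, plus
  i.i.d. Gaussian noise (σn); between bins b is linearly interpolated.

C is symmetric: the all-ones direction (mean) has eigenvalue (n−1)CI − CS and
every orthogonal direction (the difference subspace) has eigenvalue −CI − CS.
Stability requires 0 ≤ (n−1)CI < CS. For a dyad, the components decouple into
scalar equations with effective time constants τ/(CS−CI) (mean) and
τ/(CS+CI) (difference): positive CI amplifies and slows the mean and
suppresses and speeds the difference — the core mechanism.

Default parameters (dimensionless unless noted): CS = 1, CI = 0.4 for the
shared-environment ("one-chamber") condition and CI = 0 for the separated
("two-chambers") control; τ = 15 s; σn = 0.15; session length 100 min at
dt = 2.5 s; modulation offset −0.08 (one-chamber) or 0 (two-chambers); the
11 per-behavior modulation levels range from 0.158 (resting) to 0.367
(mating). The four-subject model uses CI = 0.1 with smoothed-noise
modulation (below).

### Integration

Because the system is linear and b(t) is piecewise linear, every 2.5-s step
has an exact closed-form update. The default integrator diagonalizes C once
and advances each eigenchannel with exponential-integrator coefficients
(φ1(z) = (e^z−1)/z, φ2(z) = (e^z−1−z)/z²), evaluated as a first-order linear
recurrence. This is exact to round-off and makes a full 100-minute session
cost a few milliseconds, which is why the test suite can afford 50-session
ensembles. An adaptive Runge–Kutta route (rtol 1e-8, atol 1e-10) is kept as
`method="rk45"` for cross-validation; it integrates knot-to-knot because
b(t) has derivative kinks at the grid knots, and agrees with the exact route
to better than 1e-9.

The initial condition is the fixed point of the *noiseless* modulation at
the first bin, a(0) = −C⁻¹ bd(0); modulation noise is excluded from the
initialization.

## Behavior model

Joint behavior is a Markov chain whose states are pairs of labels from an
11-behavior vocabulary, stepped every 2.5 s. Fitting pools transition counts
across sessions; with symmetry pooling the count for AB → CD and the count
for BA → DC are each replaced by their sum (self-symmetric transitions
double), making the subjects statistically exchangeable. States with fewer
than `min_transitions` (default 100) outgoing transitions are excluded;
because dropping a state removes transitions *into* it, the exclusion is
iterated to a fixed point and the remaining rows renormalized. Laplace
smoothing (pseudo-count α) is applied after exclusion; with α > 0 the state
space is the full vocabulary product, so held-out sequences always have
support.

Order comparison fits order-0 (independent), order-1 (Markov), and order-2
models on random 80/20 session splits (default 100 splits, α = 1, no
exclusion) and scores the summed held-out log-likelihood. All orders are
scored from the third bin onward, so each order conditions on its own
history depth but scores the same number of terms. The order-2 state space
is restricted to observed history pairs, with unobserved histories falling
back to the uniform row implied by smoothing zero counts; the full product
space of histories would be astronomically large. Orders ≥ 3 are out of
scope.

The stationary distribution is the eigenvector of Pᵀ at eigenvalue 1, with a
power-iteration fallback; uniqueness is checked via strong connectivity of
the positive-probability graph, and reducible chains raise with the
components named.

## Reduced model and coupling recovery

With flat-spectrum inputs of equal power to both components, the components
become Ornstein–Uhlenbeck processes and the ratios depend only on the
couplings:

    rVar ≈ (CS + CI)/(CS − CI),    rPSC ≈ (CS − CI)/(CS + CI)

`simulate_reduced` uses the exact OU discretization (per-step i.i.d.
Gaussian innovations with variance p(e^{2λh}−1)/(2λ)), whose stationary
variance equals the closed form −p/(2λ) exactly. Feeding grid-step noise
through a linear interpolant instead would impose a sinc⁴ spectral rolloff
and bias the variance ratio upward by ~10%, which is why the OU route is
the default realization of "flat-spectrum input".

Inverting the formulas gives coupling estimates: CI = CS·(r−1)/(r+1) from a
variance ratio, CI = CS·(1−r)/(1+r) from a centroid ratio; estimates outside
[0, CS) are returned flagged, never clamped.

**A caveat the package makes explicit.** The centroid closed form is an
asymptotic statement: the centroid sums diverge, and the ratio of their
partial sums approaches 1 only logarithmically in the truncation index. At
the default conditions (τ = 15 s, T = 100 min, truncation at the 0.2 Hz
Nyquist frequency, i.e. kt = 1200), the *exact truncated* flat-spectrum
theory gives rPSC ≈ 0.55 rather than 3/7 ≈ 0.43, and simulations agree with
the truncated theory (0.54 ± 0.02). Consequently the centroid-route coupling
estimate at these conditions is ≈ 0.30, not 0.40; the variance route is
accurate (≈ 0.41). The acceptance suite reports both honestly.

### Perturbation analysis of (rVar, rPSC)

With arbitrary component input spectra B_{M,k}, B_{D,k} and decay spectra
F_k = |f̃_k|² (f̃_k the Fourier coefficients of the exponential decay),
`ratio_gradients` implements the four families of partial derivatives of
rVar and rPSC with respect to the spectra, truncated at kt with kt/T =
0.2 Hz. For perturbations δB uniform on a sphere in 2kt dimensions, the
covariance of (δBᵀ∇rVar, δBᵀ∇rPSC) is ‖δB‖²/(2kt) times the gradient Gram
matrix; the leading eigenvector of this 2×2 matrix is the local linear
trend relating the two ratios, and the eigenvalue gap measures its
strength. The default perturbation norm is 1% of ‖B‖ — the trend direction
is norm-independent. Both the gradients (against finite differences) and
the covariance (against a 10⁴-sample Monte-Carlo oracle) are verified in
the tests.

## Surrogate construction

Given a dyadic session, the surrogate keeps the mean component and replaces
the difference component by: uniform noise smoothed with a 1000-s moving
average (edges truncated), mean-subtracted, orthogonalized against the mean
component, combined with cot(angle(ÂM, ÂD))·ÂM/‖ÂM‖, rescaled to ‖ÂD‖, and
re-offset by the original difference's time mean. The construction preserves
the inter-brain correlation and both component variances *exactly* (the
tests check 1e-10) while the surrogate difference inherits the smoothing
filter's slow timescales — demonstrating that relative timescales are not
implied by magnitudes or correlation. Degenerate inputs (collinear
components, zero-norm residual after orthogonalization) raise informative
errors; the internal noise draw is retried a bounded number of times.

## Kuramoto alternative

The alternative coupling mechanism treats each brain as an oscillator phase,
dθi/dt = ωi + K Σj sin(θj − θi), activity (sin θ + 1)/2, integrated from
θ = (0, 0). Natural frequencies are lognormal with distributional means
0.005 and 0.01 and standard deviation 0.0005; these are interpreted as
radians/s (the source does not state a unit), which yields session-scale
oscillation periods of 10–20 min comparable to the slow power fluctuations
the pipeline analyzes — both the unit and the lognormal parameterization
(by the distribution's own mean/sd, not the underlying normal's) are
config-exposed choices rather than assertions. K = 0.0035 (one-chamber) or
0 (two-chambers). Classic theory: the phase difference locks when
|Δω| ≤ 2K. Phase coupling reproduces positive correlation and the
variance-ratio pattern but *not* the centroid-ratio reduction — its
difference component oscillates at the same frequencies as its mean — which
is the discriminating prediction the tests check.

## Analyses

* **Spectral summary**: variance is the plain 1/N sample variance; the
  centroid is the power-weighted mean frequency of the mean-subtracted,
  Hamming-windowed periodogram over k/(N·dt), k = 1..⌊N/2⌋ (DC excluded —
  after mean subtraction that bin holds leakage only). Whether the
  periodogram is normalized before the weighted average is immaterial: the
  centroid is scale-invariant, so no normalization is applied.
* **Autocorrelation**: biased (1/N) estimator of the mean-subtracted
  series, peak-normalized to exactly 1 at lag zero.
* **Rotation scans**: a′ = U⁻¹a for the counter-clockwise rotation U(θ);
  the rotated coupling is the off-diagonal of U⁻¹CU = CI·cos 2θ, vanishing
  at 45° where the rotated variables are the components. Correlation
  between rotated variables is reported raw and after regressing out both
  subjects' behavior indicator time-courses (OLS with intercept,
  minimum-norm under the rank deficiency caused by indicators summing to
  one — residuals are unique regardless).
* **Coordinated-epoch removal** drops every bin where the two labels are
  equal and correlates the concatenated remainder.
* **Cross-brain encoding**: the observer's own behavior (only) is
  regressed out of its activity; residual distributions conditional on the
  *other* subject's behavior pairs are scored by the rank-based ROC area
  (ties half-counted), classes assigned so AUC ≥ 0.5 — which also means
  finite noisy samples give AUC > 0.5 even without encoding, so only the
  coupled/uncoupled *contrast* is meaningful.
* **Difference subspace (n ≥ 3)**: the mean direction is the unit-norm
  all-ones projection; the difference subspace is its orthogonal
  complement. The average difference variance is the total variance of the
  orthonormal subspace projections divided by n−1 (equivalently computed
  from the variance partition), and subspace centroids/correlations are
  averaged over random unit directions drawn by projecting Gaussian
  vectors off the all-ones axis. The mean-direction variance is reported in
  the same orthonormal convention so the magnitude comparison is
  basis-consistent; the plain across-subject average (which differs by a
  √n amplitude scale, immaterial to centroids and correlations) is exposed
  as `mean_series` for plotting.

## Synthetic-data generator

No recordings ship with the package; the generator emulates the study
conditions. Joint behavior chains are products of two per-subject chains —
persistence (stay probability) 0.97 per 2.5-s step, switch targets uniform
by default with an optional "bat-like" preset weighting resting/active/
self-grooming — exponentially tilted toward same-behavior joint states and
renormalized. For one-chamber-like chains the tilt is calibrated by
bisection so the stationary same-behavior probability hits 0.58 (within
0.01); two-chambers-like chains use exact independence (the coordination of
separated subjects is only as high as chance).

The persistence default was calibrated once against the qualitative regime
the generator must occupy, over a grid 0.94–0.98 with 30 paired sessions
per point: every point reproduced per-session variance-ratio > 1 and
centroid-ratio < 1, surrogate timescale reversal, and the coupled/uncoupled
post-removal correlation contrast; 0.97 (≈80-s bouts, a typical ethogram
bout scale) sits mid-grid with the uncoupled mean closest to zero. Two
features matter mechanistically: bouts must be long relative to the neural
time constants (bin-level flicker between coordinated and non-coordinated
states lets the dynamics' ~25-s memory bleed coordinated modulation into
the "different-behavior" bins), and switch-target weights must not be
dominated by one behavior (conditioning on different labels then
anticorrelates the modulation levels).

What the generator does *not* emulate: session-to-session variability in
transition statistics, behavior-specific dwell times, multi-label bins,
asymmetric subjects, and the empirical transition matrices themselves.
Passing tests therefore show that the *models and estimators* behave as the
theory predicts under controlled conditions — not that any particular real
dataset does.

## Problem sizes and runtime

The exact integrator makes sessions cheap, so the test suite runs the full
prescribed ensemble sizes (50 one-chamber + 50 two-chamber sessions, 50
coupled/uncoupled pairs, 100 Kuramoto seeds per condition, 20 group-model
seeds with 1000 subspace directions, 100 order-comparison splits) in well
under a minute total. The acceptance script simulates 20 reduced-model
sessions per condition at T = 100 min.

## Known limitations

* The centroid-route coupling recovery is biased at finite session length
  (see the reduced-model caveat above); use the variance route when the
  session length is comparable to the one analyzed here.
* Coupling is symmetric, linear, and time-invariant by construction;
  nonlinear, asymmetric, or time-varying coupling is out of scope, as is
  any closed-loop influence of activity on behavior (the behavior chain is
  open-loop).
* The uncoupled control's post-removal correlation is near but not exactly
  zero (≈ +0.02–0.06 across calibration settings): the dynamics' memory
  carries some coordinated-epoch modulation into adjacent bins, a real
  property of the model rather than an estimator artifact.
* Group-model predictions are qualitative: its modulation is smoothed
  noise, not behavior-driven.
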