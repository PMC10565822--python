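# Methods

## Model and procedure

The estimator targets the zero-shear (Newtonian) viscosity of an isotropic
equilibrium system via the Green–Kubo identity: η is the time integral of
the pressure-tensor autocorrelation function (ACF) scaled by V/(k_B T).
The implementation assumes

* a stationary input series on a uniform time grid (the reader verifies
  uniformity to a relative tolerance of 1e-6);
* constant box volume per trajectory (NVT), supplied as metadata rather
  than parsed from energy files;
* isotropy, which makes six channels statistically equivalent: the three
  off-diagonal elements (transpose-pair averaged where both were stored)
  and the three diagonal half-differences (P_xx−P_yy)/2, (P_xx−P_zz)/2,
  (P_yy−P_zz)/2. All channels enter the ACF average with equal weight.

ACFs are averaged over all time origins with an FFT estimator
(zero-padded to ≥2N so the circular convolution is linear); it is
numerically identical to the direct O(N²) sum, which the tests enforce at
1e-10 relative tolerance. No mean is subtracted by default: every shear
channel has zero ensemble mean by symmetry, and subtracting a noisy sample
mean biases the long-lag tail. The unbiased (N−k) lag normalisation is the
default so the trapezoidal running integral has the correct expectation;
the biased (N) variant is available.

The running integral uses the trapezoidal rule on the uniform lag grid —
second-order accurate, so with sampling cadences of a few femtoseconds the
discretisation error is negligible against sampling noise.

### Time-decomposition fit

Per-trajectory running integrals η_i(t) are averaged to ⟨η(t)⟩ with
inter-trajectory standard deviation σ(t) (sample, N−1 divisor). Stage one
fits σ(t) = A·t^b by ordinary least squares in log–log space: exact on
noiseless power laws, A > 0 by construction, and a non-positive fitted b is
rejected as a degenerate ensemble. Stage two fits ⟨η(t)⟩ with a saturating
bi- or triexponential weighted by t^(−b), excluding t = 0 (σ(0) = 0 and the
weight diverges). The fitted asymptote η_∞ = B·Σ aᵢτᵢ is the estimate. The
functional form is empirical — it is what integrating a multi-exponential
ACF decay yields — and the time constants carry no physical interpretation.

Numerical choices in stage two:

* **Parameterisation.** B and the time constants are optimised in log
  space (positivity for free); the amplitude fractions use a stick-breaking
  map so the simplex constraint α + β ≤ 1 becomes box bounds. Gradients are
  analytic. Time constants are reported sorted.
* **Tau bounds.** τ is confined to [t_min/10, 2·t_max] of the fitted
  window. The window carries no information about much longer timescales,
  and without the bound an unbounded slow mode (huge τ, tiny amplitude) can
  ride tail noise to an arbitrarily inflated asymptote.
* **Multi-start.** 16 restarts by default: the first uses τ guesses
  log-spaced over [10·Δt, t_max/2] with equal amplitudes, the rest draw
  uniform log-τ and Dirichlet amplitudes from a seeded generator; B is
  initialised from the curve's final value over the τ-weighted amplitude
  sum. Best weighted residual wins; failure is reported only if every
  start fails. An optional warm start (e.g. the full-ensemble optimum when
  refitting subsets) is prepended to the start list.
* **Striding.** The uniform lag grid is strided down to at most
  `max_fit_points` (default 4000) before fitting. The curve is massively
  oversampled relative to a 6-parameter smooth model, so striding changes
  the solution only within optimizer tolerance while bounding cost.
* **Nesting.** On any curve the best triexponential weighted residual is
  ≤ the best biexponential one (the bi model is a boundary case of the tri
  model); the tests assert this, mirroring the empirical finding that two
  exponentials cannot capture slow-rising running integrals.

Repeat-set estimates are aggregated with uncertainty
√(Σᵢ(ηᵢ−η̄)²) — for n sets this is the sample standard deviation times
√(n−1), a deliberately conservative convention for few repeats (it
reproduces the reference workflow's printed ±5.8 / ±7.8 mPa·s from its
per-set values); the plain sample standard deviation is exposed alongside.
A truncated-range refit (`truncation_check`) quantifies how much of the
estimate rides on dynamics slower than a given window; truncating below
the slowest timescale biases the asymptote low, and the tests pin that
sign.

### Bootstrap

Subsets of 10–60 of the N trajectories are drawn 100 times each *without
replacement*, averaged, and refitted end to end (power-law exponent refit
per subset by default; a fixed-b mode reuses the full-ensemble exponent).
Mean and standard deviation of the resulting η_∞ are reported per size.
Subset fits default to a reduced multi-start budget plus the full-ensemble
warm start — subset means differ from the full mean only by resampling
noise, so the full-set optimum initialises them excellently. The fit seed
is held constant across draws so that identical subsets (e.g. size = N)
refit identically and the spread at size N is exactly zero. The whole
procedure is a deterministic function of the input curves and one seed.

## Synthetic generator

Validation inputs are sums of stationary Ornstein–Uhlenbeck (OU) modes
with ACF Σ cᵢ·e^(−t/τᵢ), making the target viscosity
V/(k_B T)·Σ cᵢτᵢ exact. Sampling uses the exact discrete AR(1) update
x_{n+1} = x_n·e^(−Δt/τ) + √(c(1−e^(−2Δt/τ)))·ξ_n initialised from the
stationary distribution, so there is no time-discretisation bias — the
sampled path *is* the stationary OU process on the grid. The default
two-mode spec (c = 0.5 bar² at τ = 1 ps plus c = 0.05 bar² at τ = 50 ps,
Δt = 0.1 ps, V = 100 nm³, T = 298 K) mimics the structure of real pressure
ACFs: a fast collisional component and a slow tail two decades apart, which
is precisely the regime where the weighted fit earns its keep.

Off-diagonal components are independent OU sums with amplitudes cᵢ.
Diagonal components are independent OU sums with amplitudes 2cᵢ, so each
half-difference channel again has exactly the target marginal ACF. The
three difference channels are then pairwise cross-correlated — unavoidable,
since the three half-differences obey the linear identity
d_xy − d_xz + d_yz = 0 and cannot be mutually independent — but the
ensemble-averaged ACF remains an unbiased estimate of the target and the
analytic oracle stays exact. Raw synthetic diagonals carry no physical
meaning beyond producing those difference channels.

What the generator does *not* emulate: the t^(−3/2) hydrodynamic long-time
tail of real pressure ACFs, fast oscillatory (non-monotone) short-time
structure, cross-correlations between off-diagonal channels of a real
tensor, and any non-Gaussianity. Passing tests therefore demonstrate that
the estimator recovers a known GK integral from realistic noise levels and
timescale spreads, not that any particular force field or system is
converged.

## Study-scale validation conditions

The end-to-end tests run the two-mode spec above with 63 trajectories in 3
sets of 21 — the reference ensemble design — at 10⁶ steps (100 ns at 0.1 ps)
per trajectory, ACFs truncated at 2000 ps (40× the slowest mode; beyond
that the running integral is pure noise). Under these conditions the
pipeline recovers the analytic viscosity to well within 10 % (0.4 % at the
fixture seed), the bootstrap spread at size 10 exceeds that at size 60, and
the size-60 bootstrap mean covers the analytic value within 3 standard
deviations. Bootstrap subsets use sizes 10–60 of N = 63 so the largest
subsets are proper subsets with non-zero spread.

## Rheometry

Cone–plate conversion uses the small-angle relation η = 3Mα/(2πR³ω),
valid for shallow cones (enforced: α ≤ 0.1 rad), where the shear rate ω/α
is uniform across the gap. The Ross–Minton law is fitted on log η by
bounded least squares: the model is exponential in its argument, and
log-space fitting equalises relative errors across a ~20-fold viscosity
range. Only the ratio k/v of crowding factor to shape parameter is
identifiable, so a single `crowding_ratio` is fitted, constrained so the
model singularity lies beyond the data range. The buffer viscosity η₀ is
fitted within [0.5, 2.0] mPa·s by default (a plausible aqueous-buffer
window; the bundled table does not include a buffer measurement) or can be
fixed. Inversion is by monotone root bracketing on log η, with the
closed-form inverse ρ = L/([η](1+(k/v)L)), L = log(η/η₀), exposed
alongside. The concentration-uncertainty band refits with all
concentrations scaled by (1∓u); duplicate concentrations are retained as
genuine repeat measurements.

## Known limitations

* The triexponential asymptote is an extrapolation; when the slowest true
  timescale approaches the fitted window the estimate biases low (tested),
  and tail noise induces a small upward bias at small ensemble sizes.
* Per-set estimates share the combined fit's noise-induced bias, so the
  set spread can fail to bracket the true value even when the aggregated
  uncertainty covers it; the uncertainty, not the set range, is the
  meaningful interval.
* The power-law noise model is empirical; ensembles whose σ(t) is not
  power-law-like (e.g. strongly non-stationary inputs) violate its
  premise, and the fit will say so only through a poor residual.
* Binary energy-file decoding and coordinate trajectories are out of
  scope; inputs are text series plus volume/temperature metadata.
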