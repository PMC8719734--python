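# Methods

This note records the model, the numerical choices and the design decisions
behind `delayosc`, including the places where the design was genuinely open
and what the package's synthetic experiments do and do not demonstrate.

## Model

**Single-cell TTFL.**  mRNA abundance follows a birth–death process whose
chemical Langevin approximation has drift `H(Z) − μX` and diffusion-variance
rate `H(Z) + μX`, with `H(z) = R/(1+(z/K)^n)` a repressive Hill function and
`Z` the delayed level `∫ X(t−s) g(s) ds`.  The gamma delay density `g`
absorbs the unmodelled intermediate reactions; it is truncated at
`τ_max = 24 h` and **renormalized**, so the delayed integral of a constant
history is that constant and the equilibrium `x*` of the macroscopic
(deterministic mean) equation solves `H(x*) = μx*` exactly.  Renormalization
after truncation is our choice — the alternative (leaving mass deficit)
would shift the equilibrium by the truncated tail and break several
identities used downstream.

**Discretization.**  For dynamics the kernel is reduced to probability
masses on the simulation/filter lag grid (step `h`): cell `j`, centred on
lag `j·h`, carries the truncated-CDF increment over `[(j−½)h, (j+½)h]`,
renormalized.  This makes very small delay SDs degrade gracefully to a
single-cell (fixed-delay) kernel.  Entropy and the Laplace transform of the
kernel are evaluated on the *continuous* truncated density by adaptive
quadrature, so they are independent of the grid resolution; the stability
classifier instead uses the discrete-mass transform `Σ w_j e^{−λ j h}` so
that the characteristic analysis refers to the same dynamics the simulator
integrates.

**Measurement.**  A frame integrates the path over the exposure window
(trapezoid rule on the simulation grid), scales by `κ` and adds
`N(0, σ_η²)` read noise.  Typical scales used throughout: peak copy numbers
150–200 molecules, `κ = 2.5×10⁻³` light units per molecule-hour, exposure
`Δt = 0.5 h`, ~250 frames (5–6 days), `σ_η = e^{−5.3/2} ≈ 0.07` light units
(the scale a two-channel read-noise fit typically yields).

**Spatial hierarchy.**  `R, K, n`, delay mean and delay SD carry
multiplicative random effects `θ_i = θ·e^{ε_i}` with an intrinsic CAR prior:
`ε_i | ε_{−i} ~ N(Σ_j w_{ij}ε_j / w_{i,+}, τ / w_{i,+})` on the
8-neighbour lattice.  The conditional variance must *shrink* with the
neighbour count for the joint Gaussian Markov random field to exist, which
fixes the `τ / w_{i,+}` form.  The joint prior is improper (rank L−1); a
sum-to-zero constraint on each field restores identifiability, enforced by
re-centring every proposal.  The hyper-variance priors are Gaussian with
variance 25 **on log τ** — a Gaussian on a variance only makes sense on the
log scale.

## Filtering likelihood

The delayed CLE is non-Markov in `X` alone, so the filter tracks the
augmented Gaussian state of the current level and its lags at spacing `h`
over one delay window (dimension `M+1 = τ_max/h + 1`, i.e. 49 at the
default `h = Δt = 0.5 h`).  Each substep propagates the mean with the
Euler-discretized drift and the covariance with the Jacobian of that map
(first-order linearization of the Hill term around the filtered mean); the
process-noise variance `(H(Z̄)+μm₀)h` is evaluated plug-in at the filtered
mean.  Frames are linear observations of the substep states (trapezoid
weights times `κh`) handled by a standard Kalman update, which also
accumulates the Gaussian predictive log-density.  Covariances are
symmetrized each frame and round-off negatives on the diagonal clamped.
With `n = 0` the model is linear-Gaussian and the filter reproduces an
independent dense-matrix Kalman filter to machine precision — the
correctness anchor for the whole recursion.  The inner loop is
numba-compiled (~0.5 ms per 250-frame evaluation), which is what makes
desk-scale MCMC feasible.

**Initialization (a deliberate deviation).**  The natural diffuse choice —
history constant at the first frame's inverted level with covariance
`x*·10` — measurably biases the likelihood: the first `τ_max` of
predictions then assume a flat pre-recording history, a transient that
*damped* parameter sets explain better than strongly oscillating ones.  On
a 16-location Type-II experiment this transient alone moved the pooled
likelihood maximum ~70 nats away from the generating parameters.  The
default (`init="observed"`) therefore seeds the lag history from the first
`M` presample frames inverted through the measurement map
(`x̂ = y/(κΔt)`, inversion-noise variance `(σ_η/(κΔt))² + x*` on the
diagonal) and accumulates likelihood from the first post-presample frame.
The constant-history variant remains available (`init="constant"`) and is
the one used in the linear-oracle equivalence tests.

## MCMC

Fixed-scan blocked random-walk Metropolis.  Blocks (dimension): CAR
hyper-variances `log τ` (5), global means (5: `log R, log K, log n`, delay
mean, delay SD), five random-effect fields (L each, spherical proposals,
re-centred), `log μ` (1), `log κ` (1), `log σ_η²` (1).  Five-dimensional
blocks propose with an empirical covariance (Cholesky of `2.38²/5` times
the covariance of a trailing 1,500-draw window, refreshed every 100
iterations with a small diagonal ridge); the trailing window matters
because weakly identified directions form curved ridges that a global
covariance fits poorly.  Every block carries a scalar step multiplier
adapted on batches of 50 iterations: multiply by `(1+c_k)` when the batch
acceptance exceeds the target (0.234 multivariate, 0.45 scalar), by
`(1−c_k)` when below, with `c_1 = 0.02` and `c_k = c_{k−1} − c_{k−1}/10⁴`
per iteration (diminishing adaptation).  Note the direction: steps *grow*
when acceptance is high — the opposite convention would drive the sampler
into degeneracy.

Priors: `log R, log K, log n, log κ ~ N(0, 100)`; delay mean uniform on
(0, 24), delay SD uniform on (0, 20); `log μ ~ N(−0.55, 0.25²)`
(informative, from reporter half-life); `log σ_η² ~ N(−5.3, 0.17²)` by
default (a typical two-channel fit; replace with the output of
`fit_noise_prior` for real recordings); `log τ ~ N(0, 25)`.  Proposals
producing a per-location delay mean at or beyond `τ_max`, or any non-finite
likelihood, are auto-rejected.  Location likelihoods are cached and
recomputed only for blocks that touch them; the hyper-variance block
touches none.  The first half of every chain is burn-in.

Starting values come from coarse spectral heuristics: the dominant period
of the mean signal sets the delay mean (≈ 0.4 of a period), the signal
level sets `κ` through a reference scale of 100 molecules (mid-way to
typical peaks), and `R = 2μK` places the equilibrium at that scale.

Diagnostics: batch-means effective sample size at batch `⌊√n⌋` with the
lugsail correction `2σ̂²(b) − σ̂²(b/3)` by default.

## Stability and robustness

Linearizing the macroscopic equation about `x*` gives the characteristic
function `F(λ) = λ + μ − H'(x*)·ĝ(λ)`.  Since `H'(x*) ≤ 0`,
`F(0) = μ − H' > 0`: real roots never cross zero and instability is
Hopf-type.  Right-half-plane roots are counted by the argument principle on
the rectangle `Re λ ∈ (10⁻⁶, μ+|H'|+0.1]`, `|Im λ| ≤ max(4π/mean,
1.1(μ+|H'|))` (the second term guarantees the rectangle contains every
root admitted by the modulus bound `|λ| ≤ μ+|H'|`).  The contour is
refined wherever the phase of `F` jumps by more than π/3; a non-integer
winding number, or `|F|` within tolerance of zero on the imaginary-axis
edge (a neutral case), falls back to the simulation oracle: deterministic
integration over 20 nominal periods from a 1%-perturbed history, classified
as limit cycle if the late-window excursion exceeds twice the initial
perturbation (covering early saturation onto the cycle) or still grows.
The classifier and oracle agree on all 225 cells of the 15×15
(n, delay-SD) grid used in the acceptance suite.

Robustness `V̂` is the mean of the binary classification over post-burn-in
draws (thinned ×10 by default), with Monte-Carlo SE `√(V(1−V)/ESS)`.

## Inhibition profile

`IP(k) = −H'(x*)·g(k)/x*` follows from the chain rule: the transcription
functional depends on the past level at lag `k` only through the delay
density.  Values are stored as cell-averaged densities (`weights/h` scaled),
so the lag quadrature of the standardized profile is exactly 1 and the
total inhibition is exactly `−H'(x*)/x*`.  The standardized IP *is* the
truncated delay density; its entropy therefore equals the delay-kernel
entropy, and the finite-difference functional derivative is kept as a test
oracle only.

## Ensemble perturbation studies

Matched perturbed/unperturbed ensembles share a deterministic limit-cycle
initial history and identical Wiener increments, so paths coincide until
the shock.  Phase is read from peak times (moving-average smoothing of
width period/6, quadratic refinement), the wrapping period is the median
unperturbed inter-peak interval, and shifts over the five post-shock cycles
are wrapped to (−π, π].  Rectangular shocks are anchored at the first
trough of the deterministic continuation; `mode="scaled"` (default) injects
`amplitude` molecules per hour so a longer shock is a bigger shock,
`mode="total"` fixes the total mass.

Two caveats discovered while building the protocol.  First, the measured
phase-response curve at the trough is steeply negative for both prototype
oscillators: a 130-molecule bolus there shifts phase by 1.5–2.3 rad no
matter how the amplitude convention is read, so "small shock ⇒ no mean
shift" does not hold under trough anchoring — only the *relative* claims
(dispersion grows; the narrow-kernel Type I shifts further than Type II
under the largest shock) are reproducible, and those are what the
perturbation tests assert quantitatively.  Second, an alternative protocol
that perturbs the mRNA *inside the initial history window* (so the shock
enters only through the delay kernel) does produce near-zero 1-hour shifts,
but its type ordering depends on where the minimum happens to sit relative
to each kernel's mass and can invert the Type I/II contrast; it is not
exposed as a default.

## Synthetic data generator

`generate_synthetic_dataset` draws random-effect fields from the
constrained CAR prior (eigendecomposition of `D−W`, null direction
removed), builds per-location parameters, simulates one stochastic path per
location and applies the camera model.  Defaults are the study conditions
used throughout: Type-II-scale parameters (`R=50, K=100, μ=0.25`,
delay 9.4 h), `κ = 2.5×10⁻³`, `Δt = 0.5 h`, 250 frames, `σ_η = 0.07`, CAR
hyper-variances 0.01 (≈5% parameter variation between locations — the
modest spatial heterogeneity seen in real tissue maps).  Paths start on the
per-location *developed deterministic cycle* (with a 24 h stochastic
transient discarded): tissue has been oscillating long before any recording
starts, and for weakly unstable parameter sets an equilibrium start would
produce recordings whose amplitude is still growing — data that a damped
model explains equally well.  `init="equilibrium"` remains available.

What the generator does **not** emulate: intercellular coupling (locations
are conditionally independent given their parameters), spatially varying
`μ, κ, σ_η`, substrate-consumption trends, camera saturation, or irregular
tissue boundaries.  Passing recovery tests on this generator therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not robustness to the ways real SCN recordings violate them.

## Problem sizes in the test suite

The acceptance experiments run at desk scale: single-location tuning runs
of 20,000 iterations; recovery on a 4×4 lattice (250 frames) with 4,000
iterations for the limit-cycle truth and 2,000 for the damped truth;
perturbation ensembles of 150 paths at `dt = 0.1 h` over ~8 days with three
seeds; a 15×15 stability grid.  Recovery uses a degradation-rate prior
centred on the generator's `log μ` — the synthetic analogue of the
externally measured reporter half-life that motivates the informative prior
in real analyses; with a deliberately mis-centred `μ` prior the posterior
slides along an exact likelihood ridge (`μ` up; `R`, `n`, delay mean
compensating) and per-location coverage collapses, which is a statement
about prior–data conflict under weak identifiability, not about the
sampler.

## Known limitations

* The filtering likelihood is a first-order Gaussian approximation.  At
  copy numbers of a few hundred it is accurate enough for recovery, but its
  maximum is measurably displaced along the soft (n, delay-SD) trade-off
  ridge — (n, SD) pairs trading cooperativity against dispersion fit almost
  equally well, and their individual posteriors should be read with that
  degeneracy in mind (jointly they are much better constrained than
  marginally).
* `(μ, R, K, n, delay mean, κ)` admit a near-exact compensation ridge; the
  informative `μ` prior is what pins it down.  Conclusions about absolute
  `μ` inherit that prior.
* The intrinsic CAR prior is improper and its hyper-variance is only weakly
  identified on small lattices.
* Euler–Maruyama with reflection at zero biases path laws at very low copy
  numbers (tens of molecules); the defaults stay well above that regime.
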