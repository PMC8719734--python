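# delayosc

Spatio-temporal Bayesian inference for single-cell molecular clocks from
bioluminescence time-lapse imaging.

## The problem

Circadian gene expression in tissues such as the suprachiasmatic nucleus
(SCN) is recorded as luciferase-reported light, frame by frame, across
thousands of cell-sized locations.  Two questions about each location's
transcriptional–translational feedback loop (TTFL) are hard to answer from
the raw traces: is the oscillator a genuine **limit cycle** (self-sustained
even without noise) or a damped, **noise-induced** oscillator?  And how is
the transcriptional repression distributed over time — a sharp "on–off"
switch or a gradual, spread-out inhibition — which governs how the cell
responds to perturbations?

`delayosc` answers both by fitting a mechanistic stochastic model jointly
across all locations:

* **Single-cell dynamics.**  mRNA copy number `X_i(t)` follows a chemical
  Langevin equation with distributed-delay negative feedback,

      dX = [ R / (1 + (Z/K)^n) − μX ] dt + sqrt( R/(1+(Z/K)^n) + μX ) dW,
      Z(t) = ∫ X(t−s) g_{p,a}(s) ds,

  where the delay density `g` is a gamma distribution (shape `p`, rate `a`,
  truncated at `τ_max` = 24 h) standing in for the unmodelled intermediate
  steps (translation, dimerization, nuclear import).  `R` is the maximal
  transcription rate (molecules/h), `K` the dissociation coefficient
  (molecules), `n` the Hill coefficient, `μ` the degradation rate (1/h).
* **Measurement.**  A camera frame integrates the path over its exposure
  window: `Y_{t'} = κ ∫ X(s) ds + η`, with light scaling `κ` and Gaussian
  read noise `η ~ N(0, σ_η²)`.
* **Spatial hierarchy.**  Each of `R, K, n` and the delay mean/SD varies
  over the lattice as `θ_i = θ·exp(ε_i)`, with an intrinsic conditional
  autoregressive (CAR) prior on each random-effect field: every location
  conditions on its 8 neighbours with variance `τ / w_{i,+}`, under a
  sum-to-zero constraint.

The likelihood of a frame series is approximated by Gaussian filtering of
an augmented lag state (an extended Kalman–Bucy-style first-order
linearization), and the full posterior is sampled by a blocked adaptive
random-walk Metropolis algorithm tuned to the classical acceptance optima
(0.234 for multivariate blocks, 0.45 for scalars).

From the posterior the package computes two oscillator phenotypes:

* **Robustness `V`** — the posterior probability that a location's
  parameters imply limit-cycle dynamics of the deterministic mean, computed
  by evaluating a characteristic-root stability classifier at each MCMC
  draw and averaging.
* **Inhibition profile `IP(k)`** — the per-molecule marginal repression at
  lag `k`, `IP(k) = −H'(x*) g(k)/x*`; its standardized form is the delay
  density itself, so its entropy measures how "spread out" the regulation
  is, and its integral `−H'(x*)/x*` is the total inhibition.

## Worked example

Classify the two prototype oscillators (both on the cooperativity /
delay-dispersion trade-off ridge) and compare their inhibition profiles:

```python
from delayosc import TYPE_I, TYPE_II, classify_stability, compute_ip, \
    ip_entropy, total_inhibition

for name, p in (("I", TYPE_I), ("II", TYPE_II)):
    r = classify_stability(p, compute_root=True)
    ip = compute_ip(p)
    print(name, r.is_limit_cycle, round(r.rightmost_root_real_part, 5),
          f"{total_inhibition(ip):.4e}", round(ip_entropy(ip), 4))
```

prints

```
I True 0.01038 4.7750e-03 2.1876
II True 0.00714 6.9625e-03 2.7595
```

Both types are limit cycles (positive rightmost characteristic root, per
hour).  Type II (higher Hill coefficient `n = 5.57`, wider delay
SD = 4.2 h) has the larger total inhibition (6.96×10⁻³ vs 4.78×10⁻³ per
molecule per hour) spread over a longer time scale (IP entropy 2.76 vs
2.19 nats) — the "gradual" phenotype; Type I concentrates its repression
near the 9 h delay mean — the "switch-like", more entrainable phenotype.

Fitting a synthetic lattice end to end:

```python
from delayosc import SpatialClockModel, TYPE_II, generate_synthetic_dataset

rec, truth, _ = generate_synthetic_dataset(
    (4, 4), TYPE_II, {p: 0.01 for p in
    ("R", "K", "n", "delay_mean", "delay_sd")}, seed=42)
res = SpatialClockModel(rec).fit(n_iter=4000, seed=5)
print(res.summary())          # posterior means, 90% CIs, ESS per parameter
vmap = res.robustness_map()   # V-hat per lattice cell
```

A thin CLI mirrors the library (`delayosc preprocess | simulate | synth |
fit | robustness | profile | perturb | diagnose`); see `delayosc --help`.

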