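# Methods

## Model

A drop-on-demand ejector draws nanoliter droplets from a well-mixed
suspension of target and non-target cells and places them on a grid. The
package models one printed array of *n* droplets with four discrete random
variables:

| variable | meaning | law |
|---|---|---|
| X_d | droplet contains ≥1 cell | Bernoulli(p); count over n is Binomial(n, p) |
| X_c | cells per droplet | Poisson(λ), λ = C·V |
| X_t | target cells per droplet | Poisson(λF) (binomial thinning of X_c) |
| X_s | exactly one target cell | Bernoulli, P(X_s=1) = P(X_d≥1)·λF e^(−λF) |

Assumptions: the reservoir is well mixed and effectively infinite over the
print (no depletion), droplets are independent and of identical volume, and
each cell is a target independently with probability F. Cell settling,
aggregation, droplet-volume jitter, and ejection bias are deliberately not
modeled.

### The combined single-target law

The combined form multiplies the occupancy probability by the Poisson
singleton probability, treating occupancy and the target count as
independent given an occupied droplet (an empty droplet forces X_t = 0);
its complement rule P(X_s=0) = 1 − P(X_s=1) holds exactly. Note a
structural consequence: under the thinned-Poisson generative process the
event {X_t = 1} already implies occupancy, so the *marginal* frequency of
single-target droplets converges to λF·e^(−λF), not to
P(X_d≥1)·λF·e^(−λF). The two predictions differ by the factor
P(X_d≥1) < 1 (at λ = 0.77, F = 0.5: 26.2% vs 14.1%). The rendered
formula for the combined law is therefore implemented as stated —
occupancy × singleton — and `single_target_model_check` reports **both**
predictions with their errors against data, rather than silently picking
one. Passing simulations validate the marginal; the combined-law gap is a
property of the model form and is surfaced, not asserted away.

Two counting conventions for X_s are computed side by side: the default
counts droplets with exactly one *target* cell (co-encapsulated
non-targets allowed, consistent with building the law from X_t), and a
strict variant requires the droplet to hold exactly one cell in total.

## Sample-size planning

Chebyshev's inequality bounds the deviation of the occupancy proportion,
P(|k/n − p| ≥ ε) ≤ p(1−p)/(nε²), giving n_min = p(1−p)/(αε²) at confidence
1 − α. Defaults follow the field's customary ε = 0.15, 1 − α = 0.90.

Numerical choices:

- **Rounding**: round-to-nearest reproduces the standard planning values
  (106.7 → 107, 50.3 → 50, 108.3 → 108); a `ceiling=True` mode never
  rounds down, for conservative designs.
- The worst case over p is p = 0.5 (n = 111 at the default ε, α). The
  planning literature this package follows also quotes "100 droplets" for
  that setting; the formula does not produce 100, and the package trusts
  the formula. A 10×10 array is nevertheless an adequate operating point:
  the Chebyshev bound is conservative, and empirical coverage at n = 100
  comfortably exceeds 90%.
- **Units**: volume ratios are computed on an integer grid of 0.1 pl
  (1 ml = 10⁹ pl), so 100 × 7.6 nl / 0.1 ml is exactly 0.76%.

## Design equations

λ = C·V links concentration (cells/ml) and droplet volume (nl). Occupancy
is 1 − e^(−λ). The minimum-droplet rule V_min = V_cell/f inverts the cell
volume fraction; C_max = 1/V_min puts one expected cell in that droplet.
The default cell volume, 0.5236 pl, is a 10 µm-diameter sphere — an
*inferred* default (0.5236/0.017 = 30.8 pl reproduces the printed design
point) and configurable per cell type. The droplet volume defaults to
7.7 nl, with 7.6 nl appearing in sampling-volume accounting; both are
config-level values, never hard-wired into operations.

Two volume-fraction definitions are implemented because no single one
reconciles all reported values: `expected-total` (λ·V_cell/V_droplet,
linear in concentration, the default) and `per-cell` (V_cell/V_droplet).

### Saturation regression

Measured occupancy vs concentration is summarized by P(C) = a(1 − e^(−bC))
(C in 10⁵ cells/ml, P in %), fit by Levenberg–Marquardt from a₀ = 1.5·max P,
b₀ = 0.5, parameter tolerance 10⁻¹⁰, at most 500 function evaluations
(exhaustion raises `ConvergenceError`). On the built-in four-point
reference table the fit gives a = 138.8, b = 0.514, R² = 0.984 — the tests
confirm it coincides with an exhaustive (a, b) grid scan to within one grid
step. Published coefficients for this table (a = 131, b = 0.558,
R² = 0.995) are not reproduced by this functional form; the exact original
regression specification is not recoverable, so exact-model recovery on
noiseless synthetic curves is what the suite gates. Both plain and
adjusted R² are reported.

## Simulator

Per droplet: X_c ~ Poisson(λ) independently, then X_t | X_c ~
Binomial(X_c, F). RNG is NumPy PCG64 seeded through `SeedSequence(seed)`;
replicates use spawned child sequences so replicate k is reproducible in
isolation. The grid layout is row-major 0-based and purely cosmetic.

`occupancy_override` replaces the zero/nonzero indicator with
Bernoulli(override) and draws occupied counts from the zero-truncated
Poisson (inverse-CDF). This is the minimal departure from pure Poisson
loading that matches an empirically measured occupancy — measured
occupancy can exceed the Poisson prediction (58.3% observed vs 53.7%
predicted at λ = 0.77; whether that reflects settling, ejection bias, or a
counting convention is unresolved) — while preserving the conditional
count law. With override = 1 − e^(−λ) the output is distributionally
indistinguishable from the pure path.

What the simulator does *not* emulate: droplet-volume dispersion, spatial
placement error, cell aggregation/settling, >2 cell classes. Passing tests
therefore demonstrate correctness of the statistical layer under ideal
Poisson loading, not robustness to those experimental artifacts.

## Estimation

λ̂ is the sample mean (the Poisson MLE). Three interval methods:

- `wald` (default): λ̂ ± z·√(λ̂/n), truncated at 0 — the CLT-style interval;
  collapses to [0, 0] on all-zero counts. Exact enumeration shows it
  undercovers badly when the expected total count nλ is small (coverage
  ≈ 0.80 at nλ = 3, ≈ 0.87 at nλ = 5).
- `score`: solves (λ̂ − λ)² = z²λ/n; exact coverage stays within a few
  points of nominal down to single-digit expected totals. The recovery
  study uses this method for its coverage yardstick precisely because the
  studied grid reaches λ = 0.03 at n = 100 (nλ = 3), where Wald coverage
  is structurally broken.
- `exact`: Garwood chi-square bounds (conservative).

`model_fit_error` is the maximum absolute PMF difference in percentage
points over the unioned support — chosen because published "±2%" / "5%
error" statements never define their metric; max-abs is the strictest of
the natural candidates.

`recovery_study` runs a full factorial (λ, F) grid — defaults target the
operating range λ ∈ [0.03, 0.95] at n = 100 droplets — with per-point
mean/SD/bias of λ̂ and λ̂F and empirical interval coverage. The acceptance
suite uses the grid endpoints with F ∈ {0.1, 0.5}, 2000 replicates per
point (seed 1234), which runs in a few seconds; larger grids scale
linearly.

`lln_demonstration` is exact enumeration (no sampling): the sup-norm
distance between the Binomial(n, p)/n CDF and its normal limit, strictly
decreasing over n = 10…100 for the occupancies of interest — the
quantitative version of "the PDF approaches a normal distribution".

## Degenerate inputs and tie-breaks

- Stirling's formula has no form for 0!; `stirling_factorial(0)` returns 1
  by convention and the Stirling-binomial PMF falls back to the exact PMF
  at k ∈ {0, n}.
- Binomial PMF: naive factorial products below n = 51 (bit-stable against
  hand computation), log-gamma space above.
- Poisson normalization checks truncate at the smallest k with cumulative
  mass > 1 − 10⁻¹².
- p ∈ {0, 1}: Chebyshev bound 0; sample size floors at 1.
- `occupancy_override` > 0 with λ = 0 is rejected (the zero-truncated law
  does not exist).
- Header-only droplet CSVs parse to a valid zero-droplet array; every
  operation needing data rejects n = 0 explicitly.

## Known limitations

- The combined single-target law and the thinned marginal disagree by the
  occupancy factor (see above); users comparing against marginal counts
  should read the `marginal` fields of the model check.
- Chebyshev sizing is distribution-free and hence conservative; exact
  binomial (Clopper–Pearson-style) planning is out of scope by design.
- The saturation regression's functional form is an assumption; its
  extrapolation beyond the fitted concentration range (e.g. 2.5×10⁵
  cells/ml → ~100%) should be read as a trend, not a calibrated
  prediction.
- Reported minimum detectable target fractions of ~8–9% in this
  experimental context have no derivable closed form here and are not
  computed by the package.
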