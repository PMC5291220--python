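# Methods

## From a time series to a temporal network

A series is first lifted to a phase-space trajectory. Deterministic systems
use their native coordinates (the interval for the logistic map, the plane
for the Hénon and Ikeda maps, 3-space for the Rössler flow); scalar series
from unknown systems are reconstructed by Takens delay embedding with
dimension *m* and delay *l* (point *i* = (*sᵢ*, *sᵢ₊ₗ*, …, *sᵢ₊₍ₘ₋₁₎ₗ*)).
Random processes without attractor structure (white noise, 1/f noise, AR(3))
are symbolised directly in one dimension.

The trajectory is coarse-grained by an axis-aligned grid of equal-size cells
fitted to the data's bounding box (expanded by 10⁻⁹ of the range so no point
sits on an open boundary; cells are half-open with a closed top edge, so the
maximal point is kept). Each sample becomes the index of its cell, and the
symbol sequence becomes a temporal network with one time-stamped edge per
consecutive sample pair (timestamps 1…n−1). Consecutive identical symbols
yield self-edges by default; a `collapse_repeats` option removes them for
flows sampled faster than the typical cell-crossing time.

### Choosing the number of cells

The cell count *N* is the method's resolution parameter, and two readings of
"partition into *N* cells" are exposed because they matter:

* `fit_grid(n_cells_total=N)` — a bounding-box grid with ~*N* cells in
  total (per-dimension count `round(N^(1/m))`).
* `fit_grid_occupancy(n_occupied=N)` — the per-dimension resolution is
  calibrated by bisection so the **orbit occupies ~N cells**. On a thin
  fractal attractor a bounding-box grid leaves most cells empty, so the
  total-cell reading badly under-resolves the attractor; the occupancy
  reading makes *N* the number of distinguishable attractor states, which is
  what the memory-entropy analysis needs (see "Finite-sample regime" below).
  For a space-filling 1-D series the two coincide.

The attractor presets use occupancy calibration: logistic 900, Hénon 2500,
Ikeda 1600, Rössler 100. Scalar noise presets use 100 equal 1-D cells (the
choice is not critical; it sets only the τ = 0 level). If an occupancy target
is unreachable (a periodic orbit visits a fixed handful of cells no matter
how fine the grid), the finest grid is used and the shortfall logged —
downstream results are unaffected because a periodic symbol sequence is
deterministic at every resolution.

## Memory entropy

The null aggregate network *G*⁽⁰⁾ counts each directed cell-to-cell
transition. The consecutive memory network *G*⁽τ⁾ has the observed τ-step
paths (windows of τ+1 cells) as nodes; in the default **overlapping**
construction an edge joins a path to its one-step shift with weight the
number of (τ+2)-cell windows realising the continuation. With the empirical
stationary distribution (out-weight marginal) the entropy growth rate

H(τ) = − Σₐ πₐ Σ_b T_ab ln T_ab,  T_ab = w(a,b)/Σ_b′ w(a,b′),
π_a = Σ_b w(a,b)/Σ w

is then *exactly* the plug-in conditional block entropy of the symbol
sequence — the uncertainty (nats) of the next cell given the last τ+1 cells.
This identity is enforced by an oracle test against raw (τ+2)-gram counts.
The empirical marginal is used rather than the eigenvector of *T* because it
is always defined and, for a network built from a single long walk, the two
coincide numerically anyway. An alternative **concatenated** construction
(edges joining disjoint adjacent windows, i.e. paths of 2τ+1 edges in
*G*⁽⁰⁾) is retained behind a flag; it produces non-monotone profiles and is
not used by the reference analyses.

### Finite-sample regime and the memory exponent

For a deterministic chaotic system the true conditional entropy at fixed
resolution converges to the Kolmogorov–Sinai entropy and does not vanish.
The decay of *H(τ)* to zero that carries the memory exponent lives in the
finite-sample (undersampling) regime: the number of distinct τ-paths grows
exponentially with τ, path counts thin out, and the plug-in estimate decays
— at a rate set by how fast typical paths stop repeating, which is governed
by the trajectory's recurrence (shadowing of unstable periodic orbits). The
partition must therefore resolve enough states that this regime is reached
within the analysed τ range; that is why occupancy calibration matters, and
why the profile has three parts: a resolution-limited plateau, an exponential
decay, and an estimator floor.

ρ is −(slope) of the OLS fit of ln H(τ) on τ. Two window policies:

* `select="range"` (default): all points with τ ≤ `tau_fit_max` (default 6)
  and H > `h_floor` (default 10⁻¹²), τ = 0 included. Used in the
  bifurcation scan, where a fixed window keeps ρ(μ) comparable across μ.
* `select="best"`: the contiguous window of ≥ 5 points maximising R² of the
  log-linear fit (ties → longer, then earlier). Used by
  `attractor_analysis` (profiles computed to τ = 14), because the
  exponential stretch sits at different τ for different systems.

Degenerate rule (both policies): fewer than two usable points, or a profile
constant to within `h_floor` — the periodic case, H ≡ 0 — gives ρ = 0.

### Expected values and a known bias

At the preset conditions (2×10⁴ samples) the fitted exponents are ≈ 0.65
(logistic, λ = ln 2 ≈ 0.693), ≈ 0.47 (Ikeda, λ ≈ 0.51) and ≈ 0.29 (Hénon,
λ ≈ 0.42); the acceptance script recomputes them. The undersampling decay
rate is asymptotically bounded by the correlation (order-2 Rényi) entropy,
which equals λ only for attractors with uniform expansion (the logistic map
at μ = 4). For strongly non-uniform measures such as Hénon's, the fitted ρ
therefore sits systematically below λ at any feasible series length — an
estimator property to keep in mind when reading ρ as a λ proxy.

## Bifurcation laboratory

For each μ in the scan (default μ ∈ [3.5, 4], Δμ = 0.005, 10⁴ samples after
a 4000-sample transient), the orbit is delay-embedded (m = 2, l = 1) and
partitioned at 900 cells per embedded axis — the same state resolution as
the 900-cell partition of the unit interval; a 30×30 total-cell grid does
not reach the undersampling regime and makes ρ non-monotone in λ. ρ uses the
fixed-range fit (τ ≤ 6). The comparison axis λ(μ) is computed exactly as the
orbit average of ln|μ(1 − 2x)| on the noise-free orbit (derivative points
equal to zero are skipped with a warning), removing estimation noise from
the reference. Pearson correlations are reported over all valid μ and over
the chaotic subset (λ > 0); orbits that diverge are flagged and excluded.
One child seed per μ is spawned from the master seed, so scans are
bit-for-bit reproducible.

With observational noise (`snr_db`, SNR = 10·log₁₀(var_signal/var_noise);
the preset medium level is 28.5 dB), periodic windows keep ρ far below the
chaotic-regime values but not exactly zero: the i.i.d. blur makes symbols
stochastic, and the plug-in estimator's finite-sample bias puts a floor of
roughly 0.05 on the fitted slope at these lengths. Window detection under
noise is therefore a contrast statement, not an exact zero.

## Betweenness preference

B^υ is accumulated in one pass over consecutive symbol triples; rows and
columns are indexed by υ's in-/out-neighbours in *G*⁽⁰⁾. I^υ is the mutual
information of the normalised matrix, in bits (base configurable). Nodes
with at least one traversal are scored (a single in- or out-neighbour forces
I = 0); never-traversed nodes are reported as degenerate, without a score.
No null-model correction is applied; a normalised variant I/min(H(P₁),H(P₂))
exists behind a flag as a convenience. The spatial map writes each scored
node's cell-center coordinates with its score.

## Synthetic generators

Defaults are the study conditions: 2×10⁴ retained samples after a
4000-sample transient. All randomness goes through numpy Generators; equal
seeds give bit-identical series, and any coordinate exceeding 10⁶ aborts
with a divergence error.

* Logistic map x′ = μx(1−x), default μ = 4; initial point drawn uniformly
  inside (0,1) when not given.
* Hénon map x′ = 1 − ax² + y, y′ = bx; chaotic preset (1.4, 0.3) and a
  periodic preset (1.0, 0.3) — a stable period-4 window chosen here as a
  convenient periodic regime, not tied to any published experiment.
* Ikeda map x′ = 1 + u(x cos t − y sin t), y′ = u(x sin t + y cos t),
  t = 0.4 − 6/(1+x²+y²), u = 0.9 (the canonical chaotic form; the variant
  with −y cos t in the second component is not chaotic and is not used).
* Rössler flow (a = b = 0.2, c = 5.7), fixed-step RK4 with step 0.01,
  sampled every 1.0 time units after discarding 500 time units. The memory
  exponent of a flow scales with the sampling stride, so the Rössler ρ is
  reported without a reference comparison.
* AR(3) sₙ = 0.8sₙ₋₁ − 0.5sₙ₋₂ + 0.7sₙ₋₃ + εₙ. Note these coefficients
  place a root on the unit circle, so the process is a drifting (unit-root)
  one; this does not affect its use as a finite-memory benchmark.
* White noise: i.i.d. standard Gaussian. 1/f noise: spectral synthesis with
  amplitude ∝ f^(−1/2), random phases, zero DC bin, unit variance.

What the generators emulate is clean model data. They do not produce
non-stationarity (beyond the AR drift), measurement artefacts, missing
samples or the baseline wander of physiological recordings; tests passing on
them demonstrate the machinery and its finite-sample behaviour, not
performance on clinical data. The pipeline accepts arbitrary scalar CSV
input for real recordings (a preset m = 2, l = 15, N = 300 configuration for
short noisy physiological series is provided), but no bundled result depends
on external data.

## Problem sizes and runtime

The shipped experiments use the full study lengths: 2×10⁴ samples for the
attractor analyses and τ up to 14; 101 scan points at 10⁴ samples each. The
acceptance script averages the stochastic exponents over 5 independent
realisations and completes in well under a minute on one CPU; the test suite
runs in a few minutes.

## Known limitations

* ρ is a finite-sample quantity: it depends on series length and partition
  resolution jointly, and only tracks λ when the undersampling regime is
  reached within the fitted τ range. Its asymptotic ceiling is the
  correlation entropy (see above), so for non-uniform attractors ρ < λ.
* The noisy-window ρ has a positive bias floor (~0.05 at n = 10⁴); exact
  zeros under noise are not attainable with the plug-in estimator.
* Occupancy calibration assumes the occupied-cell count is monotone in the
  grid resolution, which holds in practice but makes the effective grid
  data-dependent; the partition sidecar records the realised grid.
* No surrogate-data significance testing and no data-driven Lyapunov
  estimation are included; λ comparisons are available only where an
  analytic derivative exists (1-D maps).
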