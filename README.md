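# tempomem

Temporal-network analysis of time series: memory entropy and betweenness
preference.

`tempomem` transforms a time series into a **temporal network**: partition the
(possibly delay-embedded) phase space into equal-size cells, treat each cell
as a node, and record one time-stamped edge *(υ, ω; t)* for every transition
of the trajectory from cell *υ* to cell *ω* at time step *t*. Because every
sample pair contributes exactly one stamped edge, the mapping between a
series and its temporal network is one-to-one. Two analyses are built on this
representation:

* **Memory entropy.** Aggregating the stamped edges gives the weighted
  directed transition network *G*⁽⁰⁾. Its order-τ memory network *G*⁽τ⁾ has
  the observed τ-step paths as nodes and their observed continuations as
  weighted edges. The entropy growth rate

  *H(τ) = − Σᵢ πᵢ Σⱼ Tᵢⱼ ln Tᵢⱼ*

  (transition probabilities *T* from the path-continuation weights, π the
  stationary distribution) measures the remaining uncertainty of the next
  jump given τ steps of memory. For chaotic signals *H(τ)* decays
  approximately exponentially, *H(τ) ∝ exp(−ρτ)*; the decay rate ρ — the
  **memory exponent** — tracks the largest Lyapunov exponent λ, vanishes for
  periodic signals, and detects periodic windows in bifurcation scans even
  under observational noise.

* **Betweenness preference.** For each node *υ*, the matrix *B^υ* counts how
  often the two-step time-respecting path *ω₁ → υ → ω₂* occurs. The score
  *I^υ* is the mutual information (bits) between the origin *ω₁* and the
  destination *ω₂*: zero when *υ* routes flow independently of where it came
  from, positive when the trajectory switches between unstable periodic
  orbits with preferences.

The package ships generators for the benchmark systems (logistic, Hénon and
Ikeda maps, the Rössler flow, an AR(3) process, white and 1/f noise), the
full pipeline from raw series to scores, and a bifurcation laboratory that
scans the logistic-map parameter μ and correlates ρ(μ) with the analytic
Lyapunov exponent λ(μ). It is aimed at researchers characterising nonlinear
and physiological signals (e.g. ECG recordings) from the network perspective.

## Worked example

Memory-entropy analysis of the fully chaotic logistic map
*x*ₙ₊₁ = 4 *x*ₙ(1 − *x*ₙ), 2×10⁴ samples after a 4000-sample transient,
partitioned at 900 cells on the unit interval:

```python
import numpy as np
import tempomem as tm

gt, part, profile, fit = tm.attractor_analysis("logistic", seed=1)
print("occupied cells:", len(gt.nodes))
for t, h in zip(profile.taus[:8], profile.h[:8]):
    print(f"tau={t}  H={h:.4f}")
print(f"rho = {fit.rho:.3f}  (fit over tau {fit.fit_taus[0]}..{fit.fit_taus[-1]}, "
      f"R^2 = {fit.r_squared:.4f})")

scores = [nb.i_score for nb in tm.bp_distribution(gt).per_node.values()]
print(f"betweenness preference: {len(scores)} nodes, "
      f"median I = {np.median(scores):.3f} bits, max I = {max(scores):.3f} bits")
```

prints

```
occupied cells: 900
tau=0  H=0.9825
tau=1  H=0.7348
tau=2  H=0.5795
tau=3  H=0.4214
tau=4  H=0.2745
tau=5  H=0.1608
tau=6  H=0.0891
tau=7  H=0.0466
rho = 0.639  (fit over tau 5..9, R^2 = 0.9994)
betweenness preference: 900 nodes, median I = 0.094 bits, max I = 1.728 bits
```

*H(τ)* decays exponentially with ρ ≈ 0.64, close to this map's Lyapunov
exponent λ = ln 2 ≈ 0.693, and the betweenness-preference distribution is
heterogeneous with most nodes near *I* = 0 — the signature of weakly
correlated routing through phase space.

The same steps are available from the shell:

```sh
tempomem generate --system logistic --n 20000 --transient 4000 --seed 1 -o series.csv
tempomem transform series.csv --occupied 900 -o edges.tsv
tempomem entropy edges.tsv --tau-max 14 -o profile.tsv
tempomem rho profile.tsv --select best
tempomem betweenness edges.tsv --partition edges.partition.json -o bp.tsv
tempomem bifurcation --d-mu 0.005 --seed 1 -o scan.tsv
```

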