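# ewsbench

Benchmarking multivariate early-warning indicators of resilience loss.

Complex systems — ecosystems, climate components, physiological networks —
can pass *tipping points*: small changes in a driver cause an abrupt shift
to a different stable state. Before a zero-eigenvalue (fold or
transcritical) bifurcation the system recovers ever more slowly from
perturbations, a phenomenon called **critical slowing down** that leaves
fingerprints in observed fluctuations: rising variance, rising lag-1
autocorrelation, rising cross-correlations. Many statistics have been
proposed to turn multivariate time series into a scalar warning signal, but
they behave very differently once real-world data problems enter: short
records, coarse sampling, measurement error, state-dependent noise,
unobserved variables, non-normal (reactive) dynamics.

`ewsbench` is a self-contained benchmark for this question, aimed at
researchers developing or applying resilience indicators. It provides:

- a **stochastic plant–pollinator community model** (bipartite
  facilitation–competition dynamics with saturating mutualism) that can be
  driven slowly toward a tipping point, in a 4-species reference version
  and randomly searched 20-species versions with full or partial collapse;
- a fast, seeded **Euler–Maruyama simulator** plus pure data-degradation
  transforms (measurement noise, truncation, decimation, variable subsets);
- the **thirteen indicator statistics** — per-variable variance and lag-1
  autocorrelation summaries, covariance/PCA statistics (degenerate
  fingerprinting, explained variance, maximum covariance), min/max
  autocorrelation factor (MAF) statistics, average absolute
  cross-correlation, and Kraskov–Stögbauer–Grassberger k-nearest-neighbour
  mutual information;
- an **evaluation layer** that scores each indicator by the Kendall tau of
  its trend along the 50-step sweep toward the bifurcation (clipped at
  zero), with worst/best-case quantiles across variable subsets and a
  constant-parameter null for specificity.

## The model

For pollinator abundances `A_k` and plant abundances `P_i`:

    dA_k = A_k [ r^A_k + G_k/(1 + h_k G_k) − Σ_l c^A_kl A_l ] dt + σ dW,
    G_k = Σ_i γ^A_ki P_i,

and symmetrically for plants. `r` are per-capita growth rates (negative for
species that depend on their mutualists), `γ` mutualistic gains with
half-saturation constant `h`, `c` within-guild competition with
self-competition exceeding interspecific competition. Lowering the
pollinator growth rates `r^A` in 50 steps moves the dominant eigenvalue of
the community Jacobian from −0.45 to −0.15 (per time unit): the system
stays stable but loses resilience, and each step contributes one stationary
time series. The "true" resilience (dominant eigenvalue) and reactivity
(largest eigenvalue of the Hermitian part of the Jacobian) are computed
analytically along the sweep.

## Worked example

```python
import numpy as np
from ewsbench import (
    default_4d_sweep, sweep_bifurcation_parameter,
    NoiseSpec, generate_sweep_series, evaluate_sweep,
)

params, r_start, r_end = default_4d_sweep(reactive=False)
steps = sweep_bifurcation_parameter(params, r_start, r_end, n_steps=50)
print(f"eigenvalue {steps[0].stability.dominant_eigenvalue:+.3f} -> "
      f"{steps[-1].stability.dominant_eigenvalue:+.3f}")

sweep = generate_sweep_series(steps, NoiseSpec(sigma=0.02),
                              length=2000, sampling_interval=0.1, seed=1)
values, entries = evaluate_sweep(sweep)
for e in sorted(entries, key=lambda e: -e.tau)[:5]:
    print(f"{e.indicator:25s} tau = {e.tau:.2f}")
```

prints

```
eigenvalue -0.450 -> -0.150
avg_variance              tau = 0.78
avg_autocorrelation       tau = 0.77
mutual_information        tau = 0.75
node_max_variance         tau = 0.70
max_covariance            tau = 0.70
```

i.e. with 2,000 samples per step every indicator family detects the
approaching transition, with the averaged variance and autocorrelation and
the lagged mutual information among the strongest trends. (Exact values
depend on the seed; at the full 10,000-sample protocol most indicators
score 0.8–0.9.)

The same pipeline is scriptable from the shell:

```bash
ewsbench run --scenario data_resolution --setting 4d --seed 1 --scale 0.2 --out out/
ewsbench search-params --collapse partial --seed 1 --out params20.yaml
ewsbench validate my_scenario.yaml
```

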