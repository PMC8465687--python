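# graphgranger

Granger-causality inference **between time series of graphs**.

Many systems — brain hemispheres, gene-regulatory modules, trade networks —
are naturally observed as a *sequence of networks*, one per time point, and
the scientific question is directional: does the evolution of network A
help predict the evolution of network B? Classical Granger causality is
defined for scalar or vector time series, not for graph-valued ones.
`graphgranger` closes that gap with a simple, well-calibrated device:

1. each graph is reduced to its **spectral radius** λ₁ (the largest
   eigenvalue of the adjacency matrix), which for common random-graph
   models is a monotone function of the generating parameter — e.g.
   E[λ₁] ≈ n·p for Erdős–Rényi, λ₁ = deg exactly for regular graphs;
2. the resulting k scalar series y_{i,t} are modeled with a VAR(p),

       y_{j,t} = v_j + Σ_i Σ_l a_{i,j}^l · y_{i,t−l} + ε_{j,t} ;

3. "series i does not Granger-cause series j" ⇔ a_{i,j}^l = 0 for all lags,
   tested by a Wald χ²_p statistic

       W = (Cβ̂_j)′ [C(Z′Z)⁻¹C′]⁻¹ (Cβ̂_j) / Σ̂_{jj}

   or, for short series, by a parametric bootstrap that resamples whole
   residual rows (preserving contemporaneous error correlation) and
   recurses the null model.

The package also ships the full simulation framework used to characterize
the test — five latent scenarios with known causal structure, mapped
through the inverse logit onto five random-graph families (Erdős–Rényi,
geometric, regular, Watts–Strogatz, Barabási–Albert) — and a front-end that
turns multivariate signals (e.g. fMRI region averages) into time-varying
Pearson-correlation graphs via spline smoothing, so two brain hemispheres
can be compared as two weighted graph series.

Intended users: researchers in network neuroscience and systems biology
with dynamic connectivity data, and methodologists who want a calibrated
reference implementation of graph-level causality testing.

## Worked example

```python
import graphgranger as gg

# latent ground truth: scenario 2 has a single causal edge y1 -> y2
latent = gg.simulate_latent(2, T=100, seed=1)

# drive Erdős–Rényi graphs (n=60) with the inverse-logit of the latent values
series = gg.to_graph_series(latent, "erdos_renyi", n=60, seed=2)

# spectral radii -> VAR(1) -> Wald tests, all pairs
results, model = gg.graph_granger(series, order=1)
for (i, j), r in sorted(results.items()):
    print(f"{r.source_label} -> {r.target_label}:  W = {r.statistic:7.2f}   p = {r.p_value:.4f}")
```

Output:

```
y1 -> y2:  W =   50.69   p = 0.0000
y2 -> y1:  W =    0.35   p = 0.5527
```

The true causal direction y1 → y2 is detected (p < 10⁻⁴); the reverse
direction is correctly not rejected. `model` exposes the fitted
coefficients, intercepts and residual covariance for inspection.

The same analysis runs from the shell:

```bash
graphgranger simulate --scenario 2 --family erdos_renyi --n 60 -T 100 --seed 1 --out sim/
graphgranger test --input sim/ --order 1 --method wald --out results.tsv
```

For signal data, `graphgranger dynnet --input signals.tsv --membership
groups.tsv --out nets/` builds time-varying correlation graph series per
group, ready for `graphgranger test`. Monte-Carlo power maps over an
(n, T) grid come from `graphgranger power --config cfg.yaml --out power.tsv`.

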