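# fluxbma

Bayesian spatial regression and model averaging for chamber-measured soil
nitrous-oxide (N₂O) fluxes.

Soil N₂O emissions measured by static chambers are strongly spatially
variable, and regressions that ignore the correlation between nearby
chambers give biased coefficients and over-confident predictions. This
package fits the same replicated, point-referenced flux regression under
three spatial correlation structures, compares them by the deviance
information criterion (DIC), and combines their predictions by DIC-weighted
Bayesian model averaging (BMA). It is aimed at soil and greenhouse-gas
researchers analysing chamber networks on the scale of a single field
(tens of chambers, monthly replicates).

## Models

For log-transformed fluxes `y_ir` at chamber `i = 1..Q`, replicate
`r = 1..M`, with covariates `x_ir` (soil moisture, temperature, NO₃⁻, pH,
sand, silt, clay):

    y_ir = β₀ + x_irᵀβ + z_i + ε_ir,   ε_ir ~ N(0, σ²)

with three choices of the site effect `z_i`:

1. **independent** — `z_i = 0`; ordinary Bayesian linear regression.
2. **exp (geostatistical)** — `z_i = s_i`, where `s ~ GP(0, σ_s² Φ)` and
   `Φ_ij = exp[−(θ d_ij)^δ]` with `δ = 1`; the decay rate θ has a uniform
   prior whose bounds put correlation 0.05 at the maximum and minimum
   inter-chamber distances.
3. **icar (CAR)** — `z_i = u_i` with the intrinsic conditional
   autoregressive prior `u_i | u_−i ~ N(mean of neighbours, σ_u²/w_i+)` on
   the first-order neighbourhood defined by shared Thiessen-polygon edges,
   identified by a sum-to-zero constraint.

Priors: `β ~ N(0, 10⁶)`, `σ ~ U(0,5)`, `σ_u ~ U(0,10)` (and `σ_s ~ U(0,10)`).
Models are fitted by bespoke Gibbs/Metropolis samplers; DIC = D̄ + pD with
pD = D̄ − D(posterior means); BMA weights are
`p(M_l|D) ∝ p(M_l) exp(−DIC_l/2)` and averaged predictions are mixture
draws across models. Surfaces of the predicted log-flux and of the spatial
effects are interpolated by ordinary kriging with a WLS-fitted exponential
variogram.

Because raw field campaigns of this kind are rarely deposited, the
`synthetic` module generates complete chamber datasets with the design of a
published year-long pasture study (17 chambers in a ≈272 m² field, 13
monthly replicates, published covariate moments), so the full pipeline runs
and is tested without external data.

## Worked example

```python
import numpy as np
import fluxbma as fb

design = fb.DesignConfig(seed=42)                     # 17 sites x 13 replicates
truth = fb.GenerativeParams(structure="exp")          # geostatistical truth
ds, weights = fb.simulate_dataset(design, truth)

cfg = lambda s: fb.McmcConfig(n_iter=15_000, burn_in=5_000, thin=10, seed=s)
fits = {
    "independent": fb.fit_independent(ds, config=cfg(1)),
    "exp": fb.fit_exp_geostat(ds, config=cfg(2)),
    "icar": fb.fit_icar(ds, weights, config=cfg(3)),
}
dics = [fb.compute_dic(f, ds) for f in fits.values()]
print(fb.dic_table(dics).round(4).to_string(index=False))
```

```
      model     Dbar      pD      DIC  prior_prob  posterior_prob
independent 856.9821  7.9217 864.9037      0.3333          0.0000
        exp 759.8096 19.6065 779.4161      0.3333          0.4182
       icar 759.5217 19.2343 778.7559      0.3333          0.5818
```

The data were generated with true spatial correlation, and DIC duly ranks
both spatial models far ahead of the independent regression (ΔDIC ≈ 86);
the BMA weights split between the two spatial structures and zero out the
independent model. Posterior predictive checks on the same fit print

```
frac outside 95% PI: 0.0226
SSR (log scale): 369.45
beta_moisture posterior mean 0.0601  95% CI (0.0382, 0.0833)  truth 0.055
```

i.e. ≈2% of observations fall outside their 95% posterior predictive
intervals and the moisture effect is recovered within its credible
interval.

The same pipeline is available from the shell:

```sh
fluxbma all --out run1 --seed 42          # simulate -> fit -> compare -> predict
fluxbma fit --data run1/chamber.csv --model car --out run1
```

which writes the chamber CSV, adjacency edge list, per-model samples and
convergence reports, the DIC/BMA table, site predictions, and kriged
surfaces (CSV + ASCII grid).

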