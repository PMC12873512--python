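# cuticula

Toolkit for studying how the water permeability of leaf cuticles responds
to contrasting microclimates — the situation of an alpine dwarf shrub
growing on opposing slopes, where north- and southeast-facing canopies a
few hundred metres apart see very different temperature, wind and
irradiation regimes.  It implements, as one tested pipeline:

* **Effective solar irradiance on tilted canopies** — solar position,
  conversion of horizontally measured PPFD to beam values
  (`PPFD/sin(elevation)` above a 10° cutoff), and projection onto the
  canopy surface normal via the scalar product of sun and normal vectors.
* **Minimum diffusive conductance (g_min)** from repeated-weighing
  bench-drying records (the mass-loss-of-detached-leaves technique):
  per-interval transpiration `E = Δm/(M_w·A·Δt)`, conductance
  `g = E/VPD_mol` with a Magnus-based mole-fraction vapour pressure
  deficit, automatic detection of the constant-conductance plateau, and
  g_min as the plateau mean.
* **Exponential temperature response**
  `g_min(T) = g_min(0 °C) + A·exp(R₀·T)` fitted by bounded nonlinear
  least squares.
* **Raman cuticle chemometrics** — crop/despike/baseline preprocessing,
  1452 cm⁻¹ band-integration imaging, non-negative spectral unmixing with
  automatic model-order selection and noise-component rejection, layer
  thickness from abundance maps, and band assignment against a table of
  cuticle compound classes (cutin, triterpenoids, flavonoids, phenolic
  acids, crystalline waxes).
* **Statistics** — two-way ANOVA with Tukey HSD, normality-gated
  two-group tests, Kruskal–Wallis with Dunn/Holm compact-letter display.
* **Synthetic data generators** for all four input kinds (microclimate
  series, drying records, cuticle cubes, thickness groups), calibrated to
  the published group-level results so every stage can be validated
  against known ground truth.

## Worked example

Simulate one calibrated drying experiment and recover g_min, then
estimate whole cells and fit the temperature response:

```python
import numpy as np
from cuticula import synthetic as syn, conductance as cond, temp_response as tr
from cuticula.pipeline import gmin_cell_estimates

p = syn.DryingForwardParams(true_gmin=2.0, ambient_temp=25.0,
                            relative_humidity=35.0, seed=11)
est = cond.estimate_gmin(syn.generate_drying_experiment(p))
print(f"g_min = {est.gmin:.3f} ± {est.sd:.3f} mmol m⁻² s⁻¹")
# g_min = 2.000 ± 0.482 mmol m⁻² s⁻¹

pts = []
for T in (25.0, 38.0, 43.0):
    e, _ = gmin_cell_estimates(syn.N_SITE, T, 20, seed=1)
    pts += [(T, g) for g in e]
    print(f"N-site {T:g} °C: mean g_min {np.mean(e):.2f}")
# N-site 25 °C: mean g_min 1.78
# N-site 38 °C: mean g_min 2.58
# N-site 43 °C: mean g_min 6.94
m = tr.fit_temperature_response(pts)
print(f"gmin0={m.gmin0:.3f}, A={m.A:.3e}, R0={m.R0:.3f} /°C")
# gmin0=1.772, A=6.268e-07, R0=0.370 /°C
```

The per-twig estimate lands on the true value because the plateau mean is
insensitive to zero-mean balance noise; the cell means reproduce the
calibrated group means (1.78 and 2.58 mmol m⁻² s⁻¹ at 25 and 38 °C, a
roughly fourfold rise by 43 °C); and the fitted exponential summarises
the steep upturn of cuticular water permeability under heat.

A command-line interface wraps each stage
(`cuticula simulate | irradiance | summarize | gmin | fit-response |
raman | stats | run-study`); `cuticula run-study --seed 1 --out-dir out/`
reproduces the full synthetic study and writes a JSON report.

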