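# spathealth

Spatial analysis of health-resource allocation and population health across
county-level units: abridged life tables, spatial autocorrelation, resource
equity, and spatially varying regression at multiple scales.

The package is aimed at health geographers and spatial epidemiologists who
want a tested, scriptable implementation of the full analysis chain that
studies of regional health inequality typically assemble from several GUI
tools:

* **Life tables** (`spathealth.lifetable`) — abridged (current-method)
  life tables from age-interval exposures `P_x` and deaths `D_x`:
  `m_x = D_x/P_x`, infant convention `q_0 = m_0`, interior
  `q_x = n·m_x/(1 + (n/2)·m_x)`, trapezoid person-years, exponential open
  tail `L = l/m`, and `e_x = T_x/l_x`.
* **Spatial autocorrelation** (`spathealth.spatial`) — rook/knn/distance
  weights, global Moran's `I` with permutation inference, and local Moran
  (LISA) with conditional permutation and HH/LL/HL/LH cluster labels.
* **Resource equity** (`spathealth.inequality`) — Lorenz curves and the
  direct-method Gini
  `G = −1 + Σ_j (W_j/W)(Y_j/Y) + 2 Σ_{j<n} (W_j/W)(1 − V_j)` over units
  sorted by per-capita resources, with a trapezoid-integration oracle and
  the conventional equity bands (0.4 alert threshold).
* **Global diagnostics** (`spathealth.regression`) — OLS, variance
  inflation factors, residual-moment normality screens.
* **Multiscale GWR** (`spathealth.mgwr`) — from-scratch geographically
  weighted regression (Gaussian kernel, adaptive bandwidths, AICc
  golden-section selection) and multiscale GWR calibrated by backfitting
  with per-covariate bandwidths and the `SOC_f` termination criterion.
* **Effect curves** (`spathealth.curves`) — per-unit coefficient ratios
  between two periods against baseline health, continuous piecewise-linear
  breakpoint fits, and V / inverted-V / oblique-L shape classification.
* **Synthetic panels** (`spathealth.synthetic`) — seeded generators for
  lattices, spatially autocorrelated covariates, multiscale coefficient
  surfaces, Gompertz–Makeham demography, Dirichlet resource allocations
  and two-period coefficient sets, so every stage can be validated against
  known ground truth.

## Worked example

```python
import numpy as np
from spathealth.lifetable import AgeSchedule, build_life_table
from spathealth.mgwr import mgwr_fit, report_scales
from spathealth.synthetic import make_multiscale_panel

# life expectancy from an age schedule (exposures, deaths per interval)
sched = AgeSchedule(start_ages=[0, 1, 5, 10, 15],
                    exposures=[50138, 198325, 274213, 293296, 293296],
                    deaths=[1930, 1024, 423, 328, 328])
lt = build_life_table(sched)
print(f"infant deaths per 100k radix: {lt.d[0]:.3f}")   # 3849.376
print(f"survivors at age 10:          {lt.l[3]:.3f}")   # 93461.468

# multiscale GWR on a synthetic 24x24 county panel whose three covariate
# effects act at different true scales (constant / gradient / hotspot)
panel, coords, X, _ = make_multiscale_panel(side=24, noise_sd=0.5, seed=3)
fit = mgwr_fit(X, panel["life_expectancy"].to_numpy(), coords,
               hat_matrix=False, max_iterations=50)
print(fit.bandwidths)                     # [362. 495.  17.   9.]
print(report_scales(fit.bandwidths, 576)) # ['local', 'local', 'local', 'local']
print(f"R2 = {fit.r_squared:.3f}")        # R2 = 0.953
```

The per-term bandwidths are adaptive neighbour counts: the constant-effect
covariate draws a near-global bandwidth (495 of 576 units) while the
hotspot covariate is fitted with only 9 neighbours — the scale separation
that a single-bandwidth GWR cannot express.

A command-line interface wraps the same functions:

```sh
spathealth simulate --side 24 --seed 7 --out panel.csv
spathealth moran --in panel.csv --column life_expectancy --perms 999 --seed 1
spathealth mgwr  --in panel.csv --response life_expectancy --covariates x0,x1,x2
spathealth run   --out-dir run --seed 0     # full pipeline with manifest
```

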