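# xylophen

Cross-species analysis tools linking the timing of spring leaf-out to stem
xylem anatomy in woody angiosperms.

In seasonally cold climates, wide xylem vessels conduct water efficiently
(Poiseuille conductance scales with diameter to the fourth power) but are
vulnerable to freezing-induced embolism above a critical diameter of about
30 μm. Species with wide vessels are therefore expected to delay leaf-out
until new earlywood forms and frost risk has passed. Testing this across
species requires combining several kinds of data — vessel measurements from
stem cross-sections, leaf-out dates on a thermal-time (growing degree day)
axis, daily temperature normals for frost risk, dye-perfusion estimates of
which vessels still conduct, and a phylogeny so that shared ancestry does
not masquerade as a trait correlation. `xylophen` implements that full
pipeline, together with a synthetic common-garden generator whose known
ground truth makes every stage testable by parameter recovery.

## What it computes

- **Anatomy** — equivalent circular diameters from lumen areas
  (d = 2·√(A/π)), per-stem means, and the percent of vessels strictly over
  the 30 μm embolism threshold; species traits are means of stem means with
  a majority-rule porosity class (diffuse, semi-ring, ring).
- **Hydraulics** — theoretical conductivity of dye-conductive vessels,
  K = (π ρ_w / 128 η) Σ dᵢ⁴ per vessel (ring/semi-ring porous), or
  K = π ρ_w D A d̄⁴ / 128 η in bulk (diffuse porous), at 20 °C water
  properties; plus the percent of previous-year xylem that still conducts.
- **Phenology** — growing degree days (sum of daily mean °C above 0 °C from
  January 1) and the freeze-safe date: the first spring day from which the
  across-years frost frequency stays below 10%.
- **Comparative statistics** — OLS with AIC model selection and
  log-transformed variants; PGLS whose residual covariance is σ²·V(λ) with
  Pagel's λ estimated by bounded ML (or REML) on [0, 1]; a χ² likelihood
  ratio test against λ = 0; Blomberg's K and Pagel's λ phylogenetic-signal
  tests with tip randomizations; the two-garden intercept adjustment for
  pooling; an exponential leaf-out model y = y₀ + a·e^{b·x}; and one-way
  ANOVA with Tukey HSD compact letters.
- **Synthetic gardens** — porosity-specific lognormal vessel-diameter
  distributions, leaf-out generated from a linear (or exponential) model on
  vessel diameter with phylogenetically correlated residuals on birth–death
  trees, and sinusoidal multi-year weather with stochastic spring frost.

The regression estimators (`PGLSRegression`, `ExponentialLeafOutModel`)
follow the scikit-learn `fit`/`predict` protocol; the `*_fit` functions are
thin wrappers returning a `FitResult` summary.

## Worked example

```python
import numpy as np
import xylophen as xp

# a synthetic diverse garden: 64 species, no phylogenetic signal in the
# leaf-out residuals, leaf-out = 50 + 9 * diameter + noise
cfg = xp.SynthConfig(n_species=64, seed=1)
garden = xp.simulate_garden(cfg)

traits = xp.species_summary(garden.vessels)  # anatomy path: stems -> species
traits = traits.merge(garden.traits[["species_id", "leafout_gdd"]],
                      on="species_id")

fit = xp.pgls_fit(traits["leafout_gdd"].to_numpy(),
                  traits["mean_vessel_diameter"].to_numpy(),
                  garden.tree, list(traits["species_id"]),
                  names=["diam"], response="leafout_gdd")
print(f"slope = {fit.coef('diam'):.2f} GDD/um, lambda_hat = {fit.lambda_hat:.3f}, "
      f"R2 = {fit.r2:.2f}")
```

prints

```
slope = 8.20 GDD/um, lambda_hat = 0.000, R2 = 0.54
```

i.e. the fitted leaf-out delay per micron of vessel diameter (truth: 9),
the estimated phylogenetic signal of the residuals (truth: 0 — the
regression correctly collapses to ordinary least squares), and the variance
explained. The same objects drive the freeze-safe date
(`xp.freeze_safe_date(garden.weather)`), conductivities
(`xp.conductivity_table(garden.vessels, garden.areas)`), and the signal
tests (`xp.blomberg_k`, `xp.pagel_lambda_signal`).

A command-line interface wraps the same stages:

```sh
xylophen simulate --seed 1 --out garden/
xylophen anatomy --vessels garden/vessels.csv --out traits.csv
xylophen pgls --traits garden/traits.csv --tree garden/tree.nwk
xylophen run --seed 1 --out results/
```

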