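# Methods

This note documents the models, numerical choices, and known limitations of
`xylophen`. It covers what each stage assumes, which parameters matter and
why their defaults are what they are, and what the synthetic-data tests do
and do not demonstrate about real data.

## Anatomy summaries

Vessel lumina are treated as circles: a measured lumen area A (μm²) becomes
an equivalent diameter d = 2·√(A/π). The embolism threshold is 30 μm, the
approximate critical diameter for freezing-induced embolism in deciduous
angiosperms at moderate water potentials (≈ −0.5 MPa); the exceedance
fraction uses a strict inequality (a vessel exactly at 30 μm does not
count), so the boundary case is deterministic. Species traits are means of
stem means with every stem weighted equally — ring-porous stems carry 200+
measured vessels and would dominate a vessel-weighted average. Porosity is
assigned per species by majority over its stems; ties break toward the
earlier class in (diffuse, semi-ring, ring), i.e. the narrower-vesseled
reading. Vascular/vasicentric tracheids are not distinguished from vessels.

## Theoretical conductivity

Both Poiseuille forms are the mass-flow convention: K has units
kg·m·s⁻¹·Pa⁻¹ and refers to a stem segment — the equations carry no
segment-length or sapwood-area normalization, so comparisons across stems
are relative, not absolute conductances. Water properties default to 20 °C:
ρ_w = 998.2 kg m⁻³, η = 1.002×10⁻³ Pa·s; both are configurable and recorded
with results. The per-vessel sum is used for ring and semi-ring porous
stems (their dyed vessels are individually measured); the bulk form
(density × dyed area × mean diameter⁴) is used for diffuse-porous stems,
where vessel width and density are assumed uniform across the dyed region.
On a homogeneous population with D·A equal to the vessel count the two
forms coincide exactly; on heterogeneous populations the bulk form is a
lower bound (Jensen's inequality on d⁴). Diameters convert from μm to m
before the fourth power; a unit mix-up changes K by 10²⁴ and is covered by
a dimensional test. Stems lacking high-resolution images receive their
species' mean diameter and density from the completely measured stems
before the bulk formula is applied; imputation is refused when a species
has no complete stems.

## Phenology

Growing degree days accumulate max(T̄_d, 0) from January 1, where T̄_d is
the daily mean temperature. The daily statistic is configurable (mean was
chosen over max as the standard thermal-time convention; the choice is
exposed as `statistic=`). Missing days inside the accumulation window are
an error that names the gap. The freeze-safe date treats each calendar day
across the years of a normals table as a Bernoulli sample (frost iff
tmin ≤ 0 °C) and returns the earliest day D such that every day from D
through the end of the spring window (day 181 by default) has frost
frequency strictly below the threshold (0.10 by default). Requiring *all
later days* to qualify prevents an isolated mild day inside a frosty
stretch from counting as safe. If no day qualifies the result is an
explicit "never safe" value, not an exception. Leap days participate when
present; day of year is the calendar ordinal of the actual year.

## PGLS and Pagel's λ

The phylogenetic variance–covariance matrix V has V[i,j] equal to the
shared root-to-MRCA branch length; a stem edge above the root (as left by
pruning) is shared history of all tips and is included, which preserves
root-to-tip depths. Pagel's transform multiplies off-diagonals by λ and
leaves the diagonal unchanged; λ = 0 is a star phylogeny (OLS), λ = 1 is
Brownian motion. The regression model is y = Xβ + ε with
ε ~ N(0, σ²·V(λ)). For fixed λ, β̂ solves the whitened least-squares
problem via the Cholesky factor of V(λ); σ² is profiled out
(ML: RSS/n; the reported coefficient covariance uses the unbiased
RSS/(n−p)). λ is estimated by bounded scalar optimization of the profile
log-likelihood on [0, 1] with absolute tolerance 1e-6, plus an explicit
check of both boundary values since the likelihood often attains its
maximum at 0 or 1. λ is deliberately bounded to [0, 1] even though some
GLS implementations allow excursions outside it (and will happily report
negative λ on small samples); boundedness keeps λ interpretable and V(λ)
positive definite on ultrametric trees. Both ML and REML are available: ML
is the default for analysis fits; the parameter-recovery study uses REML
because ML λ̂ carries the usual downward finite-sample bias of
variance-structure parameters (≈ −0.07 at λ = 0.5, n = 64 in our
simulations), while REML recovers λ ∈ {0, 0.5, 1} to within 0.05 on
average. R² and F for a GLS fit compare against the intercept-only GLS fit
under the same V(λ). AIC is −2·logL + 2k with k counting the regression
coefficients, the error variance, and λ when it is estimated, so OLS and
PGLS tables are comparable.

The λ = 0 likelihood-ratio test uses 2·(logL_full − logL_0) referred to
χ²₁ and floored at zero. Because λ̂ piles on the boundary under the null,
the χ²₁ reference is conservative (the asymptotic null is a 50:50 mixture
of χ²₀ and χ²₁); measured size is well below the nominal 5%.

## Phylogenetic signal

Blomberg's K is the observed MSE₀/MSE ratio (trait variance about the
phylogenetically weighted mean, over the V⁻¹-weighted residual variance)
divided by its Brownian-motion expectation
(tr(V) − n/(1ᵀV⁻¹1))/(n − 1): K ≈ 1 under Brownian motion, K → 0 without
signal. Significance comes from tip randomization: the variance of
standardized independent contrasts is compared between the observed
labeling and trait values shuffled across tips, counting permutations with
variance ≤ observed (ties count toward non-significance) and reporting
(r + 1)/(n_rand + 1), so p is never zero. Contrasts are linear in the
trait, so the contrast-weight matrix is built once per tree and all
permutations are scored by one matrix product. Pagel's λ signal is the ML
λ̂ of the intercept-only PGLS model; its p-value defaults to the λ = 0 LRT
(the phylosig convention), with a tip-randomization mode also available
since which convention produced published p-values is often ambiguous.
The default randomization count is 999.

## Model selection, pooling, nonlinear fit, ANOVA

`select_model` returns the lowest-AIC candidate and the full AIC table;
candidates must share response and sample size, and ties (ΔAIC < 1e-9) are
flagged rather than silently resolved. Log-transformed variants refit the
same design with natural-log covariates (a multiplicative-error robustness
check for diameter and height), rejecting nonpositive values by row.

Two gardens are pooled only when their leaf-out/diameter slopes are
statistically indistinguishable: the garden-by-diameter interaction is
tested first and pooling is refused (with diagnostics) when it is
significant at the configured α (0.05). Given parallel slopes, garden A's
response is shifted by the parallel-model garden coefficient
(intercept_B − intercept_A). When the parallel model fits to machine
precision the interaction test would divide rounding error by rounding
error, so an exact parallel fit (R² ≥ 1 − 1e−12) is treated as
non-significant by construction.

The exponential leaf-out model y = y₀ + a·e^{b·x} is fit by nonlinear
least squares from a grid of starting rates b (multi-start over
{−0.3 … 0.4}) keeping the converged attempt with the lowest residual sum
of squares; non-convergence is reported, never raised. Note an intrinsic
identifiability limit: a is the curve's value extrapolated to x = 0 μm,
far outside any realistic diameter range, and its relative sampling error
is on the order of 50% for Fig-3-scale gardens (18 species, diameters
16–33 μm, species-mean noise ≈ 20 GDD) even when the global optimum is
found; y₀ and b are well determined. Parameter-recovery claims about a at
realistic noise are therefore weak by nature.

One-way ANOVA uses the classical F; Tukey HSD p-values come from the
studentized-range distribution, and the compact letter display uses the
insert-and-absorb algorithm on the significant pairs (α = 0.01 by default,
ties at the boundary resolved as non-significant, letters ordered by
descending group mean).

## Synthetic gardens

The generator's defaults are the study conditions the pipeline is meant to
exercise: 64 species (the diverse-garden scale), 4 stems per species,
porosity mix 41:19:27 (diffuse:semi-ring:ring), diffuse vessels lognormal
around 20 μm, ring-porous wood a 30:70 mixture of 55 μm earlywood and
18 μm latewood, semi-ring wood a linear earlywood→latewood decline across
within-ring position, within-stem CV 0.2, and leaf-out
GDD = 50 + 9·diameter + ε with residual SD 60 GDD. Residuals are
multivariate normal with covariance resid_sd²·C(λ_true) where C is the
tree's correlation matrix (unit diagonal after rescaling to unit depth);
λ_true defaults to 0, the empirically observed outcome for these traits.
Lognormal diameter distributions guarantee positivity and match the
multiplicative-error rationale for the log-transformed analyses;
diffuse stems require at least 100 vessels (the measurement convention the
bulk formula assumes). Trees are birth–death (birth 1.0, death 0.5 per
unit time) conditioned on the tip count; because the simulator stops at
the final speciation (which would leave a zero-length sister pair and a
singular VCV), every extant tip is extended by the exponential waiting
time to the next event, the stem edge is dropped, and the tree is rescaled
to unit root-to-tip depth so λ is comparable across replicates. Weather is
a sinusoid (annual mean 6 °C, half-amplitude 18 °C, coldest mid-January)
with Gaussian noise (SD 3 °C) and tmin 5 °C below tmean — deep winter is
reliably frozen and the spring frost frequency decays smoothly, putting
the 10% freeze-safe date near day 120–130, as for a cold-temperate site.
Dye-perfusion emulation gives diffuse/semi-ring/ring stems previous-year
functional fractions near 80/45/10% — the qualitative pattern in which
late-leafing ring-porous species rely on new earlywood. The exponential
("salicaceous-like") garden uses 18 species, no ring-porous wood,
diameters ~16–33 μm, (y₀, a, b) = (180, 0.5, 0.2) and species-mean noise
20 GDD — a ±50 GDD individual SD over ~6 plants per species.

One global seed fans out through `numpy.random.SeedSequence.spawn` into
independent per-stage streams, making every output byte-identical under a
fixed seed while keeping stages statistically independent. Ground truth
(generating parameters and per-species expected diameters) is written to a
separate `truth.json` sidecar, never mixed into data tables.

What the generator does *not* emulate: within-plant vessel-diameter
scaling (tip-to-base widening), image segmentation error, observation-date
discretization of leaf-out (real monitoring is every 2–7 days), chilling/
forcing physiology, spatially correlated weather, non-random species
selection, or tree-topology error. Passing recovery tests therefore show
the estimators are correct and calibrated under the stated generative
model, not that the biological model is true of any real garden.

## Problem sizes and tolerances

Unit tests use frozen external references (GLS fits with a fixed-λ Pagel
correlation structure, independent contrasts, and signal statistics
computed independently in R) at tolerances of ~1e-7 for coefficients and
~2e-5 for log-likelihoods, plus exact identities at machine precision. The
simulation studies use 200 replicates at 64 species for parameter
recovery, 500 replicates at 32 species for test calibration, and 500
replicates at 50 species for the Brownian-motion K expectation; the
acceptance script scales these to 120/300 replicates, sizes chosen to keep
Monte-Carlo error a few times smaller than the property bands being
checked while completing in well under a minute each on one CPU.
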