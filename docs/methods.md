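# Methods

`treenbh` implements a two-stage analysis of how tree–tree interactions in
the immediate planting neighbourhood scale up to the community-level
biodiversity–productivity relationship (BPR) in planted diversity
experiments, together with a synthetic-experiment generator that provides
ground truth for every estimator in the chain.

## The experimental layout being emulated

The generator reproduces the design of a large subtropical
biodiversity–ecosystem-functioning planting trial: two sites, each with
square plots of 20 × 20 trees at 1.29 m spacing, a community species
richness (CSR) gradient {1, 2, 4, 8, 16, 24} drawn from a 40-species pool,
species assigned randomly to planting positions at equal per-species
frequency (per-species counts within a plot differ by at most one), and
per-site plot counts of 240 / 234 across the richness levels (76/68/46/26/
19/5 and 74/66/45/26/18/5). Species compositions are memoised into a
limited set per richness level so the composition grouping factor (CSC) has
repeated levels; compositions are random draws rather than structured
extinction scenarios. Only trees in a central focal block are analysed
(default 4 × 4 = 16 focal trees; a configurable fraction of plots at
richness ≥ 4, default 25%, uses a 10 × 10 block), surrounded by a ring of
neighbour-only trees; the remaining border buffers edge effects. Plot
topography (elevation 100–300 m, slope 15–40°, northness −1..1) is drawn
uniformly and independently — no spatially autocorrelated fields.

Initial stem diameter is lognormal (median 1.5 cm, log-sd 0.25 — a
same-age planted cohort measured near the ground) and height follows a
power-law allometry H = a·D^b (a = 60 cm, b = 0.9) with lognormal noise.
The noise sd is derived in closed form from the target Pearson correlation
of log D and log H (0.91 by default): s_e = b·s_D·√(1/r² − 1). Only the
correlation structure of real size data is reproduced; species-specific
allometries and age structure are not.

## Growth, mortality and the generative model

Wood volume treats the stem as a cylinder reduced by a form factor,
V = (πD²/4)·H·f with f = 0.5, and annual growth is G = (V₂ − V₁)/(t₂ − t₁)
over the census interval (two censuses, 2011 and 2016, by default). The
generator draws each tree's log₁₀ G from the neighbourhood growth model
itself (below) using census-1 neighbourhood predictors, adds crossed
Gaussian random intercepts (species, composition, neighbour-density class,
plot) and a residual, then back-solves the final (D, H) from
V₂ = V₁ + G·Δt holding the tree's height/diameter ratio fixed. Mortality
is a single independent Bernoulli per tree per period (17% site A, 23%
site B by default); replanting is not simulated. A small fraction of
survivors (1.7% / 2.1%) receive a slightly shrunken remeasured volume to
emulate the measurement artefacts that produce negative growth rates in
real censuses; the metrics stage excludes negative-growth trees and reports
the excluded fraction.

Default generative coefficients (standardised scale): intercept −1.3
(log₁₀ cm³ yr⁻¹ at zero predictors), size 0.35, competition −0.15,
conspecific density 0.0, neighbourhood richness +0.15, with small
interaction terms (size×richness −0.01, competition×richness −0.01,
size×competition×richness +0.005); random-effect sds 0.25 (species), 0.10
(composition), 0.05 (density), 0.06 (plot) and residual sd 0.30. Because
predictors are scaled but not centred, the standardised slopes must be
read against the population divisors: the size slope corresponds to growth
roughly proportional to volume (raw log–log slope ≈ 1.1), and the net
richness gradient raises per-tree growth by about a factor of two from
monocultures to 24-species neighbourhoods — a clearly positive
biodiversity–productivity world with species and composition effects
("monoculture productivity is highly variable") layered on top.

Two scale choices matter and were set deliberately. First, the intercept
puts median 5-year volume increments around 20–30% of initial volume.
The volume-standardised productivity measure divides by the period-mean
volume, so when period growth dominates standing volume the measure
largely cancels its own growth signal across plots; keeping increments
modest keeps community productivity responsive to the growth gradient the
generator encodes. Second, the random-effect and residual scales put
roughly 80% of plot-level log-productivity variance into the systematic
parts, matching the variance structure the analysis is designed to
resolve; far noisier worlds leave the highest richness level (five plots,
two compositions per site) sign-unstable in the community contrast.

## Neighbourhood indices

For each focal tree the up-to-eight occupants of the surrounding grid
cells (Moore neighbourhood) define:

* **NCI** — summed neighbour basal area (cm²); the *asymmetric* variant
  counts only neighbours with a strictly larger stem diameter ("larger" is
  strict; ties contribute to the symmetric variant only).
* **CND** — count of conspecific neighbours.
* **NSR** — count of distinct heterospecific neighbour species. A purely
  conspecific neighbourhood has NSR = 0, the baseline of the net
  biodiversity effect. NSR can in principle reach 8 (eight neighbours of
  eight distinct foreign species); the effect surface is evaluated on
  NSR 0..7.

Neighbours dead at a census are omitted from that census's indices, and
indices are averaged over the period's censuses so that they reflect the
neighbourhood actually experienced (the census set is configurable; the
calibration checks use first-census indices, which are the generator's
own predictors). Whatever diameter column is supplied is used as D — no
taper correction — and no distance weighting is applied (all eight cells
are equidistant neighbours by design).

## The mixed-model engine

The growth model is

log₁₀ G = α + β₁ log₁₀ V + β₂ log₁₀(NCI+1) + β₃ CND + β₄ NSR
(+ interaction terms) + γ_species + φ_composition + υ_density + τ_plot + ε,

with crossed Gaussian random intercepts and all predictors divided by their
sample standard deviation (not mean-centred) before fitting; the divisors
are stored and re-applied verbatim to any new data so cross-site
predictions use the training scale. Logs are base 10 throughout; NCI gets
a +1 offset before the log.

The engine maximises the profiled (RE)ML likelihood over relative standard
deviations θ_f = σ_f/σ using the standard sparse formulation
(A = Λ'Z'ZΛ + I, penalised residual sum of squares at the conditional
modes). θ is optimised directly with a lower bound at zero — not on a log
scale — so singular fits (variance exactly zero) are representable and are
flagged rather than hidden; L-BFGS-B with two starts (θ = 1 and θ = 0.1)
guards against local optima, warm starts reuse a previous fit's θ, and the
convergence tolerance on the deviance is ~1e-12. One factor may carry a
correlated random slope, parameterised through a per-level lower-triangular
relative Cholesky factor (3 parameters), so the likelihood-ratio test of a
species-specific NSR slope has 2 degrees of freedom. A dense
multivariate-normal evaluation (`loglik_bruteforce`) serves as an
independent oracle for small problems and agrees with the profiled
computation to better than 1e-6.

AIC counts fixed effects + variance parameters + residual; Akaike weights
are exp(−Δ/2) normalised. The two-stage convention is enforced by the API:
likelihood-ratio or AIC comparisons of *random* structures require REML
fits with identical fixed parts, comparisons of *fixed* structures require
ML; mixing raises an error. t statistics use a normal approximation for
p-values — no Satterthwaite/Kenward–Roger degrees of freedom — which is
slightly anticonservative for small level counts and is documented rather
than corrected.

## Model selection

The fixed-structure candidate set keeps initial size always, varies the
NCI/CND/NSR main effects, and includes interaction terms under a strict
hierarchy (an interaction requires all its main effects; the three-way term
requires all three constituent two-way terms): 28 candidates. The ML-AIC
best candidate is then backward-eliminated by likelihood-ratio tests at
α = 0.05, dropping the least significant droppable term first; a term is
droppable only if no retained higher-order term contains it. The final
structure is refitted by REML. Random factors with a single level are
dropped with a warning (a first-census-only configuration makes the
neighbour-count factor constant for interior focal trees).

The sensitivity analysis refits the chosen structure with the symmetric
instead of the asymmetric competition index and reports ΔAIC and Akaike
weights; under the generator's asymmetric truth the asymmetric index wins
decisively.

## Net biodiversity effect and the community scale

NE_nbh(size, NCI, NSR) = 100·(G_h − G_c)/G_c, where both growth rates are
fixed-effects predictions with size and NCI held at empirical quantiles
(20/50/80%, type-7 interpolation of the log-transformed distributions),
NSR at 0 (conspecific baseline) or 1..7, and CND held at its dataset mean
(configurable to the maximum; the mean is the default because the selected
model typically carries no CND term). The baseline cell is exactly zero by
construction, and the sign of every cell equals the sign of the NSR
contribution to the linear predictor (the back-transform is monotone).

Community productivity standardises size structure away:
AWP = Σ(G_i·V_i)/Σ V̄_i (cm³ cm⁻³ yr⁻¹), with V̄_i the mean of the tree's
per-census volumes ((V₁+V₂)/2 in the two-census default — the census
weighting is a package choice). The identical aggregation code path serves
observed growth (AWP_obs) and growth predicted for the other site from the
training site's fixed effects (AWP_nbh); covariates far outside the
training range trigger an extrapolation warning, not an error. The
community model regresses log₁₀ AWP_obs on standardised log₁₀ CSR,
log₁₀ AWP_nbh and three topography terms with a CSC random intercept,
selected by the same two-stage procedure; constant predictors (e.g. CSR in
a monoculture-only design) are dropped up front with a notice.

Variance partitioning attributes to each fixed term the variance of its
partial linear predictor after *sequential orthogonalisation* against the
terms preceding it in the model order (reported in the output); random
fractions are variance components over the total (fixed-predictor variance
+ variance components + residual), and the residual closes the sum to one
exactly. For correlated predictors the attribution is therefore
order-dependent — a convention, stated in the result's metadata, chosen
because partial attribution under collinearity has no unique definition.
Per-richness-group relationships (groups {1},{2},{4,8},{16,24} by default)
are marginal r² values of AWP_obs ~ AWP_nbh mixed fits within each group;
groups with fewer than three plots are skipped with a notice. Marginal and
conditional r² are variance shares of the fixed and fixed+random parts.

## Calibration checks and what they show

The test suite validates the chain against independent oracles: a naive
per-tree loop for the indices, dense likelihood evaluation for the engine,
OLS in the zero-variance limit, a closed-form balanced one-way likelihood,
and statsmodels' variance-components fitter as an external cross-check.
Trial-scale simulations (≈240 plots, ≈4–5k focal trees, 20 replicates)
verify estimator calibration (2-SE coverage ≥ 90%, slope bias < 0.05
standardised units), selection consistency (a true 0.05 three-way
interaction retained and a null CND dropped in ≥ 80% of replicates — run
at a reduced scale of ~38 plots with 36-tree focal blocks to keep the
suite fast), exact cross-scale transfer in the noiseless limit
(AWP_nbh = AWP_obs to 1e-6), recovery of designed variance-partition
shares (0.5/0.25 within 0.08), and a designed richness-dependent signal
gradient under which per-group r² increases with CSR. The signal-sd
gradient for that last check (0.32/0.62/1.0/1.1/1.85/1.95 by richness
level) was chosen so that the implied group r² targets (≈0.1/0.3/0.55/0.8)
are separated by well more than the sampling noise of r² at the per-group
plot counts.

Because the generator draws growth from the fitted model's own functional
form, these checks demonstrate internal consistency and statistical
calibration, not the adequacy of the model for real forests: real data add
spatial autocorrelation, species-specific allometry and mortality,
replanting, and measurement structure that the generator deliberately
omits.

## Known limitations

* Gaussian responses only; no spatial covariance structures.
* Normal-approximation p-values (no small-sample df correction).
* Sequential (order-dependent) variance attribution under collinearity.
* Mortality is covariate-independent; real mortality is size- and
  competition-dependent, which would couple the missingness to the model.
* The two sites share generative parameters; only their species pools and
  random draws differ.
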