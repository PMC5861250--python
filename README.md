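# treenbh

Neighbourhood-to-community analysis of the biodiversity–productivity
relationship (BPR) in planted tree-diversity experiments.

In a mixed-species forest, every tree interacts mostly with its immediate
neighbours. `treenbh` quantifies how those local interactions scale up to
community productivity: it models the annual wood-volume growth *G* of a
focal tree as a function of its initial volume *V* and three neighbourhood
descriptors — the competition index NCI (summed basal area of strictly
larger neighbours among the ≤ 8 adjacent grid positions), conspecific
neighbour density CND, and neighbourhood species richness NSR —

log₁₀ *G* = α + β₁ log₁₀ *V* + β₂ log₁₀(NCI + 1) + β₃ CND + β₄ NSR
(+ interactions) + γ_species + φ_composition + υ_density + τ_plot + ε,

a linear mixed model with four *crossed* random intercepts, fitted by
profiled REML/ML with AIC/Akaike-weight model selection and
likelihood-ratio backward elimination. From the fitted model it derives
the individual-based net biodiversity effect
NE_nbh = 100·(G_heterospecific − G_conspecific)/G_conspecific on a grid of
tree-size and competition quantiles, transfers fixed-effect growth
predictions to an independent second site, aggregates them to standardised
plot productivity AWP = Σ(Gᵢ·Vᵢ)/Σ V̄ᵢ (cm³ cm⁻³ yr⁻¹), and partitions the
variance of observed community productivity among neighbourhood-predicted
productivity (AWP_nbh), community species richness (CSR), topography, the
species-composition random effect (CSC) and the residual.

Because raw data from such trials are typically not openly available, the
package ships a first-class synthetic-experiment generator (20×20 planting
grids at 1.29 m spacing, richness gradient 1–24 from a 40-species pool,
correlated diameter–height allometry, mortality, growth drawn from the
model above with known coefficients) so that every estimator can be
validated against ground truth. See `docs/methods.md` for the model,
parameter defaults and their rationale.

## Worked example

```python
import treenbh

# simulate a two-site trial and run the full analysis
from treenbh.pipeline import RunConfig, SiteConfig, run_pipeline

cfg = RunConfig(
    seed=7,
    site_a=SiteConfig("A", {1: 10, 2: 8, 4: 6, 8: 4, 16: 3, 24: 2}),
    site_b=SiteConfig("B", {1: 10, 2: 8, 4: 6, 8: 4, 16: 3, 24: 2},
                      mortality_rate=0.23, negative_growth_rate=0.021),
    nci_mode="both",
    output_dir="out",
)
report = run_pipeline(cfg)
nm = report.stages["neighbourhood_model"]
print(nm["terms"], round(nm["r2_marginal"], 2))
print(report.stages["nci_comparison"]["delta_aic"])
print(report.stages["community_model"]["variance_partition"]["fixed"])
```

prints (seed 7, this small configuration):

```
['logV', 'logNCI', 'NSR'] 0.57
54.1
{'logAWPnbh': 0.2743, 'elevation_m': 0.0844}
```

i.e. model selection kept tree size, competition and neighbourhood
richness (fixed effects explaining 57% of growth variation); the
size-asymmetric competition index beat the symmetric one by ΔAIC ≈ 54
even at this 33-plot scale; and the neighbourhood-interaction prediction
took the largest share of the community-productivity variance at the
second site. The same stages are available as a
CLI (`treenbh run-all --config cfg.yaml --seed 7 --out out/`, plus
`simulate`, `metrics`, `fit-neighbourhood`, `ne-surface`, `cross-predict`,
`fit-community`, `varpart`), writing census tables and features as CSV and
fits/reports as JSON.

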