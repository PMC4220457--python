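# ecoflux

Whole-community energy fluxes through litter food webs along a land-use
gradient.

Land-use transformation — tropical forest converted to jungle rubber, rubber
monoculture or oil palm — erodes species richness, density and biomass of
litter macroinvertebrate communities. Biomass alone, however, is a poor
proxy for how much *work* a community does: metabolic activity per unit
biomass varies with body size, phylogeny and temperature. `ecoflux`
implements the full chain from individual body lengths to guild-level
annual energy fluxes so that multitrophic ecosystem functioning can be
compared across land-use systems, and its relationship with species
richness modelled. It is intended for community ecologists working with
individual-level field samples (site × subplot × morphospecies records).

## The model

1. **Allometry** — body length L (mm) → fresh mass M (mg) via taxon-keyed
   power-law regressions M = a·L^b (dry-basis regressions carry a
   dry-to-fresh factor), with family → order → class → default fallback and
   median-based imputation for damaged specimens.
2. **Metabolism** — individual rates ln I = ln i₀ + a·ln M − E/(kT)
   (J h⁻¹; T in kelvin, k = 8.617×10⁻⁵ eV K⁻¹, constants per phylogenetic
   group); community metabolism X is the per-guild, per-area sum.
3. **Energy flux** — four consumer guilds (predator, omnivore, detritivore,
   herbivore) over two basal resources (plant, detritus). With diet matrix
   W and diet-specific assimilation efficiencies e_a, each guild's ingoing
   flux F satisfies the balance e_a·F = X + L, where L_c = Σ_k W[c,k]·F_k
   is the loss to predation. The coupled system is solved exactly as
   (diag(e) − W_cc)F = X; fluxes convert to kg fresh mass ha⁻¹ yr⁻¹. The
   null diet model splits predator intake equally across the three animal
   guilds and omnivore intake 25/25/25/25 across the animal guilds and
   plant+detritus; a no-animal-omnivory variant supports sensitivity
   analysis of the diet assumptions.
4. **Diversity** — observed richness, second-order jackknife extrapolation
   S_jack2 = S_obs + Q1(2m−3)/m − Q2(m−2)²/(m(m−1)) from m subplot
   incidences, and individual-based rarefaction
   E[S_n] = Σᵢ 1 − C(N−Nᵢ,n)/C(N,n).
5. **BEF analysis** — mixed-effects models of flux on log₁₀ richness × land-use
   system with a landscape random intercept, backward AIC selection
   (ΔAIC ≥ 2, ties to the simpler model), Moran's I residual diagnostics,
   per-system summaries and percent comparisons.

A synthetic study generator emulates the sampling design (4 systems × 2
landscapes × 4 replicates, three 1-m² subplots per site) with known
ground-truth multipliers on density, richness retention and body mass, so
every stage runs — and is tested — without any field data. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from ecoflux import run_study, summarize_by_system, coverage_summary, percent_change

result = run_study(seed=42)  # default 32-site synthetic study, null diet model
summary = summarize_by_system(
    result.site_totals, ["S_obs", "biomass_kg_ha", "total_flux_kg_ha_yr"]
)
print(summary[["S_obs_mean", "biomass_kg_ha_mean", "total_flux_kg_ha_yr_mean"]].round(1))

flux = summary["total_flux_kg_ha_yr_mean"]
print("flux loss forest -> oil palm:",
      percent_change(flux["oil_palm"], flux["forest"], "loss"), "%")
cov = coverage_summary(result.site_totals)
print(f"sampling coverage: {cov['mean_coverage_pct']:.1f}% (rho = {cov['pearson_rho']:.3f})")
```

prints

```
               S_obs_mean  biomass_kg_ha_mean  total_flux_kg_ha_yr_mean
system
forest              204.0                17.5                    2463.8
jungle_rubber       168.0                15.0                    2161.5
oil_palm            105.1                 9.2                    1660.5
rubber              176.4                14.7                    2683.4
flux loss forest -> oil palm: 33 %
sampling coverage: 56.4% (rho = 0.998)
```

Mean observed richness falls from 204 morphospecies in forest to 105 in oil
palm for this realisation, biomass roughly halves, and total annual energy
flux drops by a third; the jackknife coverage summary says the three
subplots captured about 56% of estimated richness, with extrapolated and
observed richness almost perfectly correlated. `result.networks` holds the
solved per-site energy networks (per-guild demand X, effective e_a, ingoing
flux F, loss to predation L and edge fluxes), and
`fit_bef_models(result.site_totals)` runs the richness→flux model
selection.

A thin CLI mirrors the stages: `ecoflux synth`, `ecoflux mass`,
`ecoflux metabolism`, `ecoflux fluxes`, `ecoflux diversity`,
`ecoflux report` (see `--help`).

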