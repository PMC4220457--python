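# Methods

## The model

`ecoflux` computes whole-community energy flux as a measure of multitrophic
ecosystem functioning for litter macroinvertebrate communities sampled along
a land-use gradient. The chain of computation is:

1. **Length → fresh mass.** Individual body lengths L (mm) are converted to
   fresh mass M (mg) with taxon-keyed power-law regressions M = a·L^b;
   regressions published on a dry-mass basis are multiplied by a
   dry-to-fresh factor. If a taxon lacks its own regression, or L lies
   outside the regression's published length range, the registry falls back
   along a deterministic chain (family → order → class → universal default),
   and the record is flagged `fallback_regression`. Damaged individuals with
   no measurable length receive the median fresh mass of measured
   conspecifics; when the species has fewer than two measured individuals,
   the order-level median is used. Medians are taken over estimated fresh
   masses, not lengths.

2. **Mass → metabolic rate.** Individual resting metabolism follows
   ln I = ln i₀ + a·ln M − E/(kT), with I in J h⁻¹, T the site's soil
   temperature in kelvin (input in °C, averaged per system × landscape
   upstream), k = 8.617×10⁻⁵ eV K⁻¹ and (ln i₀, a, E) specific to a
   phylogenetic group. Community metabolism X is the per-guild sum of I over
   a site, divided by the sampled area (n_subplots × subplot area).

3. **Metabolism → energy flux.** Guild nodes (predator, omnivore,
   detritivore, herbivore) sit above two unlimited basal resources (plant,
   detritus). A diet matrix W gives the proportion of each consumer's
   ingoing flux drawn from each resource. Each consumer's assimilated intake
   must cover its metabolic demand and its loss to predation:

       e_a·F = X + L,   where  L_c = Σ_k W[c,k]·F_k

   and e_a is the diet-weighted assimilation efficiency
   (e_a = Σ_r W[r,c]·e(r)). Because predators and omnivores feed on each
   other under the null diet model, the equations are coupled; they are
   solved exactly as the linear system (diag(e) − W_cc)F = X over the four
   consumer nodes. Pure top-down substitution would not terminate on the
   predator↔omnivore cycle, and a fixed-point iteration would only be
   approximate, so the direct solve is used; the balance identity is
   asserted at every node of every solution at 10⁻⁹ relative tolerance, and
   a negative or singular solution raises an error naming the offending
   node. Reported fluxes are *ingoing* flux per consumer node; basal outflow
   is additionally reported for bookkeeping (no balance equation is imposed
   on basal nodes).

   The **null diet model** assumes no feeding preferences: predators draw
   1/3 from each animal guild below them; omnivores draw 25% from each of
   predator, detritivore and herbivore and 25% from plant+detritus (split
   12.5%/12.5% by default — the minimal-assumption equal split, configurable
   via `basal_plant_share`); detritivores eat only detritus, herbivores only
   plants. The **no_animal_omnivory** sensitivity variant feeds omnivores
   50% plant / 50% detritus with all other columns unchanged;
   `sensitivity_compare` contrasts per-system relative flux losses versus
   the reference system between the two models.

4. **Units.** Energy fluxes are solved in J h⁻¹ m⁻² and converted to annual
   fresh-mass fluxes as F × 8,760 h yr⁻¹ × 10⁴ m² ha⁻¹ / (ε × 10³ g kg⁻¹),
   with ε the fresh-tissue energy density (default 7,000 J g⁻¹,
   configurable). Biomass converts as mg m⁻² × 10⁻² = kg ha⁻¹.

5. **Diversity.** Observed richness is the distinct morphospecies count.
   Extrapolated richness uses the second-order jackknife over the m = 3
   subplot incidences, S_jack2 = S_obs + Q1(2m−3)/m − Q2(m−2)²/(m(m−1));
   it requires m ≥ 3. Rarefied richness is the individual-based
   (hypergeometric) expectation E[S_n] = Σᵢ 1 − C(N−Nᵢ,n)/C(N,n) computed in
   log space, cut at n = 40 (the smallest site sample in the emulated
   design); sites with fewer than 40 individuals get a flagged NaN.
   Individual-based rarefaction with an individual-count cut-off was chosen
   over subsample-based rarefaction because the cut-off is defined in
   individuals; the two readings conflict and this is the consistent one.
   Sampling coverage is S_obs/S_jack2 per site; the study summary reports
   its mean ± s.d. and the Pearson correlation of S_obs with S_jack2.

6. **BEF models.** Energy flux is regressed on log₁₀ richness, land-use
   system and their interaction, with a landscape random intercept
   (statsmodels MixedLM, maximum likelihood so AICs are comparable across
   fixed-effect sets; AIC = 2k − 2ℓ with k counting fixed effects plus
   variance components). Backward selection over {interaction, additive,
   richness-only, null} picks the lowest-AIC model only if it beats the
   runner-up by ≥ 2 AIC units; otherwise the simplest model within 2 units
   of the best wins. Singular mixed fits (e.g. a single landscape, or a
   boundary random-effect variance) fall back to fixed-intercept OLS with a
   warning; count responses (richness) use a negative-binomial GLM reading
   of the same fixed-effect structure since no mixed NB backend is
   available in statsmodels — the selection logic is identical. Residual
   spatial autocorrelation is tested with Moran's I under row-standardised
   k-nearest-neighbour weights (k = 4 by default; any weight matrix can be
   supplied), using the normality-assumption variance for the standard
   deviate and a two-sided normal p-value. Percent comparisons between
   systems are reported as half-up-rounded integer percentages (ratio or
   loss mode).

## The synthetic generator

No field dataset ships with the package, so a generator emulates the study
design the analysis assumes: 4 systems (forest, jungle rubber, rubber, oil
palm) × 2 landscapes × 4 replicates = 32 sites, each sampled with three 1-m²
subplots. Within each guild a fixed species pool carries lognormal
rank-abundance weights (sdlog 1.1), a taxon key usable by the allometry
registry, and a lognormal body-length distribution. Land use enters as
known multiplicative effects relative to forest: a density multiplier thins
expected counts (site counts are Poisson, allocated multinomially over
species), richness retention keeps each pool species with that probability
per site (binomial retention, so lost-species identity varies across
replicates), and a body-mass multiplier scales lengths by its cube root
(masses scale roughly with L³). Temperatures are constants per
system × landscape (24.4–27.7 °C). A single root seed spawns one substream
per site, so site draws are reproducible and order-independent; identical
(config, seed) pairs give byte-identical tables.

Defaults were calibrated once so a default draw resembles the emulated
design scale — roughly 7,400 individuals and 840 morphospecies over 32
sites — with multipliers (density 1/0.84/0.90/0.52, retention
1/0.85/0.80/0.55, mass 1/0.95/0.95/0.92) chosen to produce forest→oil-palm
declines of about 45% in richness, 48% in density and 52% in biomass.
Deliberately absent from the generator: true spatial autocorrelation (site
coordinates sit on a grid only so Moran's I is computable),
phylogenetically structured trait evolution, and any direct
richness→function coupling beyond what density and sampling induce. Tests
passing on these data therefore demonstrate correctness of the
computations and recoverability of injected effects, not ecological realism
of any particular parameter value.

## Parameter tables

The allometry registry (`ecoflux/data/allometry_registry.csv`) and the
metabolic constants (`ecoflux/data/metabolic_params.csv`) ship
literature-typical default values. They are editable stand-ins: the
computation is the contribution, and real analyses should substitute the
regression and metabolic tables appropriate to their taxa. The same applies
to the assimilation efficiencies (defaults e_animal = 0.906,
e_plant = 0.545, e_detritus = 0.158) and the energy-to-fresh-mass constant
(7,000 J g⁻¹).

## Numerical choices and problem sizes

- Flux-balance tolerance 10⁻⁹ relative, asserted on every solve; in
  practice residuals sit at machine precision because the solve is direct.
- Rarefaction combinatorics in log space via `gammaln`, exact at n = N.
- AIC tie rule: within 2 units the model with fewer parameters wins; exact
  ties break toward lower AIC.
- Degenerate inputs: empty sites yield zero metabolism and flux; zero-area
  sites, missing temperatures, unknown guild/diet/group labels, n > N
  rarefaction and all-equal Moran residuals raise informative errors.
- Test and verification problem sizes: the default 32-site study for
  end-to-end checks; 1,000 random feasible instances for the solver-oracle
  equivalence; a 200-site study (25 replicates per system per landscape)
  for parameter recovery, where the configured 0.5 oil-palm density
  multiplier is recovered within 5% Monte-Carlo error.

## Known limitations

- Guild-level (not species-level) networks; no dynamics or stability
  analysis.
- Default parameter tables are plausible stand-ins, so absolute flux
  magnitudes from the defaults are illustrative; relative comparisons
  between systems are the meaningful output (the sensitivity analysis shows
  per-system relative losses are robust to the omnivory assumption, with
  sub-percent disparity on synthetic data).
- Mixed-model AICs compare a MixedLM against an OLS fallback when the
  random-intercept variance is estimated at the boundary; this is the
  standard boundary issue of variance-component selection.
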