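"""Synthetic litter-macroinvertebrate study generator.

Emulates a replicated land-use-gradient field design: four transformation
systems (forest, jungle rubber, rubber, oil palm) crossed with two
landscapes and replicated four times each, giving 32 sites, each sampled
with three 1-m^2 litter-sieving subplots.  Every individual carries a guild
(predator, omnivore, detritivore, herbivore), a morphospecies id, a taxon
key usable by the allometry registry, and a body length in mm.

Land-use intensification is injected as known multiplicative ground-truth
effects per system, relative to forest (the reference, all multipliers 1):

* density multiplier — thins the expected number of individuals,
* richness retention — each species of the pool survives in a given site
  with this probability (binomial retention, so the identity of lost
  species varies between replicates),
* body-mass multiplier — scales expected fresh mass, applied to lengths as
  the cube root since mass scales roughly with length cubed.

Within each guild the species pool follows a lognormal rank-abundance
distribution, so communities are realistically uneven and rarefaction is
nontrivial.  Default pool sizes, densities and effect sizes are calibrated
so a default draw resembles the design scale this generator emulates
(~7,500 individuals, ~870 morphospecies over 32 sites, with roughly 45% /
48% / 52% forest-to-oil-palm declines in richness, density and biomass).

A single root seed spawns one substream per site (plus one for the species
pool), so individual site draws are reproducible and order-independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GUILDS",
    "SYSTEMS",
    "ConfigError",
    "SyntheticConfig",
    "GroundTruth",
    "SiteCommunity",
    "SpeciesPool",
    "build_species_pool",
    "draw_site_community",
    "generate_study",
    "study_tables",
    "true_effect",
    "write_study_csv",
]

SYSTEMS = ("forest", "jungle_rubber", "rubber", "oil_palm")
GUILDS = ("predator", "omnivore", "detritivore", "herbivore")

# taxon options per guild: (taxon_key in the allometry registry, order-level key)
GUILD_TAXA = {
    "predator": (
        ("Araneae", "Araneae"),
        ("Chilopoda", "Chilopoda"),
        ("Carabidae", "Coleoptera"),
        ("Staphylinidae", "Coleoptera"),
    ),
    "omnivore": (
        ("Formicidae", "Hymenoptera"),
        ("Blattodea", "Blattodea"),
        ("Gryllidae", "Orthoptera"),
    ),
    "detritivore": (
        ("Isopoda", "Isopoda"),
        ("Diplopoda", "Diplopoda"),
        ("Oligochaeta", "Oligochaeta"),
        ("Termitidae", "Blattodea"),
    ),
    "herbivore": (
        ("Curculionidae", "Coleoptera"),
        ("Hemiptera", "Hemiptera"),
        ("Lepidoptera_larvae", "Lepidoptera"),
        ("Gastropoda", "Gastropoda"),
    ),
}


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


def _default_densities():
    # forest-level expected individuals per m^2, per guild
    return {"predator": 22.0, "omnivore": 21.0, "detritivore": 40.0, "herbivore": 12.5}


def _default_pools():
    return {"predator": 260, "omnivore": 220, "detritivore": 300, "herbivore": 170}


def _default_lengths():
    # (meanlog, sdlog) of body length in mm
    return {
        "predator": (1.55, 0.55),
        "omnivore": (1.40, 0.50),
        "detritivore": (1.60, 0.60),
        "herbivore": (1.25, 0.50),
    }


def _default_temperatures():
    return {
        ("forest", "L1"): 24.4,
        ("forest", "L2"): 24.9,
        ("jungle_rubber", "L1"): 25.4,
        ("jungle_rubber", "L2"): 25.9,
        ("rubber", "L1"): 26.3,
        ("rubber", "L2"): 26.8,
        ("oil_palm", "L1"): 27.2,
        ("oil_palm", "L2"): 27.7,
    }


@dataclass
class SyntheticConfig:
    """Study-design and effect-size parameters of the generator."""

    systems: tuple = SYSTEMS
    n_landscapes: int = 2
    replicates_per_system_per_landscape: int = 4
    subplots_per_site: int = 3
    subplot_area_m2: float = 1.0
    species_pool_size: dict = field(default_factory=_default_pools)
    base_density_per_m2: dict = field(default_factory=_default_densities)
    abundance_model: str = "lognormal"
    abundance_sdlog: float = 1.1
    body_length_lognormal: dict = field(default_factory=_default_lengths)
    density_multiplier: dict = field(
        default_factory=lambda: {
            "forest": 1.0, "jungle_rubber": 0.84, "rubber": 0.90, "oil_palm": 0.52,
        }
    )
    richness_retention: dict = field(
        default_factory=lambda: {
            "forest": 1.0, "jungle_rubber": 0.85, "rubber": 0.80, "oil_palm": 0.55,
        }
    )
    mass_multiplier: dict = field(
        default_factory=lambda: {
            "forest": 1.0, "jungle_rubber": 0.95, "rubber": 0.95, "oil_palm": 0.92,
        }
    )
    temperature_C: dict = field(default_factory=_default_temperatures)
    damaged_fraction: float = 0.0
    seed: int = 0

    @property
    def landscapes(self) -> tuple:
        return tuple(f"L{i + 1}" for i in range(self.n_landscapes))

    def validate(self) -> None:
        if not self.systems:
            raise ConfigError("systems: must name at least one system")
        if self.n_landscapes < 1:
            raise ConfigError("n_landscapes: must be >= 1")
        if self.replicates_per_system_per_landscape < 1:
            raise ConfigError("replicates_per_system_per_landscape: must be >= 1")
        if self.subplots_per_site < 1:
            raise ConfigError("subplots_per_site: must be >= 1")
        if self.subplot_area_m2 <= 0:
            raise ConfigError("subplot_area_m2: must be > 0")
        if self.abundance_model not in ("lognormal",):
            raise ConfigError(f"abundance_model: unknown model {self.abundance_model!r}")
        if self.abundance_sdlog <= 0:
            raise ConfigError("abundance_sdlog: must be > 0")
        if not (0 <= self.damaged_fraction < 1):
            raise ConfigError("damaged_fraction: must be in [0, 1)")
        for name, d in (
            ("density_multiplier", self.density_multiplier),
            ("richness_retention", self.richness_retention),
            ("mass_multiplier", self.mass_multiplier),
        ):
            for s in self.systems:
                if s not in d:
                    raise ConfigError(f"{name}: missing system {s!r}")
                if not (d[s] > 0):
                    raise ConfigError(f"{name}[{s!r}]: must be > 0")
            ref = self.systems[0]
            if d[ref] != 1.0:
                raise ConfigError(f"{name}[{ref!r}]: reference system multiplier must be 1")
        for name, d in (
            ("species_pool_size", self.species_pool_size),
            ("base_density_per_m2", self.base_density_per_m2),
            ("body_length_lognormal", self.body_length_lognormal),
        ):
            for g in GUILDS:
                if g not in d:
                    raise ConfigError(f"{name}: missing guild {g!r}")
        for g in GUILDS:
            if self.species_pool_size[g] < 1:
                raise ConfigError(f"species_pool_size[{g!r}]: must be >= 1")
            if self.base_density_per_m2[g] < 0:
                raise ConfigError(f"base_density_per_m2[{g!r}]: must be >= 0")
            _, sdlog = self.body_length_lognormal[g]
            if sdlog <= 0:
                raise ConfigError(f"body_length_lognormal[{g!r}]: sdlog must be > 0")
        for s in self.systems:
            for l in self.landscapes:
                if (s, l) not in self.temperature_C:
                    raise ConfigError(f"temperature_C: missing ({s!r}, {l!r})")

    @property
    def site_area_m2(self) -> float:
        return self.subplots_per_site * self.subplot_area_m2

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["temperature_C"] = {f"{s}|{l}": v for (s, l), v in self.temperature_C.items()}
        data["body_length_lognormal"] = {
            g: list(v) for g, v in self.body_length_lognormal.items()
        }
        data["systems"] = list(self.systems)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["systems"] = tuple(data["systems"])
        data["temperature_C"] = {
            tuple(k.split("|")): v for k, v in data["temperature_C"].items()
        }
        data["body_length_lognormal"] = {
            g: tuple(v) for g, v in data["body_length_lognormal"].items()
        }
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class GroundTruth:
    """Realised generator truth, for parameter-recovery tests."""

    seed: int
    expected_site_count: dict  # system -> expected individuals per site
    density_multiplier: dict
    richness_retention: dict
    mass_multiplier: dict
    mean_log_mass_shift: dict  # system -> ln(mass multiplier)


@dataclass
class SpeciesPool:
    """Guild-structured species pool with fixed traits and relative abundances."""

    table: pd.DataFrame  # species_id, guild, taxon_key, order_key, rel_abundance


@dataclass
class SiteCommunity:
    """One site's sampled individuals plus its metadata."""

    site_id: str
    system: str
    landscape: str
    replicate: int
    temperature_C: float
    n_subplots: int
    subplot_area_m2: float
    x: float
    y: float
    individuals: pd.DataFrame

    @property
    def sampled_area_m2(self) -> float:
        return self.n_subplots * self.subplot_area_m2


def build_species_pool(config: SyntheticConfig, rng: np.random.Generator) -> SpeciesPool:
    """Draw the study-wide species pool: taxa and lognormal relative abundances."""
    rows = []
    for guild in GUILDS:
        n = config.species_pool_size[guild]
        taxa = GUILD_TAXA[guild]
        choice = rng.integers(0, len(taxa), size=n)
        weights = rng.lognormal(mean=0.0, sigma=config.abundance_sdlog, size=n)
        for i in range(n):
            taxon, order = taxa[choice[i]]
            rows.append(
                {
                    "species_id": f"{guild[:3]}_{i:04d}",
                    "guild": guild,
                    "taxon_key": taxon,
                    "order_key": order,
                    "rel_abundance": weights[i],
                }
            )
    return SpeciesPool(pd.DataFrame(rows))


def draw_site_community(
    config: SyntheticConfig,
    pool: SpeciesPool,
    system: str,
    landscape: str,
    replicate: int,
    rng: np.random.Generator,
    x: float = 0.0,
    y: float = 0.0,
) -> SiteCommunity:
    """Sample one site from the pool under the system's ground-truth multipliers."""
    if system not in config.systems:
        raise ConfigError(f"systems: unknown system {system!r}")
    if landscape not in config.landscapes:
        raise ConfigError(f"n_landscapes: unknown landscape {landscape!r}")
    retention = config.richness_retention[system]
    dmult = config.density_multiplier[system]
    mmult = config.mass_multiplier[system]
    area = config.site_area_m2
    records = []
    for guild in GUILDS:
        sub = pool.table[pool.table["guild"] == guild]
        retained = sub[rng.random(len(sub)) < retention]
        expected = area * config.base_density_per_m2[guild] * dmult
        n = rng.poisson(expected)
        if n == 0 or len(retained) == 0:
            continue
        probs = retained["rel_abundance"].to_numpy()
        probs = probs / probs.sum()
        counts = rng.multinomial(n, probs)
        meanlog, sdlog = config.body_length_lognormal[guild]
        # mass multiplier enters through length: M ~ L^3, so L scales as mmult^(1/3)
        meanlog_sys = meanlog + np.log(mmult) / 3.0
        for sp, k in zip(retained.itertuples(index=False), counts):
            if k == 0:
                continue
            lengths = rng.lognormal(meanlog_sys, sdlog, size=k)
            subplots = rng.integers(1, config.subplots_per_site + 1, size=k)
            for length, sp_plot in zip(lengths, subplots):
                records.append(
                    {
                        "subplot": int(sp_plot),
                        "species_id": sp.species_id,
                        "guild": guild,
                        "taxon_key": sp.taxon_key,
                        "order_key": sp.order_key,
                        "body_length_mm": float(length),
                    }
                )
    individuals = pd.DataFrame(
        records,
        columns=["subplot", "species_id", "guild", "taxon_key", "order_key", "body_length_mm"],
    )
    if config.damaged_fraction > 0 and len(individuals):
        damaged = rng.random(len(individuals)) < config.damaged_fraction
        individuals.loc[damaged, "body_length_mm"] = np.nan
    site_id = f"{landscape}_{system}_r{replicate}"
    individuals.insert(0, "site_id", site_id)
    individuals.insert(1, "landscape", landscape)
    individuals.insert(2, "system", system)
    return SiteCommunity(
        site_id=site_id,
        system=system,
        landscape=landscape,
        replicate=replicate,
        temperature_C=config.temperature_C[(system, landscape)],
        n_subplots=config.subplots_per_site,
        subplot_area_m2=config.subplot_area_m2,
        x=x,
        y=y,
        individuals=individuals,
    )


def generate_study(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[list[SiteCommunity], GroundTruth]:
    """Generate the full replicated study: one site per landscape x system x replicate.

    ``seed`` overrides ``config.seed`` when given.  Identical (config, seed)
    pairs yield byte-identical tables.
    """
    if config is None:
        config = SyntheticConfig()
    config.validate()
    root_seed = config.seed if seed is None else int(seed)
    site_plan = [
        (landscape, system, rep)
        for li, landscape in enumerate(config.landscapes)
        for system in config.systems
        for rep in range(1, config.replicates_per_system_per_landscape + 1)
    ]
    ss = np.random.SeedSequence(root_seed)
    streams = ss.spawn(len(site_plan) + 1)
    pool = build_species_pool(config, np.random.default_rng(streams[0]))

    # grid coordinates: landscapes widely separated, sites on a local grid
    per_landscape = len(config.systems) * config.replicates_per_system_per_landscape
    ncol = int(np.ceil(np.sqrt(per_landscape)))
    communities = []
    for idx, (landscape, system, rep) in enumerate(site_plan):
        li = config.landscapes.index(landscape)
        within = idx - li * per_landscape
        x = li * 10_000.0 + (within % ncol) * 100.0
        y = (within // ncol) * 100.0
        rng = np.random.default_rng(streams[idx + 1])
        communities.append(
            draw_site_community(config, pool, system, landscape, rep, rng, x=x, y=y)
        )
    truth = GroundTruth(
        seed=root_seed,
        expected_site_count={
            s: config.site_area_m2
            * sum(config.base_density_per_m2[g] for g in GUILDS)
            * config.density_multiplier[s]
            for s in config.systems
        },
        density_multiplier=dict(config.density_multiplier),
        richness_retention=dict(config.richness_retention),
        mass_multiplier=dict(config.mass_multiplier),
        mean_log_mass_shift={s: float(np.log(m)) for s, m in config.mass_multiplier.items()},
    )
    return communities, truth


def true_effect(config: SyntheticConfig, system: str, response: str) -> float:
    """Read back the configured ground-truth factor for one system and response."""
    tables = {
        "density": config.density_multiplier,
        "richness_retention": config.richness_retention,
        "body_mass": config.mass_multiplier,
    }
    if response not in tables:
        raise ValueError(
            f"unknown response {response!r}; expected one of {sorted(tables)}"
        )
    if system not in config.systems:
        raise ConfigError(f"systems: unknown system {system!r}")
    return float(tables[response][system])


def study_tables(communities: list[SiteCommunity]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a study into (sites, individuals) DataFrames."""
    sites = pd.DataFrame(
        [
            {
                "site_id": c.site_id,
                "landscape": c.landscape,
                "system": c.system,
                "replicate": c.replicate,
                "temperature_C": c.temperature_C,
                "n_subplots": c.n_subplots,
                "subplot_area_m2": c.subplot_area_m2,
                "x": c.x,
                "y": c.y,
            }
            for c in communities
        ]
    )
    individuals = pd.concat([c.individuals for c in communities], ignore_index=True)
    return sites, individuals


def write_study_csv(communities: list[SiteCommunity], outdir) -> None:
    """Write sites.csv and individuals.csv under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sites, individuals = study_tables(communities)
    sites.to_csv(out / "sites.csv", index=False)
    individuals.to_csv(out / "individuals.csv", index=False)
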