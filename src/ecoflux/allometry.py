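"""Length-to-mass conversion for litter macroinvertebrates.

Body lengths (mm) are converted to individual fresh body mass (mg) with
power-law length-mass regressions, ``M = a * L**b``, kept in an editable
registry keyed by taxon.  Regressions published on a dry-mass basis carry a
dry-to-fresh conversion factor.  When a taxon has no regression of its own,
or a measured length falls outside the regression's published length range,
the registry falls back to the next coarser taxonomic level (family ->
order -> class -> universal default).

Damaged specimens without a measurable length receive the median fresh mass
of measured conspecifics; species represented by fewer than two measured
individuals fall back to the order-level median.

The registry shipped under ``ecoflux/data/allometry_registry.csv`` holds
literature-typical default coefficients.  They are stand-ins meant to be
replaced with the regression table appropriate to a given collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AllometryEntry",
    "load_registry",
    "resolve_chain",
    "estimate_fresh_mass",
    "estimate_masses",
    "impute_missing_mass",
    "community_biomass",
    "MG_PER_M2_TO_KG_PER_HA",
]

# mg m^-2 -> kg ha^-1: 1e-6 kg/mg * 1e4 m^2/ha
MG_PER_M2_TO_KG_PER_HA = 1e-2

# mass_source provenance flags
MEASURED = "measured_regression"
FALLBACK = "fallback_regression"
IMPUTED_SPECIES = "imputed_species_median"
IMPUTED_ORDER = "imputed_order_median"


@dataclass(frozen=True)
class AllometryEntry:
    """One length-mass regression: M[mg] = a * L[mm]**b (dry or fresh basis)."""

    taxon_key: str
    a: float
    b: float
    mass_basis: str  # "dry" or "fresh"
    dry_to_fresh_factor: float | None
    len_min_mm: float
    len_max_mm: float
    fallback_key: str | None
    metabolic_group: str = "default"

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"{self.taxon_key}: coefficient a must be > 0")
        if not (self.len_min_mm < self.len_max_mm):
            raise ValueError(f"{self.taxon_key}: empty valid length range")
        if self.mass_basis not in ("dry", "fresh"):
            raise ValueError(f"{self.taxon_key}: mass_basis must be dry|fresh")
        if self.mass_basis == "dry" and not self.dry_to_fresh_factor:
            raise ValueError(f"{self.taxon_key}: dry basis needs a dry_to_fresh_factor")

    def evaluate(self, length_mm: float) -> float:
        mass = self.a * length_mm**self.b
        if self.mass_basis == "dry":
            mass *= self.dry_to_fresh_factor
        return mass

    def in_range(self, length_mm: float) -> bool:
        return self.len_min_mm <= length_mm <= self.len_max_mm


def load_registry(path=None) -> dict[str, AllometryEntry]:
    """Read a registry CSV into a dict keyed by taxon, validating the fallback chains."""
    if path is None:
        with resources.files("ecoflux.data").joinpath("allometry_registry.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    registry: dict[str, AllometryEntry] = {}
    for row in table.itertuples(index=False):
        factor = None if pd.isna(row.dry_to_fresh_factor) else float(row.dry_to_fresh_factor)
        fallback = None if pd.isna(row.fallback_key) else str(row.fallback_key)
        registry[row.taxon_key] = AllometryEntry(
            taxon_key=row.taxon_key,
            a=float(row.a_mg_per_mm_b),
            b=float(row.b),
            mass_basis=str(row.mass_basis),
            dry_to_fresh_factor=factor,
            len_min_mm=float(row.len_min_mm),
            len_max_mm=float(row.len_max_mm),
            fallback_key=fallback,
            metabolic_group=str(row.metabolic_group),
        )
    for key in registry:
        resolve_chain(key, registry)  # raises on cycles / dangling keys
    return registry


def resolve_chain(taxon_key: str, registry: dict[str, AllometryEntry]) -> list[AllometryEntry]:
    """Fallback chain from ``taxon_key`` to the universal default (fallback None)."""
    chain: list[AllometryEntry] = []
    seen: set[str] = set()
    key: str | None = taxon_key
    while key is not None:
        if key in seen:
            raise ValueError(f"cyclic fallback chain at {key!r}")
        seen.add(key)
        entry = registry.get(key)
        if entry is None:
            raise KeyError(f"taxon {key!r} not in registry and no universal default reached")
        chain.append(entry)
        key = entry.fallback_key
    return chain


def estimate_fresh_mass(
    length_mm: float, taxon_key: str, registry: dict[str, AllometryEntry]
) -> tuple[float, str]:
    """Fresh mass (mg) for one measured individual, with a provenance flag.

    Returns ``(mass, source)`` where source is ``measured_regression`` when the
    taxon's own entry covers the length and ``fallback_regression`` when a
    coarser entry had to be used (unknown taxon or out-of-range length).  The
    last entry of the chain (the universal default) is applied even if the
    length falls outside its nominal range, so every positive length maps to
    a mass.
    """
    if not (length_mm > 0) or math.isnan(length_mm):
        raise ValueError(f"length must be positive, got {length_mm}")
    try:
        chain = resolve_chain(taxon_key, registry)
    except KeyError:
        # unknown taxon: fall back to the universal default if one exists
        roots = [e for e in registry.values() if e.fallback_key is None]
        if not roots:
            raise
        chain = [roots[0]]
        return chain[0].evaluate(length_mm), FALLBACK
    for i, entry in enumerate(chain):
        if entry.in_range(length_mm):
            source = MEASURED if i == 0 else FALLBACK
            return entry.evaluate(length_mm), source
    return chain[-1].evaluate(length_mm), FALLBACK


def estimate_masses(
    individuals: pd.DataFrame,
    registry: dict[str, AllometryEntry] | None = None,
    length_col: str = "body_length_mm",
    taxon_col: str = "taxon_key",
) -> pd.DataFrame:
    """Vectorised mass estimation over an individuals table.

    Adds ``fresh_mass_mg`` and ``mass_source`` columns; rows with a missing
    length get NaN mass and source ``"missing"`` (to be filled by
    :func:`impute_missing_mass`).
    """
    if registry is None:
        registry = load_registry()
    out = individuals.copy()
    mass = np.full(len(out), np.nan)
    source = np.full(len(out), "missing", dtype=object)
    lengths = out[length_col].to_numpy(dtype=float)
    for taxon, idx in out.groupby(taxon_col, sort=False).indices.items():
        chain = resolve_chain(taxon, registry)
        sub = lengths[idx]
        measured = ~np.isnan(sub)
        if np.any(sub[measured] <= 0):
            raise ValueError(f"non-positive body length in taxon {taxon!r}")
        assigned = np.zeros(len(sub), dtype=bool)
        for depth, entry in enumerate(chain):
            hit = measured & ~assigned & (sub >= entry.len_min_mm) & (sub <= entry.len_max_mm)
            last = depth == len(chain) - 1
            if last:  # universal default applies regardless of its range
                hit = measured & ~assigned
            if not hit.any():
                continue
            m = entry.a * sub[hit] ** entry.b
            if entry.mass_basis == "dry":
                m = m * entry.dry_to_fresh_factor
            mass[idx[hit]] = m
            source[idx[hit]] = MEASURED if depth == 0 else FALLBACK
            assigned |= hit
    out["fresh_mass_mg"] = mass
    out["mass_source"] = source
    return out


def impute_missing_mass(
    individuals: pd.DataFrame,
    species_col: str = "species_id",
    order_col: str = "order_key",
) -> pd.DataFrame:
    """Fill missing fresh masses with group medians of estimated masses.

    A damaged individual takes the median fresh mass of measured conspecifics;
    if its species has fewer than two measured individuals, the median of its
    order is used instead.  Measured records are never altered and the row
    count is conserved.  Raises if any missing-mass record has no measured
    conspecifics nor ordinals.
    """
    out = individuals.copy()
    missing = out["fresh_mass_mg"].isna()
    if not missing.any():
        return out
    measured = out[~missing]
    sp_median = measured.groupby(species_col)["fresh_mass_mg"].median()
    sp_count = measured.groupby(species_col)["fresh_mass_mg"].count()
    od_median = measured.groupby(order_col)["fresh_mass_mg"].median()

    orphans = []
    for i in out.index[missing]:
        sp = out.at[i, species_col]
        if sp_count.get(sp, 0) >= 2:
            out.at[i, "fresh_mass_mg"] = sp_median[sp]
            out.at[i, "mass_source"] = IMPUTED_SPECIES
            continue
        od = out.at[i, order_col]
        if od in od_median.index:
            out.at[i, "fresh_mass_mg"] = od_median[od]
            out.at[i, "mass_source"] = IMPUTED_ORDER
        else:
            orphans.append(i)
    if orphans:
        raise ValueError(
            "no measured conspecifics or ordinals to impute from for records: "
            f"{orphans}"
        )
    return out


def community_biomass(individuals: pd.DataFrame, sampled_area_m2: float) -> pd.DataFrame:
    """Per-guild and total standing biomass of one site.

    Sums individual fresh masses and divides by the sampled area
    (n_subplots x subplot_area).  Returns a frame indexed by guild (plus a
    ``total`` row) with columns ``biomass_mg_m2`` and ``biomass_kg_ha``.
    """
    if sampled_area_m2 <= 0:
        raise ValueError("sampled area must be positive")
    if individuals["fresh_mass_mg"].isna().any():
        raise ValueError("missing fresh masses; run impute_missing_mass first")
    per_guild = individuals.groupby("guild")["fresh_mass_mg"].sum() / sampled_area_m2
    per_guild.loc["total"] = per_guild.sum()
    return pd.DataFrame(
        {
            "biomass_mg_m2": per_guild,
            "biomass_kg_ha": per_guild * MG_PER_M2_TO_KG_PER_HA,
        }
    )
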