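"""Individual metabolic rates and community metabolism.

Metabolic rates follow the temperature- and phylogeny-dependent allometry

    ln I = ln(i0) + a * ln(M) - E / (k * T)

with I the resting metabolic rate (J h^-1), M fresh body mass (mg), T the
absolute temperature (K), k Boltzmann's constant (8.617e-5 eV K^-1), and
(ln i0, a, E) regression constants specific to a phylogenetic group.
Community metabolism X is the sum of individual rates over a site (or one
feeding guild within it), normalised by the sampled area — the energetic
demand the food-web energy flux must cover.

The per-group constants shipped in ``ecoflux/data/metabolic_params.csv`` are
editable defaults in the style of published multi-taxon regressions; swap in
the table appropriate to your taxa for real analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "BOLTZMANN_EV_K",
    "MetabolicParams",
    "load_metabolic_params",
    "individual_metabolic_rate",
    "add_metabolic_rates",
    "community_metabolism",
]

BOLTZMANN_EV_K = 8.617e-5


def celsius_to_kelvin(temp_c):
    return np.asarray(temp_c, dtype=float) + 273.15


@dataclass(frozen=True)
class MetabolicParams:
    """Per-group regression constants: group -> (ln_i0 [ln J/h], a, E [eV])."""

    groups: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for g, (_, a, e) in self.groups.items():
            if a <= 0:
                raise ValueError(f"group {g!r}: mass exponent must be > 0")
            if e < 0:
                raise ValueError(f"group {g!r}: activation energy must be >= 0")

    def lookup(self, group: str) -> tuple[float, float, float]:
        try:
            return self.groups[group]
        except KeyError:
            raise KeyError(f"unknown metabolic group {group!r}") from None


def load_metabolic_params(path=None) -> MetabolicParams:
    if path is None:
        with resources.files("ecoflux.data").joinpath("metabolic_params.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    return MetabolicParams(
        {r.group: (float(r.ln_i0), float(r.a), float(r.E)) for r in table.itertuples()}
    )


def individual_metabolic_rate(mass_mg, temperature_k, group: str, params: MetabolicParams):
    """Resting metabolic rate I (J h^-1); strictly increasing in M, and in T when E > 0."""
    mass = np.asarray(mass_mg, dtype=float)
    temp = np.asarray(temperature_k, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("body mass must be positive")
    if np.any(temp <= 0):
        raise ValueError("absolute temperature must be positive")
    ln_i0, a, e_act = params.lookup(group)
    rate = np.exp(ln_i0 + a * np.log(mass) - e_act / (BOLTZMANN_EV_K * temp))
    return float(rate) if rate.ndim == 0 else rate


def add_metabolic_rates(
    individuals: pd.DataFrame,
    sites: pd.DataFrame,
    params: MetabolicParams | None = None,
    group_col: str = "metabolic_group",
) -> pd.DataFrame:
    """Attach a ``metabolic_rate_J_h`` column using each site's soil temperature (degC)."""
    if params is None:
        params = load_metabolic_params()
    site_temp = sites.set_index("site_id")["temperature_C"]
    if site_temp.isna().any():
        raise ValueError("site temperature missing for some sites")
    out = individuals.copy()
    temp_k = celsius_to_kelvin(out["site_id"].map(site_temp).to_numpy())
    if np.any(np.isnan(temp_k)):
        raise ValueError("individuals reference sites with no temperature record")
    rate = np.empty(len(out))
    for group, idx in out.groupby(group_col, sort=False).indices.items():
        rate[idx] = individual_metabolic_rate(
            out["fresh_mass_mg"].to_numpy()[idx], temp_k[idx], group, params
        )
    out["metabolic_rate_J_h"] = rate
    return out


def community_metabolism(
    individuals: pd.DataFrame,
    sampled_area_m2: float,
    guilds=("predator", "omnivore", "detritivore", "herbivore"),
) -> pd.Series:
    """Per-guild community metabolism X (J h^-1 m^-2) for one site, plus a total row."""
    if sampled_area_m2 <= 0:
        raise ValueError("sampled area must be positive")
    sums = individuals.groupby("guild")["metabolic_rate_J_h"].sum()
    x = pd.Series(0.0, index=list(guilds), name="X_J_h_m2")
    x.update(sums / sampled_area_m2)
    x.loc["total"] = x.sum()
    return x
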