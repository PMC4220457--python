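"""Species richness: observed, jackknife-extrapolated and rarefied.

Each site is sampled with m replicate subplots, which gives an incidence
table (species x subplot presence) alongside the pooled abundance vector.
Observed richness is the distinct-species count.  The second-order jackknife
extrapolates total richness from the counts of species found in exactly one
(Q1) and exactly two (Q2) subplots:

    S_jack2 = S_obs + Q1 * (2m - 3) / m - Q2 * (m - 2)^2 / (m * (m - 1))

Rarefied richness is the hypergeometric expectation of the species count in
a random draw of n individuals from the pooled site sample,

    E[S_n] = sum_i 1 - C(N - N_i, n) / C(N, n),

computed in log space.  Sampling coverage is summarised as S_obs / S_jack2
per site together with the Pearson correlation of observed and extrapolated
richness across sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "IncidenceTable",
    "incidence_table",
    "observed_richness",
    "jackknife2",
    "rarefy",
    "site_diversity",
    "coverage_summary",
]


@dataclass(frozen=True)
class IncidenceTable:
    """Subplot incidence summary for one site."""

    s_obs: int
    q1: int  # species present in exactly one subplot
    q2: int  # species present in exactly two subplots
    m: int  # number of subplots
    abundances: tuple  # pooled individuals per species

    def __post_init__(self):
        if self.q1 + self.q2 > self.s_obs:
            raise ValueError("Q1 + Q2 cannot exceed observed richness")


def observed_richness(individuals: pd.DataFrame, species_col: str = "species_id") -> int:
    """Number of distinct species with at least one individual."""
    return int(individuals[species_col].nunique())


def incidence_table(
    individuals: pd.DataFrame,
    m: int,
    species_col: str = "species_id",
    subplot_col: str = "subplot",
) -> IncidenceTable:
    """Build the incidence summary of one site from its individuals table.

    ``m`` is the number of subplots sampled (empty subplots count: they are
    part of the sampling effort even if nothing was found in them).
    """
    if m < 1:
        raise ValueError("need at least one subplot")
    n_subplots_per_species = individuals.groupby(species_col)[subplot_col].nunique()
    abund = individuals.groupby(species_col).size()
    return IncidenceTable(
        s_obs=int(len(n_subplots_per_species)),
        q1=int((n_subplots_per_species == 1).sum()),
        q2=int((n_subplots_per_species == 2).sum()),
        m=int(m),
        abundances=tuple(int(v) for v in abund),
    )


def jackknife2(inc: IncidenceTable) -> float:
    """Second-order jackknife estimate of total species richness.

    Requires m >= 3 replicate subsamples (with m = 3 the estimator reduces to
    S_obs + Q1 - Q2/6).
    """
    if inc.m < 3:
        raise ValueError(f"second-order jackknife needs >= 3 subsamples, got m={inc.m}")
    m = inc.m
    return float(
        inc.s_obs + inc.q1 * (2 * m - 3) / m - inc.q2 * (m - 2) ** 2 / (m * (m - 1))
    )


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy(abundances, n: int) -> float:
    """Expected species count in a random subsample of n individuals.

    Individual-based (hypergeometric) rarefaction from the pooled abundance
    vector; exact at n = N where it returns the observed richness.
    """
    counts = np.asarray([a for a in abundances if a > 0], dtype=float)
    total = counts.sum()
    if n > total:
        raise ValueError(f"rarefaction size n={n} exceeds sample size N={int(total)}")
    if n < 0:
        raise ValueError("n must be nonnegative")
    # P(species i absent from the draw) = C(N - N_i, n) / C(N, n), zero when N - N_i < n
    keep = total - counts >= n
    p_absent = np.zeros_like(counts)
    if keep.any():
        p_absent[keep] = np.exp(_log_comb(total - counts[keep], n) - _log_comb(total, n))
    return float(np.sum(1.0 - p_absent))


def site_diversity(
    individuals: pd.DataFrame,
    sites: pd.DataFrame,
    rarefy_n: int = 40,
) -> pd.DataFrame:
    """Per-site diversity table: S_obs, S_jack2, coverage and rarefied richness.

    Sites with fewer than ``rarefy_n`` individuals get NaN rarefied richness
    (the cut-off is chosen as the smallest site sample in the study design).
    """
    rows = []
    for site in sites.itertuples(index=False):
        sub = individuals[individuals["site_id"] == site.site_id]
        inc = incidence_table(sub, m=int(site.n_subplots))
        s_jack = jackknife2(inc)
        n_ind = int(len(sub))
        rows.append(
            {
                "site_id": site.site_id,
                "system": site.system,
                "landscape": site.landscape,
                "n_individuals": n_ind,
                "S_obs": inc.s_obs,
                "S_jack2": s_jack,
                "coverage": inc.s_obs / s_jack if s_jack > 0 else np.nan,
                f"S_rarefied_{rarefy_n}": (
                    rarefy(inc.abundances, rarefy_n) if n_ind >= rarefy_n else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def coverage_summary(diversity: pd.DataFrame) -> dict:
    """Study-level sampling-coverage summary.

    Returns mean and s.d. of per-site coverage (S_obs / S_jack2, in percent)
    and the Pearson correlation of observed versus extrapolated richness
    across sites; the correlation is flagged undefined when either vector has
    zero variance.
    """
    if len(diversity) < 3:
        raise ValueError("need at least 3 sites for a coverage summary")
    cov = diversity["coverage"].to_numpy(dtype=float) * 100.0
    s_obs = diversity["S_obs"].to_numpy(dtype=float)
    s_jack = diversity["S_jack2"].to_numpy(dtype=float)
    defined = np.std(s_obs) > 0 and np.std(s_jack) > 0
    rho = float(stats.pearsonr(s_obs, s_jack).statistic) if defined else float("nan")
    return {
        "mean_coverage_pct": float(np.mean(cov)),
        "sd_coverage_pct": float(np.std(cov, ddof=1)),
        "pearson_rho": rho,
        "rho_defined": bool(defined),
    }
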