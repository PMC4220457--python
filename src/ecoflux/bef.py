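"""Biodiversity--ecosystem-functioning statistics.

Per-system summaries (means with standard errors), the worked percent
comparisons used to contrast guild biomass and flux between systems, linear
mixed-effects models of energy flux on log10 species richness with a
land-use-system interaction and landscape random intercept (backward AIC
selection with a minimum delta-AIC of 2, otherwise the simpler model wins),
and a Moran's I test for spatial autocorrelation in model residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
import statsmodels.api as sm
import statsmodels.formula.api as smf

sm_families = sm.families

__all__ = [
    "summarize_by_system",
    "percent_change",
    "BefFit",
    "fit_bef_models",
    "MoranResult",
    "knn_weights",
    "morans_i",
]


def summarize_by_system(
    site_table: pd.DataFrame,
    responses: list[str],
    by: tuple = ("system",),
) -> pd.DataFrame:
    """Means and standard errors of per-site responses, grouped by system (and
    optionally guild).  Groups of size one get NaN s.e. (flagged by ``n``)."""
    grouped = site_table.groupby(list(by))
    parts = []
    for resp in responses:
        agg = grouped[resp].agg(["mean", "sem", "count"])
        agg.columns = [f"{resp}_mean", f"{resp}_se", "n"]
        parts.append(agg)
    out = pd.concat([p.drop(columns="n") for p in parts], axis=1)
    out["n"] = parts[0]["n"]
    return out


def percent_change(value: float, reference: float, mode: str = "ratio") -> int:
    """Integer percent comparison of a value against a reference.

    ``ratio`` -> round(100 * value / reference); ``loss`` ->
    round(100 * (1 - value / reference)); half-up rounding in both modes,
    matching how such comparisons are usually quoted.
    """
    if reference == 0:
        raise ZeroDivisionError("reference must be nonzero")
    if mode == "ratio":
        pct = 100.0 * value / reference
    elif mode == "loss":
        pct = 100.0 * (1.0 - value / reference)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return int(math.floor(pct + 0.5))


# ---------------------------------------------------------------------------
# richness -> flux mixed models with AIC backward selection

_CANDIDATES = {
    # name -> (fixed-effects RHS template, complexity rank)
    "interaction": "log10_richness * C({system})",
    "additive": "log10_richness + C({system})",
    "richness_only": "log10_richness",
    "null": "1",
}


@dataclass
class BefFit:
    """Candidate fits, their AIC table and the selected model."""

    aic_table: pd.DataFrame  # index: candidate name; columns: aic, k, converged
    selected: str
    results: dict  # name -> fitted results object
    slopes: pd.Series | None  # per-system slope of response on log10 richness
    mixed: bool  # False when the fit fell back to fixed effects only


def _n_params(result) -> int:
    k = len(result.fe_params) if hasattr(result, "fe_params") else len(result.params)
    k += 1  # residual variance
    if hasattr(result, "cov_re"):
        k += result.cov_re.shape[0]  # random-effect variance(s)
    return k


def _fit_one(formula: str, data: pd.DataFrame, landscape_col: str, mixed: bool,
             family: str = "gaussian"):
    if family == "negative_binomial":
        # no mixed NB backend available: landscape enters as a fixed effect
        rhs = formula.split("~", 1)[1].strip()
        if mixed:
            formula = f"{formula} + C({landscape_col})" if rhs != "1" else (
                f"{formula.split('~')[0]}~ C({landscape_col})"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return smf.glm(
                formula, data=data, family=sm_families.NegativeBinomial()
            ).fit()
    if mixed:
        model = smf.mixedlm(formula, data=data, groups=data[landscape_col])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=False)
        return result
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return smf.ols(formula, data=data).fit()


def fit_bef_models(
    site_table: pd.DataFrame,
    response: str = "total_flux_kg_ha_yr",
    richness_col: str = "S_obs",
    system_col: str = "system",
    landscape_col: str = "landscape",
    min_delta_aic: float = 2.0,
    family: str = "gaussian",
) -> BefFit:
    """Fit the candidate richness->flux models and select by backward AIC.

    Candidates: log10(richness) x system interaction, additive, richness only
    and intercept only, each with a landscape random intercept (maximum
    likelihood so AICs are comparable).  The lowest-AIC model is selected
    only when it beats the runner-up by at least ``min_delta_aic``; otherwise
    the simplest model within that margin of the best is chosen.  With fewer
    than two landscapes (or a singular mixed fit) the models fall back to
    fixed effects only, with a warning.

    ``family``: ``gaussian`` (identity), ``log10_gaussian`` (response is
    log10-transformed first, for right-skewed responses such as density,
    biomass or community metabolism) or ``negative_binomial`` (overdispersed
    count responses such as species richness; fitted as a GLM with landscape
    as a fixed effect since no mixed NB backend exists here).
    """
    if family not in ("gaussian", "log10_gaussian", "negative_binomial"):
        raise ValueError(f"unknown family {family!r}")
    if site_table[system_col].nunique() < 2:
        raise ValueError("need at least two transformation systems")
    data = site_table.copy()
    if (data[richness_col] <= 0).any():
        raise ValueError("richness must be positive for the log10 transform")
    data["log10_richness"] = np.log10(data[richness_col].astype(float))
    if family == "log10_gaussian":
        if (data[response] <= 0).any():
            raise ValueError("response must be positive for the log10 transform")
        data[response] = np.log10(data[response].astype(float))

    mixed = data[landscape_col].nunique() >= 2
    if not mixed:
        warnings.warn("single landscape: falling back to fixed-intercept models")

    results, rows = {}, []
    for name, rhs in _CANDIDATES.items():
        formula = f"{response} ~ {rhs.format(system=system_col)}"
        try:
            res = _fit_one(formula, data, landscape_col, mixed, family)
            converged = bool(getattr(res, "converged", True)) and np.isfinite(res.llf)
        except (np.linalg.LinAlgError, ValueError):
            res, converged = None, False
        if not converged and mixed and family != "negative_binomial":
            # singular mixed fit: retry without the random intercept
            warnings.warn(f"singular mixed fit for {name}; using fixed intercept")
            res = _fit_one(formula, data, landscape_col, mixed=False, family=family)
            converged = np.isfinite(res.llf)
        k = _n_params(res)
        aic = 2 * k - 2 * float(res.llf)
        results[name] = res
        rows.append({"model": name, "aic": aic, "k": k, "converged": converged})

    aic_table = pd.DataFrame(rows).set_index("model").sort_values("aic")
    best = aic_table.index[0]
    if len(aic_table) > 1 and aic_table["aic"].iloc[1] - aic_table["aic"].iloc[0] >= min_delta_aic:
        selected = best
    else:
        within = aic_table[aic_table["aic"] - aic_table["aic"].iloc[0] < min_delta_aic]
        selected = within.sort_values(["k", "aic"]).index[0]

    slopes = _per_system_slopes(results[selected], selected, data, system_col)
    return BefFit(aic_table=aic_table, selected=selected, results=results,
                  slopes=slopes, mixed=mixed)


def _per_system_slopes(result, name: str, data: pd.DataFrame, system_col: str):
    if name == "null":
        return None
    params = result.fe_params if hasattr(result, "fe_params") else result.params
    base = params.get("log10_richness", 0.0)
    systems = sorted(data[system_col].unique())
    slopes = {}
    for s in systems:
        inter = params.get(f"log10_richness:C({system_col})[T.{s}]", 0.0)
        slopes[s] = float(base + inter)
    return pd.Series(slopes, name="slope_flux_on_log10_richness")


# ---------------------------------------------------------------------------
# Moran's I spatial autocorrelation of residuals


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    variance: float
    zscore: float
    pvalue: float


def knn_weights(coords: np.ndarray, k: int = 4, row_standardize: bool = True) -> np.ndarray:
    """Binary k-nearest-neighbour spatial weights (row-standardised by default)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k >= n:
        raise ValueError("k must be smaller than the number of sites")
    tree = cKDTree(coords)
    # query k+1 because each point is its own nearest neighbour
    _, idx = tree.query(coords, k=k + 1)
    w = np.zeros((n, n))
    for i in range(n):
        for j in idx[i][1:]:
            w[i, j] = 1.0
    if row_standardize:
        w = w / w.sum(axis=1, keepdims=True)
    return w


def morans_i(
    residuals,
    coords=None,
    weights: np.ndarray | None = None,
    k: int = 4,
) -> MoranResult:
    """Moran's I of model residuals with a normal-approximation test.

    I = (n / S0) * (z' W z) / (z' z) with z the centred residuals; the
    expectation under no autocorrelation is -1/(n-1), and the standard
    deviate uses the normality-assumption variance.  Supply either site
    ``coords`` (kNN weights are built) or an explicit ``weights`` matrix.
    """
    z = np.asarray(residuals, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("need at least 3 sites")
    if weights is None:
        if coords is None:
            raise ValueError("provide coords or an explicit weights matrix")
        weights = knn_weights(np.asarray(coords), k=k)
    w = np.asarray(weights, dtype=float)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("all residuals identical: Moran's I undefined")
    s0 = w.sum()
    i_stat = (n / s0) * float(z @ w @ z) / denom
    expected = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - expected**2
    zscore = (i_stat - expected) / math.sqrt(var)
    pvalue = 2 * stats.norm.sf(abs(zscore))
    return MoranResult(I=float(i_stat), expected=expected, variance=float(var),
                       zscore=float(zscore), pvalue=float(pvalue))
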