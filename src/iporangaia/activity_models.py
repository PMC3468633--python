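"""Feeding-activity and movement analyses.

Feeding: monthly counts of individuals seen feeding, out of all individuals
captured, per category (females, caring males, non-caring males).  The four
candidate models are binomial random-intercept GLMMs — feeding odds affected
by nothing, by sex, by parental state, or by the full three-level category —
with sampling month as a random effect absorbing seasonal variation.  The
month intercept is integrated out by adaptive Gauss-Hermite quadrature and
models are ranked by AICc.

Movement: per-individual absolute transect displacements between successive
captures (individuals recaptured often enough to be informative), compared
between groups by an analysis of deviance under a count-family likelihood
(negative binomial by default, since displacements include exact zeros and
are overdispersed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from statsmodels.discrete.discrete_model import NegativeBinomial, Poisson

from iporangaia.encounter_io import EncounterHistory, RobustDesignLayout
from iporangaia.model_selection import ModelRanking, aicc, rank_models

CATEGORY_LEVELS = ("female", "caring male", "non-caring male")
FEEDING_STRUCTURES = ("null", "sex", "parental_state", "category")


def validate_feeding_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (month, category, n_feeding, n_captured) table invariants."""
    required = {"month", "category", "n_feeding", "n_captured"}
    if not required.issubset(table.columns):
        raise ValueError(f"feeding table needs columns {sorted(required)}")
    bad = set(table["category"]) - set(CATEGORY_LEVELS)
    if bad:
        raise ValueError(f"unknown categories {sorted(bad)}")
    if ((table["n_feeding"] < 0) | (table["n_feeding"] > table["n_captured"])).any():
        raise ValueError("need 0 <= n_feeding <= n_captured in every row")
    months = sorted(set(table["month"]))
    for month in months:
        present = set(table.loc[table["month"] == month, "category"])
        if present != set(CATEGORY_LEVELS):
            raise ValueError(f"month {month!r} missing categories "
                             f"{sorted(set(CATEGORY_LEVELS) - present)}")
    return table.sort_values(["month", "category"]).reset_index(drop=True)


def _fixed_design(categories: Sequence[str], structure: str) -> np.ndarray:
    """Per-row fixed-effect design for one feeding-odds structure."""
    cats = list(categories)
    n = len(cats)
    if structure == "null":
        return np.ones((n, 1))
    if structure == "sex":
        male = np.array([c != "female" for c in cats], dtype=float)
        return np.column_stack([np.ones(n), male])
    if structure == "parental_state":
        caring = np.array([c == "caring male" for c in cats], dtype=float)
        return np.column_stack([np.ones(n), caring])
    if structure == "category":
        caring = np.array([c == "caring male" for c in cats], dtype=float)
        noncare = np.array([c == "non-caring male" for c in cats], dtype=float)
        return np.column_stack([np.ones(n), caring, noncare])
    raise ValueError(f"unknown feeding structure {structure!r}")


@dataclass
class GlmmFit:
    """One fitted binomial random-intercept model of feeding activity."""

    structure: str
    fixed: dict[str, float]
    sigma_u: float
    log_likelihood: float
    k: int
    n: int
    aicc_value: float
    converged: bool
    quad_points: int

    @property
    def K(self) -> int:  # noqa: N802
        return self.k

    @property
    def label(self) -> str:
        return self.structure


def _month_loglik(
    f: np.ndarray, c: np.ndarray, eta: np.ndarray, sigma: float,
    nodes: np.ndarray, weights: np.ndarray, log_binom: np.ndarray,
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood of one month's counts.

    The quadrature grid is recentred at the mode of the integrand and
    rescaled by its curvature, so a modest number of nodes integrates the
    month random intercept accurately even for extreme counts.
    """
    if sigma < 1e-10:
        pi = np.clip(special.expit(eta), 1e-12, 1 - 1e-12)
        return float(np.sum(log_binom + special.xlogy(f, pi)
                            + special.xlogy(c - f, 1.0 - pi)))
    # Newton search for the mode of log integrand h(u)
    u = 0.0
    for _ in range(50):
        pi = special.expit(eta + u)
        g = float(np.sum(f - c * pi)) - u / sigma**2
        h = -float(np.sum(c * pi * (1.0 - pi))) - 1.0 / sigma**2
        step = g / h
        u -= step
        if abs(step) < 1e-12:
            break
    pi = special.expit(eta + u)
    curv = float(np.sum(c * pi * (1.0 - pi))) + 1.0 / sigma**2
    shat = 1.0 / math.sqrt(curv)
    uq = u + math.sqrt(2.0) * shat * nodes
    pq = np.clip(special.expit(eta[:, None] + uq[None, :]), 1e-12, 1 - 1e-12)
    log_binpmf = (
        log_binom[:, None]
        + special.xlogy(f[:, None], pq)
        + special.xlogy((c - f)[:, None], 1.0 - pq)
    ).sum(axis=0)
    log_gauss = -0.5 * math.log(2.0 * math.pi) - math.log(sigma) - uq**2 / (2.0 * sigma**2)
    log_g = log_binpmf + log_gauss + nodes**2 + math.log(math.sqrt(2.0) * shat)
    m = log_g.max()
    return float(m + np.log(np.dot(weights, np.exp(log_g - m))))


def _month_blocks(table: pd.DataFrame, structure: str) -> list[tuple]:
    """Pre-extract (f, c, design, log-binom) per month for fast refits."""
    blocks = []
    for _, sub in table.groupby("month", sort=True):
        x = _fixed_design(sub["category"], structure)
        f = sub["n_feeding"].to_numpy(dtype=float)
        c = sub["n_captured"].to_numpy(dtype=float)
        log_binom = (
            special.gammaln(c + 1) - special.gammaln(f + 1)
            - special.gammaln(c - f + 1)
        )
        blocks.append((f, c, x, log_binom))
    return blocks


def feeding_marginal_loglik(
    table: pd.DataFrame, structure: str, fixed: np.ndarray, sigma: float,
    quad_points: int = 15,
) -> float:
    """Marginal log-likelihood at given fixed effects and random-effect sd."""
    table = validate_feeding_table(table)
    nodes, weights = special.roots_hermite(quad_points)
    return sum(
        _month_loglik(f, c, x @ fixed, sigma, nodes, weights, lb)
        for f, c, x, lb in _month_blocks(table, structure)
    )


def fit_feeding_glmm(
    table: pd.DataFrame,
    structure: str = "category",
    quad_points: int = 15,
    sigma_u: Optional[float] = None,
) -> GlmmFit:
    """Fit one feeding-odds structure by maximum marginal likelihood.

    ``sigma_u`` fixes the month random-effect sd (``0`` collapses the model
    to an ordinary binomial regression); left ``None`` it is estimated, and
    a boundary estimate near 0 is reported as is.
    """
    table = validate_feeding_table(table)
    if quad_points < 5:
        raise ValueError("quad_points must be at least 5")
    n_fixed = _fixed_design(["female"], structure).shape[1]
    free_sigma = sigma_u is None
    blocks = _month_blocks(table, structure)
    nodes, weights = special.roots_hermite(quad_points)

    def nll(params):
        fixed = params[:n_fixed]
        sig = math.exp(params[n_fixed]) if free_sigma else sigma_u
        ll = sum(
            _month_loglik(f, c, x @ fixed, sig, nodes, weights, lb)
            for f, c, x, lb in blocks
        )
        return -ll if np.isfinite(ll) else 1e12

    pooled = table["n_feeding"].sum() / max(table["n_captured"].sum(), 1)
    eta0 = special.logit(min(max(pooled, 1e-4), 1 - 1e-4))
    x0 = np.concatenate([
        [eta0], np.zeros(n_fixed - 1), [math.log(0.5)] if free_sigma else []
    ])
    from scipy import optimize

    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 5000, "xatol": 1e-8,
                                     "fatol": 1e-10})
    polish = optimize.minimize(nll, res.x, method="BFGS",
                               options={"maxiter": 500})
    best = polish if polish.fun < res.fun else res
    fixed = best.x[:n_fixed]
    sig = math.exp(best.x[n_fixed]) if free_sigma else float(sigma_u)
    k = n_fixed + (1 if free_sigma else 0)
    names = {
        "null": ["intercept"],
        "sex": ["intercept", "male"],
        "parental_state": ["intercept", "caring"],
        "category": ["intercept", "caring male", "non-caring male"],
    }[structure]
    n = len(table)
    ll = -float(best.fun)
    return GlmmFit(
        structure=structure,
        fixed=dict(zip(names, fixed)),
        sigma_u=sig,
        log_likelihood=ll,
        k=k,
        n=n,
        aicc_value=aicc(ll, k, n),
        converged=bool(res.success or polish.success),
        quad_points=quad_points,
    )


def rank_feeding_structures(
    table: pd.DataFrame, quad_points: int = 15
) -> ModelRanking:
    """Fit all four feeding-odds structures and rank them by AICc."""
    fits = [fit_feeding_glmm(table, s, quad_points) for s in FEEDING_STRUCTURES]
    n = len(validate_feeding_table(table))
    return rank_models(fits, ess=n, chat=1.0, criterion="AICc")


# ---------------------------------------------------------------------------
# Movement
# ---------------------------------------------------------------------------

def movement_distances(
    histories: Sequence[EncounterHistory],
    layout: RobustDesignLayout,
    positions: Optional[pd.DataFrame] = None,
    min_recaptures: int = 5,
    min_months: int = 2,
) -> dict:
    """Per-individual displacement series along the transect.

    Only individuals recaptured at least ``min_recaptures`` times (captures
    beyond the first) and captured in at least ``min_months`` different
    primary occasions qualify.  Each successive-capture pair contributes the
    absolute position difference, labelled with the individual's state at
    the earlier capture; individuals are summarised by their median
    displacement.

    Returns ``{"pairs": ..., "individuals": ..., "n_excluded": int}``.
    """
    pos_lookup: dict[str, dict[int, float]] = {}
    if positions is not None:
        for row in positions.itertuples(index=False):
            pos_lookup.setdefault(str(row.individual_id), {})[
                int(row.secondary_index)
            ] = float(row.position_m)

    sec_to_primary = np.repeat(np.arange(layout.n_primary), layout.secondaries)
    pair_rows, ind_rows, n_excluded = [], [], 0
    for h in histories:
        pmap = pos_lookup.get(h.individual_id, h.positions)
        caps = [j for j, c in enumerate(h.codes) if c != "0" and j in pmap]
        n_caps_all = sum(1 for c in h.codes if c != "0")
        months = {int(sec_to_primary[j]) for j, c in enumerate(h.codes) if c != "0"}
        if n_caps_all - 1 < min_recaptures or len(months) < min_months:
            n_excluded += 1
            continue
        dists = []
        for a, b in zip(caps, caps[1:]):
            d = abs(pmap[b] - pmap[a])
            dists.append(d)
            pair_rows.append({
                "individual_id": h.individual_id,
                "group": "female" if h.group == "female" else
                         ("caring male" if h.codes[a] == "C" else "non-caring male"),
                "from_secondary": a,
                "to_secondary": b,
                "distance_m": d,
            })
        states = {c for c in h.codes if c != "0"}
        group = ("female" if h.group == "female"
                 else "caring male" if states == {"C"}
                 else "non-caring male" if states == {"N"} else "both states")
        ind_rows.append({
            "individual_id": h.individual_id,
            "group": group,
            "n_captures": n_caps_all,
            "n_distances": len(dists),
            "median_distance_m": float(np.median(dists)) if dists else np.nan,
        })
    return {
        "pairs": pd.DataFrame(
            pair_rows, columns=["individual_id", "group", "from_secondary",
                                "to_secondary", "distance_m"]),
        "individuals": pd.DataFrame(
            ind_rows, columns=["individual_id", "group", "n_captures",
                               "n_distances", "median_distance_m"]),
        "n_excluded": n_excluded,
    }


def movement_deviance_test(
    distances: Sequence[float] | pd.Series,
    grouping: Sequence[str] | pd.Series,
    family: str = "nbinom",
) -> dict:
    """Analysis of deviance for group differences in displacement.

    Fits a null (intercept-only) and a grouping model of the integer-metre
    displacements under a count likelihood — negative binomial by default
    (zeros occur, and displacements are overdispersed), or Poisson — and
    returns twice the log-likelihood difference with a chi-square p-value
    on ``levels - 1`` degrees of freedom.
    """
    y = np.asarray(distances, dtype=float)
    groups = pd.Series(list(grouping), dtype="object")
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(y) == 0:
        raise ValueError("all displacements identical; deviance test undefined")
    x_null = np.ones((len(y), 1))
    dummies = pd.get_dummies(groups, drop_first=True, dtype=float).to_numpy()
    x_full = np.column_stack([x_null, dummies])

    def fit(exog):
        if family == "nbinom":
            model = NegativeBinomial(y, exog)
        elif family == "poisson":
            model = Poisson(y, exog)
        else:
            raise ValueError("family must be 'nbinom' or 'poisson'")
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=500, method="bfgs")
        return float(res.llf)

    ll_null, ll_full = fit(x_null), fit(x_full)
    delta_dev = 2.0 * (ll_full - ll_null)
    df = len(levels) - 1
    return {
        "delta_deviance": delta_dev,
        "df": df,
        "p_value": float(stats.chi2.sf(max(delta_dev, 0.0), df)),
        "family": family,
        "loglik_null": ll_null,
        "loglik_group": ll_full,
    }
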