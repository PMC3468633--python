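"""Information-criterion ranking, overdispersion, and step-down selection.

Candidate capture-mark-recapture models are ranked by QAICc — the
small-sample Akaike criterion with the log-likelihood divided by an
overdispersion factor c-hat.  c-hat comes either from a goodness-of-fit
deviance/df ratio of the global model or from a parametric bootstrap.
Rather than fitting the full 4 x 6 x 15 x 15 = 5,400-model grid, the
step-down procedure fixes a general structure and optimises one parameter
class at a time: general time surrogate, then transitions (psi), then
recapture (p), then survival (phi).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from iporangaia.cmr_likelihood import (
    CmrData,
    FittedCmrModel,
    OptimisationError,
    ParameterStructure,
    PHI_P_STRUCTURES,
    PSI_STRUCTURES,
    TIME_SURROGATES,
    build_design,
    fit_ml,
)
from iporangaia.encounter_io import EncounterHistory, RobustDesignLayout


def aicc(loglik: float, k: int, n: float) -> float:
    """Small-sample bias-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc needs n > K + 1 (n={n}, K={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def qaicc(loglik: float, k: int, n: float, chat: float = 1.0) -> float:
    """AICc with the log-likelihood divided by the overdispersion factor."""
    if chat <= 0:
        raise ValueError("chat must be positive")
    return aicc(loglik / chat, k, n)


def akaike_weights(criteria: Sequence[float]) -> np.ndarray:
    """Akaike weights ``exp(-delta_i/2) / sum_j exp(-delta_j/2)``."""
    crit = np.asarray(criteria, dtype=float)
    if crit.size == 0:
        raise ValueError("need at least one model")
    delta = crit - crit.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def chat_from_ratio(chi2: float, df: float) -> tuple[float, str]:
    """Overdispersion factor as deviance over degrees of freedom.

    Returns ``(chat, adequacy)`` where adequacy classifies the global-model
    fit: adequate when the ratio falls between 1 and 3 (closer to 1 is
    better), over-dispersed beyond 3, under-dispersed below 1.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    chat = chi2 / df
    if chat < 1.0:
        adequacy = "under-dispersed"
    elif chat <= 3.0:
        adequacy = "adequate"
    else:
        adequacy = "inadequate fit"
    return chat, adequacy


def gof_pvalue(chi2: float, df: float) -> float:
    """Upper-tail chi-square probability of a goodness-of-fit statistic."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(stats.chi2.sf(chi2, df))


def effective_sample_size(
    data: CmrData | Sequence[EncounterHistory],
    layout: Optional[RobustDesignLayout] = None,
    policy: str = "releases",
) -> float:
    """Effective sample size for (Q)AICc in the capture-recapture context.

    ``"releases"`` (default): frequency-weighted count of primaries at which
    each animal was captured and released alive.  ``"captures"``: total
    secondary detections.  ``"individuals"``: frequency-weighted history
    count.
    """
    if not isinstance(data, CmrData):
        if layout is None:
            raise ValueError("layout required when passing raw histories")
        data = CmrData.from_histories(data, layout)
    if policy == "releases":
        return data.n_releases()
    if policy == "captures":
        return data.n_captures()
    if policy == "individuals":
        return float(sum(c.freq.sum() for c in data.chains))
    raise ValueError(f"unknown effective-sample-size policy {policy!r}")


@dataclass
class ModelRanking:
    """Fits ordered by an information criterion.

    ``table`` columns mirror a publication ranking: structure label,
    criterion, K, delta, weight.  Ties break by smaller K, then label order.
    """

    table: pd.DataFrame
    fits: tuple
    chat: float
    ess: float
    criterion: str = "QAICc"

    @property
    def best(self):
        return self.fits[int(self.table.index[0])]

    def to_csv(self, path) -> None:
        out = self.table[["structure", self.criterion, "K",
                          f"delta_{self.criterion}", "weight"]]
        out.to_csv(path, index=False)


def rank_models(
    fits: Sequence, ess: float, chat: float = 1.0, criterion: str = "QAICc",
    labels: Optional[Sequence[str]] = None,
) -> ModelRanking:
    """Rank fitted models (anything with ``log_likelihood`` and ``K``)."""
    if labels is None:
        labels = [getattr(f, "label", None) or f.structure.label for f in fits]
    crit = np.array([qaicc(f.log_likelihood, f.K, ess, chat) for f in fits])
    weights = akaike_weights(crit)
    ks = np.array([f.K for f in fits])
    order = sorted(
        range(len(fits)), key=lambda i: (round(crit[i], 10), ks[i], labels[i])
    )
    table = pd.DataFrame(
        {
            "structure": [labels[i] for i in order],
            criterion: crit[order],
            "K": ks[order],
            f"delta_{criterion}": crit[order] - crit.min(),
            "weight": weights[order],
        },
        index=order,
    )
    return ModelRanking(table, tuple(fits), chat, ess, criterion)


def enumerate_grid() -> Iterator[ParameterStructure]:
    """All candidate structures: 4 time surrogates x 6 psi x 15 p x 15 phi."""
    for time, psi, p, phi in itertools.product(
        TIME_SURROGATES, PSI_STRUCTURES, PHI_P_STRUCTURES, PHI_P_STRUCTURES
    ):
        yield ParameterStructure(phi=phi, p=p, psi=psi, time=time)


def grid_size() -> int:
    return (
        len(TIME_SURROGATES)
        * len(PSI_STRUCTURES)
        * len(PHI_P_STRUCTURES) ** 2
    )


def _warm_beta(
    structure: ParameterStructure,
    layout: RobustDesignLayout,
    incumbent: FittedCmrModel,
    bound: float = 15.0,
) -> np.ndarray:
    """Project an incumbent fit's natural-scale cells onto a new structure's
    design (least squares on the logit scale) to warm-start the optimiser."""
    est = incumbent.estimates()
    design = build_design(structure, layout)
    parts = []
    for x, cells in (
        (design.x_phi, est.phi), (design.x_p, est.p), (design.x_psi, est.psi)
    ):
        eta = special.logit(np.clip(cells.ravel(), 1e-9, 1 - 1e-9))
        sol, *_ = np.linalg.lstsq(x, eta, rcond=None)
        parts.append(sol)
    return np.clip(np.concatenate(parts), -bound, bound)


def _fit_sweep(
    data: CmrData,
    layout: RobustDesignLayout,
    candidates: Sequence[ParameterStructure],
    incumbent: Optional[FittedCmrModel],
    ess: float,
    chat: float,
    fit_options: dict,
) -> ModelRanking:
    fits = []
    for structure in candidates:
        beta0 = _warm_beta(structure, layout, incumbent) if incumbent else None
        fits.append(fit_ml(data, structure, layout, beta0=beta0, **fit_options))
        if incumbent is None:
            incumbent = fits[0]
    return rank_models(fits, ess, chat)


def step_down(
    histories: Sequence[EncounterHistory] | CmrData,
    layout: RobustDesignLayout,
    chat: float = 1.0,
    ess: Optional[float] = None,
    *,
    start: str = "general",
    surrogate: Optional[str] = None,
    psi_candidates: Optional[Sequence[str]] = None,
    p_candidates: Optional[Sequence[str]] = None,
    phi_candidates: Optional[Sequence[str]] = None,
    n_starts: int = 2,
    seed: Optional[int] = 0,
    gtol: float = 1e-6,
) -> dict:
    """Step-down model selection over the candidate-structure catalogues.

    With ``start="general"`` the procedure (i) compares the four time
    surrogates under the general model (phi and p additive in time and
    category, psi additive in time and state), then with the chosen
    surrogate (ii) sweeps the six psi structures holding phi/p general,
    (iii) sweeps the fifteen p structures holding phi general and psi at its
    stage winner, and (iv) sweeps the fifteen phi structures.  With
    ``start="constant"`` the non-focal classes start constant instead, as a
    robustness check on the step-down path.

    Returns ``{"stages": {name: ModelRanking}, "final": FittedCmrModel,
    "surrogate": str}``.
    """
    data = (
        histories
        if isinstance(histories, CmrData)
        else CmrData.from_histories(histories, layout)
    )
    if ess is None:
        ess = effective_sample_size(data)
    fit_options = {"n_starts": n_starts, "seed": seed, "gtol": gtol}
    psi_candidates = tuple(psi_candidates or PSI_STRUCTURES)
    p_candidates = tuple(p_candidates or PHI_P_STRUCTURES)
    phi_candidates = tuple(phi_candidates or PHI_P_STRUCTURES)
    stages: dict[str, ModelRanking] = {}

    if start == "general":
        general = [
            ParameterStructure("time+category", "time+category", "time+state", s)
            for s in TIME_SURROGATES
        ]
        stages["general"] = _fit_sweep(data, layout, general, None, ess, chat,
                                       fit_options)
        best = stages["general"].best
        chosen = best.structure.time
        fix_phi, fix_p = "time+category", "time+category"
    elif start == "constant":
        chosen = surrogate or "time"
        best = None
        fix_phi, fix_p = "constant", "constant"
    else:
        raise ValueError("start must be 'general' or 'constant'")
    if surrogate is not None:
        chosen = surrogate

    psi_structs = [
        ParameterStructure(fix_phi, fix_p, psi, chosen) for psi in psi_candidates
    ]
    stages["psi"] = _fit_sweep(data, layout, psi_structs, best, ess, chat,
                               fit_options)
    best_psi = stages["psi"].best.structure.psi

    p_structs = [
        ParameterStructure(fix_phi, p, best_psi, chosen) for p in p_candidates
    ]
    stages["p"] = _fit_sweep(data, layout, p_structs, stages["psi"].best, ess,
                             chat, fit_options)
    best_p = stages["p"].best.structure.p

    phi_structs = [
        ParameterStructure(phi, best_p, best_psi, chosen) for phi in phi_candidates
    ]
    stages["phi"] = _fit_sweep(data, layout, phi_structs, stages["p"].best, ess,
                               chat, fit_options)

    return {
        "stages": stages,
        "final": stages["phi"].best,
        "surrogate": chosen,
        "ess": ess,
        "chat": chat,
    }


# ---------------------------------------------------------------------------
# Parametric-bootstrap overdispersion
#
# The deviance is computed on the multi-state m-array: every detection of an
# animal at primary t in state s is a release, and the outcome is the primary
# and state of its next detection (or "never seen again").  Aggregating to
# these sufficient summaries keeps the number of multinomial cells fixed, so
# the deviance against the saturated m-array behaves like a chi-square with
# roughly constant degrees of freedom and the observed/simulated ratio is an
# honest variance-inflation estimate.
# ---------------------------------------------------------------------------

def _marray_counts(data: CmrData) -> dict:
    """Observed next-encounter counts per release cohort.

    Keys are ``(chain_idx, t, s)``; values map outcome ``(t', s')`` or
    ``"never"`` to frequency-weighted counts.
    """
    counts: dict = {}
    for ci, chain in enumerate(data.chains):
        t_all = len(chain.k)
        for i in range(chain.n):
            seen_at = np.nonzero(chain.seen[i])[0]
            for idx, t in enumerate(seen_at):
                if t == t_all - 1:
                    continue  # terminal release carries no information
                s = int(chain.state[i, t])
                nxt = seen_at[idx + 1] if idx + 1 < len(seen_at) else None
                outcome = (
                    "never" if nxt is None
                    else (int(nxt), int(chain.state[i, nxt]))
                )
                cohort = counts.setdefault((ci, int(t), s), {})
                cohort[outcome] = cohort.get(outcome, 0.0) + float(chain.freq[i])
    return counts


def _marray_probs(
    chain, est, layout: RobustDesignLayout, t: int, s: int
) -> dict:
    """Model-implied next-encounter probabilities for one release cohort."""
    rows = list(chain.cat_index)
    phi = est.phi[rows]
    p = est.p[rows]
    n_states = chain.n_states
    v = np.zeros(n_states)
    v[s] = 1.0
    probs: dict = {}
    for t2 in range(t + 1, layout.n_primary):
        # survive-then-transition from t2-1 to t2
        if n_states == 2:
            q_nc, q_cn = est.psi[0, t2 - 1], est.psi[1, t2 - 1]
            live = np.array([[1.0 - q_nc, q_nc], [q_cn, 1.0 - q_cn]])
        else:
            live = np.array([[1.0]])
        v = (v * phi[:, t2 - 1]) @ live
        pstar = 1.0 - (1.0 - p[:, t2]) ** layout.secondaries[t2]
        for s2 in range(n_states):
            probs[(t2, s2)] = float(v[s2] * pstar[s2])
        v = v * (1.0 - pstar)
    probs["never"] = max(1.0 - sum(probs.values()), 1e-12)
    return probs


def marray_deviance(data: CmrData, fitted: FittedCmrModel) -> float:
    """Deviance of a fit against the saturated next-encounter m-array."""
    est = fitted.estimates()
    counts = _marray_counts(data)
    dev = 0.0
    for (ci, t, s), cohort in counts.items():
        chain = data.chains[ci]
        probs = _marray_probs(chain, est, fitted.layout, t, s)
        total = sum(cohort.values())
        for outcome, n_obs in cohort.items():
            expected = total * max(probs.get(outcome, 1e-12), 1e-12)
            dev += 2.0 * n_obs * np.log(n_obs / expected)
    return dev


def _simulate_from_fit(
    fitted: FittedCmrModel, data: CmrData, rng: np.random.Generator
) -> list[EncounterHistory]:
    """Simulate histories from a fitted model, conditional on the observed
    releases (same first-capture primary, state, and within-primary timing)."""
    layout = fitted.layout
    est = fitted.estimates()
    slices = layout.primary_slices()
    out: list[EncounterHistory] = []
    for chain in data.chains:
        rows = list(chain.cat_index)
        phi = est.phi[rows]
        p = est.p[rows]
        two_state = chain.n_states == 2
        for i in range(chain.n):
            for _ in range(int(chain.freq[i])):
                codes = ["0"] * layout.n_secondary
                fp = int(chain.first[i])
                state = int(chain.state[i, fp])
                # release primary: first capture fixed, Bernoulli afterwards
                j0 = layout.secondaries[fp] - int(chain.rel_n[i]) - 1
                sl = slices[fp]
                labels = chain.states
                codes[sl.start + j0] = labels[state]
                for j in range(j0 + 1, layout.secondaries[fp]):
                    if rng.random() < p[state, fp]:
                        codes[sl.start + j] = labels[state]
                alive = True
                for t in range(fp + 1, layout.n_primary):
                    if alive:
                        if rng.random() >= phi[state, t - 1]:
                            alive = False
                        elif two_state:
                            q = est.psi[state, t - 1]
                            if rng.random() < q:
                                state = 1 - state
                    if alive:
                        sl = slices[t]
                        for j in range(layout.secondaries[t]):
                            if rng.random() < p[state, t]:
                                codes[sl.start + j] = labels[state]
                out.append(
                    EncounterHistory(f"sim{len(out)}", tuple(codes), frequency=1)
                )
    return out


def bootstrap_chat(
    fitted: FittedCmrModel,
    data: CmrData | Sequence[EncounterHistory],
    layout: Optional[RobustDesignLayout] = None,
    n_sim: int = 100,
    seed: int = 0,
    max_failure_rate: float = 0.2,
) -> float:
    """Parametric-bootstrap overdispersion factor.

    Simulates ``n_sim`` datasets from the fitted model (conditional on the
    observed releases), refits the same structure to each, and returns the
    observed m-array deviance over the mean simulated m-array deviance.
    Seed-reproducible.
    """
    layout = layout or fitted.layout
    if not isinstance(data, CmrData):
        data = CmrData.from_histories(data, layout)
    rng = np.random.default_rng(seed)
    obs_dev = marray_deviance(data, fitted)
    devs, failures = [], 0
    for _ in range(n_sim):
        sim = _simulate_from_fit(fitted, data, rng)
        try:
            sim_data = CmrData.from_histories(sim, layout)
            refit = fit_ml(
                sim_data, fitted.structure, layout,
                n_starts=1, seed=None, beta0=fitted.beta,
            )
            devs.append(marray_deviance(sim_data, refit))
        except OptimisationError:
            failures += 1
    if n_sim and failures / n_sim > max_failure_rate:
        raise OptimisationError(
            f"{failures}/{n_sim} bootstrap refits failed; chat unreliable"
        )
    return obs_dev / float(np.mean(devs))
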