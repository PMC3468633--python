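"""Huggins closed robust-design multi-state capture-mark-recapture likelihood.

The model follows every marked animal through hidden states — females
``F``/dead, males ``N`` (non-caring), ``C`` (caring), dead — across primary
occasions.  Between primaries an animal survives with apparent-survival
probability ``phi`` (indexed by the state at the start of the interval) and
then, if male, switches state with transition probability ``psi``
(survive-then-transition order).  Within a primary the population is closed
and each secondary occasion is an independent Bernoulli(``p``) detection,
with first capture and recapture sharing the same ``p``.  Transitions
between sexes are structurally zero, so the two sexes run as separate
hidden-state chains.

The likelihood conditions on first capture: the release primary contributes
Bernoulli terms for the secondary occasions after the first capture, later
primaries contribute Binomial(``k``, ``p``) detection-count emissions when
the animal is seen (hidden state pinned to the observed state) and a
sum over live states of ``(1-p)^k`` — plus the dead state's certain
non-detection — when it is not.  Abundance is not a likelihood parameter;
it is derived afterwards by Horvitz-Thompson.

All parameters are driven by coefficient vectors through a logit link and
design matrices; the gradient of the log-likelihood is computed analytically
by backward propagation through the forward recursion, which is what makes
the 5,400-model selection grid tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from iporangaia.encounter_io import (
    EncounterHistory,
    RobustDesignLayout,
    ValidationError,
    collapse_to_primary,
)

#: Global category order used for survival/detection cells.
CATEGORIES = ("F", "N", "C")
#: Transition directions (male states only).
DIRECTIONS = ("NtoC", "CtoN")
#: Time surrogates for time-dependent structures.
TIME_SURROGATES = ("time", "season", "temperature", "rainfall")

_LOG_FLOOR = 1e-300


class CatalogueError(ValueError):
    """Unknown parameter-structure label."""


class OptimisationError(RuntimeError):
    """All optimisation starts failed."""


# ---------------------------------------------------------------------------
# Structure catalogues
#
# Each entry is either ("blocks", ((members, time_varying), ...)) where the
# members partition the units (categories F/N/C, or the two transition
# directions) and each block gets its own constant or time course, or
# ("additive", (group, group, ...)) for a shared time course plus additive
# group offsets (first group is the baseline).
# ---------------------------------------------------------------------------

_F, _N, _C = 0, 1, 2

PHI_P_STRUCTURES: dict[str, tuple] = {
    "constant": ("blocks", (((_F, _N, _C), False),)),
    "time": ("blocks", (((_F, _N, _C), True),)),
    "category": ("blocks", (((_F,), False), ((_N,), False), ((_C,), False))),
    "time+category": ("additive", ((_F,), (_N,), (_C,))),
    "time(F)&const(C)&const(N)": (
        "blocks", (((_F,), True), ((_C,), False), ((_N,), False))),
    "time(N)&const(C)&const(F)": (
        "blocks", (((_N,), True), ((_C,), False), ((_F,), False))),
    "time(C)&const(N)&const(F)": (
        "blocks", (((_C,), True), ((_N,), False), ((_F,), False))),
    "sex": ("blocks", (((_F,), False), ((_N, _C), False))),
    "time+sex": ("additive", ((_F,), (_N, _C))),
    "time(F)&const(M)": ("blocks", (((_F,), True), ((_N, _C), False))),
    "time(M)&const(F)": ("blocks", (((_N, _C), True), ((_F,), False))),
    "state": ("blocks", (((_F, _N), False), ((_C,), False))),
    "time+state": ("additive", ((_F, _N), (_C,))),
    "time(NC)&const(C)": ("blocks", (((_F, _N), True), ((_C,), False))),
    "time(C)&const(NC)": ("blocks", (((_C,), True), ((_F, _N), False))),
}

PSI_STRUCTURES: dict[str, tuple] = {
    "constant": ("blocks", (((0, 1), False),)),
    "time": ("blocks", (((0, 1), True),)),
    "state": ("blocks", (((0,), False), ((1,), False))),
    "time+state": ("additive", ((0,), (1,))),
    "time(NtoC)&const(CtoN)": ("blocks", (((0,), True), ((1,), False))),
    "time(CtoN)&const(NtoC)": ("blocks", (((1,), True), ((0,), False))),
}


@dataclass(frozen=True)
class ParameterStructure:
    """A candidate design: one structure label per parameter class plus the
    time surrogate in force for every time-varying term."""

    phi: str = "constant"
    p: str = "constant"
    psi: str = "constant"
    time: str = "time"

    def __post_init__(self) -> None:
        if self.phi not in PHI_P_STRUCTURES:
            raise CatalogueError(f"unknown survival structure {self.phi!r}")
        if self.p not in PHI_P_STRUCTURES:
            raise CatalogueError(f"unknown recapture structure {self.p!r}")
        if self.psi not in PSI_STRUCTURES:
            raise CatalogueError(f"unknown transition structure {self.psi!r}")
        if self.time not in TIME_SURROGATES:
            raise CatalogueError(f"unknown time surrogate {self.time!r}")

    @property
    def label(self) -> str:
        return f"phi[{self.phi}] p[{self.p}] psi[{self.psi}] ({self.time})"


def _time_covariate(
    layout: RobustDesignLayout, surrogate: str, for_intervals: bool
) -> Optional[np.ndarray]:
    """Covariate values per time index; ``None`` means a full time factor."""
    if surrogate == "time":
        return None
    if surrogate == "season":
        seasons = layout.interval_season if for_intervals else layout.season
        return np.array([1.0 if s == "wet-warm" else 0.0 for s in seasons])
    if surrogate == "temperature":
        z = layout.interval_temperature if for_intervals else layout.occasion_temperature
    else:
        z = layout.interval_rainfall if for_intervals else layout.occasion_rainfall
    z = np.asarray(z, dtype=float)
    scale = z.std() if z.std() > 0 else 1.0
    return (z - z.mean()) / scale


def _structure_matrix(
    spec: tuple, n_units: int, n_time: int, z: Optional[np.ndarray]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix over cells (unit-major, time-minor) for one catalogue entry."""
    kind, parts = spec
    cols: list[np.ndarray] = []
    names: list[str] = []
    cell_unit = np.repeat(np.arange(n_units), n_time)
    cell_time = np.tile(np.arange(n_time), n_units)

    if kind == "additive":
        if z is None:
            for t in range(n_time):
                cols.append((cell_time == t).astype(float))
                names.append(f"t{t}")
        else:
            cols.append(np.ones(n_units * n_time))
            names.append("intercept")
            cols.append(z[cell_time])
            names.append("z")
        for g, members in enumerate(parts):
            if g == 0:
                continue  # baseline group
            ind = np.isin(cell_unit, members).astype(float)
            cols.append(ind)
            names.append(f"group{g}")
    else:
        for b, (members, time_varying) in enumerate(parts):
            ind = np.isin(cell_unit, members).astype(float)
            if not time_varying:
                cols.append(ind)
                names.append(f"block{b}")
            elif z is None:
                for t in range(n_time):
                    cols.append(ind * (cell_time == t))
                    names.append(f"block{b}:t{t}")
            else:
                cols.append(ind)
                names.append(f"block{b}:intercept")
                cols.append(ind * z[cell_time])
                names.append(f"block{b}:z")
    return np.column_stack(cols), names


@dataclass(frozen=True)
class CmrDesign:
    """Design matrices mapping one coefficient vector to all logit-scale cells."""

    x_phi: np.ndarray  # (3 * (T-1), k_phi), category-major
    x_p: np.ndarray    # (3 * T, k_p)
    x_psi: np.ndarray  # (2 * (T-1), k_psi), direction-major
    names: tuple[str, ...]

    @property
    def k(self) -> int:
        return self.x_phi.shape[1] + self.x_p.shape[1] + self.x_psi.shape[1]

    def split(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        k1, k2 = self.x_phi.shape[1], self.x_p.shape[1]
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.k,):
            raise ValueError(f"beta must have length {self.k}")
        return beta[:k1], beta[k1:k1 + k2], beta[k1 + k2:]

    def natural(self, beta: np.ndarray, n_primary: int):
        """Natural-scale (phi, p, psi) cell arrays from a coefficient vector.

        Probabilities are kept a hair inside (0, 1) so the score stays finite
        when a coefficient sits on its optimisation bound.
        """
        b_phi, b_p, b_psi = self.split(beta)
        eps = 1e-12
        phi = np.clip(special.expit(self.x_phi @ b_phi), eps, 1 - eps)
        p = np.clip(special.expit(self.x_p @ b_p), eps, 1 - eps)
        psi = np.clip(special.expit(self.x_psi @ b_psi), eps, 1 - eps)
        return (phi.reshape(3, n_primary - 1), p.reshape(3, n_primary),
                psi.reshape(2, n_primary - 1))


def build_design(
    structure: ParameterStructure, layout: RobustDesignLayout
) -> CmrDesign:
    """Build logit-link design matrices for a candidate structure.

    Cells are ordered category-major (``F``, ``N``, ``C``) then time;
    transition cells direction-major (``NtoC``, ``CtoN``).  Additive
    structures share time columns across categories with category offsets
    (no interaction columns).
    """
    t = layout.n_primary
    z_int = _time_covariate(layout, structure.time, for_intervals=True)
    z_occ = _time_covariate(layout, structure.time, for_intervals=False)
    x_phi, n_phi = _structure_matrix(PHI_P_STRUCTURES[structure.phi], 3, t - 1, z_int)
    x_p, n_p = _structure_matrix(PHI_P_STRUCTURES[structure.p], 3, t, z_occ)
    x_psi, n_psi = _structure_matrix(PSI_STRUCTURES[structure.psi], 2, t - 1, z_int)
    names = tuple(
        [f"phi:{s}" for s in n_phi] + [f"p:{s}" for s in n_p] + [f"psi:{s}" for s in n_psi]
    )
    return CmrDesign(x_phi, x_p, x_psi, names)


# ---------------------------------------------------------------------------
# Data preparation: encounter histories -> per-sex hidden-state chains
# ---------------------------------------------------------------------------

_STATE_INDEX = {"F": 0, "N": 0, "C": 1}  # live-state index within each sex's chain


@dataclass
class _Chain:
    """Vectorised per-sex capture data aligned to the primary occasions."""

    states: tuple[str, ...]         # live-state labels, chain order
    cat_index: tuple[int, ...]      # map live state -> global category row
    first: np.ndarray               # (n,) release primary
    seen: np.ndarray                # (n, T) bool
    state: np.ndarray               # (n, T) live-state index, -1 when unseen
    count: np.ndarray               # (n, T) secondary detections
    comb: np.ndarray                # (n, T) C(k_t, count)
    rel_n: np.ndarray               # (n,) secondaries after first capture at release
    rel_x: np.ndarray               # (n,) detections among those
    freq: np.ndarray                # (n,)
    k: np.ndarray                   # (T,) secondaries per primary

    @property
    def n(self) -> int:
        return len(self.first)

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass
class CmrData:
    """Validated, vectorised capture data for both sexes."""

    layout: RobustDesignLayout
    female: Optional[_Chain]
    male: Optional[_Chain]
    histories: tuple[EncounterHistory, ...] = ()

    @classmethod
    def from_histories(
        cls, histories: Sequence[EncounterHistory], layout: RobustDesignLayout
    ) -> "CmrData":
        groups: dict[str, list[EncounterHistory]] = {"female": [], "male": []}
        for h in histories:
            groups[h.group].append(h)
        chains = {}
        for name, hs in groups.items():
            if not hs:
                chains[name] = None
                continue
            states = ("F",) if name == "female" else ("N", "C")
            cat_index = (0,) if name == "female" else (1, 2)
            t, slices, k = layout.n_primary, layout.primary_slices(), layout.secondaries
            n = len(hs)
            first = np.zeros(n, dtype=int)
            seen = np.zeros((n, t), dtype=bool)
            state = np.full((n, t), -1, dtype=int)
            count = np.zeros((n, t), dtype=int)
            rel_n = np.zeros(n, dtype=int)
            rel_x = np.zeros(n, dtype=int)
            freq = np.zeros(n, dtype=float)
            for i, h in enumerate(hs):
                summaries = collapse_to_primary(h, layout)
                fp = next(j for j, s in enumerate(summaries) if s.captures > 0)
                first[i] = fp
                freq[i] = h.frequency
                for j, s in enumerate(summaries):
                    if s.captures:
                        seen[i, j] = True
                        state[i, j] = _STATE_INDEX[s.observed_state]
                        count[i, j] = s.captures
                within = h.codes[slices[fp]]
                j0 = next(a for a, c in enumerate(within) if c != "0")
                rel_n[i] = k[fp] - j0 - 1
                rel_x[i] = count[i, fp] - 1
            karr = np.asarray(k, dtype=int)
            comb = special.comb(karr[None, :], count)
            chains[name] = _Chain(
                states, cat_index, first, seen, state, count, comb,
                rel_n, rel_x, freq, karr,
            )
        return cls(layout, chains["female"], chains["male"], tuple(histories))

    @property
    def chains(self) -> list[_Chain]:
        return [c for c in (self.female, self.male) if c is not None]

    def n_releases(self) -> float:
        """Total releases: frequency-weighted count of detection primaries."""
        return float(
            sum((c.seen.sum(axis=1) * c.freq).sum() for c in self.chains)
        )

    def n_captures(self) -> float:
        """Frequency-weighted total secondary detections."""
        return float(sum((c.count.sum(axis=1) * c.freq).sum() for c in self.chains))


# ---------------------------------------------------------------------------
# Forward algorithm and its adjoint
# ---------------------------------------------------------------------------

def primary_detection_prob(p: float | np.ndarray, k: int | np.ndarray):
    """Probability of at least one detection in a closed session of ``k``
    Bernoulli(``p``) secondary occasions: ``1 - (1-p)^k``."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** np.asarray(k)


def _chain_transition(
    chain: _Chain, phi_rows: np.ndarray, psi: Optional[np.ndarray]
) -> np.ndarray:
    """(T-1, S+1, S+1) transition matrices, survive-then-transition, with an
    absorbing dead state as the last row/column."""
    s = chain.n_states
    t1 = phi_rows.shape[1]
    m = np.zeros((t1, s + 1, s + 1))
    for t in range(t1):
        if s == 1:
            live = np.array([[1.0]])
        else:
            q_nc, q_cn = psi[0, t], psi[1, t]
            live = np.array([[1.0 - q_nc, q_nc], [q_cn, 1.0 - q_cn]])
        m[t, :s, :s] = phi_rows[:, t][:, None] * live
        m[t, :s, s] = 1.0 - phi_rows[:, t]
        m[t, s, s] = 1.0
    return m


def _emissions(chain: _Chain, p_rows: np.ndarray, t: int) -> np.ndarray:
    """(n, S+1) emission vector at primary ``t`` (see module docstring)."""
    n, s = chain.n, chain.n_states
    pv = p_rows[:, t]
    k = chain.k[t]
    e = np.empty((n, s + 1))
    e[:, :s] = (1.0 - pv) ** k
    e[:, s] = 1.0
    obs = chain.seen[:, t] & (chain.first != t)
    if obs.any():
        i = np.nonzero(obs)[0]
        si = chain.state[i, t]
        ci = chain.count[i, t]
        val = chain.comb[i, t] * pv[si] ** ci * (1.0 - pv[si]) ** (k - ci)
        e[i] = 0.0
        e[i, si] = val
    rel = chain.first == t
    if rel.any():
        i = np.nonzero(rel)[0]
        si = chain.state[i, t]
        m, x = chain.rel_n[i], chain.rel_x[i]
        val = pv[si] ** x * (1.0 - pv[si]) ** (m - x)
        e[i] = 0.0
        e[i, si] = val
    return e


def _chain_loglik(
    chain: _Chain,
    phi_rows: np.ndarray,
    psi: Optional[np.ndarray],
    p_rows: np.ndarray,
    want_grad: bool,
):
    """Log-likelihood of one sex's chain, optionally with analytic gradients
    with respect to the natural-scale cells (``phi_rows``, ``psi`` directions,
    ``p_rows``).

    The gradient comes from the adjoint of the forward recursion: with
    pre-emission state distributions ``a_t``, emissions ``e_t`` and backward
    vectors ``beta_t``, the likelihood satisfies ``L = sum(a_t * e_t * beta_t)``
    for every ``t``, giving ``dL/dM_t = alpha_t^T (e_{t+1} * beta_{t+1})`` and
    ``dL/de_t = a_t * beta_t``.
    """
    n, s, t_all = chain.n, chain.n_states, len(chain.k)
    m = _chain_transition(chain, phi_rows, psi)
    a_pre = np.zeros((t_all, n, s + 1))
    e_all = np.zeros((t_all, n, s + 1))
    alpha = np.zeros((t_all, n, s + 1))
    prev = np.zeros((n, s + 1))
    for t in range(t_all):
        a = prev @ m[t - 1] if t > 0 else np.zeros((n, s + 1))
        rel = chain.first == t
        if rel.any():
            i = np.nonzero(rel)[0]
            a[i] = 0.0
            a[i, chain.state[i, t]] = 1.0
        e = _emissions(chain, p_rows, t)
        a_pre[t], e_all[t] = a, e
        alpha[t] = a * e
        prev = alpha[t]
    lik = np.maximum(prev.sum(axis=1), _LOG_FLOOR)
    ll = float(np.dot(chain.freq, np.log(lik)))
    if not want_grad:
        return ll, None, None, None

    w = chain.freq / lik
    d_phi = np.zeros_like(phi_rows)
    d_psi = np.zeros((2, t_all - 1)) if s == 2 else None
    d_p = np.zeros_like(p_rows)
    beta = np.ones((n, s + 1))
    for t in range(t_all - 1, -1, -1):
        g_e = w[:, None] * a_pre[t] * beta  # dlogL/de_t
        pv = p_rows[:, t]
        k = chain.k[t]
        rel = chain.first == t
        obs = chain.seen[:, t] & ~rel
        unseen = ~chain.seen[:, t] & (chain.first <= t)
        if unseen.any():
            contrib = g_e[unseen, :s].sum(axis=0)
            d_p[:, t] += contrib * (-k) * (1.0 - pv) ** (k - 1)
        if obs.any():
            i = np.nonzero(obs)[0]
            si = chain.state[i, t]
            ci = chain.count[i, t]
            dv = g_e[i, si] * e_all[t][i, si] * (
                ci / pv[si] - (k - ci) / (1.0 - pv[si])
            )
            np.add.at(d_p[:, t], si, dv)
        if rel.any():
            i = np.nonzero(rel)[0]
            si = chain.state[i, t]
            mm, x = chain.rel_n[i], chain.rel_x[i]
            dv = g_e[i, si] * e_all[t][i, si] * (
                x / pv[si] - (mm - x) / (1.0 - pv[si])
            )
            np.add.at(d_p[:, t], si, dv)
        if t > 0:
            b = e_all[t] * beta
            d_m = (alpha[t - 1] * w[:, None]).T @ b
            if s == 1:
                d_phi[0, t - 1] += d_m[0, 0] - d_m[0, 1]
            else:
                q_nc, q_cn = psi[0, t - 1], psi[1, t - 1]
                live = np.array([[1.0 - q_nc, q_nc], [q_cn, 1.0 - q_cn]])
                for si in range(2):
                    d_phi[si, t - 1] += (
                        d_m[si, 0] * live[si, 0] + d_m[si, 1] * live[si, 1]
                        - d_m[si, 2]
                    )
                d_psi[0, t - 1] += phi_rows[0, t - 1] * (d_m[0, 1] - d_m[0, 0])
                d_psi[1, t - 1] += phi_rows[1, t - 1] * (d_m[1, 0] - d_m[1, 1])
            beta = b @ m[t - 1].T
    return ll, d_phi, d_psi, d_p


def _total_loglik_grad(
    data: CmrData, design: CmrDesign, beta: np.ndarray, want_grad: bool = True
):
    t_all = data.layout.n_primary
    phi, p, psi = design.natural(beta, t_all)
    ll = 0.0
    d_phi = np.zeros_like(phi)
    d_p = np.zeros_like(p)
    d_psi = np.zeros_like(psi)
    for chain in data.chains:
        rows = list(chain.cat_index)
        psi_arg = psi if chain.n_states == 2 else None
        res = _chain_loglik(chain, phi[rows], psi_arg, p[rows], want_grad)
        ll += res[0]
        if want_grad:
            d_phi[rows] += res[1]
            d_p[rows] += res[3]
            if res[2] is not None:
                d_psi += res[2]
    if not want_grad:
        return ll, None
    # chain rule through the logit link to the coefficient vector
    g_phi = design.x_phi.T @ (d_phi * phi * (1.0 - phi)).ravel()
    g_p = design.x_p.T @ (d_p * p * (1.0 - p)).ravel()
    g_psi = design.x_psi.T @ (d_psi * psi * (1.0 - psi)).ravel()
    return ll, np.concatenate([g_phi, g_p, g_psi])


# ---------------------------------------------------------------------------
# Public likelihood API
# ---------------------------------------------------------------------------

@dataclass
class CmrParameters:
    """Natural-scale parameter cells.

    ``phi`` has one row per category (``F``, ``N``, ``C``) and one column per
    between-primary interval; ``p`` one column per primary; ``psi`` rows are
    the ``N->C`` and ``C->N`` directions.
    """

    phi: np.ndarray
    p: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.p = np.atleast_2d(np.asarray(self.p, dtype=float))
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        for name in ("phi", "p", "psi"):
            arr = getattr(self, name)
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.phi.shape[0] != 3 or self.p.shape[0] != 3 or self.psi.shape[0] != 2:
            raise ValidationError(
                "phi and p need 3 category rows (F, N, C); psi needs 2 direction rows"
            )

    @classmethod
    def from_beta(
        cls, structure: ParameterStructure, layout: RobustDesignLayout,
        beta: np.ndarray,
    ) -> "CmrParameters":
        design = build_design(structure, layout)
        return cls(*design.natural(np.asarray(beta, dtype=float), layout.n_primary))

    @classmethod
    def constant(
        cls, layout: RobustDesignLayout, *,
        phi_f: float, phi_n: float, phi_c: float,
        p_f: float, p_n: float, p_c: float,
        psi_nc: float, psi_cn: float,
    ) -> "CmrParameters":
        t = layout.n_primary
        phi = np.repeat([[phi_f], [phi_n], [phi_c]], t - 1, axis=1)
        p = np.repeat([[p_f], [p_n], [p_c]], t, axis=1)
        psi = np.repeat([[psi_nc], [psi_cn]], t - 1, axis=1)
        return cls(phi, p, psi)


def forward_loglik(
    history: EncounterHistory, params: CmrParameters, layout: RobustDesignLayout
) -> float:
    """Log-likelihood contribution of a single history (frequency ignored)."""
    h = EncounterHistory(history.individual_id, history.codes, frequency=1)
    data = CmrData.from_histories([h], layout)
    chain = data.chains[0]
    rows = list(chain.cat_index)
    psi_arg = params.psi if chain.n_states == 2 else None
    ll, *_ = _chain_loglik(chain, params.phi[rows], psi_arg, params.p[rows], False)
    return ll


def total_loglik(
    histories: Sequence[EncounterHistory] | CmrData,
    beta: np.ndarray,
    structure: ParameterStructure,
    layout: RobustDesignLayout,
) -> float:
    """Frequency-weighted total log-likelihood at a coefficient vector."""
    data = (
        histories
        if isinstance(histories, CmrData)
        else CmrData.from_histories(histories, layout)
    )
    design = build_design(structure, layout)
    ll, _ = _total_loglik_grad(data, design, np.asarray(beta, dtype=float), False)
    if not np.isfinite(ll) or ll <= np.log(_LOG_FLOOR) * 0.5:
        raise OptimisationError("non-finite likelihood; check parameter values")
    return ll


@dataclass
class FittedCmrModel:
    """A maximum-likelihood fit of one candidate structure."""

    structure: ParameterStructure
    beta: np.ndarray
    log_likelihood: float
    k: int
    converged: bool
    n_starts: int
    seed: Optional[int]
    layout: RobustDesignLayout
    cov_beta: Optional[np.ndarray] = None
    start_logliks: tuple[float, ...] = ()

    @property
    def K(self) -> int:  # noqa: N802 -- information-criterion convention
        return self.k

    def estimates(self) -> CmrParameters:
        return CmrParameters.from_beta(self.structure, self.layout, self.beta)

    def design(self) -> CmrDesign:
        return build_design(self.structure, self.layout)

    def wald_intervals(self, level: float = 0.95) -> pd.DataFrame:
        """Logit-scale Wald intervals mapped to the probability scale.

        Requires the finite-difference covariance (``se=True`` at fit time).
        """
        if self.cov_beta is None:
            raise ValueError("fit was run without standard errors")
        design = self.design()
        zcrit = float(special.ndtri(0.5 + level / 2.0))
        t = self.layout.n_primary
        rows = []
        blocks = [
            ("phi", design.x_phi, CATEGORIES, t - 1, 0),
            ("p", design.x_p, CATEGORIES, t, design.x_phi.shape[1]),
            ("psi", design.x_psi, DIRECTIONS, t - 1,
             design.x_phi.shape[1] + design.x_p.shape[1]),
        ]
        for name, x, units, n_time, offset in blocks:
            kcols = x.shape[1]
            b = self.beta[offset:offset + kcols]
            cov = self.cov_beta[offset:offset + kcols, offset:offset + kcols]
            eta = x @ b
            var = np.einsum("ij,jk,ik->i", x, cov, x)
            se_eta = np.sqrt(np.maximum(var, 0.0))
            est = special.expit(eta)
            lo = special.expit(eta - zcrit * se_eta)
            hi = special.expit(eta + zcrit * se_eta)
            for cell in range(len(eta)):
                rows.append({
                    "parameter": name,
                    "unit": units[cell // n_time],
                    "time": cell % n_time,
                    "estimate": est[cell],
                    "se_logit": se_eta[cell],
                    "lower": lo[cell],
                    "upper": hi[cell],
                })
        return pd.DataFrame(rows)

    def report(self) -> dict:
        """JSON-serialisable fit report."""
        est = self.estimates()
        return {
            "structure": {
                "phi": self.structure.phi, "p": self.structure.p,
                "psi": self.structure.psi, "time": self.structure.time,
            },
            "beta": [float(b) for b in self.beta],
            "log_likelihood": self.log_likelihood,
            "K": self.k,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "estimates": {
                "phi": est.phi.tolist(),
                "p": est.p.tolist(),
                "psi": est.psi.tolist(),
            },
        }


def _fd_hessian(fun_grad, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian from an analytic gradient."""
    k = len(x)
    h = np.zeros((k, k))
    for j in range(k):
        d = np.zeros(k)
        d[j] = step
        gp = fun_grad(x + d)
        gm = fun_grad(x - d)
        h[:, j] = (gp - gm) / (2.0 * step)
    return 0.5 * (h + h.T)


def fit_ml(
    histories: Sequence[EncounterHistory] | CmrData,
    structure: ParameterStructure,
    layout: RobustDesignLayout,
    *,
    n_starts: int = 5,
    seed: Optional[int] = 0,
    se: bool = False,
    beta0: Optional[np.ndarray] = None,
    gtol: float = 1e-6,
    bound: float = 15.0,
    maxiter: int = 1000,
) -> FittedCmrModel:
    """Maximise the total log-likelihood with multi-start bounded quasi-Newton.

    Starts from zero on the logit scale (all probabilities 0.5), optionally a
    warm start ``beta0``, plus seeded jittered restarts; returns the best
    local optimum found.  Coefficients are bounded at ``+-bound`` to keep the
    likelihood away from degenerate 0/1 probabilities.
    """
    data = (
        histories
        if isinstance(histories, CmrData)
        else CmrData.from_histories(histories, layout)
    )
    design = build_design(structure, layout)
    k = design.k

    def objective(beta):
        ll, grad = _total_loglik_grad(data, design, beta)
        return -ll, -grad

    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)]
    if beta0 is not None:
        b0 = np.clip(np.asarray(beta0, dtype=float), -bound, bound)
        if b0.shape == (k,):
            starts.insert(0, b0)
    while len(starts) < n_starts:
        starts.append(rng.normal(scale=0.5, size=k))

    best = None
    logliks = []
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B",
            bounds=[(-bound, bound)] * k,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        if not np.isfinite(res.fun):
            continue
        logliks.append(-float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise OptimisationError(
            f"all {len(starts)} starts failed for structure {structure.label}"
        )

    cov = None
    if se:
        grad_only = lambda b: _total_loglik_grad(data, design, b)[1] * -1.0
        hess = _fd_hessian(grad_only, best.x)
        try:
            cov = np.linalg.pinv(hess)
        except np.linalg.LinAlgError:
            cov = None
    return FittedCmrModel(
        structure=structure,
        beta=np.asarray(best.x, dtype=float),
        log_likelihood=-float(best.fun),
        k=k,
        converged=bool(best.success),
        n_starts=len(starts),
        seed=seed,
        layout=layout,
        cov_beta=cov,
        start_logliks=tuple(logliks),
    )


def derived_abundance(
    fitted: FittedCmrModel,
    histories: Sequence[EncounterHistory] | CmrData,
    layout: RobustDesignLayout,
) -> pd.DataFrame:
    """Horvitz-Thompson abundance per primary occasion and category.

    ``N_hat = captured / (1 - (1 - p_hat)^k)`` — abundance is not a parameter
    of the conditional (Huggins) likelihood, so it is derived afterwards.
    """
    data = (
        histories
        if isinstance(histories, CmrData)
        else CmrData.from_histories(histories, layout)
    )
    p_hat = fitted.estimates().p
    rows = []
    for chain in data.chains:
        for local, cat in enumerate(chain.cat_index):
            for t in range(layout.n_primary):
                captured = float(
                    chain.freq[(chain.seen[:, t]) & (chain.state[:, t] == local)].sum()
                )
                if captured == 0:
                    continue
                pstar = float(primary_detection_prob(p_hat[cat, t], chain.k[t]))
                if pstar < 1e-8:
                    raise ValueError(
                        f"detection probability ~0 at primary {t}; abundance undefined"
                    )
                rows.append({
                    "primary": t,
                    "month": layout.month_labels[t],
                    "category": CATEGORIES[cat],
                    "n_captured": captured,
                    "p_hat": p_hat[cat, t],
                    "p_star": pstar,
                    "N_hat": captured / pstar,
                })
    return pd.DataFrame(rows)
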