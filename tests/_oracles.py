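"""Independent reference computations used to check the fast implementations.

Everything here is deliberately brute force — exhaustive hidden-path
enumeration for the multi-state likelihood, dense trapezoid integration for
the random-intercept marginal likelihood — and shares no code with the
package's forward/quadrature machinery.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import comb, expit, gammaln, xlogy

from iporangaia.encounter_io import (
    EncounterHistory,
    RobustDesignLayout,
    collapse_to_primary,
)

_CAT = {"F": 0, "N": 1, "C": 2}


def tiny_layout(n_primary: int = 3, k: int = 2) -> RobustDesignLayout:
    labels = tuple(f"2003-{m:02d}" for m in range(1, n_primary + 1))
    return RobustDesignLayout(
        labels, (k,) * n_primary,
        (15.0,) * n_primary, (100.0,) * n_primary,
        (15.0,) * (n_primary - 1), (100.0,) * (n_primary - 1),
    )


def enumerate_loglik(h: EncounterHistory, params, layout) -> float:
    """Likelihood of one history by summing over every hidden state path."""
    t_all = layout.n_primary
    slices = layout.primary_slices()
    live = ["F"] if h.group == "female" else ["N", "C"]
    summaries = collapse_to_primary(h, layout)
    first = next(i for i, s in enumerate(summaries) if s.captures > 0)
    s0 = summaries[first].observed_state
    within = h.codes[slices[first]]
    j0 = next(a for a, c in enumerate(within) if c != "0")
    m = layout.secondaries[first] - j0 - 1
    x = summaries[first].captures - 1

    def emission(state, t):
        s = summaries[t]
        k = layout.secondaries[t]
        if s.captures > 0:
            if state != s.observed_state:
                return 0.0
            p = params.p[_CAT[state], t]
            return comb(k, s.captures) * p ** s.captures * (1 - p) ** (k - s.captures)
        if state == "dead":
            return 1.0
        return (1 - params.p[_CAT[state], t]) ** k

    def transition(a, b, t):
        if a == "dead":
            return 1.0 if b == "dead" else 0.0
        phi = params.phi[_CAT[a], t]
        if b == "dead":
            return 1.0 - phi
        if h.group == "female":
            return phi if b == "F" else 0.0
        q = params.psi[0, t] if a == "N" else params.psi[1, t]
        return phi * (1.0 - q) if b == a else phi * q

    p0 = params.p[_CAT[s0], first]
    total = 0.0
    for path in itertools.product(live + ["dead"], repeat=t_all - first - 1):
        pr = p0 ** x * (1 - p0) ** (m - x)
        prev = s0
        for i, st in enumerate(path):
            pr *= transition(prev, st, first + i)
            pr *= emission(st, first + i + 1)
            prev = st
        total += pr
    return math.log(total)


def random_history(rng, layout, sex=None, p_detect=0.5) -> EncounterHistory:
    """A random closure-respecting history with at least one capture."""
    while True:
        s = sex or rng.choice(["female", "male"])
        codes = []
        for t in range(layout.n_primary):
            state = "F" if s == "female" else rng.choice(["N", "C"])
            codes.extend(
                state if rng.random() < p_detect else "0"
                for _ in range(layout.secondaries[t])
            )
        if any(c != "0" for c in codes):
            return EncounterHistory("rnd", tuple(codes))


def enumerate_outcome_probs(release_state, first, params, layout):
    """Probabilities of every distinguishable post-release outcome.

    Outcomes are count-level: within the release primary the number of
    detections after the first capture (weighted by the number of secondary
    patterns realising it); at every later primary either no detection or a
    (live state, detection count >= 1) pair.  Used for sum-to-one checks.
    """
    t_all = layout.n_primary
    live = ["F"] if release_state == "F" else ["N", "C"]
    m = layout.secondaries[first] - 1  # first capture at the first secondary

    later = []
    for t in range(first + 1, t_all):
        opts = [None]
        for st in live:
            for c in range(1, layout.secondaries[t] + 1):
                opts.append((st, c))
        later.append(opts)

    results = []
    for x in range(m + 1):
        mult = comb(m, x)
        for combo in itertools.product(*later) if later else [()]:
            codes = ["0"] * layout.n_secondary
            slices = layout.primary_slices()
            sl = slices[first]
            codes[sl.start] = release_state
            for j in range(x):
                codes[sl.start + 1 + j] = release_state
            ok = True
            for i, opt in enumerate(combo):
                if opt is None:
                    continue
                st, c = opt
                sl = slices[first + 1 + i]
                for j in range(c):
                    codes[sl.start + j] = st
            if ok:
                results.append((EncounterHistory("enum", tuple(codes)), mult))
    return results


def brute_force_feeding_loglik(
    table, structure, fixed, sigma, n_points=10001, span=8.0
) -> float:
    """Marginal log-likelihood by dense trapezoid integration over the month
    random intercept."""
    from iporangaia.activity_models import _fixed_design, validate_feeding_table

    table = validate_feeding_table(table)
    if sigma < 1e-10:
        u = np.array([0.0])
    else:
        u = np.linspace(-span * sigma, span * sigma, n_points)
    ll = 0.0
    for _, sub in table.groupby("month", sort=True):
        x = _fixed_design(sub["category"], structure)
        eta = x @ np.asarray(fixed, dtype=float)
        f = sub["n_feeding"].to_numpy(dtype=float)
        c = sub["n_captured"].to_numpy(dtype=float)
        lb = gammaln(c + 1) - gammaln(f + 1) - gammaln(c - f + 1)
        pq = np.clip(expit(eta[:, None] + u[None, :]), 1e-12, 1 - 1e-12)
        lg = (lb[:, None] + xlogy(f[:, None], pq)
              + xlogy((c - f)[:, None], 1 - pq)).sum(axis=0)
        if sigma < 1e-10:
            ll += float(lg[0])
        else:
            dens = np.exp(-u**2 / (2 * sigma**2)) / (math.sqrt(2 * math.pi) * sigma)
            peak = lg.max()
            ll += peak + math.log(np.trapezoid(np.exp(lg - peak) * dens, u))
    return ll
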