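"""Body-condition models: joint mean-variance selection under paternal care.

Body condition is measured two ways: body volume ``V`` controlled for
structural size (dorsal scute length, ``DSL``), and body mass ``TBM``
controlled for ``V``.  Volume comes from the three-diameter ellipsoid
approximation ``V = (pi/6) * TBL * BW * BH``.  The time a caring male has
invested in egg-guarding is read off his oldest eggs' embryonic stage via a
cumulative development schedule; non-caring males get zero.

Candidate models are normal likelihoods with a linear mean and a power
variance function, fitted by maximum likelihood and ranked by AICc in two
steps: first size alone (on mean, variance, both, or neither), then — for
every step-1 structure within 2 AICc of the best — care effects (caring
period or parental state, on mean, variance, or both).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

from iporangaia.model_selection import ModelRanking, rank_models

#: Cumulative days to complete embryonic stages 1-6 in the wet-warm season,
#: and the observed per-stage duration ranges (days).
DEFAULT_CUMULATIVE = (6.6, 9.7, 18.2, 24.5, 28.9, 32.0)
DEFAULT_RANGES = ((5, 10), (2, 4), (6, 10), (5, 8), (4, 5), (2, 4))


class InsufficientContrastError(ValueError):
    """Both parental states are needed to estimate a care effect."""


@dataclass(frozen=True)
class EggSchedule:
    """Stage -> cumulative development time (days) lookup for egg-batches.

    ``cumulative[s-1]`` is how long recently laid eggs take to complete
    stage ``s``; it doubles as the caring-period covariate of a male whose
    oldest eggs are in stage ``s``.
    """

    cumulative: tuple[float, ...] = DEFAULT_CUMULATIVE
    ranges: Optional[tuple[tuple[float, float], ...]] = DEFAULT_RANGES

    def __post_init__(self) -> None:
        if len(self.cumulative) != 6:
            raise ValueError("schedule must cover stages 1-6")
        if any(b <= a for a, b in zip(self.cumulative, self.cumulative[1:])):
            raise ValueError("cumulative durations must be strictly increasing")
        if self.ranges is not None:
            if len(self.ranges) != 6:
                raise ValueError("ranges must cover stages 1-6")
            for s in range(1, 6):
                lo = self.ranges[s][0]
                if self.cumulative[s] < self.cumulative[s - 1] + lo - 1e-9:
                    raise ValueError(
                        f"stage {s + 1} cumulative duration inconsistent with "
                        f"its observed range"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EggSchedule":
        doc = yaml.safe_load(Path(path).read_text())
        ranges = doc.get("ranges")
        return cls(
            cumulative=tuple(float(v) for v in doc["cumulative"]),
            ranges=tuple((float(a), float(b)) for a, b in ranges) if ranges else None,
        )

    def to_yaml(self, path: str | Path) -> Path:
        doc = {"cumulative": list(self.cumulative)}
        if self.ranges is not None:
            doc["ranges"] = [list(r) for r in self.ranges]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
        return Path(path)


def caring_period_from_stage(
    stage: int, schedule: Optional[EggSchedule] = None
) -> float:
    """Days invested in care, from the oldest eggs' stage (0 = non-caring)."""
    schedule = schedule or EggSchedule()
    if not isinstance(stage, (int, np.integer)) or not 0 <= stage <= 6:
        raise ValueError(f"egg stage must be an integer in 0-6, got {stage!r}")
    if stage == 0:
        return 0.0
    return float(schedule.cumulative[stage - 1])


def ellipsoid_volume(tbl: float, bw: float, bh: float):
    """Ellipsoid body volume (mm^3) from three body diameters (mm):
    ``(pi/6) * TBL * BW * BH``."""
    tbl, bw, bh = (np.asarray(v, dtype=float) for v in (tbl, bw, bh))
    if np.any(tbl <= 0) or np.any(bw <= 0) or np.any(bh <= 0):
        raise ValueError("all body dimensions must be positive")
    out = (math.pi / 6.0) * tbl * bw * bh
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MeanVarStructure:
    """Which covariates enter the mean and the variance of a normal model.

    Tokens are ``"size"`` (the structural-size covariate) and ``"care"``
    (the care covariate); ``care_type`` says whether care is the continuous
    caring period or the binary parental state.
    """

    mean: tuple[str, ...] = ()
    variance: tuple[str, ...] = ()
    care_type: str = "caring_period"

    def __post_init__(self) -> None:
        for tok in self.mean + self.variance:
            if tok not in ("size", "care"):
                raise ValueError(f"unknown covariate token {tok!r}")
        if self.care_type not in ("caring_period", "parental_state"):
            raise ValueError(f"unknown care covariate type {self.care_type!r}")

    @property
    def uses_care(self) -> bool:
        return "care" in self.mean or "care" in self.variance

    def label(self, size_name: str = "size") -> str:
        care = "caring period" if self.care_type == "caring_period" else "parental state"

        def side(tokens):
            parts = [size_name if t == "size" else care for t in tokens]
            return "+".join(parts) if parts else "-"

        return f"{side(self.mean)} | {side(self.variance)}"


@dataclass
class MeanVarFit:
    """ML fit of a linear-mean / power-variance normal model.

    Mean: ``mu_i = b0 + b1 * size_i (+ b2 * care_i)``.  Standard deviation:
    ``sd_i = alpha * prod_j (z_ij + off_j)^theta_j`` over the variance
    covariates, with offset 1 for covariates that can be zero (care) and 0
    for strictly positive ones (size).
    """

    structure: MeanVarStructure
    coefficients: dict[str, float]
    alpha: float
    thetas: dict[str, float]
    log_likelihood: float
    k: int
    n: int
    aicc_value: float
    converged: bool
    size_name: str = "size"

    @property
    def K(self) -> int:  # noqa: N802
        return self.k

    @property
    def label(self) -> str:
        return self.structure.label(self.size_name)


def _loglik_meanvar(params, y, mean_mat, var_covs, var_offsets):
    n_beta = mean_mat.shape[1]
    beta = params[:n_beta]
    log_alpha = params[n_beta]
    thetas = params[n_beta + 1:]
    mu = mean_mat @ beta
    log_sd = np.full(len(y), log_alpha)
    for j, z in enumerate(var_covs):
        log_sd = log_sd + thetas[j] * np.log(z + var_offsets[j])
    resid = (y - mu) / np.exp(log_sd)
    return float(
        -0.5 * len(y) * math.log(2.0 * math.pi)
        - log_sd.sum()
        - 0.5 * np.dot(resid, resid)
    )


def fit_meanvar(
    y: np.ndarray,
    x: np.ndarray,
    care: Optional[np.ndarray],
    structure: MeanVarStructure,
    size_name: str = "size",
) -> MeanVarFit:
    """Maximum-likelihood fit of one mean-variance structure.

    With an empty variance set the model is homoscedastic and the mean
    coefficients reduce to ordinary least squares (with the ML, divide-by-n,
    residual variance).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if structure.uses_care and care is None:
        raise ValueError("structure requires a care covariate")
    care_arr = None if care is None else np.asarray(care, dtype=float)

    cov_map = {"size": x}
    if care_arr is not None:
        cov_map["care"] = care_arr
    cols = [np.ones(n)] + [cov_map[t] for t in structure.mean]
    mean_mat = np.column_stack(cols)
    var_covs = [cov_map[t] for t in structure.variance]
    # care covariates take value 0 (non-caring males), so their power law is
    # anchored at z+1; size covariates are strictly positive and enter as-is
    var_offsets = [0.0 if t == "size" else 1.0 for t in structure.variance]

    k = mean_mat.shape[1] + 1 + len(var_covs)
    if n <= k + 1:
        raise ValueError(f"need n > K + 1 (n={n}, K={k})")

    beta0, *_ = np.linalg.lstsq(mean_mat, y, rcond=None)
    resid0 = y - mean_mat @ beta0
    sd0 = max(float(np.sqrt(np.mean(resid0**2))), 1e-8)
    x0 = np.concatenate([beta0, [math.log(sd0)], np.zeros(len(var_covs))])

    def nll(params):
        ll = _loglik_meanvar(params, y, mean_mat, var_covs, var_offsets)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"maxiter": 2000, "gtol": 1e-8})
    polish = optimize.minimize(nll, res.x, method="Nelder-Mead",
                               options={"maxiter": 4000, "xatol": 1e-10,
                                        "fatol": 1e-10})
    best = polish if polish.fun < res.fun else res
    n_beta = mean_mat.shape[1]
    beta_names = ["intercept"] + list(structure.mean)
    ll = -float(best.fun)
    from iporangaia.model_selection import aicc as _aicc

    return MeanVarFit(
        structure=structure,
        coefficients=dict(zip(beta_names, best.x[:n_beta])),
        alpha=float(np.exp(best.x[n_beta])),
        thetas=dict(zip(structure.variance, best.x[n_beta + 1:])),
        log_likelihood=ll,
        k=k,
        n=n,
        aicc_value=_aicc(ll, k, n),
        converged=bool(res.success or polish.success),
        size_name=size_name,
    )


def _step2_variants(
    base: MeanVarStructure, care_type: str
) -> list[MeanVarStructure]:
    out = []
    for on_mean, on_var in ((True, False), (False, True), (True, True)):
        mean = base.mean + (("care",) if on_mean else ())
        var = base.variance + (("care",) if on_var else ())
        out.append(MeanVarStructure(mean, var, care_type))
    return out


def two_step_selection(
    records: pd.DataFrame,
    response: str = "volume",
    schedule: Optional[EggSchedule] = None,
    carry_delta: float = 2.0,
) -> dict:
    """Two-step AICc selection of mean-variance body-condition models.

    Step 1 ranks the four size-only structures (size on mean, variance,
    both, or neither).  Every step-1 structure within ``carry_delta`` AICc
    of the best is carried into step 2, where care effects — caring period
    or parental state, on the mean, the variance, or both — are added and
    all variants are ranked together.

    ``records`` needs columns ``dsl``, ``tbl``, ``bw``, ``bh``, ``tbm``,
    ``parental_state`` (``caring``/``non-caring``) and ``egg_stage``; body
    volume and the caring period are derived if absent.  ``response`` is
    ``"volume"`` (V vs DSL) or ``"mass"`` (TBM vs V).
    """
    records = records.copy()
    if "volume" not in records:
        records["volume"] = ellipsoid_volume(
            records["tbl"].to_numpy(), records["bw"].to_numpy(),
            records["bh"].to_numpy(),
        )
    if "caring_period" not in records:
        records["caring_period"] = [
            caring_period_from_stage(int(s), schedule) for s in records["egg_stage"]
        ]
    states = set(records["parental_state"])
    if len(records) < 20 or states != {"caring", "non-caring"}:
        raise InsufficientContrastError(
            "need >= 20 records with both caring and non-caring males"
        )
    if response == "volume":
        y = records["volume"].to_numpy()
        x = records["dsl"].to_numpy()
        size_name = "DSL"
    elif response == "mass":
        y = records["tbm"].to_numpy()
        x = records["volume"].to_numpy()
        size_name = "V"
    else:
        raise ValueError("response must be 'volume' or 'mass'")
    care_period = records["caring_period"].to_numpy(dtype=float)
    state_bin = (records["parental_state"] == "caring").to_numpy(dtype=float)

    def fit(structure: MeanVarStructure) -> MeanVarFit:
        care = care_period if structure.care_type == "caring_period" else state_bin
        return fit_meanvar(y, x, care, structure, size_name=size_name)

    step1_structs = [
        MeanVarStructure(("size",), ()),
        MeanVarStructure(("size",), ("size",)),
        MeanVarStructure((), ("size",)),
        MeanVarStructure((), ()),
    ]
    step1_fits = [fit(s) for s in step1_structs]
    n = len(records)
    step1 = rank_models(step1_fits, ess=n, chat=1.0, criterion="AICc")

    best_crit = step1.table["AICc"].iloc[0]
    carried = [
        f for f in step1_fits if (f.aicc_value - best_crit) < carry_delta
    ]

    seen_labels = set()
    step2_fits = []
    for base_fit in carried:
        candidates = [base_fit.structure]
        for care_type in ("caring_period", "parental_state"):
            candidates.extend(_step2_variants(base_fit.structure, care_type))
        for struct in candidates:
            lab = struct.label(size_name)
            if lab in seen_labels:
                continue
            seen_labels.add(lab)
            if struct.uses_care:
                step2_fits.append(fit(struct))
            else:
                step2_fits.append(base_fit)
    step2 = rank_models(step2_fits, ess=n, chat=1.0, criterion="AICc")
    return {
        "step1": step1,
        "step2": step2,
        "carried": tuple(f.label for f in carried),
        "selected": step2.best,
    }
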