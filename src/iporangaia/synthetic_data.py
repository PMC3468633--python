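"""Synthetic field data with the statistical structure the analyses assume.

The generator emulates a one-year riparian transect study: individuals are
recruited at primary occasions, survive and (males) switch parental state
between months (survive-then-transition), are detected on each sampling day
with state- and month-dependent probability, and drift along a 0-200 m
transect — caring males barely move, everyone else takes multi-metre steps.
Morphometric and feeding tables follow the generative assumptions of the
body-condition and feeding-activity models: linear mean with power-variance
noise for body volume and mass, and binomial monthly feeding counts with a
month-level random intercept.

Ground truth (parameters and latent fates) is always returned next to the
observable data; analyses in tests never re-infer what the generator knows.
Every draw is reproducible from ``config.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special

from iporangaia.condition_models import EggSchedule, ellipsoid_volume
from iporangaia.encounter_io import (
    EncounterHistory,
    RobustDesignLayout,
    default_layout,
    write_inp,
    write_positions,
)

# Irregular month-to-month wiggles (logit scale) used by the default
# time-varying survival, detection and transition patterns.  Fixed values, so
# the default study conditions are the same in every run.
_PHI_WIGGLE = (0.3, -0.4, -1.0, 0.5, 0.9, -0.7, -0.1, 0.7, -1.1, -0.2, 0.4)
_P_WIGGLE = (0.2, -0.5, 0.4, -0.3, 0.6, -0.6, 0.1, 0.5, -0.8, 0.0, -0.2, 0.3)
_PSI_WIGGLE = (0.5, -0.6, 0.2, 0.8, -0.4, 0.3, -0.9, 0.6, -0.2, 0.1, -0.5)


def _default_phi(layout: RobustDesignLayout) -> np.ndarray:
    """Survival truth: non-caring individuals (females and non-caring males)
    share an irregular time course around 0.75; caring males a constant 0.9."""
    t1 = layout.n_primary - 1
    w = np.resize(_PHI_WIGGLE, t1)
    nc = special.expit(special.logit(0.75) + 0.8 * w)
    return np.vstack([nc, nc, np.full(t1, 0.9)])


def _default_p(layout: RobustDesignLayout) -> np.ndarray:
    """Detection truth: additive month course + category offsets (caring
    males, sitting on their egg-batches, are the easiest to find)."""
    t = layout.n_primary
    w = np.resize(_P_WIGGLE, t)
    base = special.logit(0.35) + 0.7 * w
    return np.vstack([
        special.expit(base),          # females
        special.expit(base - 0.2),    # non-caring males
        special.expit(base + 0.8),    # caring males
    ])


def _default_psi(layout: RobustDesignLayout) -> np.ndarray:
    """Transition truth: additive month course + direction offset."""
    t1 = layout.n_primary - 1
    w = np.resize(_PSI_WIGGLE, t1)
    return np.vstack([
        special.expit(special.logit(0.25) + 0.7 * w),  # N -> C
        special.expit(special.logit(0.30) + 0.7 * w),  # C -> N
    ])


def _default_recruitment(total: int, layout: RobustDesignLayout) -> tuple[int, ...]:
    """Front-loaded recruitment with extra arrivals in the wet-warm season."""
    weights = np.array(
        [3.0 if s == "wet-warm" else 1.5 for s in layout.season]
    )
    weights[0] *= 3.0  # the standing population at the study start
    raw = np.floor(total * weights / weights.sum()).astype(int)
    raw[0] += total - raw.sum()
    return tuple(int(v) for v in raw)


@dataclass
class SimulationConfig:
    """Full generative specification for one synthetic study.

    Defaults reproduce the one-year field design: 12 primary occasions with
    46 secondary occasions, roughly 500 males and 350 females marked,
    state-dependent survival/detection/transition, near-stationary caring
    males on a 200 m transect, 93-male morphometric samples, and monthly
    feeding counts on the order of tens of feeders among thousands of
    captures.
    """

    seed: int
    layout: RobustDesignLayout = field(default_factory=default_layout)
    phi: Optional[np.ndarray] = None              # (3, T-1) rows F, N, C
    p: Optional[np.ndarray] = None                # (3, T)
    psi: Optional[np.ndarray] = None              # (2, T-1) rows NtoC, CtoN
    recruitment_males: Optional[tuple[int, ...]] = None
    recruitment_females: Optional[tuple[int, ...]] = None
    initial_caring_prob: float = 0.35
    # movement: per-state sd (metres) of the per-secondary position step
    step_sd: dict = field(default_factory=lambda: {"F": 6.0, "N": 6.0, "C": 0.4})
    transect_length: float = 200.0
    # morphometrics: V = b0 + b1*DSL + b2*caring_period + e,
    #                sd(e) = alpha_v * (caring_period + 1)^theta_v
    dsl_mean: float = 4.0
    dsl_sd: float = 0.3
    v_beta: tuple[float, float, float] = (10.0, 10.0, -0.45)
    v_alpha: float = 8.0
    v_theta: float = -0.25
    # TBM = g0 + g1*V + g2*caring + e, sd(e) = alpha_t * V^theta_tv * (1+caring)^theta_ts
    tbm_beta: tuple[float, float, float] = (0.02, 0.006, -0.03)
    tbm_alpha: float = 0.004
    tbm_theta_v: float = 0.3
    tbm_theta_state: float = 0.6
    caring_fraction_morph: float = 0.45
    # feeding: logit rates per category and month random-effect sd
    feeding_rates: dict = field(default_factory=lambda: {
        "female": 0.025, "non-caring male": 0.014, "caring male": 0.0025,
    })
    feeding_sigma_u: float = 0.5
    feeding_captured_mean: dict = field(default_factory=lambda: {
        "female": 110.0, "non-caring male": 130.0, "caring male": 45.0,
    })

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.phi is None:
            self.phi = _default_phi(self.layout)
        if self.p is None:
            self.p = _default_p(self.layout)
        if self.psi is None:
            self.psi = _default_psi(self.layout)
        self.phi = np.asarray(self.phi, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        t = self.layout.n_primary
        if self.phi.shape != (3, t - 1) or self.p.shape != (3, t) or \
                self.psi.shape != (2, t - 1):
            raise ValueError("phi/p/psi shapes must match the layout")
        for name in ("phi", "p", "psi"):
            arr = getattr(self, name)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.recruitment_males is None:
            self.recruitment_males = _default_recruitment(501, self.layout)
        if self.recruitment_females is None:
            self.recruitment_females = _default_recruitment(349, self.layout)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "phi": self.phi.tolist(),
            "p": self.p.tolist(),
            "psi": self.psi.tolist(),
            "recruitment_males": list(self.recruitment_males),
            "recruitment_females": list(self.recruitment_females),
            "initial_caring_prob": self.initial_caring_prob,
            "step_sd": dict(self.step_sd),
            "transect_length": self.transect_length,
            "dsl_mean": self.dsl_mean, "dsl_sd": self.dsl_sd,
            "v_beta": list(self.v_beta), "v_alpha": self.v_alpha,
            "v_theta": self.v_theta,
            "tbm_beta": list(self.tbm_beta), "tbm_alpha": self.tbm_alpha,
            "tbm_theta_v": self.tbm_theta_v,
            "tbm_theta_state": self.tbm_theta_state,
            "caring_fraction_morph": self.caring_fraction_morph,
            "feeding_rates": dict(self.feeding_rates),
            "feeding_sigma_u": self.feeding_sigma_u,
            "feeding_captured_mean": dict(self.feeding_captured_mean),
        }


def simulate_population(config: SimulationConfig, seed: Optional[int] = None) -> dict:
    """Simulate the capture-mark-recapture data.

    Returns ``histories`` (first-capture-conditioned encounter histories),
    ``positions`` (sidecar DataFrame of transect positions at captures), and
    ``truth`` — generating parameters plus the latent per-primary state of
    every simulated animal (including the never-detected ones), coded
    ``-2`` not yet recruited, ``-1`` dead, otherwise the category row
    (0 female, 1 non-caring, 2 caring).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layout = config.layout
    t = layout.n_primary
    slices = layout.primary_slices()
    histories: list[EncounterHistory] = []
    latent_rows = []
    pos_rows = []

    for sex, recruits in (("female", config.recruitment_females),
                          ("male", config.recruitment_males)):
        counter = 0
        for t0 in range(t):
            for _ in range(int(recruits[t0])):
                counter += 1
                ind_id = f"{'F' if sex == 'female' else 'M'}{counter:05d}"
                if sex == "female":
                    cat = 0
                else:
                    cat = 2 if rng.random() < config.initial_caring_prob else 1
                latent = np.full(t, -2, dtype=int)
                codes = ["0"] * layout.n_secondary
                position = rng.uniform(0.0, config.transect_length)
                positions: dict[int, int] = {}
                alive = True
                for tt in range(t0, t):
                    if tt > t0:
                        state_label = "FNC"[cat]
                        if rng.random() >= config.phi[cat, tt - 1]:
                            alive = False
                        elif sex == "male":
                            direction = 0 if cat == 1 else 1
                            if rng.random() < config.psi[direction, tt - 1]:
                                cat = 3 - cat  # swap 1 <-> 2
                    if not alive:
                        latent[tt:] = -1
                        break
                    latent[tt] = cat
                    sl = slices[tt]
                    for j in range(layout.secondaries[tt]):
                        position += rng.normal(0.0, config.step_sd["FNC"[cat]])
                        position = float(np.clip(position, 0.0, config.transect_length))
                        if rng.random() < config.p[cat, tt]:
                            codes[sl.start + j] = "FNC"[cat]
                            positions[sl.start + j] = int(round(position))
                latent_rows.append({"individual_id": ind_id, "sex": sex,
                                    "latent": latent.copy()})
                if any(c != "0" for c in codes):
                    h = EncounterHistory(ind_id, tuple(codes), 1, positions)
                    histories.append(h)
                    for jj, pos in sorted(positions.items()):
                        pos_rows.append({"individual_id": ind_id,
                                         "secondary_index": jj,
                                         "position_m": pos})

    latent = pd.DataFrame(
        [
            {"individual_id": r["individual_id"], "sex": r["sex"],
             **{f"t{i}": int(v) for i, v in enumerate(r["latent"])}}
            for r in latent_rows
        ]
    )
    return {
        "histories": histories,
        "positions": pd.DataFrame(
            pos_rows, columns=["individual_id", "secondary_index", "position_m"]),
        "truth": {
            "phi": config.phi.copy(),
            "p": config.p.copy(),
            "psi": config.psi.copy(),
            "latent": latent,
            "n_simulated": len(latent_rows),
            "n_detected": len(histories),
        },
    }


def simulate_morphometrics(
    config: SimulationConfig, n_males: int = 93, seed: Optional[int] = None
) -> dict:
    """Simulate one summer's morphometric sample of males.

    Structural size (DSL) is normal; body volume follows a linear mean in
    DSL and caring period with power-variance noise shrinking over the
    caring period; body mass follows a linear mean in volume and parental
    state with power-variance noise in both.  Body length/width/height are
    drawn so the ellipsoid formula reproduces the simulated volume exactly.
    """
    if n_males < 2:
        raise ValueError("need at least two males")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    schedule = EggSchedule()
    caring = rng.random(n_males) < config.caring_fraction_morph
    if caring.all() or not caring.any():  # force contrast at tiny n
        caring[0] = True
        caring[1] = False
    stage = np.where(caring, rng.integers(1, 7, size=n_males), 0)
    period = np.where(
        stage > 0, np.asarray(schedule.cumulative)[np.maximum(stage - 1, 0)], 0.0
    )
    dsl = rng.normal(config.dsl_mean, config.dsl_sd, size=n_males)
    b0, b1, b2 = config.v_beta
    v_mean = b0 + b1 * dsl + b2 * period
    v_sd = config.v_alpha * (period + 1.0) ** config.v_theta
    volume = rng.normal(v_mean, v_sd)
    volume = np.maximum(volume, 1.0)
    g0, g1, g2 = config.tbm_beta
    tbm_mean = g0 + g1 * volume + g2 * caring
    tbm_sd = (
        config.tbm_alpha * volume ** config.tbm_theta_v
        * (1.0 + caring) ** config.tbm_theta_state
    )
    tbm = np.maximum(rng.normal(tbm_mean, tbm_sd), 1e-3)
    bw = rng.normal(4.2, 0.25, size=n_males)
    bh = rng.normal(3.2, 0.2, size=n_males)
    tbl = volume / (np.pi / 6.0 * bw * bh)
    records = pd.DataFrame({
        "male_id": [f"S{i + 1:03d}" for i in range(n_males)],
        "dsl": dsl, "tbl": tbl, "bw": bw, "bh": bh, "tbm": tbm,
        "parental_state": np.where(caring, "caring", "non-caring"),
        "egg_stage": stage,
    })
    assert np.allclose(
        ellipsoid_volume(records["tbl"].to_numpy(), records["bw"].to_numpy(),
                         records["bh"].to_numpy()),
        volume,
    )
    return {
        "records": records,
        "truth": {
            "v_beta": config.v_beta, "v_alpha": config.v_alpha,
            "v_theta": config.v_theta,
            "tbm_beta": config.tbm_beta, "tbm_alpha": config.tbm_alpha,
            "tbm_theta_v": config.tbm_theta_v,
            "tbm_theta_state": config.tbm_theta_state,
            "caring_period": period,
        },
    }


def simulate_feeding(config: SimulationConfig, seed: Optional[int] = None) -> dict:
    """Simulate the monthly feeding-count table.

    Month effects are normal on the log-odds scale; counts are binomial in
    the number captured, so overdispersion across months enters only through
    the shared random intercept.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    months = config.layout.month_labels
    u = rng.normal(0.0, config.feeding_sigma_u, size=len(months))
    rows = []
    for m, month in enumerate(months):
        for category in ("female", "caring male", "non-caring male"):
            n_cap = int(rng.poisson(config.feeding_captured_mean[category]))
            eta = special.logit(config.feeding_rates[category]) + u[m]
            n_feed = int(rng.binomial(n_cap, special.expit(eta))) if n_cap else 0
            rows.append({"month": month, "category": category,
                         "n_feeding": n_feed, "n_captured": n_cap})
    return {
        "table": pd.DataFrame(rows),
        "truth": {
            "rates": dict(config.feeding_rates),
            "sigma_u": config.feeding_sigma_u,
            "month_effects": u,
        },
    }


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate everything and write the on-disk artifact set.

    Produces the encounter ``.inp`` file, positions CSV, layout YAML,
    morphometrics CSV, feeding CSV, and a truth/config JSON.  Byte-identical
    for identical configs.
    """
    from iporangaia.encounter_io import write_layout

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop = simulate_population(config)
    morph = simulate_morphometrics(config)
    feeding = simulate_feeding(config)
    paths = {
        "inp": outdir / "encounters.inp",
        "positions": outdir / "positions.csv",
        "layout": outdir / "layout.yaml",
        "morphometrics": outdir / "morphometrics.csv",
        "feeding": outdir / "feeding.csv",
        "truth": outdir / "truth.json",
    }
    write_inp(pop["histories"], config.layout, paths["inp"])
    write_positions(pop["histories"], paths["positions"])
    write_layout(config.layout, paths["layout"])
    morph["records"].to_csv(paths["morphometrics"], index=False)
    feeding["table"].to_csv(paths["feeding"], index=False)
    truth = {
        "config": config.to_dict(),
        "cmr": {k: v.tolist() for k, v in pop["truth"].items()
                if isinstance(v, np.ndarray)},
        "n_simulated": pop["truth"]["n_simulated"],
        "n_detected": pop["truth"]["n_detected"],
        "morph": {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                  for k, v in morph["truth"].items()},
        "feeding": {"rates": feeding["truth"]["rates"],
                    "sigma_u": feeding["truth"]["sigma_u"],
                    "month_effects": feeding["truth"]["month_effects"].tolist()},
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
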