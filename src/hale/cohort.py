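"""Synthetic ageing-cohort generator and Monte-Carlo occupancy oracle.

Generates panel datasets with the structure the inference assumes: subjects
aged 60+ with baseline ages drawn from survey-like 5-year band weights,
independent Bernoulli covariates at stated prevalences, a baseline health
state from a logistic model, continuous-time illness-death trajectories
under a Gompertz truth (simulated exactly on a fine piecewise-constant
grid), living states read only at scheduled waves, exact death ages, and
optional attrition.

Age-band presets named ``"eps"`` (Chile 2004/06), ``"creles"`` (Costa Rica
2005/07, oversampled 80+) and ``"share"`` (Spain 2004–07) mirror the
male/female sample distributions of those panel surveys; covariate
prevalence presets likewise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .expectancy import InitialStateModel
from .intensities import GompertzIntensityParams, _as_z
from .panel import PanelDataset
from .states import DEAD, HEALTHY, UNHEALTHY

AGE_BANDS = [(60, 65), (65, 70), (70, 75), (75, 80), (80, 85), (85, 90), (90, 95)]

#: Survey-like baseline age-band weights (percent) by sex, 60+ samples.
AGE_PRESETS: Dict[str, Dict[str, List[float]]] = {
    "eps": {  # Chile
        "male": [32.12, 24.15, 20.52, 11.96, 6.60, 3.27, 1.37],
        "female": [28.38, 23.69, 17.56, 14.79, 8.54, 4.75, 2.29],
    },
    "creles": {  # Costa Rica: note the oversampling of 80+
        "male": [13.25, 20.92, 21.14, 19.72, 13.80, 7.12, 4.05],
        "female": [15.33, 22.04, 19.58, 15.89, 14.29, 9.74, 3.12],
    },
    "share": {  # Spain
        "male": [22.80, 22.45, 24.87, 16.93, 7.77, 3.80, 1.38],
        "female": [20.87, 20.60, 20.87, 17.62, 12.20, 5.83, 2.03],
    },
}

#: Survey-like covariate prevalences: P(female), P(secondary+ education),
#: P(social participation in the last six months).
COVARIATE_PRESETS: Dict[str, Dict[str, float]] = {
    "eps": {"sex": 0.4973, "edu": 0.324, "part": 0.3218},
    "creles": {"sex": 0.5365, "edu": 0.157, "part": 0.5817},
    "share": {"sex": 0.5604, "edu": 0.204, "part": 0.2331},
}


def default_true_params(covariates: Sequence[str] = ("part",),
                        reference_age: float = 60.0) -> GompertzIntensityParams:
    """Gompertz truth used as the generator's study conditions.

    Per-year rates at age 60: onset 0.08 (slope .07/y), mortality from
    health 0.008 (slope .09/y), recovery 0.25 (slope −.03/y), mortality
    from ill health 0.045 (slope .08/y) — magnitudes that give a total
    life expectancy at 60 in the high teens and a healthy share around
    70%, plausible for 60+ functional-limitation panels.  Covariate log-hazard-ratios: social
    participation protective on onset and both mortalities, positive on
    recovery; female lower mortality, slightly higher onset; education
    mildly protective.
    """
    effects = {
        "part": (-0.3, -0.4, 0.2, -0.3),
        "sex": (0.2, -0.35, -0.1, -0.35),
        "edu": (-0.1, -0.15, 0.05, -0.1),
    }
    covariates = tuple(covariates)
    gamma = {}
    from .states import TRANSITIONS
    for i, t in enumerate(TRANSITIONS):
        gamma[t] = {name: effects[name][i] for name in covariates if name in effects}
    return GompertzIntensityParams.from_rates(
        rates={(1, 2): 0.08, (1, 3): 0.008, (2, 1): 0.25, (2, 3): 0.045},
        xi={(1, 2): 0.07, (1, 3): 0.09, (2, 1): -0.03, (2, 3): 0.08},
        gamma=gamma, covariates=covariates, reference_age=reference_age)


def default_initial_model(covariates: Sequence[str] = ("part",),
                          reference_age: float = 60.0) -> InitialStateModel:
    """Baseline-state truth: ~13% unhealthy at 60, rising with age."""
    effects = {"part": -0.4, "sex": 0.25, "edu": -0.2}
    coef = [-1.9, 0.045] + [effects.get(name, 0.0) for name in covariates]
    return InitialStateModel(np.array(coef), None, tuple(covariates),
                             include_age=True, reference_age=reference_age)


# ----------------------------------------------------------------------
@dataclass
class Trajectory:
    """One subject's latent path: ordered (age, state) events.

    The first event is the baseline (age, living state); subsequent events
    are state changes; a final state-3 event is the exact death age.  A
    trajectory without a death event survived to ``omega_max``.
    """

    subject_id: str
    z: Dict[str, float]
    events: List[Tuple[float, int]]

    @property
    def death_age(self) -> Optional[float]:
        return self.events[-1][0] if self.events[-1][1] == DEAD else None

    def state_at(self, age: float) -> Optional[int]:
        """Living state occupied at ``age`` (None if already dead)."""
        state = None
        for a, s in self.events:
            if a <= age + 1e-12:
                state = s
            else:
                break
        if state == DEAD:
            return None
        return state

    def occupancy(self, x: float, omega_max: float) -> Tuple[float, float]:
        """Time spent in (healthy, unhealthy) over [x, death or omega_max]."""
        occ = {HEALTHY: 0.0, UNHEALTHY: 0.0}
        end_age = self.death_age if self.death_age is not None else omega_max
        for (a0, s0), a1 in zip(self.events,
                                [a for a, _ in self.events[1:]] + [end_age]):
            if s0 == DEAD:
                break
            lo, hi = max(a0, x), min(a1, end_age)
            if hi > lo:
                occ[s0] += hi - lo
        return occ[HEALTHY], occ[UNHEALTHY]


@dataclass
class TrajectorySet:
    trajectories: List[Trajectory]

    def __len__(self):
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)


# ----------------------------------------------------------------------
class _HazardGrid:
    """Per-profile transition rates frozen on the fine simulation grid."""

    def __init__(self, params: GompertzIntensityParams, start_age: float,
                 omega_max: float, z, h_sim: float):
        self.h = float(h_sim)
        self.t0 = float(start_age)
        self.omega = float(omega_max)
        n = max(int(np.ceil((self.omega - self.t0) / self.h - 1e-12)), 1)
        self.edges = self.t0 + self.h * np.arange(n + 1)
        self.edges[-1] = self.omega
        mids = 0.5 * (self.edges[:-1] + self.edges[1:])
        q = params.rates(mids, _as_z(z, params.covariates))  # (n, 4)
        self.q = q
        self.exit_total = {HEALTHY: q[:, 0] + q[:, 1], UNHEALTHY: q[:, 2] + q[:, 3]}

    def next_event(self, age: float, state: int, rng: np.random.Generator):
        """Draw the next transition after ``age``: (event_age, new_state) or None."""
        j0 = min(int((age - self.t0) / self.h), len(self.edges) - 2)
        tot = self.exit_total[state][j0:]
        seg_len = np.diff(self.edges[j0:])
        seg_len = seg_len.copy()
        seg_len[0] = self.edges[j0 + 1] - age
        cum = np.cumsum(tot * seg_len)
        e = rng.exponential()
        j = int(np.searchsorted(cum, e))
        if j >= len(cum):
            return None  # survives without transition to omega
        prev = cum[j - 1] if j > 0 else 0.0
        start = age if j == 0 else self.edges[j0 + j]
        t = start + (e - prev) / tot[j]
        row = self.q[j0 + j]
        if state == HEALTHY:
            p_ill = row[0] / (row[0] + row[1])
            new = UNHEALTHY if rng.random() < p_ill else DEAD
        else:
            p_rec = row[2] / (row[2] + row[3])
            new = HEALTHY if rng.random() < p_rec else DEAD
        return t, new


def simulate_trajectory(params: GompertzIntensityParams, start_age: float,
                        start_state: int, z, omega_max: float,
                        rng: np.random.Generator, h_sim: float = 0.1,
                        subject_id: str = "s0",
                        _grid: Optional[_HazardGrid] = None) -> Trajectory:
    """Forward-simulate one illness-death path under the Gompertz truth.

    Competing-risks event simulation with the hazards frozen on a fine
    grid (step ``h_sim``): the exponential total-hazard clock is inverted
    against the piecewise-constant cumulative hazard, and the destination
    drawn proportional to the intensities at the event's grid cell.
    """
    if start_state not in (HEALTHY, UNHEALTHY):
        raise ValueError("start_state must be a living state")
    grid = _grid or _HazardGrid(params, start_age, omega_max, z, h_sim)
    zd = dict(zip(params.covariates, _as_z(z, params.covariates)))
    events: List[Tuple[float, int]] = [(float(start_age), int(start_state))]
    age, state = float(start_age), int(start_state)
    while age < omega_max and state != DEAD:
        nxt = grid.next_event(age, state, rng)
        if nxt is None:
            break
        age, state = nxt
        events.append((age, state))
    return Trajectory(subject_id, zd, events)


def observe_waves(trajectory: Trajectory, offsets: Sequence[float],
                  attrition_prob: float = 0.0,
                  rng: Optional[np.random.Generator] = None,
                  health_attrition_logodds: float = 0.0) -> List[Tuple[float, int]]:
    """Read the latent path at scheduled wave ages; deaths at exact ages.

    ``offsets`` are years after baseline, starting at 0.  If the subject
    dies before a scheduled wave, a state-3 record at the exact death age
    is appended and observation stops.  Attrition (missing a follow-up
    wave, default completely at random; optionally more likely when last
    seen unhealthy) truncates all later observation, including death
    reporting.
    """
    offsets = list(offsets)
    if not offsets or offsets[0] != 0:
        raise ValueError("offsets must start at 0 (the baseline wave)")
    if any(b <= a for a, b in zip(offsets[:-1], offsets[1:])):
        raise ValueError("offsets must be strictly increasing")
    if attrition_prob and rng is None:
        raise ValueError("attrition requires an rng")
    base_age = trajectory.events[0][0]
    rows: List[Tuple[float, int]] = [(base_age, trajectory.events[0][1])]
    last_state = trajectory.events[0][1]
    for off in offsets[1:]:
        wave_age = base_age + off
        if attrition_prob:
            p = attrition_prob
            if health_attrition_logodds and last_state == UNHEALTHY:
                logit = np.log(p / (1 - p)) + health_attrition_logodds
                p = 1.0 / (1.0 + np.exp(-logit))
            if rng.random() < p:
                break
        death_age = trajectory.death_age
        if death_age is not None and death_age <= wave_age:
            rows.append((death_age, DEAD))
            break
        state = trajectory.state_at(wave_age)
        rows.append((wave_age, state))
        last_state = state
    return rows


# ----------------------------------------------------------------------
@dataclass
class SimulationConfig:
    """Study conditions for a synthetic two-wave (or multi-wave) cohort."""

    n_subjects: int = 2000
    age_preset: Union[str, Tuple[float, float]] = "eps"
    covariate_prevalences: Dict[str, float] = field(
        default_factory=lambda: {"part": 0.3218})
    true_params: Optional[GompertzIntensityParams] = None
    true_initial_model: Optional[InitialStateModel] = None
    wave_offsets: Tuple[float, ...] = (0.0, 2.5)
    attrition_prob: float = 0.06
    health_attrition_logodds: float = 0.0
    omega_max: float = 115.0
    h_sim: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self):
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")
        offs = self.wave_offsets
        if not offs or offs[0] != 0 or any(b <= a for a, b in zip(offs[:-1], offs[1:])):
            raise ValueError("wave_offsets must start at 0 and strictly increase")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        names = tuple(self.covariate_prevalences)
        if self.true_params is None:
            self.true_params = default_true_params(names)
        if self.true_initial_model is None:
            self.true_initial_model = default_initial_model(names)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "true_params" in d and isinstance(d["true_params"], Mapping):
            d["true_params"] = GompertzIntensityParams.from_dict(d["true_params"])
        if "true_initial_model" in d and isinstance(d["true_initial_model"], Mapping):
            d["true_initial_model"] = InitialStateModel.from_dict(
                d["true_initial_model"])
        if "wave_offsets" in d:
            d["wave_offsets"] = tuple(d["wave_offsets"])
        if "age_preset" in d and isinstance(d["age_preset"], (list, tuple)):
            d["age_preset"] = tuple(d["age_preset"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> Dict:
        return {
            "n_subjects": self.n_subjects,
            "age_preset": list(self.age_preset)
            if isinstance(self.age_preset, tuple) else self.age_preset,
            "covariate_prevalences": dict(self.covariate_prevalences),
            "true_params": self.true_params.to_dict(),
            "true_initial_model": self.true_initial_model.to_dict(),
            "wave_offsets": list(self.wave_offsets),
            "attrition_prob": self.attrition_prob,
            "health_attrition_logodds": self.health_attrition_logodds,
            "omega_max": self.omega_max,
            "h_sim": self.h_sim,
            "seed": self.seed,
        }


def _draw_baseline_age(cfg: SimulationConfig, sex: float,
                       rng: np.random.Generator) -> float:
    if isinstance(cfg.age_preset, tuple):
        lo, hi = cfg.age_preset
        return float(rng.uniform(lo, hi))
    preset = AGE_PRESETS[cfg.age_preset]
    weights = np.asarray(preset["female" if sex >= 0.5 else "male"])
    weights = weights / weights.sum()
    band = rng.choice(len(AGE_BANDS), p=weights)
    lo, hi = AGE_BANDS[band]
    return float(rng.uniform(lo, hi))


def generate_cohort(config: SimulationConfig
                    ) -> Tuple[PanelDataset, TrajectorySet]:
    """Simulate a validated panel plus the latent truth behind it."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    names = tuple(cfg.covariate_prevalences)
    params, init = cfg.true_params, cfg.true_initial_model
    obs_rows, cov_rows, trajs = [], [], []
    width = max(4, len(str(max(cfg.n_subjects, 1))))
    for i in range(cfg.n_subjects):
        sid = f"s{i:0{width}d}"
        z = {name: float(rng.random() < cfg.covariate_prevalences[name])
             for name in names}
        sex = z.get("sex", float(rng.random() < 0.5))
        age0 = _draw_baseline_age(cfg, sex, rng)
        _, p2 = init.predict_pi(age0, z)
        state0 = UNHEALTHY if rng.random() < p2 else HEALTHY
        traj = simulate_trajectory(params, age0, state0, z, cfg.omega_max,
                                   rng, cfg.h_sim, subject_id=sid)
        trajs.append(traj)
        rows = observe_waves(traj, cfg.wave_offsets, cfg.attrition_prob, rng,
                             cfg.health_attrition_logodds)
        for age, state in rows:
            obs_rows.append((sid, age, state))
        cov_rows.append((sid, *[z[name] for name in names]))
    obs = pd.DataFrame(obs_rows, columns=["subject_id", "age", "state"])
    cov = pd.DataFrame(cov_rows, columns=["subject_id", *names]
                       ).set_index("subject_id")
    if cfg.n_subjects == 0:
        dataset = PanelDataset(obs=obs, covariates=cov, min_age=None)
    else:
        dataset = PanelDataset.from_frames(obs, cov, min_age=None)
    return dataset, TrajectorySet(trajs)


# ----------------------------------------------------------------------
@dataclass
class OracleLE:
    """Monte-Carlo occupancy-time estimates with standard errors (years)."""

    hle: float
    ule: float
    tle: float
    hle_se: float
    ule_se: float
    tle_se: float
    n_paths: int


def oracle_le(true_params: GompertzIntensityParams, x: float, z,
              init: Union[int, Tuple[float, float], InitialStateModel] = HEALTHY,
              n_paths: int = 10_000, omega_max: float = 115.0,
              rng: Optional[np.random.Generator] = None,
              h_sim: float = 0.1) -> OracleLE:
    """Simulation oracle for life expectancies at age ``x``.

    ``init`` selects the starting state: a fixed living state, explicit
    (pi_healthy, pi_unhealthy) weights, or a baseline-state model evaluated
    at ``x``.  Independent of the numerical-integration route, so it serves
    as its cross-check.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = rng or np.random.default_rng()
    if isinstance(init, InitialStateModel):
        pi = init.predict_pi(x, z)
    elif isinstance(init, (tuple, list, np.ndarray)):
        pi = (float(init[0]), float(init[1]))
    else:
        pi = (1.0, 0.0) if init == HEALTHY else (0.0, 1.0)
    grid = _HazardGrid(true_params, x, omega_max, z, h_sim)
    occ = np.empty((n_paths, 2))
    for i in range(n_paths):
        s0 = HEALTHY if rng.random() < pi[0] else UNHEALTHY
        traj = simulate_trajectory(true_params, x, s0, z, omega_max, rng,
                                   h_sim, _grid=grid)
        occ[i] = traj.occupancy(x, omega_max)
    hle, ule = occ.mean(axis=0)
    tot = occ.sum(axis=1)
    n = n_paths
    return OracleLE(
        hle=float(hle), ule=float(ule), tle=float(tot.mean()),
        hle_se=float(occ[:, 0].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        ule_se=float(occ[:, 1].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        tle_se=float(tot.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        n_paths=n,
    )


def write_truth(config: SimulationConfig, path,
                trajectories: Optional[TrajectorySet] = None) -> None:
    """Sidecar JSON with the generating truth (optionally the paths too)."""
    doc = config.to_dict()
    if trajectories is not None:
        doc["trajectories"] = [
            {"subject_id": t.subject_id, "z": t.z, "events": t.events}
            for t in trajectories
        ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
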