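"""Marginal and state-specific life expectancies with simulation CIs.

State-specific expectancies are occupancy-time integrals

    e_rs(x) = int_x^omega P_rs(x, u) du,   r, s in {healthy, unhealthy},

evaluated by the composite trapezoid rule on an age grid, with P built from
the piecewise-constant Gompertz generator (extrapolated beyond the observed
age range up to ``omega_max``).  Marginal expectancies weight the starting
state by the baseline state distribution pi(x, z) from a logistic
(multinomial with two living categories) regression of the baseline state
on age and covariates:

    HLE = pi_1 e_11 + pi_2 e_21,  ULE = pi_1 e_12 + pi_2 e_22,
    TLE = HLE + ULE.

Confidence intervals are percentile intervals across parameter vectors
drawn from the multivariate normal at the MLE (intensity and baseline-state
blocks drawn independently), mirroring the simulation-based CIs of
multistate life-expectancy practice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .intensities import GompertzIntensityParams, _as_z
from .likelihood import FittedModel, _flatten, _unflatten
from .panel import PanelDataset
from .states import HEALTHY, UNHEALTHY

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
@dataclass
class InitialStateModel:
    """Log-odds model of being unhealthy (vs healthy) at baseline.

    ``coef`` is ordered (intercept[, age][, covariates...]); age enters
    centred at ``reference_age``.
    """

    coef: np.ndarray
    cov: Optional[np.ndarray]
    covariates: Tuple[str, ...] = ()
    include_age: bool = True
    reference_age: float = 60.0

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float).ravel()
        self.covariates = tuple(self.covariates)
        expected = 1 + int(self.include_age) + len(self.covariates)
        if self.coef.size != expected:
            raise ValueError(f"coef has length {self.coef.size}, expected {expected}")
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)

    def design_row(self, age: float, z) -> np.ndarray:
        zv = _as_z(z, self.covariates)
        row = [1.0]
        if self.include_age:
            row.append(age - self.reference_age)
        return np.concatenate([row, zv])

    def predict_pi(self, age: float, z) -> Tuple[float, float]:
        """Baseline state distribution (pi_healthy, pi_unhealthy) at ``age``."""
        eta = float(self.design_row(age, z) @ self.coef)
        p2 = 1.0 / (1.0 + math.exp(-eta))
        return 1.0 - p2, p2

    def with_coef(self, coef: np.ndarray) -> "InitialStateModel":
        return InitialStateModel(coef, None, self.covariates,
                                 self.include_age, self.reference_age)

    def to_dict(self) -> Dict:
        return {
            "coef": self.coef.tolist(),
            "cov": None if self.cov is None else self.cov.tolist(),
            "covariates": list(self.covariates),
            "include_age": self.include_age,
            "reference_age": self.reference_age,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "InitialStateModel":
        cov = d.get("cov")
        return cls(np.asarray(d["coef"], dtype=float),
                   None if cov is None else np.asarray(cov, dtype=float),
                   tuple(d.get("covariates", ())),
                   bool(d.get("include_age", True)),
                   float(d.get("reference_age", 60.0)))


def fit_initial_state(dataset: PanelDataset,
                      covariates: Optional[Sequence[str]] = None,
                      include_age: bool = True,
                      reference_age: float = 60.0) -> InitialStateModel:
    """Fit the baseline-state regression on each subject's first observation.

    Uses a multinomial logit (statsmodels MNLogit), which with two living
    categories reduces to binary logistic regression of unhealthy vs
    healthy on centred age and the time-fixed covariates.
    """
    import statsmodels.api as sm

    names = tuple(covariates if covariates is not None else dataset.covariate_names)
    first = dataset.obs.groupby("subject_id", sort=False).first().reset_index()
    if not first["state"].isin((HEALTHY, UNHEALTHY)).all():
        raise ValueError("baseline observations must be living states")
    y = (first["state"] == UNHEALTHY).astype(int).to_numpy()
    cols = [np.ones(len(first))]
    if include_age:
        cols.append(first["age"].to_numpy() - reference_age)
    for name in names:
        cols.append(dataset.covariates.loc[first["subject_id"], name].to_numpy(float))
    X = np.column_stack(cols)
    if y.min() == y.max():
        raise ValueError("baseline states are all identical; cannot fit model")
    try:
        with np.errstate(all="ignore"):
            fit = sm.MNLogit(y, X).fit(disp=False, maxiter=200)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "baseline-state regression failed (likely complete separation: "
            f"{exc}); remove or recode the offending covariate") from exc
    coef = np.asarray(fit.params, dtype=float).ravel()
    if not np.all(np.isfinite(coef)) or np.any(np.abs(coef) > 30):
        raise ValueError(
            "baseline-state regression appears completely separated "
            f"(coefficients {coef}); remove or recode the offending covariate")
    cov = np.asarray(fit.cov_params(), dtype=float)
    return InitialStateModel(coef, cov, names, include_age, reference_age)


# ----------------------------------------------------------------------
@dataclass
class LifeExpectancyEstimate:
    """TLE/HLE/ULE at one age and covariate profile (years)."""

    age: float
    profile: Dict[str, float]
    tle: float
    hle: float
    ule: float
    pct_healthy: float
    ci: Optional[Dict[str, Tuple[float, float]]] = None
    n_sims: int = 0

    def as_dict(self) -> Dict:
        d = {"age": self.age, **{f"z_{k}": v for k, v in self.profile.items()},
             "tle": self.tle, "hle": self.hle, "ule": self.ule,
             "pct_healthy": self.pct_healthy, "n_sims": self.n_sims}
        if self.ci:
            for q, (lo, hi) in self.ci.items():
                d[f"{q}_lo"], d[f"{q}_hi"] = lo, hi
        return d


def estimates_to_frame(estimates: Sequence[LifeExpectancyEstimate]):
    """Tidy frame: one row per age x profile x quantity."""
    import pandas as pd

    rows = []
    for est in estimates:
        for q in ("tle", "hle", "ule"):
            row = {"age": est.age, **{k: v for k, v in est.profile.items()},
                   "quantity": q.upper(), "point": getattr(est, q)}
            if est.ci and q in est.ci:
                row["ci_low"], row["ci_high"] = est.ci[q]
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def _occupancy_batch(beta0, xi, gamma, zv, a0, x, omega_max, step):
    """Occupancy-time matrices for a batch of parameter vectors.

    beta0, xi: (S, 4); gamma: (S, 4, k); returns E of shape (S, 2, 2) with
    E[., r, s] = int_x^omega P_rs(x, u) du (trapezoid on the step grid,
    generator frozen at each subinterval's left endpoint).
    """
    from .intensities import expm_living

    S = beta0.shape[0]
    gz = gamma @ zv if gamma.size else np.zeros((S, 4))
    n = max(int(np.ceil((omega_max - x) / step - 1e-12)), 1)
    P = np.broadcast_to(np.eye(2), (S, 2, 2)).copy()
    E = np.zeros((S, 2, 2))
    age = x
    for _ in range(n):
        dt = min(step, omega_max - age)
        # generator frozen at the subinterval midpoint: second-order in the
        # step, which keeps halving the step below reporting precision
        logq = beta0 + xi * (age + 0.5 * dt - a0) + gz
        # cap log-rates: beyond e^30/y survival is already numerically zero,
        # and the cap keeps extreme CI draws from overflowing
        q = np.exp(np.minimum(logq, 30.0))
        B = np.empty((S, 2, 2))
        B[:, 0, 0] = -(q[:, 0] + q[:, 1])
        B[:, 0, 1] = q[:, 0]
        B[:, 1, 0] = q[:, 2]
        B[:, 1, 1] = -(q[:, 3] + q[:, 2])
        B *= dt
        Pnext = P @ expm_living(B)
        E += 0.5 * dt * (P + Pnext)
        P = Pnext
        age += dt
    return E


def state_specific_le(params: GompertzIntensityParams, x: float, z,
                      omega_max: float = 115.0, step: float = 0.25) -> np.ndarray:
    """2x2 matrix of expected occupancy times e_rs from age ``x`` (years).

    Row r: starting living state; column s: state occupied.  ``omega_max``
    truncates the integral where survival is numerically negligible.
    """
    if omega_max <= x:
        raise ValueError(f"omega_max={omega_max} must exceed x={x}")
    zv = _as_z(z, params.covariates)
    E = _occupancy_batch(params.beta0[None], params.xi[None],
                         params.gamma[None], zv, params.reference_age,
                         float(x), float(omega_max), float(step))
    return E[0]


def _marginal_from_E(E: np.ndarray, pi: Tuple[float, float]):
    hle = pi[0] * E[0, 0] + pi[1] * E[1, 0]
    ule = pi[0] * E[0, 1] + pi[1] * E[1, 1]
    return hle, ule


def marginal_le(params: GompertzIntensityParams, init_model: InitialStateModel,
                x: float, z, omega_max: float = 115.0,
                step: float = 0.25) -> LifeExpectancyEstimate:
    """Point estimate of marginal TLE/HLE/ULE at age ``x`` and profile ``z``.

    The starting-state weights pi are evaluated at age ``x`` itself.
    """
    E = state_specific_le(params, x, z, omega_max, step)
    pi = init_model.predict_pi(x, z)
    hle, ule = _marginal_from_E(E, pi)
    tle = hle + ule
    profile = dict(zip(params.covariates, _as_z(z, params.covariates)))
    return LifeExpectancyEstimate(
        age=x, profile=profile, tle=tle, hle=hle, ule=ule,
        pct_healthy=100.0 * hle / tle if tle > 0 else float("nan"))


def simulate_ci(fitted: FittedModel, init_model: InitialStateModel, x: float,
                z, n_sims: int = 500, seed=None, omega_max: float = 115.0,
                step: float = 0.25) -> LifeExpectancyEstimate:
    """Marginal LEs with percentile CIs from parameter-vector draws.

    ``n_sims`` vectors are drawn from the multivariate normal at the MLE —
    the intensity block from the fitted covariance and the baseline-state
    block from its own covariance, independently — and the marginal LEs
    recomputed per draw; the 2.5th/97.5th percentiles across draws bound
    each quantity.  The point estimate is from the MLE itself.
    """
    if fitted.covariance is None:
        raise ValueError(
            "fitted model has no covariance; use marginal_le for point estimates")
    point = marginal_le(fitted.params, init_model, x, z, omega_max, step)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = fitted._mask()
    mean = _flatten(fitted.params, mask)
    draws = rng.multivariate_normal(mean, fitted.covariance, size=n_sims,
                                    method="svd")
    k = len(fitted.params.covariates)
    beta0 = draws[:, :4]
    xi = draws[:, 4:8]
    gamma = np.zeros((n_sims, 4, k))
    gamma[:, mask] = draws[:, 8:]
    zv = _as_z(z, fitted.params.covariates)
    if init_model.cov is not None:
        init_draws = rng.multivariate_normal(init_model.coef, init_model.cov,
                                             size=n_sims, method="svd")
    else:
        init_draws = np.tile(init_model.coef, (n_sims, 1))
    E = _occupancy_batch(beta0, xi, gamma, zv, fitted.params.reference_age,
                         float(x), float(omega_max), float(step))
    row = init_model.design_row(x, z)
    eta = init_draws @ row
    pi2 = 1.0 / (1.0 + np.exp(-eta))
    hle = (1 - pi2) * E[:, 0, 0] + pi2 * E[:, 1, 0]
    ule = (1 - pi2) * E[:, 0, 1] + pi2 * E[:, 1, 1]
    tle = hle + ule
    ci = {}
    for name, vals in (("tle", tle), ("hle", hle), ("ule", ule)):
        lo, hi = np.percentile(vals, [2.5, 97.5])
        ci[name] = (float(lo), float(hi))
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * hle / tle
    lo, hi = np.percentile(pct, [2.5, 97.5])
    ci["pct_healthy"] = (float(lo), float(hi))
    point.ci = ci
    point.n_sims = n_sims
    return point


def le_trajectory(fitted: Union[FittedModel, GompertzIntensityParams],
                  init_model: InitialStateModel, ages: Sequence[float], z,
                  omega_max: float = 115.0, step: float = 0.25,
                  n_sims: int = 0, seed=None) -> List[LifeExpectancyEstimate]:
    """Marginal LEs over an increasing age sequence (with CIs if n_sims>0)."""
    ages = list(ages)
    if any(b <= a for a, b in zip(ages[:-1], ages[1:])):
        raise ValueError("ages must be strictly increasing")
    out = []
    for age in ages:
        if n_sims > 0 and isinstance(fitted, FittedModel):
            out.append(simulate_ci(fitted, init_model, age, z, n_sims=n_sims,
                                   seed=seed, omega_max=omega_max, step=step))
        else:
            params = fitted.params if isinstance(fitted, FittedModel) else fitted
            out.append(marginal_le(params, init_model, age, z, omega_max, step))
    return out
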