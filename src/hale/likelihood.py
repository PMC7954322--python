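"""Panel likelihood for interval-censored living states with exact deaths.

Each consecutive within-subject pair (t1, r) -> (t2, s) contributes

* s living:  log P_rs(t1, t2)                       (interval censoring)
* s dead:    log sum_u P_ru(t1, t2-) q_u3(t2)       (exact death time)

where P is the piecewise-constant-generator interval probability and the
sum runs over the living states u.  Subjects with a single observation
contribute nothing.  The total log-likelihood is maximised by a BFGS
quasi-Newton search started from crude occupancy rates; the covariance of
the estimates is the inverse of a central-difference numerical Hessian of
the negative log-likelihood at the optimum.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .intensities import (TRANSITIONS, TRANSITION_KEYS, GompertzIntensityParams,
                          _as_z, expm_living)
from .panel import PanelDataset
from .states import DEAD, LIVING_STATES

logger = logging.getLogger(__name__)

_PFLOOR = 1e-300


# ----------------------------------------------------------------------
class _PreparedPanel:
    """Flattened pair/segment arrays for fast repeated likelihood evaluation.

    Segments depend only on the observation ages and the grid step h, so
    they are built once per fit; each evaluation only recomputes rates,
    batched 2x2 exponentials and the ordered per-pair products.
    """

    def __init__(self, dataset: PanelDataset, covariates: Sequence[str],
                 h: float, reference_age: float):
        p = dataset.pairs(covariates)
        self.subject_id = p["subject_id"]
        self.age1 = p["age1"]
        self.state1 = p["state1"]
        self.age2 = p["age2"]
        self.state2 = p["state2"]
        self.z = p["z"]
        self.covariates = p["covariates"]
        self.h = float(h)
        self.a0 = float(reference_age)
        n = len(self.age1)
        self.n_pairs = n

        seg_pair, seg_age, seg_dt, seg_pos = [], [], [], []
        for i in range(n):
            length = self.age2[i] - self.age1[i]
            m = max(int(np.ceil(length / h - 1e-12)), 1)
            starts = self.age1[i] + h * np.arange(m)
            dts = np.minimum(h, self.age2[i] - starts)
            seg_pair.extend([i] * m)
            seg_age.extend(starts)
            seg_dt.extend(dts)
            seg_pos.extend(range(m))
        self.seg_pair = np.asarray(seg_pair, dtype=np.intp)
        self.seg_age = np.asarray(seg_age)
        self.seg_dt = np.asarray(seg_dt)
        seg_pos = np.asarray(seg_pos)
        self.max_pos = int(seg_pos.max()) + 1 if n else 0
        # per grid position: segment rows and the pairs they belong to
        self.pos_rows = [np.flatnonzero(seg_pos == k) for k in range(self.max_pos)]
        self.pos_pairs = [self.seg_pair[rows] for rows in self.pos_rows]
        self.is_death = self.state2 == DEAD
        # centred ages and covariates per segment
        self.seg_x = self.seg_age - self.a0
        self.seg_z = self.z[self.seg_pair]

    # ------------------------------------------------------------------
    def pair_probabilities(self, params: GompertzIntensityParams) -> np.ndarray:
        """Likelihood contribution (probability scale) of every pair."""
        lograte = (params.beta0 + params.xi * self.seg_x[:, None]
                   + self.seg_z @ params.gamma.T)
        q = np.exp(lograte)
        q12, q13, q21, q23 = q.T
        B = np.empty((len(q12), 2, 2))
        B[:, 0, 0] = -(q12 + q13)
        B[:, 0, 1] = q12
        B[:, 1, 0] = q21
        B[:, 1, 1] = -(q21 + q23)
        B *= self.seg_dt[:, None, None]
        M = expm_living(B)
        P = np.broadcast_to(np.eye(2), (self.n_pairs, 2, 2)).copy()
        for rows, pairs in zip(self.pos_rows, self.pos_pairs):
            P[pairs] = P[pairs] @ M[rows]
        r = self.state1 - 1
        idx = np.arange(self.n_pairs)
        prob = np.empty(self.n_pairs)
        living = ~self.is_death
        prob[living] = P[idx[living], r[living], self.state2[living] - 1]
        if self.is_death.any():
            d = idx[self.is_death]
            logr_d = (params.beta0 + params.xi * (self.age2[d, None] - self.a0)
                      + self.z[d] @ params.gamma.T)
            qd = np.exp(logr_d)  # columns: q12, q13, q21, q23 at death age
            prob[d] = (P[d, r[d], 0] * qd[:, 1] + P[d, r[d], 1] * qd[:, 3])
        return prob

    def loglik(self, params: GompertzIntensityParams,
               on_zero: str = "raise") -> float:
        prob = self.pair_probabilities(params)
        if on_zero == "raise" and np.any(prob <= 0):
            bad = np.flatnonzero(prob <= 0)[:5]
            pairs = [(self.subject_id[i], float(self.age1[i]), int(self.state1[i]),
                      float(self.age2[i]), int(self.state2[i])) for i in bad]
            raise ValueError(f"zero-probability pairs (subject, t1, r, t2, s): {pairs}")
        return float(np.log(np.maximum(prob, _PFLOOR)).sum())


# ----------------------------------------------------------------------
def subject_loglik(observations, params: GompertzIntensityParams, z,
                   h: float = 1.0) -> float:
    """Log-likelihood contribution of one subject.

    ``observations`` is a sequence of (age, state) in age order; ``z`` the
    subject's covariate profile.  A single-observation subject contributes
    0 (with a warning).
    """
    obs = [(float(a), int(s)) for a, s in observations]
    if len(obs) < 2:
        warnings.warn("single-observation subject contributes 0 to the likelihood")
        return 0.0
    zv = _as_z(z, params.covariates)
    total = 0.0
    from .intensities import living_transition_matrix  # local to avoid cycle noise
    for (t1, r), (t2, s) in zip(obs[:-1], obs[1:]):
        if r not in LIVING_STATES or t2 <= t1:
            raise ValueError(f"invalid pair ({t1},{r})->({t2},{s})")
        PLL = living_transition_matrix(params, t1, t2, zv, h)
        if s in LIVING_STATES:
            p = PLL[r - 1, s - 1]
        elif s == DEAD:
            qd = params.rates(t2, zv)
            p = PLL[r - 1, 0] * qd[1] + PLL[r - 1, 1] * qd[3]
        else:
            raise ValueError(f"unknown state {s}")
        if p <= 0:
            raise ValueError(
                f"zero-probability pair ({t1},{r})->({t2},{s}) at the given parameters")
        total += math.log(p)
    return total


def total_loglik(dataset: PanelDataset, params: GompertzIntensityParams,
                 h: float = 1.0) -> float:
    """Sum of subject log-likelihood contributions over the panel."""
    prep = _PreparedPanel(dataset, params.covariates, h, params.reference_age)
    return prep.loglik(params)


# ----------------------------------------------------------------------
def crude_init(dataset: PanelDataset, covariates: Sequence[str] = (),
               reference_age: float = 60.0) -> GompertzIntensityParams:
    """Crude occupancy-rate starting values.

    beta0_rs = log(count of r->s moves / person-years observed leaving
    state r), with unobserved transitions floored at 0.5 events; age slopes
    and covariate effects start at zero.
    """
    p = dataset.pairs(())
    exposure = {1: 0.0, 2: 0.0}
    for r in LIVING_STATES:
        sel = p["state1"] == r
        exposure[r] = float((p["age2"][sel] - p["age1"][sel]).sum())
    total_exposure = exposure[1] + exposure[2]
    if total_exposure <= 0:
        raise ValueError("no person-years at risk in the panel")
    counts = dataset.transition_counts()
    beta0 = np.empty(4)
    for i, (r, s) in enumerate(TRANSITIONS):
        # a state never observed as origin still needs a finite start value
        py = exposure[r] if exposure[r] > 0 else total_exposure
        c = counts[r - 1, s - 1]
        if c == 0:
            logger.info("no %d->%d transitions observed; flooring initial rate", r, s)
            c = 0.5
        beta0[i] = math.log(c / py)
    covariates = tuple(covariates)
    return GompertzIntensityParams(beta0, np.zeros(4),
                                   np.zeros((4, len(covariates))),
                                   covariates, reference_age)


# ----------------------------------------------------------------------
@dataclass
class FittedModel:
    """Maximum-likelihood fit of the Gompertz illness-death model."""

    params: GompertzIntensityParams
    loglik: float
    covariance: Optional[np.ndarray]
    converged: bool
    n_subjects: int
    n_transitions: int
    param_names: Tuple[str, ...]
    grad_norm: float = float("nan")
    n_iter: int = 0
    h: float = 1.0

    def param_vector(self) -> np.ndarray:
        return _flatten(self.params, self._mask())

    def _mask(self) -> np.ndarray:
        k = len(self.params.covariates)
        mask = np.zeros((4, k), dtype=bool)
        for name in self.param_names:
            parts = name.split(".")
            if len(parts) == 3:
                i = TRANSITION_KEYS.index(parts[0])
                mask[i, self.params.covariates.index(parts[2])] = True
        return mask

    def param_se(self, name: str) -> Optional[float]:
        if self.covariance is None or name not in self.param_names:
            return None
        i = self.param_names.index(name)
        v = self.covariance[i, i]
        return math.sqrt(v) if v >= 0 else None

    def wald_ci(self, name: str, level: float = 0.95) -> Optional[Tuple[float, float]]:
        se = self.param_se(name)
        if se is None:
            return None
        from scipy.stats import norm
        i = self.param_names.index(name)
        est = self.param_vector()[i]
        half = norm.ppf(0.5 + level / 2) * se
        return est - half, est + half

    def to_dict(self) -> Dict:
        return {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "covariance": None if self.covariance is None
            else self.covariance.tolist(),
            "converged": bool(self.converged),
            "n_subjects": self.n_subjects,
            "n_transitions": self.n_transitions,
            "param_names": list(self.param_names),
            "grad_norm": self.grad_norm,
            "n_iter": self.n_iter,
            "h": self.h,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Dict) -> "FittedModel":
        cov = d.get("covariance")
        return cls(
            params=GompertzIntensityParams.from_dict(d["params"]),
            loglik=float(d["loglik"]),
            covariance=None if cov is None else np.asarray(cov, dtype=float),
            converged=bool(d["converged"]),
            n_subjects=int(d["n_subjects"]),
            n_transitions=int(d["n_transitions"]),
            param_names=tuple(d["param_names"]),
            grad_norm=float(d.get("grad_norm", float("nan"))),
            n_iter=int(d.get("n_iter", 0)),
            h=float(d.get("h", 1.0)),
        )

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ----------------------------------------------------------------------
def _param_names(covariates: Tuple[str, ...], mask: np.ndarray) -> Tuple[str, ...]:
    names = [f"{k}.beta0" for k in TRANSITION_KEYS]
    names += [f"{k}.xi" for k in TRANSITION_KEYS]
    for i, k in enumerate(TRANSITION_KEYS):
        for j, c in enumerate(covariates):
            if mask[i, j]:
                names.append(f"{k}.gamma.{c}")
    return tuple(names)


def _flatten(params: GompertzIntensityParams, mask: np.ndarray) -> np.ndarray:
    return np.concatenate([params.beta0, params.xi, params.gamma[mask]])


def _unflatten(vec: np.ndarray, template: GompertzIntensityParams,
               mask: np.ndarray) -> GompertzIntensityParams:
    gamma = np.zeros_like(template.gamma)
    gamma[mask] = vec[8:]
    return GompertzIntensityParams(vec[:4].copy(), vec[4:8].copy(), gamma,
                                   template.covariates, template.reference_age)


def _numerical_hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of ``fun`` at ``x``."""
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / step ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * step ** 2)
    return H


def fit_mle(
    dataset: PanelDataset,
    covariates: Sequence[str] = (),
    h: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    init: Optional[GompertzIntensityParams] = None,
    covariate_mask: Optional[Mapping[Tuple[int, int], Sequence[str]]] = None,
    reference_age: float = 60.0,
    hessian_step: float = 1e-4,
    compute_covariance: bool = True,
    seed: Optional[int] = None,
    n_restarts: int = 0,
) -> "FittedModel":
    """Maximise the panel likelihood; quasi-Newton (BFGS) from crude rates.

    ``covariates`` enter every allowed transition unless ``covariate_mask``
    restricts, per transition, which covariates carry an effect.  The
    covariance is the inverse numerical Hessian of the negative
    log-likelihood; when the Hessian is singular the covariance is absent
    and a warning is issued.  ``n_restarts`` > 0 adds seed-controlled
    random restarts around the crude start for flat likelihoods.
    """
    covariates = tuple(covariates)
    k = len(covariates)
    if covariate_mask is None:
        mask = np.ones((4, k), dtype=bool)
    else:
        mask = np.zeros((4, k), dtype=bool)
        for t, names in covariate_mask.items():
            for name in names:
                mask[TRANSITIONS.index(t), covariates.index(name)] = True
    if init is None:
        init = crude_init(dataset, covariates, reference_age)
    prep = _PreparedPanel(dataset, covariates, h, reference_age)
    if prep.n_pairs == 0:
        raise ValueError("dataset contains no observation pairs")

    def nll(vec: np.ndarray) -> float:
        if not np.all(np.isfinite(vec)):
            return 1e12
        p = _unflatten(vec, init, mask)
        return -prep.loglik(p, on_zero="floor")

    x0s = [_flatten(init, mask)]
    if n_restarts:
        rng = np.random.default_rng(seed)
        x0s += [x0s[0] + rng.normal(scale=0.5, size=x0s[0].shape)
                for _ in range(n_restarts)]

    best = None
    for x0 in x0s:
        res = optimize.minimize(
            nll, x0, method="BFGS",
            options={"gtol": tol, "maxiter": max_iter},
            callback=lambda xk: logger.debug("loglik %.6f", -nll(xk)),
        )
        if best is None or res.fun < best.fun:
            best = res
    res = best
    grad_norm = float(np.linalg.norm(res.jac)) if res.jac is not None else float("nan")
    converged = bool(res.success) or grad_norm < 10 * tol * max(1.0, abs(res.fun))
    if not converged:
        logger.warning("optimiser did not converge: %s", res.message)
    params = _unflatten(res.x, init, mask)

    cov = None
    if compute_covariance:
        H = _numerical_hessian(nll, res.x, hessian_step)
        try:
            cov = np.linalg.inv(H)
            cov = 0.5 * (cov + cov.T)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError("non-positive variances")
        except np.linalg.LinAlgError:
            warnings.warn("singular or indefinite Hessian; covariance unavailable")
            cov = None

    return FittedModel(
        params=params,
        loglik=-float(res.fun),
        covariance=cov,
        converged=converged,
        n_subjects=dataset.n_subjects,
        n_transitions=prep.n_pairs,
        param_names=_param_names(covariates, mask),
        grad_norm=grad_norm,
        n_iter=int(res.nit),
        h=h,
    )
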