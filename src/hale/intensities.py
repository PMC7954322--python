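"""Gompertz transition intensities and interval transition probabilities.

Each allowed transition (r, s) of the illness-death-with-recovery structure
{(1,2), (1,3), (2,1), (2,3)} has instantaneous intensity

    q_rs(x, z) = exp(beta0_rs + xi_rs * (x - a0) + gamma_rs . z)

i.e. a Gompertz (log-linear) age dependence with proportional covariate
effects, age centred at a reference a0 (default 60 y).  Interval transition
probabilities P(x, y) are obtained by freezing the generator at the start of
each subinterval of a grid of step h (piecewise-constant approximation) and
multiplying the subinterval matrix exponentials in age order.

The 2x2 living-state block of an illness-death generator always has real,
non-positive eigenvalues, so its exponential has a closed spectral form;
``expm_living`` evaluates it vectorised over a batch of blocks.  This is the
work-horse of the likelihood and of life-expectancy integration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .states import TRANSITIONS

TRANSITION_KEYS = tuple(f"q{r}{s}" for r, s in TRANSITIONS)
_TIDX = {t: i for i, t in enumerate(TRANSITIONS)}


def _as_z(z, covariates: Tuple[str, ...]) -> np.ndarray:
    """Coerce a covariate profile (mapping or sequence) to a float vector."""
    if z is None:
        z = {}
    if isinstance(z, Mapping):
        return np.array([float(z.get(name, 0.0)) for name in covariates])
    z = np.asarray(z, dtype=float).ravel()
    if z.size != len(covariates):
        raise ValueError(
            f"covariate vector of length {z.size}, expected {len(covariates)}"
        )
    return z


@dataclass
class GompertzIntensityParams:
    """Per-transition Gompertz parameters with covariate log-hazard-ratios.

    Arrays are ordered like :data:`hale.states.TRANSITIONS`:
    (1→2, 1→3, 2→1, 2→3).  ``gamma`` has one column per covariate name.
    """

    beta0: np.ndarray
    xi: np.ndarray
    gamma: np.ndarray
    covariates: Tuple[str, ...] = ()
    reference_age: float = 60.0

    def __post_init__(self):
        self.beta0 = np.asarray(self.beta0, dtype=float).reshape(4)
        self.xi = np.asarray(self.xi, dtype=float).reshape(4)
        k = len(self.covariates)
        self.covariates = tuple(self.covariates)
        self.gamma = np.asarray(self.gamma, dtype=float).reshape(4, k)
        for name, arr in (("beta0", self.beta0), ("xi", self.xi),
                          ("gamma", self.gamma)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")

    # -- construction helpers ------------------------------------------
    @classmethod
    def from_rates(cls, rates: Mapping[Tuple[int, int], float],
                   xi: Union[float, Mapping[Tuple[int, int], float]] = 0.0,
                   gamma: Optional[Mapping[Tuple[int, int], Mapping[str, float]]] = None,
                   covariates: Sequence[str] = (),
                   reference_age: float = 60.0) -> "GompertzIntensityParams":
        """Build from per-transition rates at the reference age."""
        beta0 = np.array([math.log(rates.get(t, 1e-12)) for t in TRANSITIONS])
        if isinstance(xi, Mapping):
            xi_arr = np.array([float(xi.get(t, 0.0)) for t in TRANSITIONS])
        else:
            xi_arr = np.full(4, float(xi))
        covariates = tuple(covariates)
        g = np.zeros((4, len(covariates)))
        if gamma:
            for t, effs in gamma.items():
                for name, val in effs.items():
                    g[_TIDX[t], covariates.index(name)] = float(val)
        return cls(beta0, xi_arr, g, covariates, reference_age)

    # -- evaluation ----------------------------------------------------
    def log_rates(self, age, z) -> np.ndarray:
        """Log-intensities of the four allowed transitions at ``age``."""
        zv = _as_z(z, self.covariates)
        age = np.asarray(age, dtype=float)
        return (self.beta0 + self.xi * (age[..., None] - self.reference_age)
                + self.gamma @ zv)

    def rates(self, age, z) -> np.ndarray:
        return np.exp(self.log_rates(age, z))

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> Dict:
        d: Dict = {"reference_age": self.reference_age,
                   "covariates": list(self.covariates)}
        for i, key in enumerate(TRANSITION_KEYS):
            d[f"{key}.beta0"] = float(self.beta0[i])
            d[f"{key}.xi"] = float(self.xi[i])
            for j, name in enumerate(self.covariates):
                d[f"{key}.gamma.{name}"] = float(self.gamma[i, j])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GompertzIntensityParams":
        covariates = tuple(d.get("covariates", ()))
        beta0 = [d[f"{k}.beta0"] for k in TRANSITION_KEYS]
        xi = [d[f"{k}.xi"] for k in TRANSITION_KEYS]
        gamma = [[d.get(f"{k}.gamma.{name}", 0.0) for name in covariates]
                 for k in TRANSITION_KEYS]
        return cls(np.array(beta0), np.array(xi), np.array(gamma),
                   covariates, float(d.get("reference_age", 60.0)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GompertzIntensityParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def copy_with(self, **kw) -> "GompertzIntensityParams":
        return replace(self, **kw)


# ----------------------------------------------------------------------
def intensity_matrix(params: GompertzIntensityParams, age: float, z) -> np.ndarray:
    """3x3 generator Q(age, z): off-diagonals the allowed intensities,
    diagonal minus the row sum, absorbing third row identically zero."""
    q12, q13, q21, q23 = params.rates(float(age), z)
    return np.array([
        [-(q12 + q13), q12, q13],
        [q21, -(q21 + q23), q23],
        [0.0, 0.0, 0.0],
    ])


def living_block(params: GompertzIntensityParams, age, z) -> np.ndarray:
    """2x2 living-state sub-generator at ``age`` (batched over age)."""
    q = params.rates(age, z)
    q12, q13, q21, q23 = np.moveaxis(q, -1, 0)
    B = np.empty(q12.shape + (2, 2))
    B[..., 0, 0] = -(q12 + q13)
    B[..., 0, 1] = q12
    B[..., 1, 0] = q21
    B[..., 1, 1] = -(q21 + q23)
    return B


def expm_living(B: np.ndarray) -> np.ndarray:
    """Closed-form exponentials of a batch of 2x2 living-state blocks.

    For B = dt * Q_LL the discriminant (b11-b22)^2 + 4 b12 b21 is
    non-negative (off-diagonals are >= 0), so the eigenvalues l1 >= l2 are
    real and expm(B) = e^{l2} I + phi (B - l2 I) with the divided
    difference phi = (e^{l1} - e^{l2})/(l1 - l2), evaluated by series when
    the eigenvalues nearly coincide.
    """
    B = np.asarray(B, dtype=float)
    a = B[..., 0, 0]
    b = B[..., 0, 1]
    c = B[..., 1, 0]
    d = B[..., 1, 1]
    tr = a + d
    s = np.sqrt(np.maximum((a - d) ** 2 + 4.0 * b * c, 0.0))
    l1 = 0.5 * (tr + s)
    l2 = 0.5 * (tr - s)
    e1 = np.exp(l1)
    e2 = np.exp(l2)
    small = s < 1e-8
    safe = np.where(small, 1.0, s)
    # series for (e^{l1}-e^{l2})/(l1-l2) around s -> 0
    phi = np.where(small, e2 * (1.0 + 0.5 * s + s * s / 6.0), (e1 - e2) / safe)
    out = np.zeros_like(B)
    out[..., 0, 0] = e2 + phi * (a - l2)
    out[..., 0, 1] = phi * b
    out[..., 1, 0] = phi * c
    out[..., 1, 1] = e2 + phi * (d - l2)
    return out


def _segments(x: float, y: float, h: float) -> Tuple[np.ndarray, np.ndarray]:
    """Left endpoints and lengths of the piecewise-constant grid on [x, y]."""
    if h <= 0:
        raise ValueError("grid step h must be positive")
    length = y - x
    n = max(int(np.ceil(length / h - 1e-12)), 0)
    starts = x + h * np.arange(n)
    dts = np.minimum(h, y - starts)
    return starts, dts


def living_transition_matrix(params: GompertzIntensityParams, x: float,
                             y: float, z, h: float = 1.0) -> np.ndarray:
    """2x2 matrix of P(alive in state s at y | state r at x) for r, s living."""
    if y < x:
        raise ValueError(f"require x <= y, got x={x}, y={y}")
    starts, dts = _segments(float(x), float(y), float(h))
    if starts.size == 0:
        return np.eye(2)
    B = living_block(params, starts, z) * dts[:, None, None]
    mats = expm_living(B)
    P = np.eye(2)
    for M in mats:
        P = P @ M
    return P


def transition_probability(params: GompertzIntensityParams, x: float, y: float,
                           z, h: float = 1.0) -> np.ndarray:
    """3x3 interval transition-probability matrix P(x, y) under profile z.

    The interval is split into subintervals of length <= h; on each the
    generator is frozen at the subinterval's start age and the matrix
    exponentials are multiplied in age order.  Rows are stochastic; the
    third (dead) row is the identity row.
    """
    PLL = living_transition_matrix(params, x, y, z, h)
    PLL = np.clip(PLL, 0.0, 1.0)
    P = np.zeros((3, 3))
    P[:2, :2] = PLL
    P[:2, 2] = np.clip(1.0 - PLL.sum(axis=1), 0.0, 1.0)
    P[2, 2] = 1.0
    return P


def hazard_ratio(source, transition: Tuple[int, int], covariate: str,
                 se: Optional[float] = None):
    """Hazard ratio exp(gamma) of a covariate on one transition.

    ``source`` may be a :class:`GompertzIntensityParams` or a fitted model
    exposing ``params`` and ``covariance``/``param_names``; a 95% Wald CI is
    returned when a standard error is available (else ``None``).
    """
    params = getattr(source, "params", source)
    if transition not in _TIDX:
        raise ValueError(f"transition {transition} not allowed")
    if covariate not in params.covariates:
        raise ValueError(f"unknown covariate {covariate!r}")
    i, j = _TIDX[transition], params.covariates.index(covariate)
    g = params.gamma[i, j]
    if se is None and hasattr(source, "param_se"):
        se = source.param_se(f"q{transition[0]}{transition[1]}.gamma.{covariate}")
    hr = math.exp(g)
    if se is None:
        return hr, None
    half = 1.959963984540054 * se
    return hr, (math.exp(g - half), math.exp(g + half))
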