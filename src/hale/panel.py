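"""Interval-censored ageing-panel data: container, validation and I/O.

A panel records, per subject, the living health state at each survey wave
(interval-censored: the transition time between waves is unknown) and, when
the subject died between waves, a final record at the exact death age.
Covariates are time-fixed at baseline.

Canonical long format (CSV/TSV), one row per subject per observation::

    subject_id, age, state, sex, edu, part[, wave][, exact]

with ``state`` coded 1 = healthy, 2 = unhealthy, 3 = dead and ``exact`` true
exactly for death rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .states import ALL_STATES, DEAD, LIVING_STATES

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("subject_id", "age", "state")
DEFAULT_COVARIATES = ("sex", "edu", "part")
_MISSING_TOKENS = ["N/R", "N/A", "NR", "NA", "n/r", "n/a", ""]


class PanelValidationError(ValueError):
    """Raised when a panel violates the model's structural assumptions.

    Attributes
    ----------
    subjects : list
        Identifiers of the offending subjects.
    """

    def __init__(self, message: str, subjects: Sequence = ()):  # noqa: D107
        super().__init__(message)
        self.subjects = list(subjects)


@dataclass
class PanelDataset:
    """Validated long-format panel with one covariate profile per subject.

    ``obs`` holds columns ``subject_id, age, state`` (plus optional ``wave``
    and ``exact``), sorted by subject and age; ``covariates`` is indexed by
    subject id.
    """

    obs: pd.DataFrame
    covariates: pd.DataFrame
    min_age: Optional[float] = 60.0
    report: Dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @classmethod
    def from_frames(
        cls,
        obs: pd.DataFrame,
        covariates: pd.DataFrame,
        min_age: Optional[float] = 60.0,
        validate: bool = True,
    ) -> "PanelDataset":
        obs = obs.copy()
        obs["subject_id"] = obs["subject_id"].astype(str)
        obs["age"] = obs["age"].astype(float)
        obs["state"] = obs["state"].astype(int)
        # row order within subject is the observation sequence (wave order
        # when given); ages are then validated as strictly increasing rather
        # than silently re-sorted
        if "wave" in obs.columns:
            obs = obs.sort_values(["wave"], kind="stable")
        obs = obs.sort_values(["subject_id"], kind="stable").reset_index(drop=True)
        covariates = covariates.copy()
        covariates.index = covariates.index.astype(str)
        ds = cls(obs=obs, covariates=covariates, min_age=min_age)
        if validate:
            ds.validate()
        return ds

    # ------------------------------------------------------------------
    def validate(self) -> Dict:
        """Check structural invariants; raise PanelValidationError on failure."""
        obs = self.obs
        bad_state = sorted(
            obs.loc[~obs["state"].isin(ALL_STATES), "subject_id"].unique()
        )
        if bad_state:
            raise PanelValidationError(
                f"unknown state codes for subjects {bad_state}", bad_state
            )
        non_monotone, post_death, young, incons = [], [], [], []
        for sid, g in obs.groupby("subject_id", sort=False):
            ages = g["age"].to_numpy()
            states = g["state"].to_numpy()
            if len(ages) > 1 and not np.all(np.diff(ages) > 0):
                non_monotone.append(sid)
            dead_idx = np.flatnonzero(states == DEAD)
            if dead_idx.size and (dead_idx.size > 1 or dead_idx[0] != len(states) - 1):
                post_death.append(sid)
            if self.min_age is not None and ages[0] < self.min_age - 1e-9:
                young.append(sid)
            if "exact" in g.columns:
                ex = g["exact"].astype(bool).to_numpy()
                if np.any(ex != (states == DEAD)):
                    incons.append(sid)
        problems = []
        for label, subjects in (
            ("non-monotone ages", non_monotone),
            ("records at or after death", post_death),
            (f"first observation below age floor {self.min_age}", young),
            ("exact flag inconsistent with state", incons),
        ):
            if subjects:
                problems.append((label, subjects))
        if problems:
            msg = "; ".join(f"{lab}: subjects {subj}" for lab, subj in problems)
            raise PanelValidationError("invalid panel: " + msg,
                                       sorted({s for _, ss in problems for s in ss}))
        missing_cov = sorted(
            set(obs["subject_id"].unique()) - set(self.covariates.index)
        )
        if missing_cov:
            raise PanelValidationError(
                f"subjects without covariate profile: {missing_cov}", missing_cov
            )
        self.report.update(
            n_subjects=int(obs["subject_id"].nunique()),
            n_observations=int(len(obs)),
            n_deaths=int((obs["state"] == DEAD).sum()),
        )
        return self.report

    # ------------------------------------------------------------------
    @property
    def covariate_names(self) -> Tuple[str, ...]:
        return tuple(self.covariates.columns)

    @property
    def n_subjects(self) -> int:
        return int(self.obs["subject_id"].nunique())

    def subject_ids(self) -> List[str]:
        return list(dict.fromkeys(self.obs["subject_id"]))

    # ------------------------------------------------------------------
    def pairs(self, covariates: Optional[Sequence[str]] = None):
        """Consecutive observation pairs as flat arrays for the likelihood.

        Returns a dict with arrays ``age1, state1, age2, state2`` over all
        consecutive within-subject pairs, the per-pair covariate matrix
        ``z`` (n_pairs x k) and the pair's ``subject_id``.
        """
        names = list(covariates if covariates is not None else self.covariate_names)
        sid = self.obs["subject_id"].to_numpy()
        age = self.obs["age"].to_numpy()
        state = self.obs["state"].to_numpy()
        same = sid[1:] == sid[:-1]
        i1 = np.flatnonzero(same)
        zfull = self.covariates.loc[sid[i1], names].to_numpy(float) if names else \
            np.zeros((len(i1), 0))
        return {
            "subject_id": sid[i1],
            "age1": age[i1],
            "state1": state[i1].astype(int),
            "age2": age[i1 + 1],
            "state2": state[i1 + 1].astype(int),
            "z": zfull,
            "covariates": tuple(names),
        }

    # ------------------------------------------------------------------
    def transition_counts(self) -> np.ndarray:
        """3x3 matrix of observed consecutive-pair movements r -> s."""
        p = self.pairs(covariates=())
        counts = np.zeros((3, 3), dtype=int)
        np.add.at(counts, (p["state1"] - 1, p["state2"] - 1), 1)
        return counts

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Single canonical long-format frame (observations + covariates)."""
        out = self.obs.copy()
        if "exact" not in out.columns:
            out["exact"] = (out["state"] == DEAD).astype(int)
        else:
            out["exact"] = out["exact"].astype(int)
        for name in self.covariate_names:
            out[name] = self.covariates.loc[out["subject_id"], name].to_numpy()
        return out

    def write(self, path) -> None:
        """Write the validated canonical CSV (or TSV by extension)."""
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        self.to_frame().to_csv(path, sep=sep, index=False)

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report, fh, indent=2)


# ----------------------------------------------------------------------
def load_panel(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    min_age: Optional[float] = 60.0,
    proxy_col: Optional[str] = None,
    sep: Optional[str] = None,
) -> PanelDataset:
    """Read and validate a long-format panel CSV/TSV.

    ``column_map`` maps canonical names (``subject_id``, ``age``, ``state``,
    covariate names, optionally ``wave``/``exact``) to the file's actual
    headers.  Subjects with any missing covariate value (tokens like
    ``N/R``/``N/A`` or empty) are dropped with a logged count; subjects
    flagged in ``proxy_col`` (proxy respondents) are dropped before
    validation.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, na_values=_MISSING_TOKENS,
                     keep_default_na=True, skipinitialspace=True)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing_cols = [c for c in (*CANONICAL_COLUMNS, *covariates) if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"missing required columns: {missing_cols}")
    df["subject_id"] = df["subject_id"].astype(str)

    report: Dict = {}
    if proxy_col is not None and proxy_col in df.columns:
        proxy_subjects = df.loc[df[proxy_col].fillna(0).astype(float) > 0,
                                "subject_id"].unique()
        report["n_proxy_dropped"] = int(len(proxy_subjects))
        df = df[~df["subject_id"].isin(proxy_subjects)]
        if len(proxy_subjects):
            logger.info("dropped %d proxy-respondent subjects", len(proxy_subjects))

    essential = df[["age", "state"]].isna().any(axis=1)
    if essential.any():
        bad = sorted(df.loc[essential, "subject_id"].unique())
        raise PanelValidationError(f"missing age/state for subjects {bad}", bad)

    cov_first = df.groupby("subject_id", sort=False)[list(covariates)].first()
    cov_nunique = df.groupby("subject_id", sort=False)[list(covariates)].nunique(
        dropna=True)
    varying = sorted(cov_nunique.index[(cov_nunique > 1).any(axis=1)])
    if varying:
        raise PanelValidationError(
            f"covariates not constant within subjects {varying}", varying
        )
    incomplete = cov_first.index[cov_first.isna().any(axis=1)]
    report["n_dropped_missing_covariates"] = int(len(incomplete))
    if len(incomplete):
        logger.info("dropped %d subjects with missing covariates", len(incomplete))
        df = df[~df["subject_id"].isin(incomplete)]
        cov_first = cov_first.drop(index=incomplete)
    if df.empty:
        raise PanelValidationError("no subjects remain after filtering")

    keep = ["subject_id", "age", "state"] + [c for c in ("wave", "exact")
                                             if c in df.columns]
    ds = PanelDataset.from_frames(df[keep], cov_first.astype(float), min_age=min_age)
    ds.report.update(report)
    return ds


def transition_counts(dataset: PanelDataset) -> np.ndarray:
    """Module-level alias for :meth:`PanelDataset.transition_counts`."""
    return dataset.transition_counts()
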