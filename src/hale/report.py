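"""Reporting helpers: healthy-years shares, group contrasts, grouped tables.

Derived numbers are computed on unrounded values and rounded only for
display (years to 2 decimals in tables, differences and percentages to
1 decimal in prose-style output), which is the convention that reproduces
published summaries from their underlying point estimates.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expectancy import LifeExpectancyEstimate

QUANTITIES = ("tle", "hle", "ule")


def percent_healthy(tle: float, hle: float, decimals: int = 1) -> float:
    """Share of remaining life expected in good health, 100*HLE/TLE (%)."""
    if tle <= 0:
        raise ValueError("TLE must be positive")
    if hle < 0 or hle > tle + 1e-9:
        raise ValueError("HLE must lie in [0, TLE]")
    return round(100.0 * hle / tle, decimals)


def group_difference(est_a: LifeExpectancyEstimate, est_b: LifeExpectancyEstimate,
                     quantity: str = "tle", decimals: int = 1) -> float:
    """Point difference a − b in years for one quantity, at matching ages."""
    if quantity.lower() not in QUANTITIES:
        raise ValueError(f"quantity must be one of {QUANTITIES}")
    if est_a.age != est_b.age:
        raise ValueError(f"age mismatch: {est_a.age} vs {est_b.age}")
    q = quantity.lower()
    return round(getattr(est_a, q) - getattr(est_b, q), decimals)


def significance_marker(draws_a: np.ndarray, draws_b: np.ndarray,
                        levels: Tuple[float, float] = (0.05, 0.10)
                        ) -> Optional[str]:
    """Two-sided simulation-overlap test between two sets of draws.

    Pairs the draws by index, computes p = 2 min(P(a>b), P(a<b)) and
    returns 'a' below the first level, 'b' below the second, else None.
    The marker method is a documented convention, not an exact test.
    """
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    n = min(len(a), len(b))
    d = a[:n] - b[:n]
    p = 2.0 * min((d > 0).mean(), (d < 0).mean())
    if p < levels[0]:
        return "a"
    if p < levels[1]:
        return "b"
    return None


def build_le_table(
    estimates: Mapping[str, Mapping[str, LifeExpectancyEstimate]],
    age: float = 60.0,
) -> pd.DataFrame:
    """Grouped LE table: rows (group x quantity), columns per stratum.

    ``estimates`` maps a group label (e.g. a dataset/country tag) to a
    mapping of stratum label (e.g. "men"/"women") to its estimate at
    ``age``.  Missing strata produce labelled gaps (NaN), not failure.
    The healthy-years share is recomputed from the row's unrounded values.
    """
    strata: list = []
    for group in estimates.values():
        for s in group:
            if s not in strata:
                strata.append(s)
    rows = []
    for gname, group in estimates.items():
        for q in QUANTITIES:
            row: Dict = {"group": gname, "quantity": q.upper()}
            for s in strata:
                est = group.get(s)
                if est is None:
                    row[f"{s}_point"] = np.nan
                    continue
                if est.age != age:
                    raise ValueError(
                        f"estimate for {gname}/{s} is at age {est.age}, not {age}")
                row[f"{s}_point"] = round(getattr(est, q), 2)
                if est.ci and q in est.ci:
                    lo, hi = est.ci[q]
                    row[f"{s}_ci_low"] = round(lo, 2)
                    row[f"{s}_ci_high"] = round(hi, 2)
                if q == "tle":
                    row[f"{s}_pct_healthy"] = percent_healthy(est.tle, est.hle)
            rows.append(row)
    return pd.DataFrame(rows)


def format_le_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a grouped LE table."""
    return table.to_string(index=False, na_rep="-")


def write_le_table(table: pd.DataFrame, path) -> None:
    if str(path).endswith(".csv"):
        table.to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            fh.write(format_le_table(table) + "\n")
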