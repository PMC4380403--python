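"""Monthly climate -> seasonal aggregates, lapse correction, screening.

Monthly precipitation is pooled by summation and temperatures by
arithmetic mean over fixed month windows: Annual (Jan-Dec),
hydrological year ``Hyd`` (Oct of the previous year-Sep), growing
season ``Grow`` (Apr-Sep), ``Spr`` (Mar-May), ``Sum`` (Jun-Aug),
``MJJ`` (May-Jul), ``JJ`` (Jun-Jul), ``Aut`` (Sep-Nov) and ``Win``
(Dec of the previous year-Feb).  A pool value is reported only when
every member month is present — no silent partial sums.

Candidate covariates are screened against a BAI chronology with the
tie-corrected Kendall tau-b rank correlation (BAI distributions are
skewed, so a nonparametric measure is used); screening is advisory and
the fitted covariates remain an explicit modelling choice.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

__all__ = ["POOLS", "aggregate_climate", "lapse_correct", "kendall_screen"]

#: pool name -> list of (year offset, month number)
POOLS: dict[str, list[tuple[int, int]]] = {
    "Annual": [(0, m) for m in range(1, 13)],
    "Hyd": [(-1, m) for m in (10, 11, 12)] + [(0, m) for m in range(1, 10)],
    "Grow": [(0, m) for m in range(4, 10)],
    "Spr": [(0, m) for m in (3, 4, 5)],
    "Sum": [(0, m) for m in (6, 7, 8)],
    "MJJ": [(0, m) for m in (5, 6, 7)],
    "JJ": [(0, m) for m in (6, 7)],
    "Aut": [(0, m) for m in (9, 10, 11)],
    "Win": [(-1, 12), (0, 1), (0, 2)],
}

_TEMP_PREFIX = {"tmean": "Tmean", "tmax": "Tmax", "tmin": "Tmin"}


def aggregate_climate(monthly: pd.DataFrame) -> pd.DataFrame:
    """Seasonal aggregates per year from a monthly climate table.

    Parameters
    ----------
    monthly : DataFrame
        Columns ``year``, ``month``, ``prec`` and any of ``tmean``,
        ``tmax``, ``tmin``.

    Returns
    -------
    DataFrame indexed by year with columns ``P_<pool>`` (mm, summed)
    and ``T<var>_<pool>`` (degC, averaged); NaN where a member month is
    missing (including previous-year months for Hyd/Win in the first
    year of record).
    """
    req = {"year", "month", "prec"}
    if not req <= set(monthly.columns):
        raise ValueError(f"monthly climate needs columns {sorted(req)}")
    if monthly.duplicated(["year", "month"]).any():
        raise ValueError("duplicate year-month rows")
    temp_cols = [c for c in ("tmean", "tmax", "tmin") if c in monthly.columns]

    pivots = {
        var: monthly.pivot(index="year", columns="month", values=var)
        for var in ["prec"] + temp_cols
    }
    years = pivots["prec"].index.to_numpy()
    out = pd.DataFrame(index=pd.Index(years, name="year"))

    for pool, members in POOLS.items():
        for var in ["prec"] + temp_cols:
            piv = pivots[var].reindex(columns=range(1, 13))
            cols = []
            for off, m in members:
                col = piv[m] if off == 0 else piv[m].shift(-off)  # off=-1: previous year
                cols.append(col)
            block = pd.concat(cols, axis=1)
            if var == "prec":
                vals = block.sum(axis=1, min_count=len(members))
                out[f"P_{pool}"] = vals
            else:
                vals = block.mean(axis=1)
                vals[block.isna().any(axis=1)] = np.nan
                out[f"{_TEMP_PREFIX[var]}_{pool}"] = vals
    return out


def lapse_correct(temperatures, altitude_delta: float, rate: float = 0.5):
    """Adjust temperatures to a site ``altitude_delta`` m higher.

    Standard environmental lapse: T - rate * delta / 100 with ``rate``
    in degC per 100 m (default 0.5).  Negative deltas (a lower site)
    warm the series.
    """
    t = np.asarray(temperatures, dtype=float)
    out = t - rate * altitude_delta / 100.0
    return float(out) if np.isscalar(temperatures) else out


def kendall_screen(
    bai: pd.Series, aggregates: pd.DataFrame, min_overlap: int = 8
) -> pd.DataFrame:
    """Rank candidate climate variables by |Kendall tau-b| against BAI.

    Variables with fewer than ``min_overlap`` overlapping years are
    skipped with a warning.  Returns a DataFrame with columns
    ``variable``, ``tau``, ``p_value``, ``n``, sorted by |tau|
    descending.
    """
    rows = []
    for col in aggregates.columns:
        joined = pd.concat([bai.rename("bai"), aggregates[col]], axis=1, join="inner")
        joined = joined.dropna()
        if len(joined) < min_overlap:
            warnings.warn(
                f"{col}: only {len(joined)} overlapping years (< {min_overlap}); skipped"
            )
            continue
        tau, p = kendalltau(joined[col], joined["bai"])
        rows.append({"variable": col, "tau": tau, "p_value": p, "n": len(joined)})
    if not rows:
        raise ValueError(f"no variable has >= {min_overlap} overlapping years with BAI")
    df = pd.DataFrame(rows)
    return df.reindex(df["tau"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
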