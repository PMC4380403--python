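"""Assemble plot-year observation tables from ingest-side inputs.

Glue between the data modules and the estimator: cores become plot
chronologies, inventories become annual competition series, monthly
climate becomes seasonal pools, and the three are joined on plot and
year into the ``bai/size/comp/prec/temp`` table that
:class:`~dendrofit.fitting.GrowthML` consumes.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd

from .chronology import (
    RingWidthCore,
    build_plot_chronology,
    competition_series,
    tree_bai,
    tree_dbh,
)
from .climate import aggregate_climate

__all__ = ["plot_chronologies", "build_observations"]


def _plot_of(core: RingWidthCore) -> str:
    # core ids follow <plot>T<tree>_<core>; fall back to the tree id
    tid = core.tree_id
    return tid.split("T")[0] if "T" in tid else tid


def plot_chronologies(cores, min_depth: int = 5, plot_of=None) -> dict:
    """Group cores by plot and build one chronology per plot."""
    plot_of = plot_of or _plot_of
    by_plot_tree = defaultdict(lambda: defaultdict(list))
    for c in cores:
        by_plot_tree[plot_of(c)][c.tree_id].append(c)
    out = {}
    for pid, trees in by_plot_tree.items():
        bai = {tid: tree_bai(cs) for tid, cs in trees.items()}
        dbh = {tid: tree_dbh(cs) for tid, cs in trees.items()}
        out[pid] = build_plot_chronology(bai, dbh, plot_id=pid, min_depth=min_depth)
    return out


def build_observations(
    cores,
    inventories: pd.DataFrame,
    thinnings: pd.DataFrame,
    monthly_climate: pd.DataFrame,
    prec_var: str,
    temp_var: str,
    min_depth: int = 5,
    site: str | None = None,
) -> pd.DataFrame:
    """Join chronologies, competition and climate into an observation table.

    Returns a DataFrame with columns ``plot, year, bai, size, comp,
    prec, temp`` (plus ``site`` when given), restricted to years where
    all three sources are available.  Rows with non-positive plot-mean
    BAI are dropped with their count reported via a ``UserWarning``
    inside the estimator; here they are simply excluded from the join
    by the chronology's own construction (mean BAI of live rings).
    """
    chronos = plot_chronologies(cores, min_depth=min_depth)
    agg = aggregate_climate(monthly_climate)
    for col in (prec_var, temp_var):
        if col not in agg.columns:
            raise ValueError(f"climate table cannot provide covariate {col!r}")
    clim = agg[[prec_var, temp_var]].rename(
        columns={prec_var: "prec", temp_var: "temp"}
    )

    frames = []
    for pid, chrono in chronos.items():
        if len(chrono.years) == 0:
            continue
        inv = inventories[inventories["plot"] == pid]
        thin = thinnings[thinnings["plot"] == pid] if len(thinnings) else thinnings
        comp = competition_series(inv, thin, plot_id=pid).to_frame().set_index("year")
        df = chrono.to_frame().set_index("year")
        df = df.join(comp["basal_area"], how="inner").join(clim, how="inner")
        df = df.rename(columns={"mean_bai": "bai", "mean_dbh": "size", "basal_area": "comp"})
        df["plot"] = pid
        frames.append(df.reset_index()[["plot", "year", "bai", "size", "comp", "prec", "temp"]])
    if not frames:
        raise ValueError("no plot produced any observation rows")
    out = pd.concat(frames, ignore_index=True).dropna()
    if site is not None:
        out["site"] = site
    return out
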