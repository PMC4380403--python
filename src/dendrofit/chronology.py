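"""From ring-width cores to plot BAI chronologies and competition series.

Ring widths (mm) are converted to basal area increments (BAI, mm^2/yr)
inside-out: the cumulative radius at year t is the pith offset plus the
summed ring widths, and BAI is the area of the annulus grown that year.
Core series are averaged per tree, tree series per plot, and chronology
years are kept only while at least ``min_depth`` trees contribute
(five, by default) so that plot means are not dominated by one or two
individuals.

Periodic inventories (basal area m^2/ha, density trees/ha) become
annual competition series by linear interpolation, with thinning
removals superimposed as a step at the start of the thinning year so
that the covariate of a thinning year reflects post-thinning crowding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RingWidthCore",
    "PlotChronology",
    "CompetitionSeries",
    "bai_from_core",
    "dbh_from_core",
    "tree_bai",
    "tree_dbh",
    "build_plot_chronology",
    "competition_series",
]


@dataclass(frozen=True)
class RingWidthCore:
    """One measured core: contiguous annual ring widths in mm."""

    tree_id: str
    core_id: str
    first_year: int
    widths: np.ndarray
    pith_offset: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.widths, dtype=float)
        object.__setattr__(self, "widths", w)
        if w.ndim != 1 or w.size == 0:
            raise ValueError(f"core {self.core_id}: widths must be a nonempty 1-d array")
        if np.any(w < 0) or np.any(~np.isfinite(w)):
            raise ValueError(f"core {self.core_id}: negative or non-finite ring widths")
        if self.pith_offset < 0:
            raise ValueError(f"core {self.core_id}: pith offset must be >= 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.widths))


@dataclass(frozen=True)
class PlotChronology:
    """Annual plot-mean BAI, sample depth and mean DBH."""

    plot_id: str
    years: np.ndarray
    mean_bai: np.ndarray
    sample_depth: np.ndarray
    mean_dbh: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "mean_bai": self.mean_bai,
                "depth": self.sample_depth,
                "mean_dbh": self.mean_dbh,
            }
        )


@dataclass(frozen=True)
class CompetitionSeries:
    """Annual plot basal area and density reconstructed from inventories."""

    plot_id: str
    years: np.ndarray
    basal_area: np.ndarray
    density: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "basal_area": self.basal_area, "density": self.density}
        )


# ----------------------------------------------------------------------
def bai_from_core(core: RingWidthCore) -> pd.Series:
    """Annual basal area increment (mm^2/yr) of one core.

    BAI_t = pi (r_t^2 - r_{t-1}^2) with r_t the cumulative radius
    (pith offset + summed widths).  Exact inverse of the annulus
    construction used by the growth simulator.
    """
    r = core.pith_offset + np.cumsum(core.widths)
    r_prev = np.concatenate([[core.pith_offset], r[:-1]])
    bai = math.pi * (r**2 - r_prev**2)
    return pd.Series(bai, index=pd.Index(core.years, name="year"), name=core.core_id)


def dbh_from_core(core: RingWidthCore) -> pd.Series:
    """Diameter (mm) at the start of each growing season.

    DBH_t = 2 r_{t-1}: the cumulative radius *before* the ring dated t,
    since that is the size in place while ring t forms — the dated
    ring's own width cannot drive the growth that produced it.
    """
    r_prev = core.pith_offset + np.cumsum(core.widths) - core.widths
    return pd.Series(
        2.0 * r_prev, index=pd.Index(core.years, name="year"), name=core.core_id
    )


def _mean_across_cores(series: list[pd.Series], tree_id: str) -> pd.Series:
    df = pd.concat(series, axis=1)
    present = df.notna().any(axis=1)
    years = df.index[present]
    if len(years) and (years.max() - years.min() + 1) != len(years):
        warnings.warn(
            f"tree {tree_id}: cores leave a gap in year coverage", stacklevel=3
        )
    return df.mean(axis=1).dropna()


def tree_bai(cores: list[RingWidthCore]) -> pd.Series:
    """Per-year mean BAI across the cores of one tree."""
    if not cores:
        raise ValueError("tree_bai needs at least one core")
    tree_ids = {c.tree_id for c in cores}
    if len(tree_ids) > 1:
        raise ValueError(f"cores belong to different trees: {sorted(tree_ids)}")
    return _mean_across_cores([bai_from_core(c) for c in cores], cores[0].tree_id)


def tree_dbh(cores: list[RingWidthCore]) -> pd.Series:
    """Per-year mean reconstructed DBH across the cores of one tree."""
    if not cores:
        raise ValueError("tree_dbh needs at least one core")
    return _mean_across_cores([dbh_from_core(c) for c in cores], cores[0].tree_id)


def build_plot_chronology(
    tree_bai_series: dict[str, pd.Series],
    tree_dbh_series: dict[str, pd.Series],
    plot_id: str = "plot",
    min_depth: int = 5,
) -> PlotChronology:
    """Average tree series into a plot chronology.

    Years contributed by fewer than ``min_depth`` trees are dropped
    (boundary inclusive: depth == min_depth is kept).
    """
    if set(tree_bai_series) != set(tree_dbh_series):
        raise ValueError("BAI and DBH series must cover the same trees")
    bai = pd.DataFrame(tree_bai_series)
    dbh = pd.DataFrame(tree_dbh_series)
    depth = bai.notna().sum(axis=1)
    keep = depth >= min_depth
    if not keep.any():
        warnings.warn(f"plot {plot_id}: no year reaches sample depth {min_depth}")
        empty = np.array([])
        return PlotChronology(plot_id, empty, empty, empty, empty)
    years = bai.index[keep].to_numpy()
    return PlotChronology(
        plot_id=plot_id,
        years=years,
        mean_bai=bai.loc[keep].mean(axis=1).to_numpy(),
        sample_depth=depth[keep].to_numpy(),
        mean_dbh=dbh.loc[keep].mean(axis=1).to_numpy(),
    )


# ----------------------------------------------------------------------
def _interp_with_thinning(inv: pd.Series, removals: pd.Series) -> pd.Series:
    """Annual series between inventories with harvest steps.

    Between consecutive inventories the non-harvest ("natural") change
    is spread evenly per year; a thinning's removal is applied as an
    extra step at the start of its year, so the series still passes
    through every inventory value exactly.
    """
    years = np.arange(inv.index.min(), inv.index.max() + 1)
    out = pd.Series(index=years, dtype=float)
    inv_years = list(inv.index)
    out.loc[inv_years[0]] = inv.iloc[0]
    for (y0, v0), (y1, v1) in zip(inv.items(), list(inv.items())[1:]):
        span = y1 - y0
        removed = removals[(removals.index > y0) & (removals.index <= y1)]
        natural = (v1 - v0 + removed.sum()) / span
        val = v0
        for y in range(y0 + 1, y1 + 1):
            val += natural
            if y in removed.index:
                val -= removed[y]
            out.loc[y] = val
    return out


def competition_series(
    inventories: pd.DataFrame,
    thinnings: pd.DataFrame | None = None,
    plot_id: str | None = None,
) -> CompetitionSeries:
    """Annual competition series for one plot.

    Parameters
    ----------
    inventories : DataFrame
        Columns ``year``, ``basal_area`` (m^2/ha), ``density``
        (trees/ha); at least two rows, chronologically ordered.
    thinnings : DataFrame, optional
        Columns ``year``, ``removed_basal_area``, ``removed_density``.
    """
    inv = inventories.sort_values("year") if len(inventories) else inventories
    if len(inv) < 2:
        raise ValueError("need at least two inventories to interpolate")
    if inv["year"].duplicated().any():
        raise ValueError("duplicate inventory years")
    if not inventories["year"].is_monotonic_increasing:
        raise ValueError("inventories must be chronologically ordered")
    if (inv[["basal_area", "density"]] < 0).any().any():
        raise ValueError("inventories contain negative values")

    if thinnings is None or len(thinnings) == 0:
        rem_ba = pd.Series(dtype=float)
        rem_n = pd.Series(dtype=float)
    else:
        t = thinnings.sort_values("year")
        rem_ba = pd.Series(t["removed_basal_area"].to_numpy(), index=t["year"].to_numpy())
        rem_n = pd.Series(t["removed_density"].to_numpy(), index=t["year"].to_numpy())

    ba = _interp_with_thinning(
        pd.Series(inv["basal_area"].to_numpy(), index=inv["year"].to_numpy()), rem_ba
    )
    dens = _interp_with_thinning(
        pd.Series(inv["density"].to_numpy(), index=inv["year"].to_numpy()), rem_n
    )
    if (ba < 0).any() or (dens < 0).any():
        bad = ba.index[(ba < 0) | (dens < 0)].tolist()
        raise ValueError(f"negative interpolated competition values in years {bad}")
    return CompetitionSeries(
        plot_id=plot_id or "plot",
        years=ba.index.to_numpy(),
        basal_area=ba.to_numpy(),
        density=dens.to_numpy(),
    )
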