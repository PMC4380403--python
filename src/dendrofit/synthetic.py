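"""Synthetic study-shaped datasets: stands, thinnings, climate, growth.

The generator emulates the structure of a long-term thinning-trial
network in even-aged monospecific stands: plots of a few hundred to a
few thousand trees per hectare, thinned from below on roughly
ten-year rotations at basal-area removal fractions between 0.15 and
0.5, inventoried every 4-10 years, with two cores sampled per
above-average tree.  Growth is simulated forward from a known
:class:`~dendrofit.model.GrowthModel`: each plot-year the covariates
(mean sampled-tree DBH, plot basal area, seasonal climate pools) are
assembled, the plot-mean BAI is drawn from the Gamma observation
model, shared across trees in proportion to their basal area, and
converted to ring widths by inverting the annulus relation.  Ring
widths are quantised to 0.01 mm (measurement resolution) *before* the
realised growth is recorded, so that writing the data to disk and
re-ingesting it reproduces the simulator's internal covariates
exactly.

All randomness flows from one explicit seed through independent named
streams (climate, stand, mortality, growth), so each stage can be
regenerated independently and bit-identically.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chronology import RingWidthCore
from .climate import aggregate_climate
from .model import GrowthModel
from .modifiers import Modifier

__all__ = [
    "ClimateConfig",
    "StandConfig",
    "Stand",
    "SimulatedDataset",
    "generate_climate",
    "generate_stand",
    "thin_from_below",
    "simulate_growth",
    "simulate_observations",
    "make_study_fixture",
    "ARCHETYPES",
    "qufg_model",
    "qupy_model",
    "pisy_model",
]

#: mm^2 -> m^2/ha conversion for a plot of `area` m^2
def _ba_factor(area: float) -> float:
    return 1e-6 * 1e4 / area


def _rng(seed: int, label: str) -> np.random.Generator:
    """Named independent stream derived from one master seed."""
    h = zlib.crc32(label.encode()) & 0xFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, h)))


# ----------------------------------------------------------------------
@dataclass
class ClimateConfig:
    """Monthly climate generator settings.

    Normals are 12-vectors (Jan..Dec).  Interannual variability is an
    AR(1) annual anomaly applied to every month of the year: additive
    (degC) for temperatures, multiplicative (fractional) for
    precipitation.  Trends are per decade.
    """

    prec_normals: np.ndarray
    tmax_normals: np.ndarray
    tmean_normals: np.ndarray | None = None
    tmin_normals: np.ndarray | None = None
    temp_sd: float = 0.8
    prec_sd_frac: float = 0.18
    ar1: float = 0.2
    temp_trend_per_decade: float = 0.0
    prec_trend_frac_per_decade: float = 0.0
    years: tuple[int, int] = (1960, 2012)
    seed: int = 0

    def __post_init__(self) -> None:
        self.prec_normals = np.asarray(self.prec_normals, float)
        self.tmax_normals = np.asarray(self.tmax_normals, float)
        if self.tmean_normals is None:
            self.tmean_normals = self.tmax_normals - 6.0
        if self.tmin_normals is None:
            self.tmin_normals = self.tmax_normals - 12.0
        self.tmean_normals = np.asarray(self.tmean_normals, float)
        self.tmin_normals = np.asarray(self.tmin_normals, float)
        for v in (self.prec_normals, self.tmax_normals, self.tmean_normals, self.tmin_normals):
            if v.shape != (12,):
                raise ValueError("normals must be 12-vectors (Jan..Dec)")
        if self.temp_sd < 0 or self.prec_sd_frac < 0:
            raise ValueError("interannual sd must be >= 0")
        if not abs(self.ar1) < 1:
            raise ValueError("|lag-1 autocorrelation| must be < 1")


def _ar1_series(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    z = np.empty(n)
    innov = rng.standard_normal(n)
    z[0] = innov[0]
    c = math.sqrt(1.0 - rho**2)
    for t in range(1, n):
        z[t] = rho * z[t - 1] + c * innov[t]
    return z


def generate_climate(config: ClimateConfig) -> pd.DataFrame:
    """Monthly climate table (year, month, prec, tmax, tmean, tmin)."""
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    n = len(years)
    rng_t = _rng(config.seed, "climate-temp")
    rng_p = _rng(config.seed, "climate-prec")
    zt = _ar1_series(n, config.ar1, rng_t) * config.temp_sd
    zp = _ar1_series(n, config.ar1, rng_p) * config.prec_sd_frac
    decades = (years - y0) / 10.0

    rows = []
    for i, year in enumerate(years):
        dt = zt[i] + config.temp_trend_per_decade * decades[i]
        fp = max(0.0, 1.0 + zp[i]) * (1.0 + config.prec_trend_frac_per_decade * decades[i])
        for m in range(12):
            rows.append(
                {
                    "year": int(year),
                    "month": m + 1,
                    "prec": config.prec_normals[m] * fp,
                    "tmax": config.tmax_normals[m] + dt,
                    "tmean": config.tmean_normals[m] + dt,
                    "tmin": config.tmin_normals[m] + dt,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
@dataclass
class StandConfig:
    """Even-aged monospecific stand and its management schedule."""

    n_plots: int = 4
    plot_area: float = 1000.0  # m^2
    initial_density: float = 2000.0  # trees/ha
    initial_dbh_mean: float = 80.0  # mm
    dbh_sd: float = 20.0
    years: tuple[int, int] = (1975, 2010)
    treatments: tuple = (0.0, 0.2, 0.35, 0.5)  # BA removal fractions, cycled over plots
    rotation_years: int = 10
    inventory_interval: int = 5
    n_sampled: int = 10  # cored trees per plot
    mortality_rate: float = 0.005  # annual density loss, smallest trees
    thinning_schedule: dict | None = None  # plot_id -> [(year, fraction)] override
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years[1] - self.years[0] < 30:
            raise ValueError("stand span must cover at least 30 years")
        if not (4 <= self.inventory_interval <= 10):
            raise ValueError("inventory interval must lie in 4..10 years")
        if any(f >= 1.0 or f < 0.0 for f in self.treatments):
            raise ValueError("removal fractions must lie in [0, 1)")


@dataclass
class Stand:
    """Initialised stand: trees, sampling, and the thinning plan."""

    config: StandConfig
    dbh0: dict  # plot_id -> initial DBH array (mm)
    sampled: dict  # plot_id -> indices of cored trees
    thinning_plan: dict  # plot_id -> list of (year, fraction)

    @property
    def plot_ids(self):
        return list(self.dbh0)


def generate_stand(config: StandConfig) -> Stand:
    """Initial tree lists, sampled-tree sets and the thinning plan.

    Initial DBH is Gaussian (clipped at 25 mm); sampled trees are drawn
    from those above the plot mean, mirroring the field protocol of
    coring above-average trees that survive management.
    """
    rng = _rng(config.seed, "stand")
    n_trees = int(round(config.initial_density * config.plot_area / 1e4))
    if n_trees < config.n_sampled:
        raise ValueError("plot has fewer trees than the number to be sampled")
    dbh0, sampled, plan = {}, {}, {}
    y_est = config.years[0]
    for p in range(config.n_plots):
        pid = f"P{p + 1}"
        d = np.clip(rng.normal(config.initial_dbh_mean, config.dbh_sd, n_trees), 25.0, None)
        dbh0[pid] = d
        above = np.flatnonzero(d > d.mean())
        if len(above) < config.n_sampled:
            above = np.argsort(d)[-config.n_sampled :]
        sampled[pid] = np.sort(rng.choice(above, size=config.n_sampled, replace=False))
        if config.thinning_schedule and pid in config.thinning_schedule:
            plan[pid] = list(config.thinning_schedule[pid])
        else:
            frac = config.treatments[p % len(config.treatments)]
            plan[pid] = (
                []
                if frac == 0.0
                else [
                    (y, frac)
                    for y in range(y_est, config.years[1] + 1, config.rotation_years)
                ]
            )
    return Stand(config=config, dbh0=dbh0, sampled=sampled, thinning_plan=plan)


def thin_from_below(basal_areas: np.ndarray, fraction: float, protected=None) -> np.ndarray:
    """Indices removed by a thinning-from-below of ``fraction`` of BA.

    The smallest trees are removed greedily until the removed basal
    area reaches the target fraction (overshoot bounded by one tree's
    basal area).  ``protected`` indices are never removed.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("removal fraction must lie in [0, 1)")
    ba = np.asarray(basal_areas, float)
    target = fraction * ba.sum()
    protected = set() if protected is None else set(np.atleast_1d(protected).tolist())
    order = np.argsort(ba, kind="stable")
    removed, acc = [], 0.0
    for i in order:
        if acc >= target:
            break
        if int(i) in protected:
            continue
        removed.append(int(i))
        acc += ba[i]
    if acc < target:
        raise ValueError(
            f"cannot remove {fraction:.0%} of basal area without touching protected trees"
        )
    return np.array(removed, dtype=int)


# ----------------------------------------------------------------------
@dataclass
class SimulatedDataset:
    """Everything one simulated study site produces."""

    site: str
    model: GrowthModel
    cores: list
    pith_offsets: dict
    inventories: pd.DataFrame
    thinnings: pd.DataFrame
    climate: pd.DataFrame
    truth: pd.DataFrame  # plot-year covariates and BAI as realised

    def write(self, outdir) -> None:
        """Write the ingest-side file formats plus truth tables."""
        from .rwl import write_rwl

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_rwl(self.cores, out / "cores.rwl")
        pd.DataFrame(
            {"core_id": list(self.pith_offsets), "pith_offset": list(self.pith_offsets.values())}
        ).to_csv(out / "pith_offsets.csv", index=False)
        self.inventories.to_csv(out / "inventories.csv", index=False)
        self.thinnings.to_csv(out / "thinnings.csv", index=False)
        self.climate.to_csv(out / "climate.csv", index=False)
        self.truth.to_csv(out / "truth_plot_year.csv", index=False)
        (out / "truth_model.txt").write_text(self.model.to_text())


def simulate_growth(
    model: GrowthModel,
    stand: Stand,
    climate: pd.DataFrame,
    seed: int = 0,
    site: str | None = None,
) -> SimulatedDataset:
    """Forward-simulate growth and emit the full ingest-format dataset.

    Within each year the order of operations is: thinning (start of
    year, so the covariate reflects post-thinning competition), natural
    mortality, covariate assembly, Gamma-noised plot growth, per-tree
    allocation proportional to basal area, ring-width quantisation.
    """
    cfg = stand.config
    agg = aggregate_climate(climate)
    prec_col = model.covariates["precipitation"]
    temp_col = model.covariates["temperature"]
    cov = agg[[prec_col, temp_col]].dropna()
    y0, y1 = cfg.years
    years = [y for y in range(y0, y1 + 1) if y in cov.index]
    if len(years) < (y1 - y0 + 1):
        missing = sorted(set(range(y0, y1 + 1)) - set(years))
        raise ValueError(f"climate cannot cover stand years; missing {missing[:5]}")

    rng_g = _rng(seed, "growth")
    ba_f = _ba_factor(cfg.plot_area)
    site = site or "S1"

    cores, pith_offsets = [], {}
    inv_rows, thin_rows, truth_rows = [], [], []
    inv_years = set(range(y0, y1 + 1, cfg.inventory_interval)) | {y1}

    for pid in stand.plot_ids:
        r = stand.dbh0[pid] / 2.0  # radii mm
        alive = np.ones(len(r), dtype=bool)
        sampled = stand.sampled[pid]
        protected = set(sampled.tolist())
        plan = dict(stand.thinning_plan[pid])
        widths = {int(i): [] for i in sampled}
        r0_sampled = {int(i): float(r[i]) for i in sampled}
        death_debt = 0.0

        for year in years:
            ba_tree = math.pi * r**2  # mm^2
            # --- thinning from below at the start of the year
            if year in plan:
                idx_alive = np.flatnonzero(alive)
                prot_local = [k for k, i in enumerate(idx_alive) if int(i) in protected]
                rem_local = thin_from_below(ba_tree[idx_alive], plan[year], prot_local)
                rem = idx_alive[rem_local]
                thin_rows.append(
                    {
                        "plot": pid,
                        "year": year,
                        "removed_basal_area": float(ba_tree[rem].sum()) * ba_f,
                        "removed_density": len(rem) * 1e4 / cfg.plot_area,
                    }
                )
                alive[rem] = False
            # --- background mortality: smallest unprotected trees die first
            death_debt += alive.sum() * cfg.mortality_rate
            n_die = int(death_debt)
            if n_die > 0:
                death_debt -= n_die
                candidates = [i for i in np.flatnonzero(alive) if int(i) not in protected]
                candidates.sort(key=lambda i: r[i])
                for i in candidates[:n_die]:
                    alive[i] = False

            # --- covariates (start-of-year state)
            ba_tree = math.pi * r**2
            plot_ba = float(ba_tree[alive].sum()) * ba_f
            density = alive.sum() * 1e4 / cfg.plot_area
            mean_dbh = float(2.0 * r[sampled].mean())
            prec = float(cov.loc[year, prec_col])
            temp = float(cov.loc[year, temp_col])
            mu = model.predict(mean_dbh, plot_ba, prec, temp,
                               site=site if model.comp_intercept_by_site else None)
            if not (mu > 0 and np.isfinite(mu)):
                raise ValueError(
                    f"non-positive predicted mean at {pid} {year}: "
                    f"dbh={mean_dbh:.1f} ba={plot_ba:.2f} prec={prec:.0f} temp={temp:.1f}"
                )
            bai_draw = rng_g.gamma(model.dispersion, mu / model.dispersion)

            # --- allocate growth across living trees, quantise widths
            mean_ba_sampled = float(ba_tree[sampled].mean())
            share = bai_draw / mean_ba_sampled
            bai_tree = share * ba_tree  # mm^2, all trees
            r_new = np.sqrt(r**2 + np.where(alive, bai_tree, 0.0) / math.pi)
            w = np.round(r_new - r, 2)  # 0.01 mm measurement resolution
            for i in sampled:
                widths[int(i)].append(w[i])
            realized = math.pi * ((r[sampled] + w[sampled]) ** 2 - r[sampled] ** 2)
            r = r + np.where(alive, w, 0.0)

            if year in inv_years:
                inv_rows.append(
                    {"plot": pid, "year": year, "basal_area": plot_ba, "density": density}
                )
            truth_rows.append(
                {
                    "site": site,
                    "plot": pid,
                    "year": year,
                    "mean_dbh": mean_dbh,
                    "basal_area": plot_ba,
                    "density": density,
                    "prec": prec,
                    "temp": temp,
                    "mu_true": mu,
                    "bai_drawn": bai_draw,
                    "bai_realized": float(realized.mean()),
                }
            )

        for i in sampled:
            tid = f"{pid}T{int(i):02d}"
            for tag in ("A", "B"):
                cid = f"{tid}_{tag}"
                cores.append(
                    RingWidthCore(
                        tree_id=tid,
                        core_id=cid,
                        first_year=years[0],
                        widths=np.array(widths[int(i)]),
                        pith_offset=r0_sampled[int(i)],
                    )
                )
                pith_offsets[cid] = r0_sampled[int(i)]

    return SimulatedDataset(
        site=site,
        model=model,
        cores=cores,
        pith_offsets=pith_offsets,
        inventories=pd.DataFrame(inv_rows),
        thinnings=pd.DataFrame(thin_rows),
        climate=climate,
        truth=pd.DataFrame(truth_rows),
    )


# ----------------------------------------------------------------------
def simulate_observations(
    model: GrowthModel,
    n_plots: int = 40,
    n_years: int = 40,
    ranges: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Plot-year observation table drawn directly from the model.

    The lightweight forward experiment used for parameter recovery and
    model-selection power: per plot a monotone size trajectory and a
    smoothly varying basal-area path, per plot-year independent climate
    covariates, all spanning the given ranges, with Gamma-noised BAI.

    Default ranges emulate the xeric-oak study conditions: mean DBH
    88-301 mm, basal area 2.4-19 m^2/ha, hydrological-year
    precipitation 280-780 mm (interannual spread around a ~500 mm
    normal), spring maximum temperature 12-20 degC.
    """
    ranges = dict(ranges or {})
    ranges.setdefault("size", (88.0, 301.0))
    ranges.setdefault("comp", (2.4, 19.0))
    ranges.setdefault("prec", (280.0, 780.0))
    ranges.setdefault("temp", (12.0, 20.0))
    rng = _rng(seed, "observations")
    rows = []
    for p in range(n_plots):
        s_lo, s_hi = ranges["size"]
        start = rng.uniform(s_lo, 0.5 * (s_lo + s_hi))
        end = rng.uniform(0.5 * (s_lo + s_hi), s_hi)
        size = np.linspace(start, end, n_years)
        c_lo, c_hi = ranges["comp"]
        c0, c1 = rng.uniform(c_lo, c_hi, 2)
        comp = np.linspace(c0, c1, n_years) + rng.normal(0, 0.02 * (c_hi - c_lo), n_years)
        comp = np.clip(comp, c_lo, c_hi)
        prec = rng.uniform(*ranges["prec"], n_years)
        temp = rng.uniform(*ranges["temp"], n_years)
        mu = model.predict(size, comp, prec, temp)
        bai = rng.gamma(model.dispersion, mu / model.dispersion)
        for t in range(n_years):
            rows.append(
                {
                    "plot": f"P{p + 1}",
                    "year": 1971 + t,
                    "bai": bai[t],
                    "size": size[t],
                    "comp": comp[t],
                    "prec": prec[t],
                    "temp": temp[t],
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Species archetypes: the published parameterisations used as truth.
def qufg_model(dispersion: float = 20.0) -> GrowthModel:
    """Xeric oak archetype (slow growth, strong competition effect)."""
    return GrowthModel(
        mg=1055.2,
        size=Modifier("logistic", 83.8, -5.26),
        competition=Modifier("negative_exponential", 1.0, -0.1217),
        precipitation=Modifier("logistic", 221.0, -2.13),
        temperature=Modifier("modified_laplace", 16.1, 0.0312),
        dispersion=dispersion,
        covariates={"precipitation": "P_Hyd", "temperature": "Tmax_Spr"},
    )


def qupy_model(dispersion: float = 20.0) -> GrowthModel:
    """Mesic oak archetype (temperature-dominated climate response)."""
    return GrowthModel(
        mg=1965.9,
        size=Modifier("logistic", 227.5, -1.48),
        competition=Modifier("negative_exponential", 1.0, -0.0191),
        precipitation=Modifier("logistic", 87.7, -20.27),
        temperature=Modifier("modified_laplace", 13.3, 0.0393),
        dispersion=dispersion,
        covariates={"precipitation": "P_Spr", "temperature": "Tmax_Spr"},
    )


def pisy_model(dispersion: float = 20.0) -> GrowthModel:
    """Mountain pine archetype with site-specific competition intercepts."""
    return GrowthModel(
        mg=5546.8,
        size=Modifier("logistic", 205.7, -2.09),
        competition=Modifier("negative_exponential", 1.0, -0.0209),
        precipitation=Modifier("logistic", 39.0, -1.63),
        temperature=Modifier("modified_laplace", 14.0, 0.0701),
        dispersion=dispersion,
        covariates={"precipitation": "P_MJJ", "temperature": "Tmax_Hyd"},
        comp_intercept_by_site={"DU": 0.6660, "NE": 1.0},
    )


def _site_climate_config(annual_prec: float, tmax_spr: float, seed: int, years) -> ClimateConfig:
    """Dry-summer regime: wet winters/springs, hot dry summers."""
    weights = np.array([0.11, 0.09, 0.09, 0.10, 0.09, 0.05, 0.02, 0.03, 0.07, 0.13, 0.12, 0.10])
    months = np.arange(12)
    # sinusoidal annual cycle peaking in July, calibrated so Mar-May mean = tmax_spr
    cycle = -np.cos(2.0 * math.pi * (months - 0.5) / 12.0)
    amp = 9.0
    base = tmax_spr - amp * cycle[2:5].mean()
    return ClimateConfig(
        prec_normals=annual_prec * weights,
        tmax_normals=base + amp * cycle,
        years=years,
        seed=seed,
    )


#: site label -> dict of archetype settings (model factory, climate
#: normals targets, stand initial state, per-site thinning cycle)
ARCHETYPES = {
    "BP": dict(factory=qufg_model, prec=505.0, tmax_spr=16.0, density=2500.0,
               dbh0=70.0, treatments=(0.0, 0.15, 0.25, 0.35), mortality=0.005,
               site_id=None),
    "NA": dict(factory=qupy_model, prec=927.0, tmax_spr=14.0, density=830.0,
               dbh0=165.0, treatments=(0.0, 0.05, 0.08, 0.10), mortality=0.01,
               site_id=None),
    "RA": dict(factory=qupy_model, prec=790.0, tmax_spr=13.2, density=2150.0,
               dbh0=116.0, treatments=(0.0, 0.08, 0.12, 0.15), mortality=0.012,
               site_id=None),
    "DU": dict(factory=pisy_model, prec=860.0, tmax_spr=13.8, density=1150.0,
               dbh0=170.0, treatments=(0.0, 0.1, 0.15, 0.2), mortality=0.005,
               site_id="DU"),
    "NE": dict(factory=pisy_model, prec=860.0, tmax_spr=13.1, density=1500.0,
               dbh0=190.0, treatments=(0.0, 0.08, 0.12, 0.15), mortality=0.01,
               site_id="NE"),
}


def make_study_fixture(seed: int = 0, sites=None, years=(1975, 2010)) -> dict:
    """Deterministic five-site synthetic study: one xeric-oak site, two
    mesic-oak sites and two pine sites, each simulated from its
    archetype model.  Returns site label -> :class:`SimulatedDataset`.
    """
    out = {}
    for k, label in enumerate(sites or list(ARCHETYPES)):
        arch = ARCHETYPES[label]
        model = arch["factory"]()
        clim_cfg = _site_climate_config(
            arch["prec"], arch["tmax_spr"], seed=seed + 101 * (k + 1),
            years=(years[0] - 1, years[1]),
        )
        climate = generate_climate(clim_cfg)
        stand_cfg = StandConfig(
            n_plots=4,
            initial_density=arch["density"],
            initial_dbh_mean=arch["dbh0"],
            dbh_sd=0.18 * arch["dbh0"],
            years=years,
            treatments=arch["treatments"],
            rotation_years=12,
            mortality_rate=arch["mortality"],
            n_sampled=8,
            seed=seed + 13 * (k + 1),
        )
        stand = generate_stand(stand_cfg)
        out[label] = simulate_growth(
            model, stand, climate, seed=seed + 29 * (k + 1),
            site=arch["site_id"] or label,
        )
    return out
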