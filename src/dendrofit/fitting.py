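"""Maximum-likelihood estimation of multiplicative growth models.

The estimator follows the Model/Results idiom: :class:`GrowthML` is
built from a plot-year observation table plus a template
:class:`~dendrofit.model.GrowthModel` (which fixes the modifier
families and any frozen parameters); ``fit()`` runs a seeded simulated
annealing search followed by a derivative-free polish and returns a
:class:`GrowthMLResults` carrying the estimates, 2-unit
profile-likelihood support intervals, goodness-of-fit statistics and a
``summary()`` table.

Annealing schedule: geometric cooling (factor 0.9 by default), Gaussian
proposals scaled to 10% of each parameter's bound range, 100 steps per
temperature level, with the initial temperature calibrated so that
roughly 80% of initial uphill moves are accepted.  The search is
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import gammaln

from .model import FitStatistics, GrowthModel, aic, fit_statistics
from .modifiers import FAMILIES, Modifier

__all__ = [
    "AnnealingSchedule",
    "GrowthML",
    "GrowthMLResults",
    "ModelComparison",
    "fit_model",
    "compare_models",
    "candidate_template",
]

_BIG = 1e30
_MOD_ROLES = ("size", "comp", "prec", "temp")
_ROLE_ATTR = {
    "size": "size",
    "comp": "competition",
    "prec": "precipitation",
    "temp": "temperature",
}


@dataclass(frozen=True)
class AnnealingSchedule:
    """Control parameters for the simulated-annealing search."""

    initial_temperature: float | None = None  # None -> auto-calibrated
    cooling_factor: float = 0.9
    steps_per_temperature: int = 100
    max_evaluations: int = 30_000
    proposal_scale: float = 0.1
    stall_levels: int = 10
    n_chains: int = 3  # independent annealing chains, best polished result wins
    polish: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_temperature is not None and self.initial_temperature <= 0:
            raise ValueError("initial_temperature must be > 0")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must lie in (0, 1)")
        if (
            min(
                self.steps_per_temperature,
                self.max_evaluations,
                self.stall_levels,
                self.n_chains,
            )
            <= 0
        ):
            raise ValueError("counts must be positive")
        if not (0.0 < self.proposal_scale <= 1.0):
            raise ValueError("proposal_scale must lie in (0, 1]")


def _param_names(template: GrowthModel):
    """All parameter names of a template, in canonical order."""
    names = ["mg"]
    for role in _MOD_ROLES:
        if role == "comp" and template.comp_intercept_by_site is not None:
            names += [f"comp_a[{s}]" for s in sorted(template.comp_intercept_by_site)]
            names.append("comp_b")
        else:
            names += [f"{role}_a", f"{role}_b"]
    names.append("dispersion")
    return names


class GrowthML:
    """Gamma maximum-likelihood fit of a multiplicative growth model.

    Parameters
    ----------
    data : pandas.DataFrame
        Plot-year observations with columns ``bai``, ``size`` (mean DBH,
        mm), ``comp`` (basal area, m^2/ha), ``prec``, ``temp`` and
        optionally ``site`` (use :meth:`from_dataframe` to map other
        column names).  All BAI values must be strictly positive.
    template : GrowthModel
        Fixes the modifier families, covariate names, and the values of
        any parameters excluded from ``free``.
    free : sequence of str, optional
        Names of the free parameters.  Default: everything except the
        competition intercept (``comp_a``), which stays fixed at the
        template value — unless the template declares per-site
        intercepts, in which case those are free.
    bounds : dict, optional
        name -> (low, high) overrides; the rest come from
        :meth:`default_bounds`, which derives them from the data ranges.
    """

    def __init__(self, data: pd.DataFrame, template: GrowthModel, free=None, bounds=None):
        required = {"bai", "size", "comp", "prec", "temp"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns {sorted(missing)}")
        data = data.dropna(subset=sorted(required))
        if len(data) == 0:
            raise ValueError("no complete observations")
        bad = data[(data["bai"] <= 0) | ~np.isfinite(data["bai"])]
        if len(bad):
            raise ValueError(
                f"{len(bad)} non-positive BAI observation(s); first offending rows:\n"
                f"{bad.head(3)}"
            )
        self.data = data.reset_index(drop=True)
        self.template = template
        self._y = self.data["bai"].to_numpy(float)
        self._x = {r: self.data[r].to_numpy(float) for r in _MOD_ROLES}
        self._sum_log_y = float(np.sum(np.log(self._y)))
        self._n = len(self._y)

        if template.comp_intercept_by_site is not None:
            if "site" not in self.data.columns:
                raise ValueError("template has per-site intercepts but data has no 'site'")
            declared = set(template.comp_intercept_by_site)
            present = set(self.data["site"].unique())
            unknown = present - declared
            if unknown:
                raise KeyError(f"unknown site id(s) in data: {sorted(unknown)}")
            self._site_masks = {
                s: (self.data["site"] == s).to_numpy() for s in sorted(declared & present)
            }
        else:
            self._site_masks = None

        if free is None:
            free = [
                n
                for n in _param_names(template)
                if n != "comp_a" or template.comp_intercept_by_site is not None
            ]
        unknown = set(free) - set(_param_names(template))
        if unknown:
            raise ValueError(f"unknown free parameter(s) {sorted(unknown)}")
        self.free = list(free)
        self.n_params = len(self.free)

        self._full = self._template_values()
        self.bounds = self.default_bounds()
        if bounds:
            self.bounds.update(bounds)
        for name in self.free:
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        template: GrowthModel,
        *,
        bai="bai",
        size="size",
        comp="comp",
        prec=None,
        temp=None,
        site=None,
        free=None,
        bounds=None,
    ) -> "GrowthML":
        """Build from a table with arbitrary column names.

        ``prec``/``temp`` default to the covariate columns named by the
        template (e.g. ``P_Hyd``, ``Tmax_Spr``).
        """
        prec = prec or template.covariates["precipitation"]
        temp = temp or template.covariates["temperature"]
        cols = {bai: "bai", size: "size", comp: "comp", prec: "prec", temp: "temp"}
        if site is not None:
            cols[site] = "site"
        return cls(df.rename(columns=cols), template, free=free, bounds=bounds)

    # ------------------------------------------------------------------
    def _template_values(self) -> dict:
        t = self.template
        vals = {"mg": t.mg, "dispersion": t.dispersion}
        for role in _MOD_ROLES:
            m: Modifier = getattr(t, _ROLE_ATTR[role])
            vals[f"{role}_a"] = m.a
            vals[f"{role}_b"] = m.b
        if t.comp_intercept_by_site is not None:
            for s, a in t.comp_intercept_by_site.items():
                vals[f"comp_a[{s}]"] = a
        return vals

    def default_bounds(self) -> dict:
        """Data-driven default bounds for every parameter.

        MG in (0, 10x max observed BAI]; location parameters within the
        observed covariate range widened by a margin (temperature by
        +/- 5 degC); shape parameters on generous fixed ranges; Gamma
        shape in [0.05, 500].
        """
        y, x = self._y, self._x
        b: dict = {"mg": (1e-6, 10.0 * float(y.max())), "dispersion": (0.05, 500.0)}
        spans = {}
        for role in _MOD_ROLES:
            xr = x[role]
            lo, hi = float(xr.min()), float(xr.max())
            spans[role] = (lo, hi)
        t = self.template
        for role in _MOD_ROLES:
            fam = getattr(t, _ROLE_ATTR[role]).family
            lo, hi = spans[role]
            width = max(hi - lo, 1e-6)
            if role == "temp":
                a_lo, a_hi = lo - 5.0, hi + 5.0
            else:
                a_lo, a_hi = max(1e-3, lo - width), hi + width
            if fam in ("negative_exponential", "negative_potential"):
                b[f"{role}_a"] = (1e-3, 1.0)
            else:
                b[f"{role}_a"] = (a_lo, a_hi)
            if fam == "logistic":
                # the template's b sign declares the response's monotonicity
                tb = getattr(t, _ROLE_ATTR[role]).b
                b[f"{role}_b"] = (-50.0, 0.0) if tb < 0 else (0.0, 50.0)
            elif fam == "modified_gaussian":
                b[f"{role}_b"] = (1e-3 * width, 10.0 * width)
            elif fam == "negative_exponential":
                b[f"{role}_b"] = (-10.0 / max(abs(hi), 1e-6), 0.0)
            elif fam == "negative_potential":
                b[f"{role}_b"] = (-10.0, 0.0)
            elif fam == "log_normal":
                b[f"{role}_b"] = (1e-3, 10.0)
            elif fam == "modified_laplace":
                b[f"{role}_b"] = (0.0, 100.0 / max(width, 1e-6))
        if t.comp_intercept_by_site is not None:
            for s in t.comp_intercept_by_site:
                b[f"comp_a[{s}]"] = b.get("comp_a", (1e-3, 1.0))
        return b

    # ----------------------------- likelihood -------------------------
    def _mu(self, p: dict):
        """Predicted means for a full parameter dict; NaN-tolerant."""
        x = self._x
        t = self.template
        f = FAMILIES
        mu = p["mg"] * f[t.size.family](x["size"], p["size_a"], p["size_b"])
        if self._site_masks is None:
            mu = mu * f[t.competition.family](x["comp"], p["comp_a"], p["comp_b"])
        else:
            comp_vals = np.empty(self._n)
            for s, mask in self._site_masks.items():
                comp_vals[mask] = f[t.competition.family](
                    x["comp"][mask], p[f"comp_a[{s}]"], p["comp_b"]
                )
            mu = mu * comp_vals
        mu = mu * f[t.precipitation.family](x["prec"], p["prec_a"], p["prec_b"])
        mu = mu * f[t.temperature.family](x["temp"], p["temp_a"], p["temp_b"])
        return mu

    def nll(self, theta) -> float:
        """Negative log-likelihood at a free-parameter vector.

        Returns +inf for invalid regions (non-positive means, shape out
        of range) so the optimizer can traverse bounded space freely.
        """
        p = dict(self._full)
        p.update(zip(self.free, np.asarray(theta, float)))
        k = p["dispersion"]
        if not (k > 0 and p["mg"] > 0):
            return math.inf
        with np.errstate(all="ignore"):
            mu = self._mu(p)
            if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
                return math.inf
            log_theta = np.log(mu) - math.log(k)
            nll = -(
                (k - 1.0) * self._sum_log_y
                - float(np.sum(self._y * k / mu))
                - k * float(np.sum(log_theta))
                - self._n * gammaln(k)
            )
        return nll if np.isfinite(nll) else math.inf

    # ----------------------------- fitting ----------------------------
    def _start_point(self, rng, midpoint: bool = True) -> np.ndarray:
        lo = np.array([self.bounds[n][0] for n in self.free])
        hi = np.array([self.bounds[n][1] for n in self.free])
        if midpoint:
            x0 = 0.5 * (lo + hi)
            if np.isfinite(self.nll(x0)):
                return x0
        for _ in range(2000):
            x0 = lo + rng.random(len(lo)) * (hi - lo)
            if np.isfinite(self.nll(x0)):
                return x0
        raise RuntimeError(
            "no finite-likelihood point found within bounds; "
            f"bounds={self.bounds}, free={self.free}"
        )

    def _anneal_chain(self, rng, lo, hi, step, schedule, budget, midpoint=True):
        """One annealing chain; returns (best_x, best_f, evaluations)."""
        x = self._start_point(rng, midpoint=midpoint)
        fx = self.nll(x)
        best_x, best_f = x.copy(), fx
        evals = 1

        T = schedule.initial_temperature
        if T is None:
            uphill = []
            for _ in range(50):
                xp = np.clip(x + rng.normal(size=len(x)) * step, lo, hi)
                fp = self.nll(xp)
                evals += 1
                if np.isfinite(fp) and fp > fx:
                    uphill.append(fp - fx)
                if np.isfinite(fp) and fp < best_f:
                    best_x, best_f = xp.copy(), fp
            # accept a median uphill move with probability ~0.8
            T = float(np.median(uphill)) / math.log(1.0 / 0.8) if uphill else 1.0
            T = max(T, 1e-8)

        stalled = 0
        while evals < budget and stalled < schedule.stall_levels:
            improved = False
            for _ in range(schedule.steps_per_temperature):
                xp = np.clip(x + rng.normal(size=len(x)) * step, lo, hi)
                fp = self.nll(xp)
                evals += 1
                if fp <= fx or rng.random() < math.exp(min(0.0, -(fp - fx) / T)):
                    x, fx = xp, fp
                if fx < best_f - 1e-12:
                    best_x, best_f = x.copy(), fx
                    improved = True
                if evals >= budget:
                    break
            T *= schedule.cooling_factor
            stalled = 0 if improved else stalled + 1
        return best_x, best_f, evals

    def _location_rescue(self, best_x, best_f, lo, hi, n_grid: int = 25):
        """Escape local optima in peaked-kernel location parameters.

        The location of a Laplace (or Gaussian / log-normal) response
        kernel has a kinked, potentially multimodal profile: a simplex
        that settles on the wrong flank cannot cross the peak.  Scan
        each such parameter on a coarse grid (others held fixed) and
        re-polish from any grid point that improves the likelihood.
        """
        peaked = {"modified_laplace", "modified_gaussian", "log_normal"}
        targets = []
        for i, name in enumerate(self.free):
            role = name.split("_")[0]
            if name.endswith("_a") and role in _ROLE_ATTR:
                fam = getattr(self.template, _ROLE_ATTR[role]).family
                if fam in peaked and f"{role}_b" in self.free:
                    targets.append((i, self.free.index(f"{role}_b")))
        evals = 0
        for _ in range(3):
            improved = False
            for ia, ib in targets:
                a_grid = np.linspace(lo[ia], hi[ia], n_grid)
                # rate 0 collapses the kernel to a constant, hiding the
                # location entirely; scan rates log-spaced up to the bound
                b_hi = hi[ib] if hi[ib] > 0 else 1.0
                b_grid = np.geomspace(max(1e-4 * b_hi, 1e-6), b_hi, 7)
                cand, cand_f = None, best_f - 1e-2
                for bv in b_grid:
                    for av in a_grid:
                        t = best_x.copy()
                        t[ia], t[ib] = av, np.clip(bv, lo[ib], hi[ib])
                        f = self.nll(t)
                        evals += 1
                        if f < cand_f:
                            cand, cand_f = t, f
                if cand is not None:
                    res = self._polish(cand, lo, hi, 1500)
                    evals += res.nfev
                    if np.isfinite(res.fun) and res.fun < best_f:
                        best_x, best_f = np.clip(res.x, lo, hi), float(res.fun)
                        improved = True
            if not improved:
                break
        return best_x, best_f, evals

    def _polish(self, x0, lo, hi, maxiter_factor: int):
        return minimize(
            self.nll,
            x0,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={
                "maxiter": maxiter_factor * len(self.free),
                "xatol": 1e-9,
                "fatol": 1e-9,
                "adaptive": len(self.free) > 5,
            },
        )

    def fit(self, schedule: AnnealingSchedule | None = None) -> "GrowthMLResults":
        """Run annealing chains (+ optional simplex polish), keep the best."""
        schedule = schedule or AnnealingSchedule()
        lo = np.array([self.bounds[n][0] for n in self.free])
        hi = np.array([self.bounds[n][1] for n in self.free])
        step = schedule.proposal_scale * (hi - lo)
        chain_budget = max(1, schedule.max_evaluations // schedule.n_chains)
        seeds = np.random.SeedSequence(schedule.seed).spawn(schedule.n_chains)

        best_x, best_f, evals = None, math.inf, 0
        for k, ss in enumerate(seeds):
            rng = np.random.default_rng(ss)
            cx, cf, ce = self._anneal_chain(
                rng, lo, hi, step, schedule, chain_budget, midpoint=(k == 0)
            )
            evals += ce
            if schedule.polish:
                res = self._polish(cx, lo, hi, 3000)
                evals += res.nfev
                if np.isfinite(res.fun) and res.fun <= cf:
                    cx, cf = np.clip(res.x, lo, hi), float(res.fun)
            if cf < best_f:
                best_x, best_f = np.asarray(cx, float), cf

        converged = True
        if schedule.polish:
            # one restart on the winner guards against simplex collapse
            res2 = self._polish(best_x, lo, hi, 1500)
            evals += res2.nfev
            if np.isfinite(res2.fun) and res2.fun <= best_f:
                best_x, best_f = np.clip(res2.x, lo, hi), float(res2.fun)
            best_x, best_f, extra = self._location_rescue(best_x, best_f, lo, hi)
            evals += extra

        params = dict(self._full)
        params.update(zip(self.free, best_x))
        fitted = self._build_model(params)
        mu = self._mu(params)
        r2_adj, rmse = fit_statistics(self._y, mu, self.n_params)
        stats = FitStatistics(
            log_likelihood=-best_f,
            n_params=self.n_params,
            r2_adj=r2_adj,
            rmse=rmse,
            n_obs=self._n,
        )
        results = GrowthMLResults(
            model=fitted,
            stats=stats,
            params=params,
            free=list(self.free),
            bounds={n: self.bounds[n] for n in self.free},
            converged=converged,
            evaluations=evals,
            schedule=schedule,
            _estimator=self,
            _theta=np.asarray(best_x, float),
        )
        return results

    def _build_model(self, p: dict) -> GrowthModel:
        t = self.template
        mods = {}
        for role in _MOD_ROLES:
            attr = _ROLE_ATTR[role]
            fam = getattr(t, attr).family
            mods[attr] = Modifier(fam, p[f"{role}_a"], p[f"{role}_b"])
        overrides = None
        if t.comp_intercept_by_site is not None:
            overrides = {s: p[f"comp_a[{s}]"] for s in t.comp_intercept_by_site}
            # canonical comp modifier holds the shared b; a=1 placeholder
            mods["competition"] = Modifier(t.competition.family, 1.0, p["comp_b"])
        return GrowthModel(
            mg=p["mg"],
            dispersion=p["dispersion"],
            covariates=dict(t.covariates),
            comp_intercept_by_site=overrides,
            **mods,
        )


@dataclass
class GrowthMLResults:
    """Estimates, uncertainty and diagnostics from :meth:`GrowthML.fit`."""

    model: GrowthModel
    stats: FitStatistics
    params: dict
    free: list
    bounds: dict
    converged: bool
    evaluations: int
    schedule: AnnealingSchedule
    _estimator: GrowthML = field(repr=False)
    _theta: np.ndarray = field(repr=False)
    support_delta: float = 2.0

    @property
    def llf(self) -> float:
        return self.stats.log_likelihood

    @property
    def aic(self) -> float:
        return self.stats.aic

    def support_interval(self, name: str, delta: float = 2.0, profile: bool = False):
        """Likelihood support interval for one free parameter.

        Returns ``(low, high, at_bound)``: the covariate values at which
        the (profile) log-likelihood has dropped ``delta`` units below
        its maximum, searched by bisection toward each bound.  When the
        likelihood never drops by ``delta`` before a bound, that bound
        is returned and flagged.  With ``profile=True`` the remaining
        free parameters are re-optimised at each probe (slower).
        """
        if name not in self.free:
            raise ValueError(f"{name!r} is not a free parameter")
        est = float(self.params[name])
        i = self.free.index(name)
        nll0 = -self.llf
        target = nll0 + delta
        others = [j for j in range(len(self.free)) if j != i]

        def f(v: float) -> float:
            th = self._theta.copy()
            th[i] = v
            if not profile or not others:
                return min(self._estimator.nll(th), _BIG)

            def sub(to):
                full = th.copy()
                full[others] = to
                return self._estimator.nll(full)

            res = minimize(
                sub,
                th[others],
                method="Nelder-Mead",
                bounds=[self.bounds[self.free[j]] for j in others],
                options={"maxiter": 50 * len(others), "fatol": 1e-6},
            )
            return min(float(res.fun), _BIG)

        lo_b, hi_b = self.bounds[name]
        out = []
        flagged = False
        for bound, side in ((lo_b, "low"), (hi_b, "high")):
            fb = f(bound)
            if fb < target:
                out.append(bound)
                flagged = True
                continue
            a, b = (bound, est) if side == "low" else (est, bound)
            try:
                root = brentq(lambda v: f(v) - target, a, b, xtol=1e-9 * max(1, abs(est)))
            except ValueError:
                root = bound
                flagged = True
            out.append(root)
        low, high = min(out[0], est), max(out[1], est)
        return low, high, flagged

    def support_intervals(self, delta: float = 2.0, profile: bool = False) -> dict:
        return {n: self.support_interval(n, delta=delta, profile=profile) for n in self.free}

    def summary(self) -> str:
        """Human-readable parameter and fit-statistic table."""
        lines = [
            "Multiplicative growth model (Gamma ML)",
            "=" * 54,
            f"N obs: {self.stats.n_obs}    N par: {self.stats.n_params}",
            f"LL: {self.llf:.1f}    AIC: {self.aic:.1f}    "
            f"R2adj: {self.stats.r2_adj:.2f}    RMSE: {self.stats.rmse:.1f}",
            "-" * 54,
            f"{'parameter':<14}{'estimate':>12}  {'support interval':>22}",
        ]
        si = self.support_intervals()
        for n in self.free:
            lo, hi, flag = si[n]
            mark = "*" if flag else ""
            lines.append(f"{n:<14}{self.params[n]:>12.4g}  ({lo:.4g}, {hi:.4g}){mark}")
        lines.append("-" * 54)
        lines.append("* interval truncated at a parameter bound")
        return "\n".join(lines)

    def to_text(self) -> str:
        """Serialise fit results (model, intervals, stats) as text."""
        si = self.support_intervals()
        lines = [self.model.to_text(), "[fit]"]
        lines.append(f"log_likelihood = {float(self.llf)!r}")
        lines.append(f"n_params = {self.stats.n_params}")
        lines.append(f"aic = {float(self.aic)!r}")
        lines.append(f"r2_adj = {float(self.stats.r2_adj)!r}")
        lines.append(f"rmse = {float(self.stats.rmse)!r}")
        lines.append(f"n_obs = {self.stats.n_obs}")
        lines.append(f"evaluations = {self.evaluations}")
        lines.append(f"seed = {self.schedule.seed}")
        for n in self.free:
            lo, hi, flag = si[n]
            lines.append(f"support.{n} = {float(lo)!r} {float(hi)!r} at_bound={flag}")
        return "\n".join(lines) + "\n"


def fit_model(
    data: pd.DataFrame,
    template: GrowthModel,
    bounds: dict | None = None,
    schedule: AnnealingSchedule | None = None,
    free=None,
) -> GrowthMLResults:
    """Convenience wrapper: construct :class:`GrowthML` and fit."""
    return GrowthML(data, template, free=free, bounds=bounds).fit(schedule)


def candidate_template(template: GrowthModel, active, free_sites=None) -> tuple[GrowthModel, list]:
    """Template and free-parameter list for a nested candidate model.

    ``active`` names the modifiers retained (subset of ``size``,
    ``comp``, ``prec``, ``temp``).  A deactivated modifier is pinned to
    the constant 1 (a zero-rate Laplace kernel) and its parameters
    leave the free list, so parameter counts reflect only what is
    estimated: e.g. a size-only candidate has MG, the two size
    parameters and the Gamma dispersion.

    With per-site competition intercepts, ``free_sites`` selects which
    sites' intercepts are estimated; by default those whose template
    value differs from the canonical 1 (the reference site stays
    fixed).
    """
    active = set(active)
    unknown = active - set(_MOD_ROLES)
    if unknown:
        raise ValueError(f"unknown modifier role(s) {sorted(unknown)}")
    if "size" not in active:
        raise ValueError("candidates must retain the size modifier")
    kwargs = {}
    for role in _MOD_ROLES:
        if role not in active:
            kwargs[_ROLE_ATTR[role]] = Modifier("modified_laplace", 0.0, 0.0)
    if "comp" not in active and template.comp_intercept_by_site is not None:
        kwargs["comp_intercept_by_site"] = None
    tmpl = template.replace(**kwargs)
    free = ["mg"]
    for role in _MOD_ROLES:
        if role not in active:
            continue
        if role == "comp" and tmpl.comp_intercept_by_site is not None:
            sites = (
                sorted(free_sites)
                if free_sites is not None
                else sorted(
                    s for s, a in tmpl.comp_intercept_by_site.items() if a != 1.0
                )
            )
            free += [f"comp_a[{s}]" for s in sites]
            free.append("comp_b")
        elif role == "comp":
            free.append("comp_b")  # intercept fixed at the template value
        else:
            free += [f"{role}_a", f"{role}_b"]
    free.append("dispersion")
    return tmpl, free


# ----------------------------------------------------------------------
@dataclass
class ModelComparison:
    """AIC comparison of candidate models fitted to the same data."""

    table: pd.DataFrame
    reference: str
    selected: str

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def compare_models(stats: dict | list, reference: str) -> ModelComparison:
    """Rank labelled fits by AIC against a designated reference model.

    Parameters
    ----------
    stats : dict or list of (label, FitStatistics-like)
        Each entry needs ``log_likelihood``, ``n_params``, ``r2_adj``,
        ``rmse`` (and ``n_obs`` when available — models fitted to
        different observation counts are rejected).
    reference : str
        Label whose AIC anchors the Delta-AIC column (Delta = 0 there).

    Selection rule: the lowest-AIC model wins outright only when it
    beats the runner-up by >= 2 AIC units; otherwise the model with the
    fewest parameters among those within 2 units of the minimum is
    selected.
    """
    items = list(stats.items()) if isinstance(stats, dict) else list(stats)
    if len(items) < 2:
        raise ValueError("need at least two models to compare")
    labels = [lab for lab, _ in items]
    if reference not in labels:
        raise ValueError(f"reference {reference!r} not among labels {labels}")
    n_obs = {getattr(s, "n_obs", None) for _, s in items}
    n_obs.discard(None)
    if len(n_obs) > 1:
        raise ValueError(f"models fitted on different observation counts: {sorted(n_obs)}")

    rows = []
    for lab, s in items:
        rows.append(
            {
                "model": lab,
                "log_likelihood": s.log_likelihood,
                "n_params": s.n_params,
                "aic": aic(s.log_likelihood, s.n_params),
                "r2_adj": s.r2_adj,
                "rmse": s.rmse,
            }
        )
    df = pd.DataFrame(rows)
    ref_aic = float(df.loc[df["model"] == reference, "aic"].iloc[0])
    df["delta_aic"] = df["aic"] - ref_aic

    by_aic = df.sort_values(["aic", "n_params"]).reset_index(drop=True)
    best_aic = float(by_aic["aic"].iloc[0])
    if len(by_aic) > 1 and by_aic["aic"].iloc[1] - best_aic >= 2.0:
        selected = str(by_aic["model"].iloc[0])
    else:
        close = by_aic[by_aic["aic"] - best_aic < 2.0]
        selected = str(close.sort_values(["n_params", "aic"])["model"].iloc[0])
    df = df[["model", "log_likelihood", "n_params", "aic", "delta_aic", "r2_adj", "rmse"]]
    return ModelComparison(table=df, reference=reference, selected=selected)
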