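"""The multiplicative BAI growth model and its Gamma observation model.

The annual basal area increment of a plot is modelled as

    BAI = MG * f1(Size) * f2(Competition) * f3(Precipitation) * f4(Temperature) + eps

where MG is the maximum potential growth (mm^2/yr, the growth attained
when every covariate is at its optimum), each ``f_i`` is a unit-interval
:class:`~dendrofit.modifiers.Modifier`, and the error is Gamma
distributed around the multiplicative mean.  The Gamma is
mean-parameterised: shape ``k`` equals the model's dispersion parameter
and scale ``mu / k``, so ``E[BAI] = mu`` and ``Var[BAI] = mu^2 / k`` —
the heteroscedastic, right-skewed error structure seen in raw BAI data.

The competition modifier's intercept may vary by site (parallel
competition curves on otherwise comparable sites); all other parameters
are shared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .modifiers import Modifier, eval_family

__all__ = [
    "GrowthModel",
    "FitStatistics",
    "gamma_nll",
    "fit_statistics",
    "aic",
]


@dataclass(frozen=True)
class GrowthModel:
    """A fully parameterised multiplicative growth model.

    Parameters
    ----------
    mg : float
        Maximum potential growth, mm^2/yr; must be > 0.
    size, competition, precipitation, temperature : Modifier
        The four response functions.  Size acts on mean tree diameter
        (mm), competition on plot basal area (m^2/ha), precipitation
        and temperature on the seasonal aggregates named in
        ``covariates``.
    dispersion : float
        Gamma shape parameter (> 0); larger values mean tighter
        observation noise (CV = 1/sqrt(dispersion)).
    covariates : dict
        Maps ``"precipitation"`` / ``"temperature"`` to the seasonal
        aggregate column each modifier consumes (e.g. ``"P_Hyd"``,
        ``"Tmax_Spr"``).
    comp_intercept_by_site : dict or None
        Optional site -> intercept overrides for the competition
        modifier's ``a`` parameter.  When set, predictions require a
        site id and unknown sites are rejected.
    """

    mg: float
    size: Modifier
    competition: Modifier
    precipitation: Modifier
    temperature: Modifier
    dispersion: float = 1.0
    covariates: dict = field(
        default_factory=lambda: {"precipitation": "P_Hyd", "temperature": "Tmax_Spr"}
    )
    comp_intercept_by_site: dict | None = None

    def __post_init__(self) -> None:
        if not (self.mg > 0 and np.isfinite(self.mg)):
            raise ValueError(f"MG must be positive and finite, got {self.mg}")
        if not (self.dispersion > 0 and np.isfinite(self.dispersion)):
            raise ValueError(f"dispersion must be positive, got {self.dispersion}")
        if self.comp_intercept_by_site is not None:
            for site, a in self.comp_intercept_by_site.items():
                # construct to trigger family validation of the override
                self.competition.replace(a=a)

    # ------------------------------------------------------------------
    def _comp_values(self, comp, site):
        """Competition modifier values, honouring per-site intercepts."""
        comp = np.asarray(comp, dtype=float)
        if self.comp_intercept_by_site is None:
            return eval_family(
                self.competition.family, comp, self.competition.a, self.competition.b
            )
        if site is None:
            raise ValueError(
                "model has site-specific competition intercepts; a site id is required"
            )
        shape = comp.shape
        comp = np.atleast_1d(comp)
        sites = np.asarray(site)
        if sites.ndim == 0:
            sites = np.full(comp.shape, sites)
        out = np.empty_like(comp, dtype=float)
        known = set(self.comp_intercept_by_site)
        unknown = set(np.unique(sites)) - known
        if unknown:
            raise KeyError(
                f"unknown site id(s) {sorted(unknown)}; "
                f"declared sites: {sorted(known)}"
            )
        for s in known:
            mask = sites == s
            if np.any(mask):
                out[mask] = eval_family(
                    self.competition.family,
                    comp[mask],
                    self.comp_intercept_by_site[s],
                    self.competition.b,
                )
        return out.reshape(shape)

    def predict(self, size, comp, prec, temp, site=None):
        """Mean BAI (mm^2/yr) for the given covariates.

        All arguments broadcast; returns a scalar for scalar input.
        """
        scalar = np.isscalar(size) and np.isscalar(comp)
        f1 = eval_family(self.size.family, size, self.size.a, self.size.b)
        f2 = self._comp_values(comp, site)
        f3 = eval_family(
            self.precipitation.family, prec, self.precipitation.a, self.precipitation.b
        )
        f4 = eval_family(
            self.temperature.family, temp, self.temperature.a, self.temperature.b
        )
        mu = self.mg * f1 * f2 * f3 * f4
        return float(mu) if scalar and np.ndim(mu) == 0 else mu

    def replace(self, **kwargs) -> "GrowthModel":
        return replace(self, **kwargs)

    # -------------------------- serialization -------------------------
    def to_text(self) -> str:
        """Serialise as a keyed text document (round-trips bit-exactly)."""
        lines = [
            "[growth_model]",
            f"mg = {float(self.mg)!r}",
            f"dispersion = {float(self.dispersion)!r}",
        ]
        for name in ("size", "competition", "precipitation", "temperature"):
            m: Modifier = getattr(self, name)
            lines.append(f"{name} = {m.family} a={float(m.a)!r} b={float(m.b)!r}")
        for role, col in self.covariates.items():
            lines.append(f"covariate.{role} = {col}")
        if self.comp_intercept_by_site:
            for site, a in sorted(self.comp_intercept_by_site.items()):
                lines.append(f"comp_intercept.{site} = {float(a)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "GrowthModel":
        kv = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith(("#", "[")):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        mods = {}
        for name in ("size", "competition", "precipitation", "temperature"):
            family, a_part, b_part = kv[name].split()
            mods[name] = Modifier(
                family, float(a_part.split("=")[1]), float(b_part.split("=")[1])
            )
        covs = {
            k.split(".", 1)[1]: v for k, v in kv.items() if k.startswith("covariate.")
        }
        overrides = {
            k.split(".", 1)[1]: float(v)
            for k, v in kv.items()
            if k.startswith("comp_intercept.")
        }
        kwargs = dict(
            mg=float(kv["mg"]),
            dispersion=float(kv["dispersion"]),
            comp_intercept_by_site=overrides or None,
            **mods,
        )
        if covs:
            kwargs["covariates"] = covs
        return cls(**kwargs)


# ----------------------------------------------------------------------
def gamma_nll(model: GrowthModel, bai, size, comp, prec, temp, site=None) -> float:
    """Negative log-likelihood of observed BAI under the Gamma model.

    Shape ``k = model.dispersion``, scale ``mu / k`` with ``mu`` the
    model prediction, so the mean equals the prediction.  Observations
    and predictions must be strictly positive (Gamma support): a plot
    mean BAI of zero is a data problem, not a floor-able value.
    """
    y = np.asarray(bai, dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        bad = np.flatnonzero(~np.isfinite(y) | (y <= 0))
        raise ValueError(
            f"observations must be finite and > 0; offending indices {bad[:5].tolist()}"
        )
    mu = np.asarray(model.predict(size, comp, prec, temp, site=site), dtype=float)
    if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
        bad = np.flatnonzero(~np.isfinite(mu) | (mu <= 0))
        raise ValueError(
            f"predicted means must be finite and > 0; offending indices {bad[:5].tolist()}"
        )
    k = model.dispersion
    theta = mu / k
    logpdf = (k - 1.0) * np.log(y) - y / theta - k * np.log(theta) - gammaln(k)
    return float(-np.sum(logpdf))


def aic(log_likelihood: float, n_params: int) -> float:
    """Akaike Information Criterion: -2 LL + 2 k."""
    if n_params < 0:
        raise ValueError("n_params must be >= 0")
    return -2.0 * log_likelihood + 2.0 * n_params


@dataclass(frozen=True)
class FitStatistics:
    """Goodness-of-fit summary for one fitted model."""

    log_likelihood: float
    n_params: int
    r2_adj: float
    rmse: float
    n_obs: int | None = None

    @property
    def aic(self) -> float:
        return aic(self.log_likelihood, self.n_params)


def fit_statistics(observed, predicted, n_params: int) -> tuple[float, float]:
    """Adjusted R^2 and RMSE of predictions against observations.

    RMSE is sqrt(mean squared residual); the adjusted R^2 applies the
    usual (n-1)/(n-p-1) penalty to ``1 - SSE/SST``.

    Raises
    ------
    ValueError
        If lengths differ, n < n_params + 2, or the observations have
        zero variance (R^2 undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n < n_params + 2:
        raise ValueError(f"need at least n_params + 2 = {n_params + 2} points, got {n}")
    resid = obs - pred
    sse = float(np.sum(resid**2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observations have zero variance; R^2 is undefined")
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    rmse = math.sqrt(sse / n)
    return r2_adj, rmse
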