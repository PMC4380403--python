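"""Annealing estimator, support intervals, AIC comparison."""

import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from dendrofit.fitting import (
    AnnealingSchedule,
    GrowthML,
    GrowthMLResults,
    candidate_template,
    compare_models,
)
from dendrofit.model import FitStatistics, GrowthModel, aic
from dendrofit.modifiers import Modifier
from dendrofit.synthetic import pisy_model, simulate_observations


def _flat_template(dispersion=5.0):
    one = Modifier("modified_laplace", 0.0, 0.0)
    return GrowthModel(
        mg=100.0, size=one, competition=one, precipitation=one, temperature=one,
        dispersion=dispersion,
    )


def _toy_data(n=200, mean=80.0, shape=5.0, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "bai": rng.gamma(shape, mean / shape, n),
            "size": np.full(n, 150.0),
            "comp": np.full(n, 10.0),
            "prec": np.full(n, 500.0),
            "temp": np.full(n, 15.0),
        }
    )


class TestFitModel:
    def test_mg_only_recovers_sample_mean(self):
        """With fixed Gamma shape the ML mean is the sample mean."""
        data = _toy_data()
        res = GrowthML(data, _flat_template(), free=["mg"]).fit(
            AnnealingSchedule(max_evaluations=2000, n_chains=1, seed=0)
        )
        assert res.params["mg"] == pytest.approx(data["bai"].mean(), rel=1e-3)

    def test_same_seed_same_result(self):
        data = _toy_data()
        sched = AnnealingSchedule(max_evaluations=1500, n_chains=2, seed=42)
        est = GrowthML(data, _flat_template(), free=["mg", "dispersion"])
        r1, r2 = est.fit(sched), est.fit(sched)
        assert r1.params == r2.params
        assert r1.llf == r2.llf

    def test_estimates_within_bounds(self):
        data = _toy_data()
        res = GrowthML(data, _flat_template(), free=["mg", "dispersion"]).fit(
            AnnealingSchedule(max_evaluations=1500, seed=3)
        )
        for name in res.free:
            lo, hi = res.bounds[name]
            assert lo <= res.params[name] <= hi

    def test_rejects_nonpositive_bai(self):
        data = _toy_data()
        data.loc[0, "bai"] = -1.0
        with pytest.raises(ValueError, match="non-positive BAI"):
            GrowthML(data, _flat_template())

    def test_optimum_beats_coarse_grid(self):
        """The returned NLL undercuts every point of a parameter grid."""
        data = _toy_data(n=120)
        est = GrowthML(data, _flat_template(), free=["mg"])
        res = est.fit(AnnealingSchedule(max_evaluations=1000, n_chains=1, seed=1))
        grid = np.linspace(*est.bounds["mg"], 200)
        assert -res.llf <= min(est.nll([g]) for g in grid) + 1e-9


class TestParameterRecovery:
    def test_recovery_near_optimality(self, qufg_truth):
        """On synthetic data the fit's NLL is within 2 units of the
        generating parameters' NLL (and parameters are recovered)."""
        obs = simulate_observations(qufg_truth, n_plots=20, n_years=30, seed=11)
        tmpl, free = candidate_template(qufg_truth, ("size", "comp", "prec", "temp"))
        est = GrowthML(obs, tmpl, free=free)
        res = est.fit(AnnealingSchedule(max_evaluations=12000, n_chains=3, seed=2))
        t = qufg_truth
        true_theta = [t.mg, t.size.a, t.size.b, t.competition.b,
                      t.precipitation.a, t.precipitation.b,
                      t.temperature.a, t.temperature.b, t.dispersion]
        assert -res.llf <= est.nll(true_theta) + 2.0
        assert res.params["comp_b"] == pytest.approx(t.competition.b, rel=0.25)


class TestSupportIntervals:
    def _quadratic_results(self):
        """A stub whose NLL is (theta-3)^2: LL drop of 2 at 3 +/- sqrt(2)."""
        est = SimpleNamespace(nll=lambda th: float((th[0] - 3.0) ** 2))
        return GrowthMLResults(
            model=_flat_template(),
            stats=FitStatistics(0.0, 1, 1.0, 0.0, n_obs=10),
            params={"theta": 3.0},
            free=["theta"],
            bounds={"theta": (-10.0, 10.0)},
            converged=True,
            evaluations=1,
            schedule=AnnealingSchedule(),
            _estimator=est,
            _theta=np.array([3.0]),
        )

    def test_quadratic_closed_form(self):
        lo, hi, flagged = self._quadratic_results().support_interval("theta")
        assert lo == pytest.approx(3.0 - math.sqrt(2.0), abs=1e-6)
        assert hi == pytest.approx(3.0 + math.sqrt(2.0), abs=1e-6)
        assert not flagged

    def test_flat_profile_returns_bounds_flagged(self):
        res = self._quadratic_results()
        res._estimator = SimpleNamespace(nll=lambda th: 0.0)
        lo, hi, flagged = res.support_interval("theta")
        assert (lo, hi) == (-10.0, 10.0)
        assert flagged

    def test_interval_contains_estimate(self):
        res = self._quadratic_results()
        lo, hi, _ = res.support_interval("theta", delta=0.5)
        assert lo <= res.params["theta"] <= hi


class TestAICComparison:
    def _stats(self, ll, k, n_obs=1000):
        return FitStatistics(ll, k, 0.5, 10.0, n_obs=n_obs)

    def test_delta_aic_against_reference(self):
        cmp = compare_models(
            {"size": self._stats(-3830.6, 4), "complete": self._stats(-3362.9, 9)},
            reference="complete",
        )
        row = cmp.table.set_index("model")
        assert row.loc["size", "delta_aic"] == pytest.approx(925.4, abs=1e-9)
        assert row.loc["complete", "delta_aic"] == 0.0
        assert cmp.selected == "complete"

    def test_aic_formula(self):
        assert aic(-3362.9, 9) == pytest.approx(6743.8)
        assert aic(0.0, 0) == 0.0
        assert aic(-3830.6, 4) == pytest.approx(7669.2)

    def test_tie_prefers_fewer_parameters(self):
        # identical AIC: LL difference exactly offsets the extra parameter
        cmp = compare_models(
            {"small": self._stats(-101.0, 1), "big": self._stats(-100.0, 2)},
            reference="small",
        )
        assert cmp.selected == "small"

    def test_clear_winner_needs_two_units(self):
        cmp = compare_models(
            {"a": self._stats(-100.0, 2), "b": self._stats(-103.0, 2)},
            reference="a",
        )
        assert cmp.selected == "a"

    def test_different_observation_counts_rejected(self):
        with pytest.raises(ValueError, match="observation counts"):
            compare_models(
                {"a": self._stats(-10.0, 2, 100), "b": self._stats(-12.0, 2, 90)},
                reference="a",
            )

    def test_needs_reference_and_two_models(self):
        with pytest.raises(ValueError):
            compare_models({"a": self._stats(-10.0, 2)}, reference="a")
        with pytest.raises(ValueError, match="reference"):
            compare_models(
                {"a": self._stats(-10.0, 2), "b": self._stats(-11.0, 2)}, reference="c"
            )


class TestCandidateTemplates:
    def test_parameter_counts_match_nesting(self, qufg_truth):
        for active, expected in [
            (("size",), 4),
            (("size", "prec", "temp"), 8),
            (("size", "comp"), 5),
            (("size", "comp", "prec", "temp"), 9),
        ]:
            _, free = candidate_template(qufg_truth, active)
            assert len(free) == expected

    def test_site_intercept_counting(self):
        # one free site intercept (the other fixed at 1) -> 10 parameters
        _, free = candidate_template(pisy_model(), ("size", "comp", "prec", "temp"))
        assert len(free) == 10
        assert "comp_a[DU]" in free and "comp_a[NE]" not in free

    def test_deactivated_modifier_is_constant_one(self, qufg_truth):
        tmpl, _ = candidate_template(qufg_truth, ("size",))
        assert tmpl.competition(50.0) == 1.0
        assert tmpl.temperature(35.0) == 1.0
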