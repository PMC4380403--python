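"""Scenario adjustment, competition paths, projections, spline filter."""

import math

import numpy as np
import pandas as pd
import pytest

from dendrofit.projection import (
    ProjectionResult,
    ScenarioConfig,
    adjust_scenario,
    competition_trajectory,
    project_constant_diameter,
    project_dynamic,
    smooth_spline,
    summarize_replicates,
)
from dendrofit.synthetic import _site_climate_config, generate_climate, qufg_model


def _monthly(years, prec=40.0, tmax=16.0):
    rows = [
        {"year": y, "month": m, "prec": prec, "tmax": tmax, "tmean": tmax - 5, "tmin": tmax - 10}
        for y in years
        for m in range(1, 13)
    ]
    return pd.DataFrame(rows)


class TestAdjustScenario:
    def test_identity_when_series_agree(self):
        obs = _monthly(range(2001, 2012))
        scen = _monthly(range(2001, 2101))
        out = adjust_scenario(scen, obs, (2001, 2011))
        pd.testing.assert_frame_equal(out, scen)

    def test_warm_bias_removed_additively(self):
        obs = _monthly(range(2001, 2012), tmax=16.0)
        scen = _monthly(range(2001, 2101), tmax=18.0)
        out = adjust_scenario(scen, obs, (2001, 2011))
        assert np.allclose(out["tmax"], 16.0)

    def test_dry_bias_removed_multiplicatively(self):
        obs = _monthly(range(2001, 2012), prec=40.0)
        scen = _monthly(range(2001, 2101), prec=20.0)
        out = adjust_scenario(scen, obs, (2001, 2011))
        assert np.allclose(out["prec"], 40.0)

    def test_zero_scenario_precipitation_falls_back_additive(self):
        obs = _monthly(range(2001, 2012), prec=40.0)
        scen = _monthly(range(2001, 2101), prec=40.0)
        scen.loc[scen["month"] == 7, "prec"] = 0.0
        with pytest.warns(UserWarning, match="additive"):
            out = adjust_scenario(scen, obs, (2001, 2011))
        assert np.allclose(out.loc[out["month"] == 7, "prec"], 40.0)

    def test_missing_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            adjust_scenario(_monthly(range(2050, 2060)), _monthly(range(2001, 2012)), (2001, 2011))


class TestCompetitionTrajectory:
    def _cfg(self, **kw):
        base = dict(climate=_monthly(range(2001, 2101)), competition_now=20.0,
                    recent_rate=0.5, asymptote=30.0, horizon=2100)
        base.update(kw)
        return ScenarioConfig(**base)

    def test_heavy_thinning_holds_present_level(self):
        cfg = self._cfg(competition_mode="heavy_thinning", competition_now=15.0)
        path = competition_trajectory(cfg, np.arange(2001, 2101))
        assert np.allclose(path, 15.0)

    def test_control_ramps_to_asymptote(self):
        cfg = self._cfg(competition_mode="control")
        path = competition_trajectory(cfg, np.arange(2001, 2101))
        assert path[0] == 20.0
        assert path[20] == pytest.approx(30.0)  # reached at year 20
        assert np.allclose(path[20:], 30.0)
        assert np.all(np.diff(path[:20]) > 0)

    def test_saturated_start_stays_constant(self):
        cfg = self._cfg(competition_mode="control", competition_now=30.0)
        path = competition_trajectory(cfg, np.arange(2001, 2101))
        assert np.allclose(path, 30.0)

    def test_constant_diameter_mode_freezes_competition(self):
        cfg = self._cfg(projection_mode="constant_diameter", dbh_class=100.0)
        path = competition_trajectory(cfg, np.arange(2001, 2101))
        assert np.allclose(path, 20.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            self._cfg(recent_rate=-0.1)


class TestDynamicProjection:
    def test_single_step_diameter_update(self):
        # 200 mm + 1000 mm^2 of basal area -> 203.158 mm
        assert math.sqrt(200.0**2 + 4 * 1000.0 / math.pi) == pytest.approx(203.158, abs=1e-3)

    def test_cumulative_bai_equals_basal_area_change(self):
        model = qufg_model()
        cfg = ScenarioConfig(
            climate=generate_climate(
                _site_climate_config(505.0, 16.0, seed=4, years=(2000, 2100))
            ),
            competition_mode="heavy_thinning",
            initial_dbh=100.0,
            competition_now=8.0,
            horizon=2100,
        )
        res = project_dynamic(model, cfg)
        final_dbh = math.sqrt(res.dbh_path[-1] ** 2 + 4 * res.bai[-1] / math.pi)
        assert res.bai.sum() == pytest.approx(
            math.pi / 4 * (final_dbh**2 - res.dbh_path[0] ** 2), abs=1e-9
        )
        assert np.all(np.diff(res.dbh_path) >= 0)

    def test_requires_initial_dbh(self):
        with pytest.raises(ValueError, match="initial_dbh"):
            project_dynamic(qufg_model(), ScenarioConfig(climate=_monthly(range(2001, 2101))))

    def test_extrapolation_flagging(self):
        model = qufg_model()
        clim = generate_climate(_site_climate_config(505.0, 16.0, seed=4, years=(2000, 2100)))
        cfg = ScenarioConfig(
            climate=clim, competition_mode="heavy_thinning", initial_dbh=100.0,
            competition_now=8.0, horizon=2100,
            calibration_ranges={"size": (88.0, 150.0)},
        )
        res = project_dynamic(model, cfg)
        # growth eventually pushes the diameter past the calibrated range
        assert res.extrapolated.any()
        assert not res.extrapolated[0]


class TestConstantDiameterProjection:
    def _cfg(self, clim, **kw):
        base = dict(climate=clim, projection_mode="constant_diameter",
                    competition_now=8.0, horizon=2100)
        base.update(kw)
        return ScenarioConfig(**base)

    def test_constant_inputs_give_constant_bai(self):
        clim = _monthly(range(2000, 2101), prec=60.0, tmax=16.0)
        res = project_constant_diameter(qufg_model(), self._cfg(clim, dbh_class=100.0))
        assert np.allclose(res.bai, res.bai[0])

    def test_size_class_ratio_equals_modifier_ratio(self):
        model = qufg_model()
        clim = _monthly(range(2000, 2101))
        small = project_constant_diameter(model, self._cfg(clim, dbh_class=100.0))
        large = project_constant_diameter(model, self._cfg(clim, dbh_class=150.0))
        assert np.allclose(large.bai / small.bai, model.size(150.0) / model.size(100.0))

    def test_warming_ramp_peaks_at_optimum_crossing(self):
        model = qufg_model()
        years = list(range(2000, 2061))
        rows = []
        for i, y in enumerate(years):
            t = 12.0 + 0.15 * i  # crosses the 16.1 degC optimum ~year 27
            for m in range(1, 13):
                rows.append({"year": y, "month": m, "prec": 50.0, "tmax": t,
                             "tmean": t - 5, "tmin": t - 10})
        res = project_constant_diameter(
            model, self._cfg(pd.DataFrame(rows), dbh_class=100.0, horizon=2060)
        )
        peak_year = res.years[np.argmax(res.bai)]
        assert abs(peak_year - 2027) <= 1


class TestSmoothSpline:
    def test_constant_series_unchanged(self):
        y = np.full(100, 7.3)
        assert np.allclose(smooth_spline(y), y, atol=1e-10)

    def _amplitude_ratio(self, period, n=300):
        t = np.arange(n)
        y = np.sin(2 * np.pi * t / period)
        s = smooth_spline(y)
        A = np.vstack([np.sin(2 * np.pi * t / period), np.cos(2 * np.pi * t / period)]).T
        coef, *_ = np.linalg.lstsq(A, s, rcond=None)
        return float(np.hypot(*coef))

    def test_half_amplitude_at_cutoff_period(self):
        assert self._amplitude_ratio(30) == pytest.approx(0.50, abs=0.05)

    def test_long_periods_pass_through(self):
        assert self._amplitude_ratio(100) > 0.9

    def test_short_series_warns(self):
        with pytest.warns(UserWarning, match="cutoff"):
            smooth_spline(np.sin(np.arange(12.0)))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            smooth_spline(np.arange(5.0))


class TestReplicateSummary:
    def test_band_is_pointwise_sd(self):
        years = np.arange(2000, 2050)
        reps = []
        for k in (1.0, 2.0, 3.0):
            bai = np.full(50, 10.0 * k)
            reps.append(
                ProjectionResult(
                    years=years, bai=bai, competition_path=np.full(50, 8.0),
                    dbh_path=None, smoothed_bai=bai, extrapolated=np.zeros(50, bool),
                )
            )
        out = summarize_replicates(reps)
        assert np.allclose(out.bai, 20.0)
        assert np.allclose(out.band, np.std([10.0, 20.0, 30.0]))
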