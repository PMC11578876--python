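"""Evaporative fraction, dry-downs, breakpoint regression and tiers."""

import numpy as np
import pandas as pd
import pytest

from critsoil.flux import (
    FluxSeries,
    detect_drydowns,
    ef_vpd_theta_analysis,
    evaporative_fraction,
    linear_plus_plateau,
    sapflow_daylight_aggregate,
    sapflow_theta_crit,
    season_filter,
    site_theta_crit,
)
from critsoil.synthetic import GeneratorConfig, gen_flux_series


def _daily_frame(theta, precip=None, le=None, h=None, start="2020-06-01"):
    n = len(theta)
    return pd.DataFrame(
        {
            "TIMESTAMP": pd.date_range(start, periods=n, freq="D"),
            "LE": 300.0 * np.ones(n) if le is None else le,
            "H": 100.0 * np.ones(n) if h is None else h,
            "SWC": theta,
            "P": np.zeros(n) if precip is None else precip,
        }
    )


class TestEvaporativeFraction:
    def test_ratio(self):
        fs = FluxSeries(_daily_frame([0.2], le=[300.0], h=[100.0]))
        assert evaporative_fraction(fs).iloc[0] == pytest.approx(0.75)

    def test_non_positive_flux_excluded(self):
        fs = FluxSeries(_daily_frame([0.2, 0.2], le=[100.0, 100.0], h=[0.0, 50.0]))
        ef = evaporative_fraction(fs)
        assert np.isnan(ef.iloc[0]) and not np.isnan(ef.iloc[1])

    def test_invariant_to_joint_rescaling(self):
        rng = np.random.default_rng(0)
        le = rng.uniform(10, 400, 30)
        h = rng.uniform(10, 400, 30)
        a = evaporative_fraction(FluxSeries(_daily_frame(np.full(30, 0.2), le=le, h=h)))
        b = evaporative_fraction(
            FluxSeries(_daily_frame(np.full(30, 0.2), le=3.7 * le, h=3.7 * h))
        )
        assert np.allclose(a, b)

    def test_bad_quality_flag_excluded(self):
        df = _daily_frame([0.2, 0.2]).assign(QC=[0, 2])
        ef = evaporative_fraction(FluxSeries(df))
        assert not np.isnan(ef.iloc[0]) and np.isnan(ef.iloc[1])


class TestDryDowns:
    def test_rain_then_twelve_decreasing_days(self):
        theta = [0.30] + list(np.linspace(0.28, 0.17, 12)) + [0.30]
        precip = [8.0] + [0.0] * 13
        dd = detect_drydowns(FluxSeries(_daily_frame(theta, precip)))
        assert len(dd) == 1 and len(dd[0]) == 12

    def test_nine_days_insufficient(self):
        theta = [0.30] + list(np.linspace(0.28, 0.20, 9)) + [0.30]
        precip = [8.0] + [0.0] * 10
        assert detect_drydowns(FluxSeries(_daily_frame(theta, precip))) == []

    def test_uptick_breaks_the_run(self):
        theta = [0.30] + list(np.linspace(0.28, 0.17, 12)) + [0.30]
        theta[6] = theta[5] + 0.001  # one uptick at day 6
        precip = [8.0] + [0.0] * 13
        assert detect_drydowns(FluxSeries(_daily_frame(theta, precip))) == []

    def test_runs_are_maximal_and_non_overlapping(self):
        theta = (
            [0.30]
            + list(np.linspace(0.28, 0.15, 14))
            + [0.31]
            + list(np.linspace(0.29, 0.16, 14))
        )
        precip = [8.0] + [0.0] * 14 + [9.0] + [0.0] * 14
        dd = detect_drydowns(FluxSeries(_daily_frame(theta, precip)))
        assert len(dd) == 2
        assert set(dd[0].indices).isdisjoint(dd[1].indices)

    def test_missing_precip_falls_back_to_maxima(self):
        theta = [0.20, 0.30] + list(np.linspace(0.29, 0.17, 12))
        df = _daily_frame(theta).drop(columns="P")
        with pytest.warns(UserWarning, match="precipitation"):
            dd = detect_drydowns(FluxSeries(df))
        assert len(dd) == 1


class TestSeasonFilter:
    def test_hemisphere_months(self):
        df = _daily_frame([0.2] * 400, start="2020-01-01")
        fs = FluxSeries(df)
        north = season_filter(fs, "N").data["TIMESTAMP"].dt.month.unique()
        south = season_filter(fs, "S").data["TIMESTAMP"].dt.month.unique()
        assert set(north) == {6, 7, 8}
        assert set(south) == {12, 1, 2}

    def test_idempotent(self):
        fs = FluxSeries(_daily_frame([0.2] * 400, start="2020-01-01"))
        once = season_filter(fs, "N")
        twice = season_filter(once, "N")
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_unknown_hemisphere_rejected(self):
        fs = FluxSeries(_daily_frame([0.2] * 5))
        with pytest.raises(ValueError):
            season_filter(fs, "X")
        with pytest.raises(ValueError):
            season_filter(fs)  # no latitude either


class TestLinearPlusPlateau:
    @staticmethod
    def _truth(x, a=0.1, b=4.0, x0=0.15):
        return a + b * np.minimum(x, x0)

    def test_noiseless_identification(self):
        x = np.linspace(0.02, 0.30, 200)
        fit = linear_plus_plateau(x, self._truth(x))
        assert fit.breakpoint == pytest.approx(0.15, abs=1e-6)
        assert fit.slope == pytest.approx(4.0, rel=1e-6)
        assert fit.valid and fit.p_value < 1e-10

    def test_monte_carlo_recovery_under_noise(self):
        bps = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.02, 0.30, 200)
            y = self._truth(x) + rng.normal(0, 0.03, 200)
            bps.append(linear_plus_plateau(x, y).breakpoint)
        assert abs(np.mean(bps) - 0.15) < 0.01

    def test_flat_data_fails_positive_slope(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0.02, 0.3, 100)
        fit = linear_plus_plateau(x, 0.5 + rng.normal(0, 0.01, 100))
        assert not fit.positive_slope or not fit.valid or fit.p_value > 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            linear_plus_plateau(np.full(50, 0.2), np.linspace(0, 1, 50))
        with pytest.raises(ValueError):
            linear_plus_plateau(np.linspace(0, 1, 5), np.linspace(0, 1, 5))


class TestSiteThetaCrit:
    def test_tier1_recovery(self):
        fs = gen_flux_series(GeneratorConfig(seed=5, theta_crit_true=0.12))
        est = site_theta_crit(fs, "N")
        assert est is not None
        assert est.diagnostics["tier"] == "summer_drydowns"
        assert abs(est.theta_crit - 0.12) < 0.01

    def test_tier2_when_summer_misses_drydowns(self):
        # generated dry-downs sit in JJA; evaluating as a southern-hemisphere
        # site makes the summer window DJF, so only tier 2 can fit
        fs = gen_flux_series(GeneratorConfig(seed=5, theta_crit_true=0.12))
        est = site_theta_crit(fs, "S")
        assert est is not None
        assert est.diagnostics["tier"] == "drydowns_any_season"

    def test_tier3_without_drydowns(self):
        rng = np.random.default_rng(3)
        n = 400
        theta = rng.uniform(0.05, 0.30, n)  # no monotone runs
        ef = 0.75 + 4.0 * np.minimum(theta - 0.15, 0) + rng.normal(0, 0.02, n)
        df = _daily_frame(
            theta, precip=np.zeros(n), le=ef * 400, h=(1 - ef) * 400, start="2020-01-01"
        )
        est = site_theta_crit(FluxSeries(df), "N")
        assert est is not None
        assert est.diagnostics["tier"] == "summer_only"

    def test_pure_noise_yields_no_estimate(self):
        rng = np.random.default_rng(4)
        n = 600
        theta = rng.uniform(0.05, 0.30, n)
        ef = rng.uniform(0.3, 0.7, n)
        df = _daily_frame(
            theta, precip=np.zeros(n), le=ef * 400, h=(1 - ef) * 400, start="2020-01-01"
        )
        assert site_theta_crit(FluxSeries(df), "N") is None


def _sapflow_hours(days=3, sfd_day=10.0, sfd_night=0.0, drop_hours=()):
    rows = []
    t0 = pd.Timestamp("2020-06-01")
    for d in range(days):
        for hh in range(24):
            if d == 0 and hh in drop_hours:
                continue
            ts = t0 + pd.Timedelta(days=d, hours=hh)
            rows.append(
                {
                    "TIMESTAMP": ts,
                    "SFD": sfd_day if 6 <= hh < 20 else sfd_night,
                    "SWC": 0.25,
                }
            )
    return pd.DataFrame(rows)


class TestSapflow:
    def test_constant_flux_daylight_mean(self):
        out = sapflow_daylight_aggregate(_sapflow_hours(sfd_night=10.0))
        assert np.allclose(out["SFD"], 10.0)

    def test_night_flux_excluded(self):
        out = sapflow_daylight_aggregate(_sapflow_hours(sfd_night=0.0))
        assert np.allclose(out["SFD"], 10.0)

    def test_low_coverage_day_dropped(self):
        with pytest.warns(UserWarning, match="coverage"):
            out = sapflow_daylight_aggregate(
                _sapflow_hours(days=3, drop_hours=range(8, 20))
            )
        assert len(out) == 2

    def test_per_tree_recovery(self):
        from critsoil.synthetic import gen_sapflow_series

        sf = gen_sapflow_series(GeneratorConfig(seed=1, n_trees=3))
        res = sapflow_theta_crit(sf, "N")
        assert len(res) == 3
        for est in res.values():
            assert est is not None
            assert est.source == "sapflow_breakpoint"
            assert abs(est.theta_crit - 0.15) < 0.015

    def test_negative_response_tree_rejected(self):
        # a tree whose flux rises as the soil dries violates the
        # positive-slope criterion and yields no estimate
        from critsoil.synthetic import gen_sapflow_series

        sf = gen_sapflow_series(GeneratorConfig(seed=2, n_trees=1))
        swc = sf["SWC"]
        flipped = sf.assign(SFD=sf["SFD"].max() * (0.4 - swc) / 0.4 * (sf["SFD"] > 0))
        res = sapflow_theta_crit(flipped, "N")
        assert all(v is None for v in res.values())


class TestEFVPDTheta:
    def test_theta_only_driver_dominates(self):
        fs = gen_flux_series(
            GeneratorConfig(seed=7, sub_daily=True, n_years=2, n_drydowns=4, ef_noise_sd=0.0)
        )
        g = ef_vpd_theta_analysis(fs)
        assert g.sens_theta / max(g.sens_vpd, 1e-12) > 5

    def test_vpd_only_driver_mirrored(self):
        fs = gen_flux_series(
            GeneratorConfig(seed=8, sub_daily=True, n_years=2, n_drydowns=4, ef_noise_sd=0.0)
        )
        df = fs.data.copy()
        # EF responds to VPD alone: linear decline above 1.5 kPa
        ef = np.clip(0.75 - 0.15 * np.maximum(df["VPD"] - 1.5, 0.0), 0.05, 1.0)
        avail = (df["LE"] + df["H"]).to_numpy()
        df["LE"], df["H"] = ef * avail, (1 - ef) * avail
        g = ef_vpd_theta_analysis(FluxSeries(df, latitude=45.0))
        assert g.sens_theta / max(g.sens_vpd, 1e-12) < 1 / 5

    def test_sand_like_site_more_theta_dominated_than_clay_like(self):
        # sand-like: sharp soil-moisture-only EF response; clay-like: gradual
        # theta response plus VPD co-limitation (the plant-limited regime)
        sand = ef_vpd_theta_analysis(
            gen_flux_series(
                GeneratorConfig(
                    seed=9,
                    sub_daily=True,
                    n_years=2,
                    n_drydowns=4,
                    ef_noise_sd=0.04,
                )
            )
        )
        base = gen_flux_series(
            GeneratorConfig(
                seed=9,
                sub_daily=True,
                n_years=2,
                n_drydowns=4,
                ef_noise_sd=0.0,
                theta_crit_true=0.26,
                theta_wet=0.42,
                theta_dry=0.08,
                smooth_knee=0.1,
            )
        )
        df = base.data.copy()
        rng = np.random.default_rng(9)
        avail = (df["LE"] + df["H"]).to_numpy()
        ef = avail * 0.0
        ef = df["LE"] / (df["LE"] + df["H"])
        ef = np.clip(
            ef - 0.2 * np.maximum(df["VPD"] - 1.0, 0.0) + rng.normal(0, 0.04, len(df)),
            1e-3,
            1 - 1e-3,
        )
        df["LE"], df["H"] = ef * avail, (1 - ef) * avail
        clay = ef_vpd_theta_analysis(FluxSeries(df, latitude=45.0))
        assert sand.relative_sensitivity_ratio > clay.relative_sensitivity_ratio

    def test_too_few_records_rejected(self):
        fs = gen_flux_series(
            GeneratorConfig(seed=10, sub_daily=True, n_years=1, n_drydowns=2)
        )
        with pytest.raises(ValueError, match="need >= 100"):
            ef_vpd_theta_analysis(FluxSeries(fs.data.head(300), latitude=45.0))
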