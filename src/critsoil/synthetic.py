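"""Seeded generators emulating the statistical structure of the field data.

The generators produce, without any downloads, inputs with the features the
analysis pipeline relies on: summer dry-down episodes (rain spike, then >= 10
days of monotone soil drying through the critical moisture), an evaporative
fraction that is flat above theta_crit and declines linearly below it with
additive Gaussian noise, diurnal radiation/VPD/temperature cycles for the
sub-daily filters, per-tree sap flux sharing one site environment, and
two-period climate grids with known potential-transpiration changes.

Everything is a pure function of its configuration and seed; randomness goes
through ``numpy.random.Generator`` seeded with PCG64, so outputs are
reproducible across platforms.  The truth model for EF is exactly the
linear-plus-plateau family the estimator fits, so recovery error is
attributable to noise and filtering rather than model mismatch; a smooth-knee
variant is available to probe mismatch robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .flux import FluxSeries
from .projection import ClimateGrid

__all__ = [
    "GeneratorConfig",
    "gen_flux_series",
    "gen_sapflow_series",
    "gen_climate_grid",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the flux / sap-flow series generators.

    Defaults describe a typical mid-latitude site: three summers with several
    rain-reset dry-downs each, EF plateau 0.75, EF noise sd 0.05, a true
    threshold of 0.15 m3 m-3 and exponential drying spanning it.
    """

    seed: int = 0
    theta_crit_true: float = 0.15
    ef_max: float = 0.75
    ef_min: float = 0.10
    ef_noise_sd: float = 0.05
    n_drydowns: int = 8
    drydown_length_days: int = 20
    theta_wet: float = 0.32  # post-rain soil moisture (m3 m-3)
    theta_dry: float = 0.04  # drying asymptote (m3 m-3)
    drying_timescale_days: float = 9.0
    n_years: int = 3
    start_year: int = 2015
    hemisphere: str = "N"
    sub_daily: bool = False
    steps_per_day: int = 48
    smooth_knee: float = 0.0  # >0 blends a logistic knee of that theta-width
    n_trees: int = 3
    sfd_max: float = 12.0  # cm3 cm-2 h-1 at full supply
    sfd_noise_gsd: float = 1.05  # lognormal multiplicative noise

    def __post_init__(self):
        if not (0 < self.theta_dry < self.theta_crit_true < self.theta_wet <= 1):
            raise ValueError("need 0 < theta_dry < theta_crit_true < theta_wet <= 1")
        if self.drydown_length_days > 85:
            raise ValueError("dry-down longer than the summer season window")
        per_year = -(-self.n_drydowns // self.n_years)
        if per_year * (self.drydown_length_days + 3) > 85:
            raise ValueError(
                "dry-downs do not fit the summer season window "
                f"({per_year} x {self.drydown_length_days + 3} days per summer)"
            )


def _ef_response(cfg: GeneratorConfig, theta: np.ndarray) -> np.ndarray:
    """Noise-free EF(theta): linear rise below theta_crit, plateau above."""
    slope = (cfg.ef_max - cfg.ef_min) / (cfg.theta_crit_true - cfg.theta_dry)
    ef = cfg.ef_max + slope * np.minimum(theta - cfg.theta_crit_true, 0.0)
    if cfg.smooth_knee > 0:
        # logistic blend of the two branches over a knee of given theta-width
        k = 4.0 / cfg.smooth_knee
        w = 1.0 / (1.0 + np.exp(-k * (theta - cfg.theta_crit_true)))
        lin = cfg.ef_max + slope * (theta - cfg.theta_crit_true)
        ef = w * cfg.ef_max + (1.0 - w) * lin
    return np.clip(ef, 0.0, 1.0)


def _theta_track(cfg: GeneratorConfig, rng: np.random.Generator):
    """Daily soil moisture with rain resets and exponential dry-downs.

    Returns (dates, theta, precip).  Dry-downs are placed in the summer
    months of each year; between them the soil is held wet with frequent
    small rain.
    """
    summer_months = (6, 7, 8) if cfg.hemisphere == "N" else (12, 1, 2)
    dates = pd.date_range(
        f"{cfg.start_year}-01-01", periods=365 * cfg.n_years, freq="D"
    )
    n = len(dates)
    theta = np.full(n, cfg.theta_wet)
    precip = np.zeros(n)

    in_summer = np.isin(dates.month, summer_months)
    # per-year summer start offsets for the dry-down launches
    starts = []
    per_year = int(np.ceil(cfg.n_drydowns / cfg.n_years))
    for yr in range(cfg.n_years):
        idx = np.where(in_summer & (dates.year == cfg.start_year + yr))[0]
        if len(idx) == 0:
            continue
        gap = cfg.drydown_length_days + 3
        for k in range(per_year):
            s = idx[0] + k * gap
            if s + cfg.drydown_length_days + 1 < idx[-1]:
                starts.append(s)
    starts = starts[: cfg.n_drydowns]

    # background: wet with small rain every few days
    wet_noise = rng.normal(0.0, 0.002, n)
    rain_days = rng.random(n) < 0.3
    precip[rain_days] = rng.gamma(2.0, 3.0, rain_days.sum())
    theta += wet_noise

    for s in starts:
        precip[s] = max(precip[s], 8.0)  # the rain event
        theta[s] = cfg.theta_wet
        L = cfg.drydown_length_days
        t = np.arange(1, L + 1)
        track = cfg.theta_dry + (cfg.theta_wet - cfg.theta_dry) * np.exp(
            -t / cfg.drying_timescale_days
        )
        theta[s + 1 : s + 1 + L] = track
        precip[s + 1 : s + 1 + L] = 0.0  # rain-free drying
        # recovery rain at the end
        if s + L + 1 < n:
            precip[s + L + 1] = max(precip[s + L + 1], 10.0)
    return dates, np.clip(theta, 0.0, 1.0), precip


def gen_flux_series(cfg: GeneratorConfig) -> FluxSeries:
    """Synthetic flux-tower-style series (daily, or sub-daily with diurnal
    meteorology when ``cfg.sub_daily``)."""
    rng = np.random.default_rng(cfg.seed)
    dates, theta, precip = _theta_track(cfg, rng)
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    seasonal = np.cos(2 * np.pi * (doy - 200) / 365.0)
    ta_daily = 14.0 + 12.0 * (seasonal if cfg.hemisphere == "N" else -seasonal)

    if not cfg.sub_daily:
        ef_true = _ef_response(cfg, theta)
        ef = np.clip(ef_true + rng.normal(0.0, cfg.ef_noise_sd, n), 1e-3, 1.0 - 1e-3)
        avail = 320.0 + 60.0 * seasonal  # available energy, W m-2
        le = ef * avail
        h = (1.0 - ef) * avail
        vpd = np.clip(0.2 + 0.09 * ta_daily + rng.normal(0, 0.15, n), 0.05, None)
        df = pd.DataFrame(
            {
                "TIMESTAMP": dates,
                "LE": le,
                "H": h,
                "SWC": theta,
                "VPD": vpd,
                "PPFD": np.clip(900.0 + 500.0 * seasonal, 50.0, None),
                "WS": rng.gamma(4.0, 0.5, n),
                "TA": ta_daily,
                "P": precip,
                "QC": np.zeros(n, dtype=int),
            }
        )
        return FluxSeries(df, latitude=45.0 if cfg.hemisphere == "N" else -35.0)

    # sub-daily: diurnal cycles on top of the daily drivers
    spd = cfg.steps_per_day
    hours = np.tile(np.arange(spd) * 24.0 / spd, n)
    day_idx = np.repeat(np.arange(n), spd)
    ts = pd.to_datetime(dates[0]) + pd.to_timedelta(
        day_idx * 24.0 + hours, unit="h"
    )
    sun = np.maximum(np.sin(np.pi * (hours - 6.0) / 14.0), 0.0)  # 06-20 arch
    ppfd = 1800.0 * sun * (0.75 + 0.25 * seasonal[day_idx])
    ta = ta_daily[day_idx] + 6.0 * np.maximum(
        np.sin(np.pi * (hours - 8.0) / 14.0), -0.4
    )
    es = 0.6108 * np.exp(17.27 * ta / (ta + 237.3))
    rh = np.clip(65.0 - 25.0 * sun + rng.normal(0, 5.0, len(ts)), 15.0, 98.0)
    vpd = np.clip(es * (1.0 - rh / 100.0), 0.01, None)
    theta_sub = theta[day_idx]
    ef_true = _ef_response(cfg, theta_sub)
    ef = np.clip(ef_true + rng.normal(0.0, cfg.ef_noise_sd, len(ts)), 1e-3, 1 - 1e-3)
    avail = np.maximum(520.0 * sun, 2.0)
    df = pd.DataFrame(
        {
            "TIMESTAMP": ts,
            "LE": ef * avail,
            "H": (1.0 - ef) * avail,
            "SWC": theta_sub,
            "VPD": vpd,
            "PPFD": ppfd,
            "WS": rng.gamma(4.0, 0.5, len(ts)),
            "TA": ta,
            "P": np.repeat(precip / spd, spd),
            "QC": np.zeros(len(ts), dtype=int),
        }
    )
    return FluxSeries(df, latitude=45.0 if cfg.hemisphere == "N" else -35.0)


def gen_sapflow_series(cfg: GeneratorConfig) -> pd.DataFrame:
    """Synthetic sub-daily sap-flow frame: per-tree sap flux density (SFD)
    around a shared theta-driven response, zero at night, lognormal
    multiplicative noise and a tree-specific scale."""
    if cfg.n_trees < 1:
        raise ValueError("need n_trees >= 1")
    rng = np.random.default_rng(cfg.seed)
    dates, theta, precip = _theta_track(cfg, rng)
    n = len(dates)
    spd = 24  # hourly
    hours = np.tile(np.arange(spd, dtype=float), n)
    day_idx = np.repeat(np.arange(n), spd)
    ts = pd.to_datetime(dates[0]) + pd.to_timedelta(day_idx * 24.0 + hours, unit="h")
    sun = np.maximum(np.sin(np.pi * (hours - 6.0) / 14.0), 0.0)
    # supply-limited relative response, same plateau/decline family as EF
    rel = _ef_response(cfg, theta[day_idx]) / cfg.ef_max

    frames = []
    scales = rng.lognormal(0.0, 0.25, cfg.n_trees)
    for tree in range(cfg.n_trees):
        noise = rng.lognormal(0.0, np.log(cfg.sfd_noise_gsd), len(ts))
        sfd = cfg.sfd_max * scales[tree] * rel * sun * noise
        frames.append(
            pd.DataFrame(
                {
                    "TIMESTAMP": ts,
                    "TREE": f"tree{tree + 1}",
                    "SFD": sfd,
                    "SWC": theta[day_idx],
                    "P": np.repeat(precip / spd, spd),
                }
            )
        )
    return (
        pd.concat(frames)
        .sort_values(["TIMESTAMP", "TREE"])
        .reset_index(drop=True)
    )


def gen_climate_grid(
    shape: tuple[int, int] = (6, 8),
    textures: list[tuple[float, float]] | None = None,
    t_monthly: np.ndarray | None = None,
    rh_monthly: np.ndarray | None = None,
    d_t: float = 1.8,
    d_rh: float = -5.0,
    precip_annual: float = 700.0,
    seed: int = 0,
) -> ClimateGrid:
    """Deterministic two-period climate grid with known texture layout.

    ``textures`` lists (sand%, clay%) pairs tiled over the grid; monthly
    temperature/relative-humidity climatologies default to a mid-latitude
    cycle.  The future period applies the uniform offsets ``d_t`` (degC) and
    ``d_rh`` (percentage points), so the per-pixel change in potential
    transpiration is known in closed form from the PET formula.
    """
    ny, nx = shape
    if textures is None:
        textures = [(92.0, 3.0), (20.0, 45.0)]
    rng = np.random.default_rng(seed)
    if t_monthly is None:
        t_monthly = 12.0 + 10.0 * np.cos(2 * np.pi * (np.arange(12) - 6.5) / 12.0)
    if rh_monthly is None:
        rh_monthly = np.full(12, 62.0)

    t_cur = np.broadcast_to(
        np.asarray(t_monthly)[:, None, None], (12, ny, nx)
    ).copy()
    rh_cur = np.broadcast_to(
        np.asarray(rh_monthly)[:, None, None], (12, ny, nx)
    ).copy()
    t_fut = t_cur + d_t
    rh_fut = np.clip(rh_cur + d_rh, 0.0, 100.0)

    sand = np.empty((ny, nx))
    clay = np.empty((ny, nx))
    for i in range(ny):
        for j in range(nx):
            s, c = textures[(i * nx + j) % len(textures)]
            sand[i, j], clay[i, j] = s, c
    precip = np.full((ny, nx), float(precip_annual))
    return ClimateGrid(
        t_current=t_cur,
        rh_current=rh_cur,
        t_future=t_fut,
        rh_future=rh_fut,
        precip_current=precip,
        precip_future=precip.copy(),
        sand=sand,
        clay=clay,
    )
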