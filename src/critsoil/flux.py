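"""Extraction of critical soil moisture thresholds from flux-style series.

The observable is the evaporative fraction EF = LE / (LE + H), a normalised
proxy for (evapo)transpiration.  During soil dry-downs -- runs of at least
ten consecutive days of declining daily soil moisture after a rain event --
EF is flat (energy-limited plateau) above the critical soil moisture and
declines approximately linearly below it.  theta_crit is the breakpoint of a
linear-plus-plateau regression of EF on soil moisture.

Input series are plain pandas DataFrames with flux-network-style columns
(one row per record)::

    TIMESTAMP  datetime64        record time
    LE         W m-2             latent heat flux
    H          W m-2             sensible heat flux
    SWC        m3 m-3            volumetric soil water content (surface layer)
    VPD        kPa               vapour pressure deficit
    PPFD       umol m-2 s-1      photosynthetic photon flux density
    WS         m s-1             wind speed
    TA         degC              air temperature
    P          mm                precipitation
    QC         int               quality flag (0 measured, 1 good gap-fill)

Sap-flow series use SFD (cm3 cm-2 h-1 sapwood-area sap flux density) and a
TREE column instead of LE/H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .supply import ThresholdEstimate

__all__ = [
    "FluxSeries",
    "DryDown",
    "BreakpointFit",
    "evaporative_fraction",
    "detect_drydowns",
    "season_filter",
    "linear_plus_plateau",
    "site_theta_crit",
    "sapflow_daylight_aggregate",
    "sapflow_theta_crit",
    "ef_vpd_theta_analysis",
]

#: daily precipitation (mm) that counts as a rain event starting a dry-down
RAIN_EVENT_MM = 2.0

#: daylight window (hours, inclusive start / exclusive end) for sap-flow means
DAYLIGHT_HOURS = (6, 20)


@dataclass
class FluxSeries:
    """A validated time-indexed flux/meteorology/soil-moisture record set."""

    data: pd.DataFrame
    latitude: float | None = None

    def __post_init__(self):
        df = self.data
        if "TIMESTAMP" not in df.columns:
            raise ValueError("series needs a TIMESTAMP column")
        ts = pd.to_datetime(df["TIMESTAMP"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        self.data = df.assign(TIMESTAMP=ts)
        if "SWC" in df.columns:
            swc = df["SWC"].dropna()
            if ((swc < 0) | (swc > 1)).any():
                raise ValueError("SWC must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path, latitude=None) -> "FluxSeries":
        return cls(pd.read_csv(path, parse_dates=["TIMESTAMP"]), latitude=latitude)

    @property
    def hemisphere(self) -> str:
        if self.latitude is None:
            raise ValueError("latitude unknown; cannot infer hemisphere")
        return "N" if self.latitude >= 0 else "S"

    def is_subdaily(self) -> bool:
        ts = self.data["TIMESTAMP"]
        if len(ts) < 2:
            return False
        return ts.diff().dropna().min() < pd.Timedelta(days=1)

    def daily(self) -> "FluxSeries":
        """24-h means per calendar day (precipitation summed)."""
        if not self.is_subdaily():
            return self
        df = self.data.set_index("TIMESTAMP")
        agg = {c: "mean" for c in df.columns if c != "P"}
        if "P" in df.columns:
            agg["P"] = "sum"
        out = df.resample("1D").agg(agg).dropna(how="all").reset_index()
        return FluxSeries(out, latitude=self.latitude)


@dataclass(frozen=True)
class DryDown:
    """One soil-moisture dry-down episode (daily resolution)."""

    start: pd.Timestamp
    end: pd.Timestamp
    indices: np.ndarray  # positional indices into the daily frame
    season: str = ""

    def __len__(self):
        return len(self.indices)


@dataclass(frozen=True)
class BreakpointFit:
    """Result of the linear-plus-plateau regression."""

    breakpoint: float
    slope: float
    intercept: float
    p_value: float
    r2: float
    plateau: float
    n: int
    positive_slope: bool
    edge_breakpoint: bool

    @property
    def valid(self) -> bool:
        return self.positive_slope and not self.edge_breakpoint


# ---------------------------------------------------------------------------
# record-level operations


def evaporative_fraction(series: FluxSeries) -> pd.Series:
    """EF = LE / (LE + H) per record, NaN where either flux is non-positive.

    Only strictly positive latent and sensible heat fluxes are meaningful for
    the water-limitation analysis; other records are excluded (NaN).
    """
    df = series.data
    if "LE" not in df.columns or "H" not in df.columns:
        raise ValueError("series needs LE and H columns")
    le, h = df["LE"], df["H"]
    ok = (le > 0) & (h > 0)
    if "QC" in df.columns:
        ok &= df["QC"].isin([0, 1])
    ef = pd.Series(np.nan, index=df.index, name="EF")
    ef[ok] = le[ok] / (le[ok] + h[ok])
    if not ok.any():
        warnings.warn("no records with positive LE and H: empty EF series")
    return ef


def detect_drydowns(
    series: FluxSeries,
    min_days: int = 10,
    rain_threshold: float = RAIN_EVENT_MM,
) -> list[DryDown]:
    """Maximal runs of >= ``min_days`` consecutive days of strictly decreasing
    daily-mean soil moisture that begin after a rain event.

    Sub-daily series are first aggregated to 24-h means.  Without a
    precipitation column, dry-downs are started at local soil-moisture maxima
    (with a warning).
    """
    daily = series.daily()
    df = daily.data
    theta = df["SWC"].to_numpy(dtype=float)
    n = len(theta)
    if n < min_days + 1:
        return []
    if "P" in df.columns:
        rain = df["P"].to_numpy(dtype=float) > rain_threshold
    else:
        warnings.warn("no precipitation column: starting dry-downs at SWC maxima")
        rain = np.zeros(n, dtype=bool)
        interior = (theta[1:-1] >= theta[:-2]) & (theta[1:-1] > theta[2:])
        rain[1:-1] = interior

    decreasing = np.diff(theta) < 0  # day i -> i+1 strictly drier
    events = []
    i = 0
    while i < n:
        if not rain[i]:
            i += 1
            continue
        # run of strictly decreasing theta starting the day after the event
        j = i + 1
        while j < n - 1 and decreasing[j]:
            j += 1
        run = np.arange(i + 1, j + 1)
        if len(run) >= min_days:
            events.append(
                DryDown(
                    start=df["TIMESTAMP"].iloc[run[0]],
                    end=df["TIMESTAMP"].iloc[run[-1]],
                    indices=run,
                )
            )
            i = run[-1] + 1
        else:
            i += 1
    return events


def season_filter(series: FluxSeries, hemisphere: str | None = None) -> FluxSeries:
    """Retain only summer records: JJA in the north, DJF in the south."""
    hemisphere = hemisphere or series.hemisphere
    if hemisphere not in ("N", "S"):
        raise ValueError("hemisphere must be 'N' or 'S'")
    months = (6, 7, 8) if hemisphere == "N" else (12, 1, 2)
    df = series.data
    out = df[df["TIMESTAMP"].dt.month.isin(months)].reset_index(drop=True)
    return FluxSeries(out, latitude=series.latitude)


# ---------------------------------------------------------------------------
# linear-plus-plateau breakpoint regression


def _piecewise_sse(x, y, x0):
    """Least-squares fit of y = a + b*min(x, x0); returns (sse, a, b)."""
    z = np.minimum(x, x0)
    zbar, ybar = z.mean(), y.mean()
    dz = z - zbar
    denom = np.dot(dz, dz)
    if denom == 0:
        return np.inf, ybar, 0.0
    b = np.dot(dz, y - ybar) / denom
    a = ybar - b * zbar
    resid = y - (a + b * z)
    return float(np.dot(resid, resid)), float(a), float(b)


def linear_plus_plateau(x, y) -> BreakpointFit:
    """Fit the linear-plus-plateau model y = a + b*min(x, x0).

    The breakpoint x0 is profiled over the observed x range (one candidate
    between each pair of adjacent unique x values) and refined by bounded
    scalar minimisation.  Significance is an F-test of the two-segment model
    (3 parameters) against the intercept-only model; the fit is flagged
    invalid when the rising slope is not positive or the breakpoint sits at
    the range edge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 points for the breakpoint fit")
    xu = np.unique(x)
    if len(xu) < 3:
        raise ValueError("degenerate x: breakpoint not identifiable")

    candidates = 0.5 * (xu[:-1] + xu[1:])
    sses = np.array([_piecewise_sse(x, y, c)[0] for c in candidates])
    i = int(np.argmin(sses))
    lo = candidates[max(i - 1, 0)]
    hi = candidates[min(i + 1, len(candidates) - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda c: _piecewise_sse(x, y, c)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-9},
        )
        x0 = float(res.x)
    else:
        x0 = float(candidates[i])
    sse1, a, b = _piecewise_sse(x, y, x0)

    sse0 = float(np.dot(y - y.mean(), y - y.mean()))
    df1, df2 = 2, n - 3
    if sse1 <= 0:
        p = 0.0
    else:
        f = ((sse0 - sse1) / df1) / (sse1 / df2)
        p = float(stats.f.sf(f, df1, df2))
    r2 = 1.0 - sse1 / sse0 if sse0 > 0 else np.nan
    span = xu[-1] - xu[0]
    edge = (x0 <= xu[0] + 0.01 * span) or (x0 >= xu[-1] - 0.01 * span)
    return BreakpointFit(
        breakpoint=x0,
        slope=b,
        intercept=a,
        p_value=p,
        r2=float(r2),
        plateau=a + b * x0,
        n=n,
        positive_slope=b > 0,
        edge_breakpoint=bool(edge),
    )


# ---------------------------------------------------------------------------
# site-level threshold extraction (tiered)


def _records_from_drydowns(series: FluxSeries, drydowns):
    daily = series.daily()
    idx = np.concatenate([d.indices for d in drydowns]) if drydowns else np.array([], int)
    return daily.data.iloc[idx]


def _try_fit(df: pd.DataFrame) -> BreakpointFit | None:
    if len(df) < 10:
        return None
    sub = FluxSeries(df.reset_index(drop=True))
    ef = evaporative_fraction(sub)
    ok = ef.notna() & sub.data["SWC"].notna()
    if ok.sum() < 10:
        return None
    try:
        fit = linear_plus_plateau(sub.data.loc[ok, "SWC"], ef[ok])
    except ValueError:
        return None
    if fit.valid and fit.p_value < 0.05:
        return fit
    return None


def site_theta_crit(
    series: FluxSeries, hemisphere: str | None = None
) -> ThresholdEstimate | None:
    """Tiered site-level theta_crit from a flux series.

    Tier 1 intersects summer with >= 10-day dry-downs; tier 2 keeps the
    dry-down criterion but drops the season; tier 3 keeps summer only.  The
    first tier producing a valid (positive slope, interior breakpoint,
    P < 0.05) fit wins; ``None`` when all tiers fail.
    """
    daily = series.daily()
    hemisphere = hemisphere or series.hemisphere

    summer = season_filter(daily, hemisphere)
    dd_all = detect_drydowns(daily)
    summer_months = (6, 7, 8) if hemisphere == "N" else (12, 1, 2)

    # tier 1: summer dry-downs
    dd_summer = [
        d for d in dd_all if d.start.month in summer_months and d.end.month in summer_months
    ]
    tiers = (
        ("summer_drydowns", _records_from_drydowns(daily, dd_summer)),
        ("drydowns_any_season", _records_from_drydowns(daily, dd_all)),
        ("summer_only", summer.data),
    )
    for tier, df in tiers:
        fit = _try_fit(df)
        if fit is not None:
            return ThresholdEstimate(
                theta_crit=fit.breakpoint,
                psi_crit=None,
                source="flux_breakpoint",
                diagnostics={
                    "tier": tier,
                    "n": fit.n,
                    "slope": fit.slope,
                    "p_value": fit.p_value,
                    "r2": fit.r2,
                    "n_drydowns": len(dd_all),
                },
            )
    return None


# ---------------------------------------------------------------------------
# sap flow


def sapflow_daylight_aggregate(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate sub-daily sap-flow records to daily values.

    Sap flux density becomes the 06:00-20:00 daylight mean (days with < 50%
    daylight coverage are dropped); soil moisture the 24-h mean.  With a TREE
    column the daylight mean is per tree.
    """
    if "SFD" not in df.columns:
        raise ValueError("sap-flow frame needs an SFD column")
    ts = pd.to_datetime(df["TIMESTAMP"])
    day = ts.dt.normalize()
    hours = ts.dt.hour
    daylight = (hours >= DAYLIGHT_HOURS[0]) & (hours < DAYLIGHT_HOURS[1])

    step_h = ts.drop_duplicates().sort_values().diff().dropna().min() / pd.Timedelta(
        hours=1
    )
    if not step_h > 0:
        raise ValueError("need sub-daily timestamps for daylight aggregation")
    full = int((DAYLIGHT_HOURS[1] - DAYLIGHT_HOURS[0]) / step_h)

    keys = ["DAY"] + (["TREE"] if "TREE" in df.columns else [])
    d = df.assign(DAY=day)
    day_sfd = (
        d[daylight.to_numpy()]
        .groupby(keys)["SFD"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "SFD"})
    )
    n_dropped = int((day_sfd["count"] < 0.5 * full).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} day/tree aggregates with <50% daylight coverage")
    day_sfd = day_sfd[day_sfd["count"] >= 0.5 * full].drop(columns="count")

    env_cols = [c for c in ("SWC", "VPD", "TA", "P") if c in df.columns]
    env = d.groupby("DAY")[env_cols].mean().reset_index() if env_cols else None
    if "P" in df.columns and env is not None:
        env["P"] = d.groupby("DAY")["P"].sum().to_numpy()
    out = day_sfd if env is None else day_sfd.merge(env, on="DAY", how="left")
    return out.rename(columns={"DAY": "TIMESTAMP"}).sort_values(
        ["TIMESTAMP"] + (["TREE"] if "TREE" in df.columns else [])
    ).reset_index(drop=True)


def sapflow_theta_crit(
    df: pd.DataFrame, hemisphere: str
) -> dict[object, ThresholdEstimate | None]:
    """Per-tree theta_crit from a sub-daily sap-flow frame.

    All trees share the site environmental series (soil moisture,
    precipitation); each tree's daylight-mean sap flux density is regressed
    on soil moisture within summer dry-downs using the same tiered criteria
    as the flux pipeline.
    """
    daily = sapflow_daylight_aggregate(df)
    trees = daily["TREE"].unique() if "TREE" in daily.columns else [None]
    out = {}
    for tree in trees:
        sub = daily if tree is None else daily[daily["TREE"] == tree]
        sub = sub.drop(columns=[c for c in ("TREE",) if c in sub.columns])
        # reuse the flux machinery with SFD standing in for the EF response:
        # normalise to a pseudo-EF in (0, 1) to share the fit path
        smax = sub["SFD"].max()
        if smax <= 0 or len(sub) < 10:
            out[tree] = None
            continue
        env = sub.assign(
            LE=sub["SFD"].clip(lower=1e-9), H=(smax * 1.0000001 - sub["SFD"]).clip(lower=1e-9)
        )
        fs = FluxSeries(env.reset_index(drop=True))
        est = site_theta_crit(fs, hemisphere)
        if est is not None:
            est = ThresholdEstimate(
                theta_crit=est.theta_crit,
                psi_crit=None,
                source="sapflow_breakpoint",
                diagnostics={**est.diagnostics, "tree": tree},
            )
        out[tree] = est
    return out


# ---------------------------------------------------------------------------
# EF over the VPD x theta plane


@dataclass(frozen=True)
class EFGrid:
    """Binned median evaporative fraction over the VPD x theta plane."""

    theta_edges: np.ndarray
    vpd_edges: np.ndarray
    median_ef: np.ndarray  # (n_theta, n_vpd), NaN where empty
    sens_theta: float
    sens_vpd: float
    n_records: int

    @property
    def relative_sensitivity_ratio(self) -> float:
        if self.sens_vpd == 0:
            return float("inf") if self.sens_theta > 0 else float("nan")
        return self.sens_theta / self.sens_vpd


def ef_vpd_theta_analysis(
    series: FluxSeries,
    soil: SoilHydraulicParams | None = None,
    n_bins: int = 20,
) -> EFGrid:
    """Median EF binned over the VPD x soil-moisture plane, with the median
    relative sensitivity of EF to each (range-rescaled) driver.

    Record filters: positive LE and H; PPFD > 500 umol m-2 s-1 and
    VPD in (0.5, 5] kPa (enough radiation and demand, no extreme demand);
    wind speed > 1 m s-1 (coupling); days with median air temperature < 15 degC
    excluded (cold limitation); soil moisture within (0, theta_s] of the class.

    The relative sensitivity per driver is the median, over adjacent occupied
    interior bin pairs, of |dEF/dx~| with the driver x~ rescaled to [0, 1]
    over its filtered range.  This statistic is a package definition (the
    field has no canonical one) and is labelled as such in outputs.
    """
    df = series.data.copy()
    needed = {"LE", "H", "SWC", "VPD", "PPFD", "WS", "TA", "TIMESTAMP"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing columns for EF-VPD-theta analysis: {sorted(missing)}")

    day = df["TIMESTAMP"].dt.normalize()
    cold_day = df.groupby(day)["TA"].transform("median") < 15.0
    ok = (
        (df["LE"] > 0)
        & (df["H"] > 0)
        & (df["PPFD"] > 500.0)
        & (df["VPD"] > 0.5)
        & (df["VPD"] <= 5.0)
        & (df["WS"] > 1.0)
        & (~cold_day)
        & df["SWC"].notna()
    )
    if soil is not None:
        ok &= (df["SWC"] > 0) & (df["SWC"] <= soil.theta_s)
    d = df[ok]
    if len(d) < 100:
        raise ValueError(f"only {len(d)} records after filtering; need >= 100")
    ef = (d["LE"] / (d["LE"] + d["H"])).to_numpy()
    theta = d["SWC"].to_numpy()
    vpd = d["VPD"].to_numpy()

    te = np.linspace(theta.min(), theta.max(), n_bins + 1)
    ve = np.linspace(vpd.min(), vpd.max(), n_bins + 1)
    ti = np.clip(np.digitize(theta, te) - 1, 0, n_bins - 1)
    vi = np.clip(np.digitize(vpd, ve) - 1, 0, n_bins - 1)
    med = np.full((n_bins, n_bins), np.nan)
    for a in range(n_bins):
        sel_a = ti == a
        if not sel_a.any():
            continue
        for bb in range(n_bins):
            sel = sel_a & (vi == bb)
            if sel.any():
                med[a, bb] = np.median(ef[sel])

    def _axis_sensitivity(grid, axis):
        diffs = np.abs(np.diff(grid, axis=axis)) * n_bins  # d(EF)/d(x rescaled to [0,1])
        interior = diffs[1:-1, 1:-1] if diffs.shape[0] > 2 and diffs.shape[1] > 2 else diffs
        vals = interior[np.isfinite(interior)]
        return float(np.median(vals)) if len(vals) else np.nan

    sens_theta = _axis_sensitivity(med, axis=0)
    sens_vpd = _axis_sensitivity(med, axis=1)
    return EFGrid(
        theta_edges=te,
        vpd_edges=ve,
        median_ef=med,
        sens_theta=sens_theta,
        sens_vpd=sens_vpd,
        n_records=len(d),
    )
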