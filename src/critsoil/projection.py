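"""Projection of critical-threshold shifts under changing evaporative demand.

Rising VPD raises the potential transpiration demand T_pot; because the
critical threshold is where the supply curve crosses the demand, a demand
change dT_pot shifts theta_crit by an amount set by the local steepness of
the supply curve T_max(theta) -- steep (coarse soils) means a small shift,
shallow (fine soils) a large one.

The chain is: a temperature/humidity PET formula gives the demand change per
pixel between two climate periods; an analytic four-parameter logistic fitted
to the numerical stress-onset-limit supply curve T_sol(theta) of the pixel's
textural class is inverted at the old and new demand; the difference is
delta-theta_crit.  Hyperarid pixels (aridity index <= 0.05) are excluded and
humid ones (AI > 1) flagged, as water limitation is respectively undefined
and unlikely there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from . import soil as soil_mod
from .constants import T_POT_REF, mpa_to_head
from .plant import PlantTraits, default_traits
from .soil import SoilHydraulicParams, TextureClassTable, classify_usda_texture, load_soil_table
from .supply import _sol_curve

__all__ = [
    "ClimateGrid",
    "ProjectionResult",
    "ivanov_pet",
    "aridity_index",
    "SigmoidSupply",
    "sigmoid_supply_fit",
    "delta_theta_crit",
    "project_grid",
    "DEMAND_RANGE_PCT",
]

#: projected relative change range of T_pot (%), spanned by the fitted curve
DEMAND_RANGE_PCT = (-19.0, 65.0)

#: the supply curve is fitted up to this multiple of the reference demand
DEMAND_CEILING = 1.7

#: Ivanov PET coefficient (mm month-1 degC-2 %-1)
IVANOV_COEFF = 0.0018

#: aridity-index class bounds
AI_HYPERARID = 0.05
AI_HUMID = 1.0


@dataclass(frozen=True)
class ClimateGrid:
    """Two-period gridded climate plus texture fractions.

    Temperature and relative humidity are monthly climatologies with shape
    (12, ny, nx); precipitation is annual (ny, nx) in mm yr-1; sand and clay
    are percentages (ny, nx).
    """

    t_current: np.ndarray
    rh_current: np.ndarray
    t_future: np.ndarray
    rh_future: np.ndarray
    precip_current: np.ndarray
    precip_future: np.ndarray
    sand: np.ndarray
    clay: np.ndarray

    def __post_init__(self):
        shp = self.sand.shape
        for name in ("clay", "precip_current", "precip_future"):
            if getattr(self, name).shape != shp:
                raise ValueError(f"{name} shape mismatch")
        for name in ("t_current", "rh_current", "t_future", "rh_future"):
            if getattr(self, name).shape != (12,) + shp:
                raise ValueError(f"{name} must have shape (12, ny, nx)")
        for name in ("rh_current", "rh_future"):
            rh = getattr(self, name)
            if np.any((rh < 0) | (rh > 100)):
                raise ValueError("relative humidity must lie in [0, 100]")


@dataclass(frozen=True)
class ProjectionResult:
    """Per-pixel projection outputs and their summary."""

    delta_theta_crit: np.ndarray  # NaN where masked
    d_tpot_rel: np.ndarray  # %, relative demand change
    texture_class: np.ndarray  # object array of class names ('' where missing)
    aridity_label: np.ndarray  # hyperarid_excluded | humid_flagged | analysed
    pet_current: np.ndarray  # mm yr-1
    pet_future: np.ndarray
    n_masked_texture: int
    summary: dict = field(default_factory=dict)


def ivanov_pet(T, RH):
    """Monthly potential transpiration (mm month-1) from air temperature
    (degC) and relative humidity (%): 0.0018 * (25 + T)^2 * (100 - RH),
    clamped to zero for T <= -25 degC."""
    T = np.asarray(T, dtype=float)
    RH = np.asarray(RH, dtype=float)
    if np.any((RH < 0) | (RH > 100)):
        raise ValueError("relative humidity must lie in [0, 100]")
    base = np.maximum(25.0 + T, 0.0)
    pet = IVANOV_COEFF * base**2 * (100.0 - RH)
    return pet if pet.ndim else float(pet)


def aridity_index(P, pet):
    """Annual aridity index AI = P / PET with its analysis label.

    Labels: ``hyperarid_excluded`` (AI <= 0.05), ``humid_flagged`` (AI > 1),
    ``analysed`` otherwise.  Scalar in, (float, str) out; arrays in,
    (array, object-array) out.
    """
    P = np.asarray(P, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if np.any(pet <= 0):
        raise ValueError("PET must be positive for the aridity index")
    ai = P / pet
    label = np.where(
        ai <= AI_HYPERARID,
        "hyperarid_excluded",
        np.where(ai > AI_HUMID, "humid_flagged", "analysed"),
    )
    if ai.ndim == 0:
        return float(ai), str(label)
    return ai, label.astype(object)


class SigmoidSupply:
    """Four-parameter logistic fit to the numerical supply curve T_sol(theta).

    ``T(theta) = lo + (hi - lo) / (1 + exp(-k (theta - x0)))``; invertible on
    the rising branch, which is where the demand crossings live.  Falls back
    to monotone interpolation when the fit misses the 2%-of-range tolerance.
    """

    def __init__(self, theta, t_sol, soil):
        self.soil = soil
        order = np.argsort(theta)
        self._theta = np.asarray(theta)[order]
        self._t = np.asarray(t_sol)[order]
        rng = self._t.max() - self._t.min()
        p0 = (
            self._t.min(),
            self._t.max(),
            10.0 / (self._theta.max() - self._theta.min() + 1e-9),
            float(np.median(self._theta)),
        )
        self.fallback = False
        try:
            popt, _ = curve_fit(
                self._logistic, self._theta, self._t, p0=p0, maxfev=20000
            )
            rmse = float(np.sqrt(np.mean((self._logistic(self._theta, *popt) - self._t) ** 2)))
            self.params = popt
            self.rmse = rmse
            if rmse > 0.02 * rng:
                raise RuntimeError
        except (RuntimeError, ValueError):
            warnings.warn(
                f"sigmoid fit above tolerance for {soil.class_name}; "
                "using monotone interpolation"
            )
            self.fallback = True
            self.rmse = np.nan

    @staticmethod
    def _logistic(x, lo, hi, k, x0):
        return lo + (hi - lo) / (1.0 + np.exp(-k * (x - x0)))

    def __call__(self, theta):
        if self.fallback:
            return np.interp(theta, self._theta, self._t)
        return self._logistic(np.asarray(theta, dtype=float), *self.params)

    def theta_at(self, T):
        """Invert the rising branch: theta at which the supply equals T."""
        if self.fallback:
            return float(np.interp(T, self._t, self._theta))
        lo, hi, k, x0 = self.params
        if not (lo < T < hi):
            raise ValueError(
                f"demand {T:.3f} mm/d outside the fitted supply range "
                f"({lo:.3f}, {hi:.3f}) for {self.soil.class_name}"
            )
        return float(x0 - np.log((hi - lo) / (T - lo) - 1.0) / k)


def sigmoid_supply_fit(
    soil: SoilHydraulicParams,
    traits: PlantTraits | None = None,
    T_pot_ref: float = T_POT_REF,
    n_psi: int = 300,
    n_trajectory: int = 1200,
) -> SigmoidSupply:
    """Fit the analytic sigmoid to the SOL supply curve of one soil.

    The numerical curve is computed out to at least ``DEMAND_CEILING`` times
    the reference demand so the whole projected range is inside the fit.
    """
    traits = traits or default_traits()
    grid, sol_T = _sol_curve(soil, traits, n_psi=n_psi, n_trajectory=n_trajectory)
    theta = soil_mod.water_retention(soil, mpa_to_head(np.asarray(grid)))
    if sol_T.max() < DEMAND_CEILING * T_pot_ref:
        warnings.warn(
            f"supply curve tops out at {sol_T.max():.2f} mm/d "
            f"(< {DEMAND_CEILING * T_pot_ref:.2f}); projected demands above "
            "that will raise"
        )
    # fit only the demand-relevant branch: the projection inverts the curve
    # between roughly 0.8 and 1.65 T_pot, so the far wet plateau (where the
    # SOL is plant-, not soil-, controlled) need not constrain the shape
    keep = sol_T <= 1.15 * DEMAND_CEILING * T_pot_ref
    if keep.sum() < 10:
        keep = np.ones_like(sol_T, dtype=bool)
    return SigmoidSupply(theta[keep], sol_T[keep], soil)


def delta_theta_crit(
    soil: SoilHydraulicParams,
    traits: PlantTraits | None = None,
    dTpot_rel: float = 0.0,
    T_pot_ref: float = T_POT_REF,
    fit: SigmoidSupply | None = None,
) -> float:
    """Shift of theta_crit (m3 m-3) for a relative demand change of
    ``dTpot_rel`` percent, through the inverted sigmoid supply fit."""
    if not (DEMAND_RANGE_PCT[0] <= dTpot_rel <= DEMAND_RANGE_PCT[1]):
        raise ValueError(
            f"dTpot_rel must lie in {DEMAND_RANGE_PCT} % (projection range)"
        )
    fit = fit or sigmoid_supply_fit(soil, traits, T_pot_ref)
    t_new = T_pot_ref * (1.0 + dTpot_rel / 100.0)
    return float(fit.theta_at(t_new) - fit.theta_at(T_pot_ref))


def project_grid(
    grid: ClimateGrid,
    traits: PlantTraits | None = None,
    table: TextureClassTable | None = None,
    T_pot_ref: float = T_POT_REF,
    pixel_area: np.ndarray | None = None,
) -> ProjectionResult:
    """Per-pixel texture-mediated delta-theta_crit between the two periods.

    Annual PET is the sum of the monthly PET values; the relative demand
    change scales the reference T_pot.  Texture classes come from the
    (sand, clay) fractions with silt = 100 - sand - clay; pixels whose
    fractions are missing or invalid are masked and counted.
    """
    traits = traits or default_traits()
    table = table or load_soil_table()
    ny, nx = grid.sand.shape

    pet_cur = ivanov_pet(grid.t_current, grid.rh_current).sum(axis=0)
    pet_fut = ivanov_pet(grid.t_future, grid.rh_future).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_rel = 100.0 * (pet_fut - pet_cur) / pet_cur
    ai, label = aridity_index(grid.precip_current, np.maximum(pet_cur, 1e-9))

    classes = np.empty((ny, nx), dtype=object)
    classes[:] = ""
    n_masked = 0
    fits: dict[str, SigmoidSupply] = {}
    delta = np.full((ny, nx), np.nan)
    for i in range(ny):
        for j in range(nx):
            s, c = grid.sand[i, j], grid.clay[i, j]
            silt = 100.0 - s - c
            if not np.isfinite(s) or not np.isfinite(c) or silt < -0.5:
                n_masked += 1
                continue
            cls = classify_usda_texture(s, max(silt, 0.0), c)
            classes[i, j] = cls
            if label[i, j] == "hyperarid_excluded":
                continue
            r = float(np.clip(d_rel[i, j], *DEMAND_RANGE_PCT))
            if cls not in fits:
                fits[cls] = sigmoid_supply_fit(table.get(cls), traits, T_pot_ref)
            delta[i, j] = delta_theta_crit(
                table.get(cls), traits, r, T_pot_ref, fit=fits[cls]
            )

    good = np.isfinite(delta)
    w = np.ones((ny, nx)) if pixel_area is None else np.asarray(pixel_area, float)
    summary = {
        "mean_delta_theta_crit": float(
            np.average(delta[good], weights=w[good]) if good.any() else np.nan
        ),
        "min_delta_theta_crit": float(np.nanmin(delta)) if good.any() else np.nan,
        "max_delta_theta_crit": float(np.nanmax(delta)) if good.any() else np.nan,
        "n_analysed": int(good.sum()),
        "n_hyperarid": int((label == "hyperarid_excluded").sum()),
        "n_humid_flagged": int((label == "humid_flagged").sum()),
    }
    return ProjectionResult(
        delta_theta_crit=delta,
        d_tpot_rel=d_rel,
        texture_class=classes,
        aridity_label=label,
        pet_current=pet_cur,
        pet_future=pet_fut,
        n_masked_texture=n_masked,
        summary=summary,
    )
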