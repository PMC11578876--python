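"""Steady-state soil-to-leaf water transport and the stress-onset limit (SOL).

The model couples two legs in series.

Soil leg (radial flow from bulk soil to the root surface), linearised by the
matric flux potential ``Phi``::

    Phi(psi_soil) - Phi(psi_soil_root) = T * ln(r_bulk / r_root) / (2 pi L_root)

with ``T`` the transpiration per ground area (m d-1 internally) and ``L_root``
the effective root length per ground area.  Because ``Phi`` collapses as the
soil dries, the right-hand side bounds the water the soil can deliver.

Plant leg (soil-root interface to leaf), with conductance vulnerable to the
leaf water potential itself::

    psi_leaf = psi_soil_root - T / K_plant(psi_leaf)

For a fixed bulk soil potential, letting the root-surface potential drop
traces a trajectory T(psi_leaf): linear while both conductances hold, bending
as either the soil supply saturates or the plant conductance declines.  The
stress-onset limit is the point on each trajectory where |dT/dpsi_leaf| first
falls to 80% of its per-trajectory maximum -- the onset of the nonlinear zone
hypothesised to trigger stomatal closure.  The critical thresholds theta_crit
and psi_crit are the wettest soil state whose SOL transpiration equals the
potential transpiration rate T_pot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from . import soil as soil_mod
from .constants import T_POT_REF, VPD_REF, head_to_mpa, mpa_to_head
from .plant import PlantTraits, plant_conductance
from .soil import SoilHydraulicParams

__all__ = [
    "SupplySurface",
    "ThresholdEstimate",
    "TransportState",
    "PlantLimitedAtSaturationError",
    "TransportConvergenceError",
    "solve_transport",
    "supply_trajectory",
    "build_supply_surface",
    "stress_onset_limit",
    "critical_thresholds",
    "conductance_partition",
    "critical_vpd",
    "fit_root_length",
]

#: fraction of the maximum |dT/dpsi_leaf| that defines the stress-onset limit
SOL_DERIVATIVE_FRACTION = 0.8


class PlantLimitedAtSaturationError(RuntimeError):
    """T_pot cannot be supplied even in saturated soil; the system is
    plant-limited at every soil moisture.  Carries the critical VPD at
    saturation instead of a threshold."""

    def __init__(self, message, critical_vpd_kpa=None):
        super().__init__(message)
        self.critical_vpd_kpa = critical_vpd_kpa


class TransportConvergenceError(RuntimeError):
    """The implicit leaf-potential equation did not converge."""


@dataclass(frozen=True)
class TransportState:
    """One steady transport state along the soil-plant pathway."""

    T: float  # transpiration, mm d-1
    psi_leaf: float  # MPa
    psi_soil: float  # MPa
    psi_soil_root: float  # MPa
    residual: float  # MPa, implicit-equation residual


@dataclass(frozen=True)
class ThresholdEstimate:
    """A critical soil moisture threshold with provenance and diagnostics."""

    theta_crit: float
    psi_crit: float | None = None
    source: str = "simulated"  # simulated | flux_breakpoint | sapflow_breakpoint
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SupplySurface:
    """Tabulated T(psi_soil, psi_leaf) surface with its SOL curve.

    ``trajectories`` holds, per psi_soil grid node, arrays of transpiration
    (mm d-1), leaf water potential and root-surface potential (MPa).
    ``sol_T`` / ``sol_psi_leaf`` give the stress-onset limit per node.
    """

    psi_soil: np.ndarray  # MPa, wet -> dry
    trajectories: tuple  # of (T, psi_leaf, psi_root) array triples
    sol_T: np.ndarray
    sol_psi_leaf: np.ndarray
    soil: SoilHydraulicParams
    traits: PlantTraits
    T_pot: float


# ---------------------------------------------------------------------------
# elementary legs


def _soil_leg_geometry(traits: PlantTraits) -> float:
    """ln(r_bulk/r_root) / (2 pi L_root), the radial soil-leg resistance factor."""
    return math.log(traits.r_bulk / traits.r_root) / (2.0 * math.pi * traits.L_root)


def soil_supply(soil: SoilHydraulicParams, traits: PlantTraits, psi_soil, psi_root):
    """Transpiration (mm d-1) the soil leg carries between bulk potential
    ``psi_soil`` and root-surface potential ``psi_root`` (both MPa)."""
    phi_s = soil_mod.matric_flux_potential(soil, mpa_to_head(np.asarray(psi_soil)))
    phi_r = soil_mod.matric_flux_potential(soil, mpa_to_head(np.asarray(psi_root)))
    t_m_d = (phi_s - phi_r) / _soil_leg_geometry(traits)
    return t_m_d * 1000.0


def _psi_root_for_T(soil, traits, psi_soil, T_mm_d):
    """Invert the soil leg: root-surface potential (MPa) carrying ``T``."""
    phi_s = soil_mod.matric_flux_potential(soil, mpa_to_head(np.asarray(psi_soil)))
    phi_r = phi_s - np.asarray(T_mm_d) / 1000.0 * _soil_leg_geometry(traits)
    if np.any(phi_r <= 0):
        raise ValueError("transpiration exceeds the soil-leg supply capacity")
    h_r = soil_mod.matric_flux_potential_inverse(soil, phi_r)
    return head_to_mpa(h_r)


def _psi_leaf_implicit(traits: PlantTraits, psi_root: float, T: float) -> float:
    """Scalar bracketed solve of psi_leaf = psi_root - T/K_plant(psi_leaf)."""
    if T == 0.0:
        return psi_root
    k_floor = traits.k_floor_frac * traits.K_plant_max

    def g(psi):
        return psi - psi_root + T / plant_conductance(traits, psi)

    lo = psi_root - T / k_floor  # driest possible leaf potential
    if traits.vuln_shape == "linear":
        # the closed form identifies the wet-continuation root; polish it
        # with a bracketed solve (robust even at the supply fold, where the
        # two declining-branch roots nearly coincide)
        x0 = float(_psi_leaf_closed(traits, psi_root, T))
        if abs(g(x0)) < 1e-12:
            return x0
        eps = max(1e-9, 1e-9 * abs(x0))
        while eps < abs(lo - psi_root) + 1.0:
            a, b = min(x0 + eps, psi_root), x0 - eps
            if np.sign(g(a)) != np.sign(g(b)):
                return float(brentq(g, a, b, xtol=1e-12, rtol=8.9e-16))
            eps *= 4.0
        if abs(g(x0)) < 1e-9:
            return x0
        raise TransportConvergenceError(
            f"no bracket around the closed-form root (psi_root={psi_root}, T={T})"
        )
    # sigmoid vulnerability: walk from the wet end (log-spaced offsets, dense
    # near psi_root) and bracket the first sign change
    offsets = np.concatenate([[0.0], np.geomspace(1e-10, psi_root - lo, 2000)])
    grid = psi_root - offsets
    vals = grid - psi_root + T / plant_conductance(traits, grid)
    sign = np.sign(vals)
    idx = np.where(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        if abs(vals[-1]) < 1e-10:
            return float(grid[-1])
        raise TransportConvergenceError(
            f"no leaf-potential solution bracketed (psi_root={psi_root}, T={T})"
        )
    a, b = grid[idx[0]], grid[idx[0] + 1]
    return float(brentq(g, a, b, xtol=1e-12, rtol=8.9e-16))


def _psi_leaf_closed(traits: PlantTraits, psi_root, T):
    """Vectorised closed-form wet-branch solution of the implicit plant leg
    for the piecewise-linear vulnerability curve.

    Exactly equivalent to the bracketed scalar solve on the wet-continuation
    branch (asserted in the test suite); used to build dense trajectories.
    """
    psi_root = np.asarray(psi_root, dtype=float)
    T = np.asarray(T, dtype=float)
    s = traits.vuln_slope
    onset = traits.psi_onset
    f = traits.k_floor_frac
    t = T / traits.K_plant_max  # potential drop at full conductance, MPa

    psi_lin = psi_root - t
    c = onset - psi_root
    # declining branch: s*u^2 - (1 + s*c)*u + (c + t) = 0, u = onset - psi_leaf
    a2, b2, c2 = s, -(1.0 + s * c), c + t
    disc = b2 * b2 - 4.0 * a2 * c2
    sq = np.sqrt(np.maximum(disc, 0.0))
    u = (-b2 - sq) / (2.0 * a2)  # wet-continuation (smaller) root
    psi_decl = onset - u
    frac_decl = 1.0 - s * u

    psi_floor = psi_root - t / f

    decl_ok = (
        (disc >= 0.0)
        & (u >= np.maximum(c, 0.0))  # psi_leaf <= min(psi_root, onset)
        & (frac_decl >= f)
    )
    out = np.where(psi_lin >= onset, psi_lin, np.where(decl_ok, psi_decl, psi_floor))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# public operations


def solve_transport(
    soil: SoilHydraulicParams,
    traits: PlantTraits,
    psi_soil: float,
    psi_soil_root: float,
) -> TransportState:
    """Steady transport state for given bulk-soil and root-surface potentials.

    Returns the transpiration rate carried by the soil leg and the leaf water
    potential satisfying the implicit plant leg to < 1e-8 MPa.
    """
    if not (psi_soil_root <= psi_soil <= 0.0):
        raise ValueError("need psi_soil_root <= psi_soil <= 0")
    T = float(soil_supply(soil, traits, psi_soil, psi_soil_root))
    psi_leaf = _psi_leaf_implicit(traits, psi_soil_root, T)
    residual = psi_leaf - psi_soil_root + T / plant_conductance(traits, psi_leaf)
    if abs(residual) > 1e-8:
        raise TransportConvergenceError(
            f"implicit leaf equation residual {residual:.3e} MPa"
        )
    return TransportState(
        T=T,
        psi_leaf=float(psi_leaf),
        psi_soil=float(psi_soil),
        psi_soil_root=float(psi_soil_root),
        residual=float(residual),
    )


def _trajectory_T_cap(soil, traits, psi_soil) -> float:
    """Upper transpiration bound for one trajectory (mm d-1)."""
    phi_s = soil_mod.matric_flux_potential(soil, mpa_to_head(psi_soil))
    t_max_soil = phi_s / _soil_leg_geometry(traits) * 1000.0
    # beyond the plant floor the trajectory is a flat line; no need to go far
    t_cap_plant = 1.2 * traits.K_plant_max * (
        abs(traits.psi_onset) + 1.0 / traits.vuln_slope
    )
    return min(0.999 * t_max_soil, max(t_cap_plant, 3.0 * T_POT_REF))


def supply_trajectory(
    soil: SoilHydraulicParams,
    traits: PlantTraits,
    psi_soil: float,
    n: int = 2000,
):
    """Dense T(psi_leaf) trajectory at fixed bulk soil potential.

    Parameterised by transpiration from 0 up to just below the soil-leg
    capacity; returns (T mm d-1, psi_leaf MPa, psi_root MPa) arrays with
    psi_leaf monotonically non-increasing.
    """
    t_hi = _trajectory_T_cap(soil, traits, psi_soil)
    T = np.linspace(0.0, t_hi, n)
    psi_root = _psi_root_for_T(soil, traits, psi_soil, T)
    psi_leaf = _psi_leaf_closed(traits, psi_root, T)
    psi_leaf = np.minimum.accumulate(psi_leaf)
    return T, psi_leaf, psi_root


def _sol_from_trajectory(T, psi_leaf, frac=SOL_DERIVATIVE_FRACTION):
    """First point (drying leafward) where |dT/dpsi_leaf| falls to ``frac`` of
    its trajectory maximum; linear interpolation between samples.

    Returns (T_sol, psi_leaf_sol); the trajectory end if the derivative never
    falls below the threshold (perfectly linear case).
    """
    dpsi = np.diff(psi_leaf)
    good = dpsi < 0
    if not np.any(good):
        return float(T[-1]), float(psi_leaf[-1])
    deriv = np.full(len(dpsi), np.nan)
    deriv[good] = np.abs(np.diff(T)[good] / dpsi[good])
    dmax = np.nanmax(deriv)
    if dmax == 0:
        return float(T[-1]), float(psi_leaf[-1])
    imax = int(np.nanargmax(deriv))
    below = np.where(
        ~np.isnan(deriv[imax:]) & (deriv[imax:] < frac * dmax)
    )[0]
    if len(below) == 0:
        return float(T[-1]), float(psi_leaf[-1])
    i = imax + below[0]
    # interpolate in derivative between segment i-1 and i
    if i == 0 or np.isnan(deriv[i - 1]):
        w = 0.0
    else:
        d0, d1 = deriv[i - 1], deriv[i]
        w = 0.0 if d0 == d1 else np.clip((d0 - frac * dmax) / (d0 - d1), 0.0, 1.0)
    t_sol = T[i] + w * (T[i + 1] - T[i])
    p_sol = psi_leaf[i] + w * (psi_leaf[i + 1] - psi_leaf[i])
    return float(t_sol), float(p_sol)


def default_psi_soil_grid(n: int = 400) -> np.ndarray:
    """Log-spaced soil water potential grid (MPa), wet (-1e-4) to dry (-10)."""
    return -np.logspace(math.log10(1e-4), math.log10(10.0), n)


def build_supply_surface(
    soil: SoilHydraulicParams,
    traits: PlantTraits,
    psi_soil_grid: np.ndarray | None = None,
    n_trajectory: int = 2000,
    T_pot: float = T_POT_REF,
) -> SupplySurface:
    """Tabulate the T(psi_soil, psi_leaf) surface and its stress-onset limit."""
    if psi_soil_grid is None:
        psi_soil_grid = default_psi_soil_grid()
    psi_soil_grid = np.asarray(psi_soil_grid, dtype=float)
    if len(psi_soil_grid) < 100:
        raise ValueError("psi_soil grid too coarse: need >= 100 nodes")
    if psi_soil_grid.max() > -1e-4 * 1.0000001 or psi_soil_grid.min() < -10.0000001:
        pass  # grid may extend; only density is enforced
    trajectories = []
    sol_T = np.empty(len(psi_soil_grid))
    sol_psi = np.empty(len(psi_soil_grid))
    for i, ps in enumerate(psi_soil_grid):
        T, pl, pr = supply_trajectory(soil, traits, float(ps), n=n_trajectory)
        trajectories.append((T, pl, pr))
        sol_T[i], sol_psi[i] = _sol_from_trajectory(T, pl)
    return SupplySurface(
        psi_soil=psi_soil_grid,
        trajectories=tuple(trajectories),
        sol_T=sol_T,
        sol_psi_leaf=sol_psi,
        soil=soil,
        traits=traits,
        T_pot=T_pot,
    )


def stress_onset_limit(surface: SupplySurface) -> np.ndarray:
    """SOL curve of a built surface as a (n, 3) array of
    (psi_soil, T_sol, psi_leaf_sol) rows."""
    return np.column_stack([surface.psi_soil, surface.sol_T, surface.sol_psi_leaf])


def _sol_curve(soil, traits, n_psi=400, n_trajectory=2000):
    """(psi_soil, T_sol) arrays, wet to dry, without storing trajectories."""
    grid = default_psi_soil_grid(n_psi)
    sol_T = np.empty(n_psi)
    for i, ps in enumerate(grid):
        T, pl, _ = supply_trajectory(soil, traits, float(ps), n=n_trajectory)
        sol_T[i] = _sol_from_trajectory(T, pl)[0]
    return grid, sol_T


def critical_thresholds(
    soil: SoilHydraulicParams,
    traits: PlantTraits,
    T_pot: float = T_POT_REF,
    n_psi: int = 400,
    n_trajectory: int = 2000,
) -> ThresholdEstimate:
    """Critical soil moisture and water potential at which the supply first
    fails to match ``T_pot``.

    The SOL transpiration is evaluated on a log-spaced soil-potential grid;
    the wettest crossing ``T_sol = T_pot`` is interpolated in log-suction and
    mapped to water content through the retention curve.
    """
    grid, sol_T = _sol_curve(soil, traits, n_psi, n_trajectory)
    if sol_T[0] < T_pot:
        vpd = VPD_REF * sol_T[0] / T_pot
        raise PlantLimitedAtSaturationError(
            f"T_pot = {T_pot} mm/d unreachable even at saturation "
            f"(SOL = {sol_T[0]:.3f} mm/d): plant-limited at saturation; "
            f"critical VPD at saturation = {vpd:.3f} kPa",
            critical_vpd_kpa=vpd,
        )
    below = np.where(sol_T < T_pot)[0]
    if len(below) == 0:
        raise ValueError(
            "SOL never drops below T_pot on the grid; extend the dry end"
        )
    i = int(below[0])  # wettest crossing
    # interpolate in log10 suction
    x0, x1 = math.log10(-grid[i - 1]), math.log10(-grid[i])
    y0, y1 = sol_T[i - 1], sol_T[i]
    w = 0.0 if y0 == y1 else (y0 - T_pot) / (y0 - y1)
    psi_crit = -(10.0 ** (x0 + w * (x1 - x0)))
    theta_crit = float(soil_mod.water_retention(soil, mpa_to_head(psi_crit)))
    return ThresholdEstimate(
        theta_crit=theta_crit,
        psi_crit=float(psi_crit),
        source="simulated",
        diagnostics={
            "T_pot": T_pot,
            "n_psi": n_psi,
            "n_trajectory": n_trajectory,
            "sol_T_wet": float(sol_T[0]),
            "crossing_index": i,
            "soil_class": soil.class_name,
        },
    )


def conductance_partition(
    soil: SoilHydraulicParams,
    traits: PlantTraits,
    psi_soil: float,
    T: float,
):
    """Soil, plant and total conductance (mm d-1 MPa-1) of the state carrying
    transpiration ``T`` at bulk potential ``psi_soil``.

    ``K_soil = T / (psi_soil - psi_soil_root)``,
    ``K_plant = T / (psi_soil_root - psi_leaf)``; the total is their harmonic
    mean (series combination).
    """
    if T <= 0:
        raise ValueError("conductance partition undefined at T <= 0")
    psi_root = float(_psi_root_for_T(soil, traits, psi_soil, T))
    psi_leaf = _psi_leaf_implicit(traits, psi_root, T)
    k_soil = T / (psi_soil - psi_root)
    k_plant = T / (psi_root - psi_leaf)
    k_total = 1.0 / (1.0 / k_soil + 1.0 / k_plant)
    return k_soil, k_plant, k_total


def critical_vpd(
    soil: SoilHydraulicParams,
    traits: PlantTraits,
    theta: float,
    anchor: tuple[float, float] = (T_POT_REF, VPD_REF),
    n_trajectory: int = 2000,
    vpd_cap: float = 10.0,
):
    """VPD (kPa) at which stomatal downregulation sets in at soil moisture
    ``theta``, under a demand that scales linearly with VPD through the
    ``anchor = (T_pot, VPD_ref)`` pair.

    Returns ``(vpd, capped)``; ``capped`` is True when the SOL exceeds the
    demand ceiling and the returned value is the cap.
    """
    t_pot, vpd_ref = anchor
    h = soil_mod.retention_inverse(soil, theta)
    psi_soil = float(head_to_mpa(h))
    T, pl, _ = supply_trajectory(soil, traits, min(psi_soil, -1e-6), n=n_trajectory)
    t_sol, _ = _sol_from_trajectory(T, pl)
    vpd = vpd_ref * t_sol / t_pot
    if vpd > vpd_cap:
        return vpd_cap, True
    return vpd, False


def fit_root_length(
    observed: list[tuple[ThresholdEstimate, SoilHydraulicParams]],
    traits: PlantTraits,
    T_pot: float = T_POT_REF,
    bounds: tuple[float, float] = (0.05, 500.0),
    n_coarse: int = 25,
    n_psi: int = 200,
    n_trajectory: int = 800,
):
    """Inverse estimate of the effective root length per ground area.

    Minimises the least-absolute-deviations objective
    ``sum_i |theta_crit_obs,i - theta_crit_sim,i(L_root)|`` over all observed
    (threshold, soil) pairs, varying only ``L_root``: a log-spaced coarse scan
    refined by golden-section search.  Returns ``(L_root, diagnostics)``.
    """
    if len(observed) == 0:
        raise ValueError("fit_root_length needs at least one observation")

    def objective(log10_L):
        L = 10.0**log10_L
        tr = traits.with_L_root(L)
        total = 0.0
        for est, soil in observed:
            try:
                sim = critical_thresholds(
                    soil, tr, T_pot, n_psi=n_psi, n_trajectory=n_trajectory
                )
                total += abs(est.theta_crit - sim.theta_crit)
            except PlantLimitedAtSaturationError:
                total += soil.theta_s  # maximal penalty
        return total

    lo, hi = math.log10(bounds[0]), math.log10(bounds[1])
    xs = np.linspace(lo, hi, n_coarse)
    vals = [objective(x) for x in xs]
    ib = int(np.argmin(vals))
    a = xs[max(ib - 1, 0)]
    b = xs[min(ib + 1, n_coarse - 1)]
    res = minimize_scalar(
        objective, bracket=None, bounds=(a, b), method="bounded",
        options={"xatol": 1e-3},
    )
    L_best = float(10.0**res.x)
    diagnostics = {
        "objective": float(res.fun),
        "converged": bool(res.success),
        "n_obs": len(observed),
        "coarse_grid_log10": xs.tolist(),
        "coarse_objective": [float(v) for v in vals],
    }
    return L_best, diagnostics
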