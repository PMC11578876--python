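"""Plant hydraulic conductance and its vulnerability to low leaf water potential.

The plant (root + stem, lumped) is a single conductance ``K_plant`` between
the soil-root interface and the leaf.  Its vulnerability to declining leaf
water potential is piecewise linear: full conductance ``K_plant_max`` down to
an onset potential, then a linear loss of ``vuln_slope`` (fraction of
``K_plant_max`` per MPa), crossing 50% at ``psi_x_star`` and floored at a
small residual so the implicit leaf-potential solve never divides by zero.

``K_plant_max`` is anchored to the canopy water demand: with a potential
transpiration of ``T_pot`` (mm d-1) and a wet-soil leaf water potential of
``psi_leaf_max`` (MPa), ``K_plant_max = T_pot / (-psi_leaf_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np

from .constants import T_POT_REF

__all__ = ["PlantTraits", "plant_conductance", "default_traits"]

#: default effective root length per ground area (m m-2); see docs/methods.md
L_ROOT_DEFAULT: float = 100.0

#: effective topsoil depth (m) over which the root length density is spread
TOPSOIL_DEPTH: float = 0.3


@dataclass(frozen=True)
class PlantTraits:
    """Plant hydraulic parameters of the lumped soil-root-leaf pathway.

    Parameters
    ----------
    K_plant_max : float
        Maximum plant hydraulic conductance (mm d-1 MPa-1).
    psi_x_star : float
        Leaf/xylem water potential (MPa, < 0) at which the conductance is
        reduced to 50% (approximately the xylem P50).
    vuln_slope : float
        Fractional conductance loss per MPa below the onset potential
        (MPa-1, > 0).  The onset sits at ``psi_x_star + 0.5 / vuln_slope``.
    L_root : float
        Effective root length per unit ground area (m m-2).
    r_root : float
        Effective root radius (m).
    r_bulk : float
        Effective rhizosphere/bulk-soil radius (m); the radial soil flow
        domain extends from ``r_root`` to ``r_bulk``.
    psi_leaf_max : float
        Leaf water potential (MPa, < 0) at maximum transpiration in wet soil.
    k_floor_frac : float
        Residual conductance floor as a fraction of ``K_plant_max``.
    vuln_shape : str
        ``"linear"`` (default) or ``"sigmoid"`` (logistic alternative with the
        same 50% point and midpoint slope).
    """

    K_plant_max: float = T_POT_REF / 1.0
    psi_x_star: float = -2.8
    vuln_slope: float = 1.25
    L_root: float = L_ROOT_DEFAULT
    r_root: float = 0.5e-3
    r_bulk: float | None = None
    psi_leaf_max: float = -1.0
    k_floor_frac: float = 1e-3
    vuln_shape: str = "linear"

    def __post_init__(self):
        if self.r_bulk is None:
            # half mean inter-root distance from the root length density
            l_v = self.L_root / TOPSOIL_DEPTH
            object.__setattr__(self, "r_bulk", (math.pi * l_v) ** -0.5)
        if not (self.psi_x_star < self.psi_leaf_max < 0):
            raise ValueError("need psi_x_star < psi_leaf_max < 0")
        if self.vuln_slope <= 0 or self.L_root <= 0:
            raise ValueError("vuln_slope and L_root must be positive")
        if not (self.r_bulk > self.r_root > 0):
            raise ValueError("need r_bulk > r_root > 0")
        if self.vuln_shape not in ("linear", "sigmoid"):
            raise ValueError("vuln_shape must be 'linear' or 'sigmoid'")

    @property
    def psi_onset(self) -> float:
        """Potential (MPa) at which conductance starts to decline."""
        return self.psi_x_star + 0.5 / self.vuln_slope

    def with_psi_x_star(self, psi_x_star: float) -> "PlantTraits":
        """Shift the whole vulnerability curve (onset and 50% point move
        together, slope unchanged)."""
        return replace(self, psi_x_star=psi_x_star)

    def with_L_root(self, L_root: float) -> "PlantTraits":
        """Rescale the effective root length (rhizosphere radius re-derived)."""
        return replace(self, L_root=L_root, r_bulk=None)


def default_traits(T_pot: float = T_POT_REF) -> PlantTraits:
    """Reference traits: K_plant_max anchored so that transpiring at ``T_pot``
    in wet soil pulls the leaf to -1 MPa."""
    return PlantTraits(K_plant_max=T_pot / 1.0)


def plant_conductance(traits: PlantTraits, psi_leaf):
    """Plant hydraulic conductance (mm d-1 MPa-1) at leaf water potential
    ``psi_leaf`` (MPa, <= 0).

    Piecewise linear by default: ``K_plant_max`` above the onset potential,
    linear decline below (50% at ``psi_x_star``), floored at
    ``k_floor_frac * K_plant_max``.
    """
    psi = np.asarray(psi_leaf, dtype=float)
    if np.any(psi > 0):
        raise ValueError("psi_leaf must be <= 0 MPa")
    if traits.vuln_shape == "sigmoid":
        a = 4.0 * traits.vuln_slope
        frac = 1.0 / (1.0 + np.exp(-a * (psi - traits.psi_x_star)))
    else:
        frac = 1.0 - traits.vuln_slope * np.maximum(traits.psi_onset - psi, 0.0)
    k = traits.K_plant_max * np.clip(frac, traits.k_floor_frac, 1.0)
    return k if k.ndim else float(k)
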