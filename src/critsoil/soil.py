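"""Soil water retention, unsaturated conductivity and matric flux potential.

The retention family is the Campbell power law (Brooks-Corey with zero
residual water content)::

    theta(h) = theta_s                      for h <= h_b
    theta(h) = theta_s * (h_b / h)^(1/b)    for h >  h_b

with ``h`` the suction head (m, positive), ``h_b`` the air-entry head and
``b`` the retention slope.  The conductivity follows the matching power law

    k(h) = K_sat * (h_b / h)^tau,   tau = 2 + 3/b

so that on log-log axes the conductivity drops with slope ``-tau``; coarse
soils (small ``b``, hence large ``tau``) lose conductivity far more steeply
than fine soils, which is the mechanism this package revolves around.

The matric flux potential ``Phi(h) = int_h^inf k(h') dh'`` linearises the
radial soil-to-root flow problem and has the closed form

    Phi(h) = K_sat * h_b^tau * h^(1 - tau) / (tau - 1)     for h >= h_b

extended linearly (slope ``K_sat``) between saturation (h = 0) and air entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SoilHydraulicParams",
    "TextureClassTable",
    "load_soil_table",
    "water_retention",
    "retention_inverse",
    "hydraulic_conductivity",
    "matric_flux_potential",
    "matric_flux_potential_inverse",
    "classify_usda_texture",
    "endmember_params",
    "USDA_CLASSES",
]

#: the 12 USDA classes in hydraulically coarse-to-fine order (increasing b)
USDA_CLASSES = (
    "sand",
    "loamy sand",
    "sandy loam",
    "loam",
    "silt",
    "silt loam",
    "sandy clay loam",
    "clay loam",
    "silty clay loam",
    "silty clay",
    "sandy clay",
    "clay",
)


@dataclass(frozen=True)
class SoilHydraulicParams:
    """Hydraulic parameters of one textural class.

    Parameters
    ----------
    class_name : str
        USDA textural class name (or a free label for custom soils).
    theta_s : float
        Saturated volumetric water content (m3 m-3), in (0, 1).
    h_b : float
        Air-entry suction head (m), > 0.
    b : float
        Retention-curve slope parameter (-), > 0.
    K_sat : float
        Saturated hydraulic conductivity (m d-1), > 0.
    h_b_gsd, b_gsd, K_sat_gsd : float, optional
        Geometric standard deviation factors (>= 1) of ``h_b``, ``b`` and
        ``K_sat`` across the class; one factor up/down spans the within-class
        variability used by :func:`endmember_params`.
    """

    class_name: str
    theta_s: float
    h_b: float
    b: float
    K_sat: float
    h_b_gsd: float | None = None
    b_gsd: float | None = None
    K_sat_gsd: float | None = None
    tau: float = field(init=False)

    def __post_init__(self):
        if not (0.0 < self.theta_s < 1.0):
            raise ValueError(f"theta_s must lie in (0, 1), got {self.theta_s}")
        if self.h_b <= 0 or self.b <= 0 or self.K_sat <= 0:
            raise ValueError("h_b, b and K_sat must all be positive")
        object.__setattr__(self, "tau", 2.0 + 3.0 / self.b)


@dataclass(frozen=True)
class TextureClassTable:
    """The packaged ordered collection of per-class parameters.

    Also carries the per-class sand-percentage range of the USDA triangle;
    the class mean sand fraction is the arithmetic midpoint of that range.
    """

    params: tuple[SoilHydraulicParams, ...]
    sand_range: dict[str, tuple[float, float]]

    def __post_init__(self):
        names = [p.class_name for p in self.params]
        if len(names) != len(set(names)):
            raise ValueError("duplicate class names in texture table")

    def __iter__(self):
        return iter(self.params)

    def __len__(self):
        return len(self.params)

    @property
    def class_names(self) -> list[str]:
        return [p.class_name for p in self.params]

    def get(self, class_name: str) -> SoilHydraulicParams:
        for p in self.params:
            if p.class_name == class_name:
                return p
        raise KeyError(f"unknown textural class {class_name!r}")

    def mean_sand_fraction(self, class_name: str) -> float:
        """Class mean sand percentage: midpoint of the USDA polygon range."""
        lo, hi = self.sand_range[class_name]
        return 0.5 * (lo + hi)


def load_soil_table(path: str | Path | None = None) -> TextureClassTable:
    """Load the per-class parameter table.

    By default the packaged fixture is used; pass ``path`` to substitute a
    locally measured table with the same columns (recommended whenever local
    soil hydraulic measurements exist).
    """
    if path is None:
        with resources.as_file(
            resources.files("critsoil.data").joinpath("soil_params.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    params = []
    sand_range = {}
    for _, row in df.iterrows():
        name = str(row["class"])
        params.append(
            SoilHydraulicParams(
                class_name=name,
                theta_s=float(row["theta_s"]),
                h_b=float(row["h_b_m"]),
                b=float(row["b"]),
                K_sat=float(row["ksat_m_d"]),
                h_b_gsd=float(row["h_b_gsd"]),
                b_gsd=float(row["b_gsd"]),
                K_sat_gsd=float(row["ksat_gsd"]),
            )
        )
        sand_range[name] = (float(row["sand_min"]), float(row["sand_max"]))
    return TextureClassTable(params=tuple(params), sand_range=sand_range)


# ---------------------------------------------------------------------------
# curves


def _check_h(h):
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("suction head h must be non-negative")
    return h


def water_retention(params: SoilHydraulicParams, h):
    """Volumetric water content at suction head ``h`` (m).

    Saturated (``theta_s``) at and below the air-entry head, power-law
    desaturation above it.  Accepts scalars or arrays.
    """
    h = _check_h(h)
    theta = np.where(
        h <= params.h_b,
        params.theta_s,
        params.theta_s * (params.h_b / np.maximum(h, params.h_b)) ** (1.0 / params.b),
    )
    return theta if theta.ndim else float(theta)


def retention_inverse(params: SoilHydraulicParams, theta):
    """Suction head (m) at which the water content equals ``theta``.

    The inverse of :func:`water_retention`; ``theta = theta_s`` maps to the
    air-entry head (the wettest suction with that content).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or np.any(theta > params.theta_s):
        raise ValueError("theta must lie in (0, theta_s]")
    h = params.h_b * (params.theta_s / theta) ** params.b
    return h if h.ndim else float(h)


def hydraulic_conductivity(params: SoilHydraulicParams, h):
    """Unsaturated hydraulic conductivity (m d-1) at suction head ``h`` (m)."""
    h = _check_h(h)
    k = np.where(
        h <= params.h_b,
        params.K_sat,
        params.K_sat * (params.h_b / np.maximum(h, params.h_b)) ** params.tau,
    )
    return k if k.ndim else float(k)


def matric_flux_potential(params: SoilHydraulicParams, h):
    """Matric flux potential Phi(h) = integral of k from h to infinity (m2 d-1)."""
    if params.tau <= 1.0:
        raise ValueError("matric flux potential requires tau > 1")
    h = _check_h(h)
    phi_b = params.K_sat * params.h_b / (params.tau - 1.0)
    phi = np.where(
        h >= params.h_b,
        params.K_sat
        * params.h_b**params.tau
        * np.maximum(h, params.h_b) ** (1.0 - params.tau)
        / (params.tau - 1.0),
        phi_b + params.K_sat * (params.h_b - h),
    )
    return phi if phi.ndim else float(phi)


def matric_flux_potential_inverse(params: SoilHydraulicParams, phi):
    """Suction head (m) at which the matric flux potential equals ``phi``."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("phi must be positive")
    phi_b = params.K_sat * params.h_b / (params.tau - 1.0)
    # unsaturated branch
    h_unsat = (
        phi * (params.tau - 1.0) / (params.K_sat * params.h_b**params.tau)
    ) ** (1.0 / (1.0 - params.tau))
    # linear branch between saturation and air entry
    h_sat = params.h_b - (phi - phi_b) / params.K_sat
    h = np.where(phi <= phi_b, h_unsat, np.maximum(h_sat, 0.0))
    return h if h.ndim else float(h)


# ---------------------------------------------------------------------------
# texture classification (USDA triangle)


def classify_usda_texture(sand: float, silt: float, clay: float) -> str:
    """Classify a (sand, silt, clay) composition in percent into a USDA class.

    Implements the standard USDA triangle boundary rules.  The fractions must
    be non-negative and sum to 100 within +-0.5.
    """
    if sand < 0 or silt < 0 or clay < 0:
        raise ValueError("fractions must be non-negative")
    total = sand + silt + clay
    if abs(total - 100.0) > 0.5:
        raise ValueError(f"sand+silt+clay must sum to 100 +- 0.5, got {total}")

    if silt + 1.5 * clay < 15:
        return "sand"
    if silt + 2.0 * clay < 30:
        return "loamy sand"
    if clay >= 40:
        if silt >= 40:
            return "silty clay"
        if sand <= 45:
            return "clay"
    if clay >= 35 and sand > 45:
        return "sandy clay"
    if 27 <= clay < 40:
        if sand <= 20:
            return "silty clay loam"
        if sand <= 45:
            return "clay loam"
    if 20 <= clay < 35 and sand > 45 and silt < 28:
        return "sandy clay loam"
    if silt >= 80 and clay < 12:
        return "silt"
    if silt >= 50 and (clay >= 12 or silt < 80):
        if clay < 27:
            return "silt loam"
    if 7 <= clay < 27 and 28 <= silt < 50 and sand <= 52:
        return "loam"
    return "sandy loam"


# ---------------------------------------------------------------------------
# per-class variability endmembers


def endmember_params(
    params: SoilHydraulicParams,
) -> tuple[SoilHydraulicParams, SoilHydraulicParams]:
    """Coarse-end and fine-end parameter combinations of a textural class.

    The within-class variability endmembers combine, for the coarse end, the
    minimum air-entry head, the maximum retention-curve steepness (minimum
    ``b``, hence maximum ``tau``) and the maximum saturated conductivity; the
    fine end takes the opposite extremes.  Minima and maxima sit one geometric
    standard deviation below/above the class mean (the source compilation
    reports these parameters with log-space scatter, so variability is applied
    multiplicatively).
    """
    if params.h_b_gsd is None or params.b_gsd is None or params.K_sat_gsd is None:
        raise ValueError("endmember_params requires the gsd fields on the parameters")
    if min(params.h_b_gsd, params.b_gsd, params.K_sat_gsd) < 1.0:
        raise ValueError("gsd factors must be >= 1")

    g_hb = params.h_b_gsd
    g_b = params.b_gsd
    g_k = params.K_sat_gsd

    coarse = replace(
        params,
        class_name=f"{params.class_name} (coarse end)",
        h_b=params.h_b / g_hb,
        b=params.b / g_b,
        K_sat=params.K_sat * g_k,
    )
    fine = replace(
        params,
        class_name=f"{params.class_name} (fine end)",
        h_b=params.h_b * g_hb,
        b=params.b * g_b,
        K_sat=params.K_sat / g_k,
    )
    return coarse, fine
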