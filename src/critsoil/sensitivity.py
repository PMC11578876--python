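"""Sensitivity spans of the simulated critical soil moisture threshold.

For each textural class, the span ``S_thetacrit = max(theta_crit) -
min(theta_crit)`` measures how far the threshold moves when one ingredient is
varied over its plausible range:

* ``soil_variability`` -- the within-class coarse/fine parameter endmembers;
* ``psi_x_variation`` -- the plant vulnerability threshold psi_x* swept from
  -1.5 to -5 MPa (the whole curve shifts, slope unchanged);
* ``L_root_variation`` -- the effective root length swept from 1/30 to 30
  times the reference.

Regressing the spans on the class mean sand fraction quantifies how strongly
soil texture dictates the threshold's sensitivity: spans shrink with sand
fraction for soil-parameter and vulnerability variation, while root-length
variation shows no texture trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .constants import T_POT_REF
from .plant import PlantTraits, default_traits
from .soil import SoilHydraulicParams, TextureClassTable, endmember_params, load_soil_table
from .supply import critical_thresholds

__all__ = [
    "SpanResult",
    "span_soil_variability",
    "span_plant_traits",
    "span_vs_sand_regression",
    "PSI_X_RANGE",
    "L_ROOT_FACTOR_RANGE",
]

#: psi_x* sweep endpoints (MPa)
PSI_X_RANGE = (-1.5, -5.0)

#: L_root multiplicative sweep endpoints relative to the reference
L_ROOT_FACTOR_RANGE = (1.0 / 30.0, 30.0)


@dataclass(frozen=True)
class SpanResult:
    """Span of simulated theta_crit for one class under one variation source."""

    class_name: str
    span: float
    source: str  # soil_variability | psi_x_variation | L_root_variation
    components: dict = field(default_factory=dict)  # label -> theta_crit

    def __post_init__(self):
        if self.span < 0:
            raise ValueError("span must be non-negative")


def _thresholds_kwargs(fast: bool) -> dict:
    return {"n_psi": 200, "n_trajectory": 800} if fast else {}


def span_soil_variability(
    soil: SoilHydraulicParams,
    traits: PlantTraits | None = None,
    T_pot: float = T_POT_REF,
    fast: bool = True,
) -> SpanResult:
    """theta_crit span between the coarse-end and fine-end soil parameter
    combinations of one class, default plant traits."""
    traits = traits or default_traits()
    coarse, fine = endmember_params(soil)
    comp = {}
    for label, p in (("coarse_end", coarse), ("fine_end", fine)):
        est = critical_thresholds(p, traits, T_pot, **_thresholds_kwargs(fast))
        comp[label] = est.theta_crit
    vals = list(comp.values())
    return SpanResult(
        class_name=soil.class_name,
        span=max(vals) - min(vals),
        source="soil_variability",
        components=comp,
    )


def span_plant_traits(
    soil: SoilHydraulicParams,
    which: str,
    traits: PlantTraits | None = None,
    T_pot: float = T_POT_REF,
    fast: bool = True,
) -> SpanResult:
    """theta_crit span under plant-trait variation.

    ``which = "psi_x"`` sweeps the vulnerability threshold over
    :data:`PSI_X_RANGE`; ``which = "L_root"`` sweeps the effective root length
    over :data:`L_ROOT_FACTOR_RANGE` times the reference.
    """
    traits = traits or default_traits()
    comp = {}
    if which == "psi_x":
        source = "psi_x_variation"
        for px in PSI_X_RANGE:
            est = critical_thresholds(
                soil, traits.with_psi_x_star(px), T_pot, **_thresholds_kwargs(fast)
            )
            comp[f"psi_x={px}"] = est.theta_crit
    elif which == "L_root":
        source = "L_root_variation"
        for fac in L_ROOT_FACTOR_RANGE:
            est = critical_thresholds(
                soil,
                traits.with_L_root(traits.L_root * fac),
                T_pot,
                **_thresholds_kwargs(fast),
            )
            comp[f"L_root_factor={fac:.4g}"] = est.theta_crit
    else:
        raise ValueError("which must be 'psi_x' or 'L_root'")
    vals = list(comp.values())
    return SpanResult(
        class_name=soil.class_name,
        span=max(vals) - min(vals),
        source=source,
        components=comp,
    )


def span_vs_sand_regression(
    spans: list[SpanResult],
    table: TextureClassTable | None = None,
):
    """OLS of span on class mean sand fraction (%).

    Returns ``(slope, intercept, r2_adj, p_value)`` with the two-sided
    p-value of the slope.
    """
    table = table or load_soil_table()
    if len(spans) < 3:
        raise ValueError("need at least 3 classes for the span regression")
    x = np.array([table.mean_sand_fraction(s.class_name) for s in spans])
    y = np.array([s.span for s in spans])
    if np.all(x == x[0]):
        raise ValueError("identical sand fractions: regression undefined")
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), 0.0, 1.0
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    intercept = float(model.params[0])
    return slope, intercept, float(model.rsquared_adj), float(model.pvalues[1])
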