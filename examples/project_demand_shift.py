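"""Shift of theta_crit under rising evaporative demand on a climate grid.

A two-period synthetic grid (temperature up 1.8 degC, relative humidity
down 5 points) raises the potential transpiration demand; the inverted
sigmoid supply curve of each pixel's textural class converts that into a
threshold shift delta-theta_crit.
"""

import numpy as np

from critsoil import default_traits
from critsoil.projection import project_grid
from critsoil.synthetic import gen_climate_grid

grid = gen_climate_grid(
    shape=(4, 6), textures=[(92.0, 3.0), (40.0, 18.0), (20.0, 45.0)],
    d_t=1.8, d_rh=-5.0,
)
res = project_grid(grid, default_traits())

print(f"demand change          : {res.d_tpot_rel[0, 0]:+.1f} % everywhere")
for cls in ("sand", "loam", "clay"):
    sel = res.texture_class == cls
    print(f"delta theta_crit {cls:5s} : {np.nanmean(res.delta_theta_crit[sel]):+.4f}")
print(f"grid mean              : {res.summary['mean_delta_theta_crit']:+.4f}")
print(
    "\nThresholds rise with demand everywhere, but only by a few thousandths:"
    "\nthe steepness of each class's supply curve buffers the shift."
)
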