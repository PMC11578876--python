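"""Recover theta_crit from a synthetic eddy-covariance-style series.

The generator plants a known threshold (0.14 m3 m-3) inside summer
dry-downs; the pipeline computes the evaporative fraction, intersects
summer with >= 10-day dry-downs and fits the linear-plus-plateau breakpoint.
"""

from critsoil.flux import site_theta_crit
from critsoil.synthetic import GeneratorConfig, gen_flux_series

cfg = GeneratorConfig(seed=42, theta_crit_true=0.14, ef_noise_sd=0.05)
series = gen_flux_series(cfg)
est = site_theta_crit(series, hemisphere="N")

print(f"true theta_crit      : {cfg.theta_crit_true:.3f}")
print(f"recovered theta_crit : {est.theta_crit:.3f}")
print(f"criterion tier       : {est.diagnostics['tier']}")
print(f"breakpoint p-value   : {est.diagnostics['p_value']:.2e}")
print(
    "\nThe breakpoint sits within ~0.01 m3 m-3 of the truth despite the "
    "EF noise;\nthe tier records which dry-down/season criterion produced it."
)
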