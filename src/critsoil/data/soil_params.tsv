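# Per-class soil hydraulic parameters for the 12 USDA textural classes.
# Campbell / Brooks-Corey retention:  theta(h) = theta_s * (h_b / h)^(1/b)  for h > h_b
# Conductivity:                       k(h) = K_sat * (h_b / h)^tau, tau = 2 + 3/b
# Columns and units:
#   class        USDA textural class name
#   theta_s      saturated volumetric water content (m3 m-3)
#   h_b_m        air-entry suction head (m)
#   h_b_gsd      geometric standard deviation factor of h_b (-, >= 1)
#   b            retention-curve slope parameter (-)
#   b_gsd        geometric standard deviation factor of b (-, >= 1)
#   ksat_m_d     saturated hydraulic conductivity (m d-1)
#   ksat_gsd     geometric standard deviation factor of K_sat (-, >= 1)
#   sand_min     minimum sand percentage of the class polygon (USDA triangle)
#   sand_max     maximum sand percentage of the class polygon (USDA triangle)
# Class means of theta_s, h_b, b and K_sat are transcribed from the per-class
# statistics of Cosby et al. (1984), Water Resources Research 20, 682-690
# (1448 samples, 11 USDA classes) -- the standard parameter set of the
# Campbell retention family in land-surface modelling.  The "silt" row is
# SYNTHETIC: the source carries no silt class and the row duplicates silt
# loam, the usual practice when the 12-class USDA list is needed.
# The gsd columns are package assumptions informed by the within-class scatter
# such compilations report (air-entry and conductivity scatter of roughly half a
# decade to a decade, slope scatter of 30-50%); see docs/methods.md.  Rows are
# ordered hydraulically coarse to fine, i.e. by increasing retention slope b.
class	theta_s	h_b_m	h_b_gsd	b	b_gsd	ksat_m_d	ksat_gsd	sand_min	sand_max
sand	0.339	0.069	3.2	2.79	1.4	4.026	4.0	85	100
loamy sand	0.421	0.036	3.2	4.26	1.4	1.218	4.0	70	90
sandy loam	0.434	0.141	3.2	4.74	1.4	0.452	4.0	43	85
loam	0.439	0.355	3.2	5.25	1.4	0.292	4.0	23	52
silt	0.476	0.759	3.2	5.33	1.4	0.243	4.0	0	20
silt loam	0.476	0.759	3.2	5.33	1.4	0.243	4.0	0	50
sandy clay loam	0.404	0.135	3.2	6.66	1.4	0.384	4.0	45	80
clay loam	0.465	0.263	3.2	8.17	1.4	0.212	4.0	20	45
silty clay loam	0.464	0.617	3.2	8.72	1.4	0.176	4.0	0	20
silty clay	0.468	0.324	3.2	10.39	1.4	0.116	4.0	0	20
sandy clay	0.406	0.098	3.2	10.73	1.4	0.624	4.0	45	65
clay	0.468	0.468	3.2	11.55	1.4	0.084	4.0	0	45
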