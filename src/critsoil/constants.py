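"""Unit conversions shared across the package.

Internally, soil suction is carried as a positive head in metres of water;
water potentials at the plant side are megapascals (negative in tension).
All conversions go through the single constant below.
"""

#: metres of water head per megapascal (rho * g with rho = 1000 kg m-3)
M_HEAD_PER_MPA: float = 101.97

#: reference potential transpiration rate (mm d-1) used throughout
T_POT_REF: float = 4.0

#: vapour pressure deficit (kPa) assumed to drive T_POT_REF
VPD_REF: float = 1.5


def mpa_to_head(psi_mpa):
    """Convert a (negative) water potential in MPa to positive suction head in m."""
    return -psi_mpa * M_HEAD_PER_MPA


def head_to_mpa(h_m):
    """Convert a positive suction head in m to a (negative) water potential in MPa."""
    return -h_m / M_HEAD_PER_MPA
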