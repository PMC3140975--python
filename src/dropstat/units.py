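"""Volume unit conversions.

Volumes appear in three units across an encapsulation design: droplets in
nanoliters, single cells in picoliters, and the ejection reservoir in
milliliters.  Ratios of volumes are computed on an integer grid of 0.1 pl so
that quantities like "100 droplets of 7.6 nl out of 0.1 ml = 0.76%" come out
exact rather than accumulating binary-fraction drift.
"""

PL_PER_NL = 1_000.0
PL_PER_ML = 1e9
NL_PER_ML = 1e6
ML_PER_PL = 1e-9

# integer grid: 1 deci-pl = 0.1 pl
_DECI_PL_PER_NL = 10_000
_DECI_PL_PER_ML = 10_000_000_000


def nl_to_deci_pl(volume_nl: float) -> int:
    """Resolve a nanoliter volume onto the 0.1 pl integer grid."""
    return round(volume_nl * _DECI_PL_PER_NL)


def ml_to_deci_pl(volume_ml: float) -> int:
    """Resolve a milliliter volume onto the 0.1 pl integer grid."""
    return round(volume_ml * _DECI_PL_PER_ML)
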