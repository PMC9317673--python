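"""Pulse-oximetry calibration: the empirical SpO2(R) polynomial.

Pulse oximetry compares the pulsatile (AC) to quasi-static (DC) light
absorption at two wavelengths.  The ratio-of-ratios

    R = (AC_red / DC_red) / (AC_ir / DC_ir)

maps to oxygen saturation through the sensor vendor's empirical quadratic

    SpO2(R) = -45.006 R^2 + 30.354 R + 94.84    [percent]

which peaks at the vertex R* = 30.354 / (2 * 45.006) ~= 0.3372 with a
maximum attainable saturation of ~99.96 %; physiological readings live on
the decreasing branch R >= R*.
"""

from __future__ import annotations

import math

from .errors import DomainError

# SpO2(R) = A*R^2 + B*R + C, percent
SPO2_A = -45.006
SPO2_B = 30.354
SPO2_C = 94.84

#: Abscissa of the polynomial vertex; the physical branch is R >= this.
RATIO_AT_MAX = -SPO2_B / (2.0 * SPO2_A)

#: Largest saturation the calibration can represent (value at the vertex).
SPO2_MAX = SPO2_C - SPO2_B * SPO2_B / (4.0 * SPO2_A)


def spo2_from_ratio(r: float) -> float:
    """Evaluate the calibration polynomial at ratio-of-ratios ``r``.

    Returns the raw polynomial value in percent; callers decide validity
    (physiological readings lie in (0, 100]).
    """
    return SPO2_A * r * r + SPO2_B * r + SPO2_C


def ratio_from_spo2(spo2_pct: float) -> float:
    """Invert the calibration polynomial on its decreasing branch.

    Returns the root R >= vertex abscissa such that
    ``spo2_from_ratio(ratio_from_spo2(s)) == s`` to ~1e-9.

    Raises
    ------
    DomainError
        If ``spo2_pct`` exceeds the polynomial's attainable maximum.
    """
    disc = SPO2_B * SPO2_B - 4.0 * SPO2_A * (SPO2_C - spo2_pct)
    if disc < 0.0:
        if disc > -1e-9:  # exactly at the vertex up to rounding
            disc = 0.0
        else:
            raise DomainError(
                f"SpO2 {spo2_pct}% exceeds the calibration maximum {SPO2_MAX:.4f}%"
            )
    # With A < 0 the larger root (decreasing branch) is (-B - sqrt)/(2A).
    return (-SPO2_B - math.sqrt(disc)) / (2.0 * SPO2_A)


def is_valid_spo2(value: float) -> bool:
    """Physiological validity band for a saturation reading, percent."""
    return 0.0 < value <= 100.0
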