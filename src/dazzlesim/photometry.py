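"""Photopic luminous efficiency and radiometric-to-photometric conversion.

The dazzle physics needs the corneal *illuminance* (lm/m^2) produced by a
laser of known irradiance (W/m^2).  The conversion is

    E_v = K_m * V(lambda) * E_e

with K_m = 683 lm/W the maximum luminous efficacy and V the CIE 1924
photopic luminous efficiency function, tabulated here at 5 nm resolution
over 380-780 nm and interpolated linearly in between.
"""

from __future__ import annotations

import numpy as np

#: Maximum spectral luminous efficacy for photopic vision, lm/W.
LUMINOUS_EFFICACY_CONSTANT = 683.0

# CIE 1924 photopic luminous efficiency V(lambda), 380-780 nm, 5 nm steps.
_VLAMBDA_NM = np.arange(380.0, 785.0, 5.0)
_VLAMBDA = np.array([
    0.0000390, 0.0000640, 0.0001200, 0.0002170, 0.0003960,
    0.0006400, 0.0012100, 0.0021800, 0.0040000, 0.0073000,
    0.0116000, 0.0168400, 0.0230000, 0.0298000, 0.0380000,
    0.0480000, 0.0600000, 0.0739000, 0.0909800, 0.1126000,
    0.1390200, 0.1693000, 0.2080200, 0.2586000, 0.3230000,
    0.4073000, 0.5030000, 0.6082000, 0.7100000, 0.7932000,
    0.8620000, 0.9148500, 0.9540000, 0.9803000, 0.9949500,
    1.0000000, 0.9950000, 0.9786000, 0.9520000, 0.9154000,
    0.8700000, 0.8163000, 0.7570000, 0.6949000, 0.6310000,
    0.5668000, 0.5030000, 0.4412000, 0.3810000, 0.3210000,
    0.2650000, 0.2170000, 0.1750000, 0.1382000, 0.1070000,
    0.0816000, 0.0610000, 0.0445800, 0.0320000, 0.0232000,
    0.0170000, 0.0119200, 0.0082100, 0.0057230, 0.0041020,
    0.0029290, 0.0020910, 0.0014840, 0.0010470, 0.0007400,
    0.0005200, 0.0003610, 0.0002490, 0.0001720, 0.0001200,
    0.0000848, 0.0000600, 0.0000424, 0.0000300, 0.0000212,
    0.0000150,
])


def photopic_efficiency(wavelength_nm: float) -> float:
    """CIE 1924 photopic luminous efficiency V(lambda).

    Parameters
    ----------
    wavelength_nm : float
        Wavelength in nanometres; must lie within the table support
        [380, 780] nm.

    Returns
    -------
    float
        Dimensionless efficiency in [0, 1]; V(555 nm) = 1 by definition.
    """
    w = float(wavelength_nm)
    if not (_VLAMBDA_NM[0] <= w <= _VLAMBDA_NM[-1]):
        raise ValueError(
            f"wavelength {w} nm outside the photopic table support "
            f"[{_VLAMBDA_NM[0]:.0f}, {_VLAMBDA_NM[-1]:.0f}] nm"
        )
    return float(np.interp(w, _VLAMBDA_NM, _VLAMBDA))


def illuminance_from_irradiance(irradiance_w_m2: float, wavelength_nm: float) -> float:
    """Corneal illuminance (lm/m^2) of monochromatic light of given irradiance."""
    if irradiance_w_m2 < 0:
        raise ValueError("irradiance must be non-negative")
    return LUMINOUS_EFFICACY_CONSTANT * photopic_efficiency(wavelength_nm) * irradiance_w_m2
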