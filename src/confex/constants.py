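"""Physical constants and unit conversions shared across the package.

All internal energies are J mol^-1, rates s^-1, temperatures K.
"""

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Exact offset between Celsius and Kelvin.
KELVIN_OFFSET = 273.15

#: Gyromagnetic ratio magnitudes, rad s^-1 T^-1, to 6 significant figures.
#: 15N is negative in sign; only the magnitude enters |Δω| conversions.
GAMMA = {
    "15N": 2.71262e7,
    "1H": 2.67522e8,
}


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + KELVIN_OFFSET


def kbt_kj_per_mol(temperature_k: float) -> float:
    """Thermal energy k_B·T expressed per mole (R·T), in kJ mol^-1."""
    return R_GAS * temperature_k / 1000.0


def dw_ppm_to_rad_s(dw_ppm: float, nucleus: str, field_t: float) -> float:
    """Convert a chemical-shift difference from ppm to rad s^-1.

    |δω| = dw_ppm × 1e-6 × |γ(nucleus)| × B0.
    """
    try:
        gamma = GAMMA[nucleus]
    except KeyError:
        raise ValueError(f"unknown nucleus {nucleus!r}; expected one of {sorted(GAMMA)}")
    if field_t <= 0:
        raise ValueError("field must be positive (tesla)")
    return dw_ppm * 1e-6 * gamma * field_t
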