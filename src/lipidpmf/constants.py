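"""Physical constants and unit conventions.

Units used throughout the package: lengths in nm, energies in kJ/mol,
temperatures in K, concentrations in mol/L.  1 nm^3 = 1e-24 L.
"""

#: Gas constant, kJ mol^-1 K^-1 (CODATA 2018).
R_KJ_PER_MOL_K = 8.314462618e-3

#: Avogadro's number, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Litres per cubic nanometre.
L_PER_NM3 = 1e-24

#: Default simulation temperature (K) for the coarse-grained protocol.
DEFAULT_TEMPERATURE = 323.0


def rt(temperature: float) -> float:
    """Thermal energy RT in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ_PER_MOL_K * temperature
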