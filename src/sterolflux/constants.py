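"""Physical constants shared across the package.

Energies are kJ·mol⁻¹, distances nm, temperatures K, concentrations mM,
membrane potentials mV unless a function states otherwise.
"""

#: Gas constant, kJ·mol⁻¹·K⁻¹.
R_KJ = 8.314e-3

#: Faraday constant, C·mol⁻¹ (equivalently kJ·mol⁻¹·V⁻¹ per elementary charge).
FARADAY = 96_485.0

#: Default temperature for coarse-grained free-energy data, K.
DEFAULT_CG_TEMPERATURE = 323.0

#: Default temperature for atomistic trajectory data, K.
DEFAULT_ATOMISTIC_TEMPERATURE = 310.0


def kt_kj(temperature: float) -> float:
    """Thermal energy RT in kJ·mol⁻¹ at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ * temperature
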