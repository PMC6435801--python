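"""Physical constants and unit conventions.

Energies are in kJ mol⁻¹, lengths in nm, charges in elementary charges,
temperatures in K and pressures in bar throughout the package.  Free-energy
profiles are reported in units of k_BT.
"""

#: Boltzmann constant, kJ mol⁻¹ K⁻¹
KB = 0.0083144621

#: Coulomb prefactor 1/(4πε₀), kJ mol⁻¹ nm e⁻²
COULOMB = 138.935458

#: Conversion of a P·V term: 1 bar · cm³ mol⁻¹ = 1e-4 kJ mol⁻¹
BAR_CM3_TO_KJ = 1.0e-4

#: Conversion of a slope ∂G/∂P with G in J mol⁻¹ and P in bar to cm³ mol⁻¹
J_PER_BAR_TO_CM3 = 10.0


def kt(temperature: float) -> float:
    """Thermal energy k_BT in kJ mol⁻¹ at `temperature` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
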