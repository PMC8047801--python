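"""Physical constants and unit conversions.

Internal unit system: nm (length), kJ/mol (energy), e (charge), ps (time),
g/mol (mass).  In this system ``1 kJ/mol / 1 g/mol == (1 nm/ps)**2`` exactly,
which makes thermal-velocity prefactors come out in nm/ps with no extra
factors.  Converters live at the I/O boundary only.
"""

#: Coulomb constant 1/(4 pi eps0) in kJ nm / (mol e^2), CODATA-derived.
COULOMB_CONSTANT = 138.935458

#: Boltzmann constant in kJ/(mol K) (i.e. the molar gas constant).
BOLTZMANN_KJMOL = 0.008314462618

#: 1 M standard-state volume per molecule, nm^3.
STANDARD_VOLUME_NM3 = 1.661

#: Multiply a diffusion coefficient in nm^2/ps by this to get 1e-5 cm^2/s.
NM2_PER_PS_TO_1E5_CM2_S = 1.0e3

#: Avogadro-derived conversion: mol/L -> particles/nm^3.
MOLAR_TO_PER_NM3 = 0.602214076

#: Picoseconds per second.
PS_PER_S = 1.0e12


def kT(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at ``temperature`` (K)."""
    return BOLTZMANN_KJMOL * temperature
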