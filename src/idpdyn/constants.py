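"""Physical constants and literature parametrizations used across the package.

Internal unit conventions: lengths in Å, times in ns, energies in μeV,
temperatures in K, viscosities in mPa·s (= cP), diffusion coefficients in
Å²/ns (translational) or 1/ns (rotational).  1 Å²/ns = 1e-11 m²/s.
"""

from __future__ import annotations

#: Reduced Planck constant in μeV·ns (6.582119569e-16 eV·s).
HBAR_UEV_NS = 0.6582119569

#: Boltzmann constant in J/K (SI, exact).
KB_J_PER_K = 1.380649e-23

#: Conversion: 1 Å²/ns expressed in m²/s.
A2_PER_NS_TO_M2_PER_S = 1.0e-11

#: Conversion: 1 mPa·s expressed in Pa·s.
MPAS_TO_PAS = 1.0e-3

# ---------------------------------------------------------------------------
# Water viscosity (Kestin-form correlation for light water; heavy water via
# the thermal-offset construction of the isotope-viscosity literature).
# ---------------------------------------------------------------------------

#: η(20 °C) of H2O in mPa·s (IAPWS 2008 reference point).
ETA_H2O_20C = 1.0016

#: Coefficients of the Kestin et al. (1978) log10-ratio polynomial for H2O,
#: log10(η(t)/η(20°C)) = (20−t)·(c0 + c1(20−t) + c2(20−t)² + c3(20−t)³)/(t+96),
#: t in °C.  Accurate to ~0.1% over 0–110 °C.
KESTIN_COEFFS = (1.2378, -1.303e-3, 3.06e-6, 2.55e-8)

#: Thermal offset (K) between the D2O and H2O viscosity curves: the heavy-water
#: viscosity equals the light-water viscosity evaluated 6.498 K lower, scaled by
#: the square-root molecular-mass ratio.
D2O_THERMAL_OFFSET_K = 6.498

#: √(M_D2O/M_H2O) amplitude factor for the heavy-water viscosity.
D2O_MASS_FACTOR = 1.054373  # sqrt(20.0276/18.0153)

#: Validity window of the viscosity relations (K).
VISCOSITY_T_RANGE = (270.0, 370.0)

#: Goldsack–Franchetto-form salt viscosity parameters (E, V) per salt, with
#: the salt mole fraction X as the variable: η/η0 = exp(E·X)/(1 + V·X).
#: NaCl values calibrated against Jones–Dole/CRC relative viscosities at 25 °C
#: (η_r ≈ 1.0143 at 0.15 M, 1.086 at 1 M).
SALT_VISCOSITY_PARAMS = {
    "NaCl": (4.72, 0.0),
}

#: Molar concentration of pure water (mol/L) used for mole-fraction conversion.
WATER_MOLARITY = 55.51

# ---------------------------------------------------------------------------
# Nygaard et al. empirical IDP R_g ↔ R_h relation (Biophys. J. 2017):
#   R_g/R_h = α1·(R_g − α2·N^0.33)/(N^0.6 − N^0.33) + α3,   R_g in Å.
# ---------------------------------------------------------------------------
NYGAARD_ALPHA1 = 0.216  # 1/Å
NYGAARD_ALPHA2 = 4.06   # Å
NYGAARD_ALPHA3 = 0.821
NYGAARD_EXP_LOW = 0.33
NYGAARD_EXP_HIGH = 0.6

# ---------------------------------------------------------------------------
# Finite-size (periodic-boundary) self-interaction constants.
# ---------------------------------------------------------------------------

#: Yeh–Hummer ξ for a simple-cubic periodic lattice.
XI_CUBIC = 2.837297

#: ξ for an FCC lattice, per lattice point: Hasimoto's FCC drag coefficient
#: 1.7917 times (4π/3)^(1/3).  Use with L = (volume per lattice point)^(1/3).
XI_FCC = 2.888207

# ---------------------------------------------------------------------------
# Histatin 5 reference values (inputs, not fitted quantities).
# ---------------------------------------------------------------------------

#: Specific volume of Hst5 (mL/g), Cohn–Edsall method.
HST5_SPECIFIC_VOLUME = 0.7023

#: Molecular mass of Hst5 (Da).
HST5_MASS_DA = 3036.0

#: Chain length of Hst5 (residues).
HST5_N_RESIDUES = 24

#: Family constant of the fractal diffusion relation D = C·M^(−1/d_F),
#: calibrated on α-synuclein QENS + SAXS data (D in Å²/ns, M in Da).
FRACTAL_C_DEFAULT = 10353.0

#: Default SAXS high-q window (Å⁻¹) for the fractal-dimension slope.
SAXS_DF_WINDOW = (2.0, 2.8)
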