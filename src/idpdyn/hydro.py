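"""Scalar hydrodynamics: diffusion ↔ radius conversions, solvent viscosity,
ellipsoid (Perrin) friction, crowding scaling laws, and fractal-dimension
diffusion relations for intrinsically disordered proteins.

All radii in Å, diffusion in Å²/ns (translational) or 1/ns (rotational),
viscosity in mPa·s, temperature in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from . import constants as C

__all__ = [
    "HydroContext",
    "EllipsoidShape",
    "HydrogenRadialProfile",
    "ScalingParams",
    "FractalModel",
    "viscosity_water",
    "viscosity_with_salt",
    "stokes_einstein_radius",
    "stokes_einstein_D",
    "sphere_Dr",
    "nygaard_rh",
    "nygaard_rg_inverse",
    "perrin_translational",
    "perrin_rotational",
    "apparent_diffusion",
    "volume_fraction",
    "hydrodynamic_volume_fraction",
    "hydration_shell_ratio",
    "crowding_scale",
    "fractal_predict",
    "fractal_calibrate",
    "fractal_dimension_from_saxs",
    "apply_apparent_ratio",
]


# ---------------------------------------------------------------------------
# Solvent viscosity
# ---------------------------------------------------------------------------

def viscosity_water(temperature: float, isotope: str = "H2O") -> float:
    """Viscosity of pure light or heavy water in mPa·s.

    Light water uses the Kestin-form log-ratio correlation; heavy water is
    obtained from it by the thermal-offset construction (shift the temperature
    by 6.498 K and scale by the square-root molecular-mass ratio), which
    reproduces tabulated D2O viscosities to well under 1% near ambient
    temperature.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K; must lie in the validity window 270–370 K.
    isotope : {"H2O", "D2O"}
    """
    lo, hi = C.VISCOSITY_T_RANGE
    if not (lo <= temperature <= hi):
        raise ValueError(
            f"temperature {temperature} K outside viscosity validity range {lo}-{hi} K"
        )
    if isotope == "H2O":
        return _eta_h2o(temperature)
    if isotope == "D2O":
        return C.D2O_MASS_FACTOR * _eta_h2o(temperature - C.D2O_THERMAL_OFFSET_K)
    raise ValueError(f"unknown isotope {isotope!r}; expected 'H2O' or 'D2O'")


def _eta_h2o(temperature: float) -> float:
    t = temperature - 273.15
    c0, c1, c2, c3 = C.KESTIN_COEFFS
    x = 20.0 - t
    log_ratio = x * (c0 + c1 * x + c2 * x * x + c3 * x**3) / (t + 96.0)
    return C.ETA_H2O_20C * 10.0**log_ratio


def viscosity_with_salt(eta0: float, molarity: float, salt: str = "NaCl") -> float:
    """Salt-corrected solvent viscosity (mPa·s), Goldsack–Franchetto form.

    η/η0 = exp(E·X)/(1 + V·X) with X the salt mole fraction.  Valid for dilute
    to moderately concentrated 1:1 electrolytes (≤ ~2 M).
    """
    if molarity < 0:
        raise ValueError("molarity must be non-negative")
    if salt not in C.SALT_VISCOSITY_PARAMS:
        raise ValueError(f"unknown salt {salt!r}")
    if molarity == 0:
        return eta0
    E, V = C.SALT_VISCOSITY_PARAMS[salt]
    x = molarity / (molarity + C.WATER_MOLARITY)
    return eta0 * math.exp(E * x) / (1.0 + V * x)


@dataclass
class HydroContext:
    """Solvent context tying temperature, isotope, and salt to a viscosity.

    The viscosity is computed from the Cho-style isotope relations plus the
    salt correction unless explicitly overridden.
    """

    temperature: float = 298.0
    isotope: str = "D2O"
    salt_molarity: float = 0.0
    salt: str = "NaCl"
    viscosity_override: float | None = None

    def __post_init__(self) -> None:
        lo, hi = C.VISCOSITY_T_RANGE
        if not (lo <= self.temperature <= hi):
            raise ValueError(f"temperature must lie in [{lo}, {hi}] K")
        if self.viscosity is not None and self.viscosity <= 0:
            raise ValueError("viscosity must be positive")

    @property
    def viscosity(self) -> float:
        """Solvent viscosity in mPa·s."""
        if self.viscosity_override is not None:
            return self.viscosity_override
        eta0 = viscosity_water(self.temperature, self.isotope)
        return viscosity_with_salt(eta0, self.salt_molarity, self.salt)

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in J."""
        return C.KB_J_PER_K * self.temperature


# ---------------------------------------------------------------------------
# Stokes–Einstein / Einstein–Smoluchowski
# ---------------------------------------------------------------------------

def _kt_over_6pi_eta(ctx: HydroContext) -> float:
    """k_B T / (6πη) in units of Å³/ns (so dividing by Å gives Å²/ns)."""
    eta_si = ctx.viscosity * C.MPAS_TO_PAS
    val_si = ctx.kT / (6.0 * math.pi * eta_si)  # m³/s
    # m³/s → Å³/ns: ×1e30 Å³/m³ × 1e-9 s/ns
    return val_si * 1.0e21


def stokes_einstein_radius(D: float, ctx: HydroContext) -> float:
    """Effective hydrodynamic radius (Å) of a sphere diffusing at ``D`` Å²/ns."""
    if D <= 0:
        raise ValueError("D must be positive")
    return _kt_over_6pi_eta(ctx) / D


def stokes_einstein_D(R: float, ctx: HydroContext) -> float:
    """Translational diffusion coefficient (Å²/ns) of a sphere of radius R Å."""
    if R <= 0:
        raise ValueError("R must be positive")
    return _kt_over_6pi_eta(ctx) / R


def sphere_Dr(R: float, ctx: HydroContext) -> float:
    """Rotational diffusion coefficient (1/ns) of a sphere of radius R Å,
    D_r = k_B T / (8πηR³)."""
    if R <= 0:
        raise ValueError("R must be positive")
    return _kt_over_6pi_eta(ctx) * 0.75 / R**3


# ---------------------------------------------------------------------------
# Nygaard IDP R_g ↔ R_h relation
# ---------------------------------------------------------------------------

def nygaard_rh(R_g: float, N: int) -> float:
    """Hydrodynamic radius (Å) from the radius of gyration via the empirical
    IDP relation of Nygaard et al. for a chain of ``N`` residues."""
    if N < 2:
        raise ValueError("N must be at least 2")
    if R_g <= 0:
        raise ValueError("R_g must be positive")
    ratio = _nygaard_rg_over_rh(R_g, N)
    if ratio <= 0:
        raise ValueError("Nygaard relation outside its physical branch")
    return R_g / ratio


def _nygaard_rg_over_rh(R_g: float, N: int) -> float:
    n_lo = N**C.NYGAARD_EXP_LOW
    n_hi = N**C.NYGAARD_EXP_HIGH
    return (
        C.NYGAARD_ALPHA1 * (R_g - C.NYGAARD_ALPHA2 * n_lo) / (n_hi - n_lo)
        + C.NYGAARD_ALPHA3
    )


def nygaard_rg_inverse(R_h: float, N: int, bracket: tuple[float, float] = (0.5, 100.0)) -> float:
    """Numerically invert the Nygaard relation: the R_g (Å) whose predicted
    hydrodynamic radius equals ``R_h``.  Unique on the physical branch."""
    if R_h <= 0:
        raise ValueError("R_h must be positive")

    def f(rg: float) -> float:
        return rg - R_h * _nygaard_rg_over_rh(rg, N)

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError("no root of the Nygaard inverse in the given bracket")
    return optimize.brentq(f, lo, hi, xtol=1e-10)


# ---------------------------------------------------------------------------
# Perrin (spheroid) hydrodynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipsoidShape:
    """Spheroid with polar semiaxis ``a`` and equatorial semiaxis ``b`` (Å).

    ``a > b`` is prolate, ``a < b`` oblate, ``a == b`` a sphere.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semiaxes must be positive")

    @property
    def kind(self) -> str:
        if self.a > self.b:
            return "prolate"
        if self.a < self.b:
            return "oblate"
        return "sphere"

    @property
    def volume_equivalent_radius(self) -> float:
        return (self.a * self.b**2) ** (1.0 / 3.0)


def _perrin_requiv(shape: EllipsoidShape) -> float:
    """Radius (Å) of the sphere with the same orientation-averaged
    translational friction as the spheroid (closed Perrin forms)."""
    a, b = shape.a, shape.b
    if a == b:
        return a
    if a > b:  # prolate
        xi = math.sqrt(a * a - b * b)
        return xi / math.log((a + xi) / b)
    xi = math.sqrt(b * b - a * a)  # oblate
    return xi / math.atan(xi / a)


def _ellipsoid_integrals(a: float, b: float, c: float) -> tuple[float, np.ndarray]:
    """Jeffery/Perrin elliptic integrals χ = ∫ds/Δ and α_i = ∫ds/((a_i²+s)Δ),
    Δ = √((a²+s)(b²+s)(c²+s)), computed numerically (general triaxial)."""
    semi = np.array([a, b, c], dtype=float)

    def delta(s: float) -> float:
        return math.sqrt((a * a + s) * (b * b + s) * (c * c + s))

    chi, _ = integrate.quad(lambda s: 1.0 / delta(s), 0.0, np.inf, limit=200)
    alphas = np.empty(3)
    for i, ai in enumerate(semi):
        alphas[i], _ = integrate.quad(
            lambda s: 1.0 / ((ai * ai + s) * delta(s)), 0.0, np.inf, limit=200
        )
    return chi, alphas


def perrin_translational(shape: EllipsoidShape, ctx: HydroContext) -> tuple[float, float]:
    """Orientation-averaged translational diffusion of a spheroid.

    Returns ``(D_t, R_h_equiv)`` with D_t in Å²/ns and the friction-equivalent
    sphere radius in Å.
    """
    r_eq = _perrin_requiv(shape)
    return _kt_over_6pi_eta(ctx) / r_eq, r_eq


def perrin_translational_factor(shape: EllipsoidShape) -> float:
    """Perrin friction factor f/f_sphere relative to the volume-equivalent
    sphere; ≥ 1 with equality only for a sphere."""
    return _perrin_requiv(shape) / shape.volume_equivalent_radius


def perrin_rotational(shape: EllipsoidShape, ctx: HydroContext) -> float:
    """Orientation-averaged rotational diffusion coefficient (1/ns) of the
    spheroid from the Perrin rotational friction tensor,
    ζ_i = (16πη/3)(a_j²+a_k²)/(a_j²α_j + a_k²α_k)."""
    a, b = shape.a, shape.b
    chi, al = _ellipsoid_integrals(a, b, b)
    semi2 = np.array([a * a, b * b, b * b])
    eta_si = ctx.viscosity * C.MPAS_TO_PAS
    pref = 16.0 * math.pi * eta_si / 3.0  # SI, lengths still in Å — fix units below
    d_rot = np.empty(3)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        zeta = pref * (semi2[j] + semi2[k]) / (semi2[j] * al[j] + semi2[k] * al[k])
        d_rot[i] = ctx.kT / zeta
    # zeta carries Å³ from the semiaxis²/α ratio: convert Å³→m³ then 1/s→1/ns
    return float(np.mean(d_rot)) * 1.0e30 * 1.0e-9


# ---------------------------------------------------------------------------
# Apparent diffusion from rotational + translational superposition
# ---------------------------------------------------------------------------

@dataclass
class HydrogenRadialProfile:
    """Normalized radial hydrogen distribution ρ_H(r) on a grid (Å, 1/Å).

    ρ_H includes the radial volume weight, so ∫ρ_H(r)dr = 1.
    """

    r_grid: np.ndarray
    rho_H: np.ndarray

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.rho_H = np.asarray(self.rho_H, dtype=float)
        if np.any(self.rho_H < 0):
            raise ValueError("rho_H must be non-negative")
        norm = np.trapezoid(self.rho_H, self.r_grid)
        if not math.isclose(norm, 1.0, rel_tol=1e-6):
            raise ValueError(f"rho_H must integrate to 1 (got {norm:.6g})")

    @classmethod
    def uniform_sphere(cls, radius: float, n: int = 512) -> "HydrogenRadialProfile":
        """Hydrogens distributed uniformly through a sphere: ρ(r) = 3r²/R³."""
        r = np.linspace(0.0, radius, n)
        rho = 3.0 * r**2 / radius**3
        rho /= np.trapezoid(rho, r)
        return cls(r, rho)

    @classmethod
    def point(cls) -> "HydrogenRadialProfile":
        """All scatterers at the center of mass (delta at r = 0)."""
        # narrow triangular spike at the origin; width far below any 1/q scale
        r = np.linspace(0.0, 1e-4, 8)
        rho = np.linspace(2.0 / 1e-4, 0.0, 8)
        rho /= np.trapezoid(rho, r)
        return cls(r, rho)


def _spherical_jn_sq_weights(profile: HydrogenRadialProfile, q: float,
                             tol: float = 1e-4, l_max: int = 100) -> np.ndarray:
    """Weights B_l(q) = ∫ρ_H(r)(2l+1)j_l²(qr)dr, truncated once the cumulative
    weight exceeds 1 − tol."""
    from scipy.special import spherical_jn

    r = profile.r_grid
    weights = []
    cum = 0.0
    for l in range(l_max + 1):
        jl = spherical_jn(l, q * r)
        B = (2 * l + 1) * np.trapezoid(profile.rho_H * jl**2, r)
        weights.append(B)
        cum += B
        if cum >= 1.0 - tol:
            return np.asarray(weights)
    raise RuntimeError(
        f"multipole truncation not reached by l={l_max} (cumulative weight {cum:.4f})"
    )


def _fit_single_lorentzian(omega: np.ndarray, intensity: np.ndarray,
                           gamma0: float) -> float:
    """HWHM (μeV) of the best least-squares single Lorentzian A·L(ω; Γ)."""

    def resid(p: np.ndarray) -> np.ndarray:
        amp, gam = p
        lor = gam / (math.pi * (omega**2 + gam**2))
        return amp * lor - intensity

    res = optimize.least_squares(
        resid, x0=np.array([1.0, gamma0]), bounds=([0.0, 1e-8], [np.inf, np.inf])
    )
    return float(res.x[1])


def apparent_diffusion(D_t: float, D_r: float, profile: HydrogenRadialProfile,
                       q_range: tuple[float, float] = (0.2, 1.8),
                       n_q: int = 12, omega_window: float = 30.0,
                       n_omega: int = 481) -> float:
    """Apparent diffusion coefficient (Å²/ns) seen by a single-Lorentzian
    analysis of the rotational–translational line superposition.

    For each q the spectrum Σ_l B_l(q)·L(ω; ħ(D_t q² + l(l+1)D_r)) is built on
    the instrument energy window and fitted with one Lorentzian; the apparent
    widths are then regressed against ħq² through the origin.  Rotation only
    broadens, so the result is ≥ D_t, with equality when D_r = 0 or for a
    point-like scatterer distribution.
    """
    if D_t < 0 or D_r < 0:
        raise ValueError("diffusion coefficients must be non-negative")
    qs = np.linspace(q_range[0], q_range[1], n_q)
    omega = np.linspace(-omega_window, omega_window, n_omega)
    hbar = C.HBAR_UEV_NS
    gamma_app = np.empty(n_q)
    for i, q in enumerate(qs):
        B = _spherical_jn_sq_weights(profile, q)
        ls = np.arange(B.size)
        widths = hbar * (D_t * q * q + ls * (ls + 1) * D_r)
        widths = np.maximum(widths, 1e-10)
        spec = np.sum(
            B[:, None] * widths[:, None]
            / (math.pi * (omega[None, :] ** 2 + widths[:, None] ** 2)),
            axis=0,
        )
        gamma_app[i] = _fit_single_lorentzian(omega, spec, float(np.sum(B * widths)))
    x = hbar * qs**2
    return float(np.sum(x * gamma_app) / np.sum(x * x))


# ---------------------------------------------------------------------------
# Volume fractions and crowding
# ---------------------------------------------------------------------------

def volume_fraction(c_p: float, nu_p: float = C.HST5_SPECIFIC_VOLUME,
                    convention: str = "solution") -> float:
    """Dry protein volume fraction from concentration (mg/mL) and specific
    volume (mL/g).

    ``convention='solution'`` (default) is φ = c·ν_p with c per solution
    volume; ``'solvent'`` is φ = c·ν_p/(1 + c·ν_p) with c per solvent volume.
    """
    if c_p < 0 or nu_p <= 0:
        raise ValueError("inputs must be positive")
    x = (c_p / 1000.0) * nu_p  # mg/mL → g/mL
    if convention == "solution":
        return x
    if convention == "solvent":
        return x / (1.0 + x)
    raise ValueError(f"unknown convention {convention!r}")


def hydrodynamic_volume_fraction(phi: float, R_h: float, R_g: float) -> float:
    """Effective hydrodynamic volume fraction φ_h = (R_h/R_g)³·φ."""
    if R_h <= 0 or R_g <= 0:
        raise ValueError("radii must be positive")
    phi_h = (R_h / R_g) ** 3 * phi
    if phi_h > 1:
        raise ValueError(f"phi_h = {phi_h:.3f} > 1 is unphysical")
    return phi_h


def hydration_shell_ratio(R_g: float, shell: float = 5.5) -> float:
    """R_h/R_g ratio obtained by assuming R_h = R_g + hydration shell (Å)."""
    if R_g <= 0 or shell < 0:
        raise ValueError("invalid inputs")
    return (R_g + shell) / R_g


@dataclass(frozen=True)
class ScalingParams:
    """Charged-sphere short-time scaling-law parameters (Banchio–Nägele form):
    D_t(φ)/D_t(0) = 1 − a_t·φ^e_t  and  D_r(φ)/D_r(0) = 1 − a_r·φ^e_r."""

    a_t: float = 2.5
    a_r: float = 1.3
    exponent_t: float = 4.0 / 3.0
    exponent_r: float = 2.0


def crowding_scale(D0: float, phi_h: float,
                   params: ScalingParams = ScalingParams(),
                   branch: str = "translational") -> float:
    """Scale a dilute-limit diffusion coefficient to volume fraction ``phi_h``
    with the charged-sphere short-time law."""
    if not (0.0 <= phi_h < 1.0):
        raise ValueError("phi_h must lie in [0, 1)")
    if branch == "translational":
        factor = 1.0 - params.a_t * phi_h**params.exponent_t
    elif branch == "rotational":
        factor = 1.0 - params.a_r * phi_h**params.exponent_r
    else:
        raise ValueError(f"unknown branch {branch!r}")
    if factor <= 0:
        raise ValueError(f"scaling factor {factor:.3f} ≤ 0: outside validity")
    return D0 * factor


# ---------------------------------------------------------------------------
# Fractal-dimension diffusion relation
# ---------------------------------------------------------------------------

_FRACTAL_C_DEFAULT = C.FRACTAL_C_DEFAULT
_HST5_MASS = C.HST5_MASS_DA


@dataclass(frozen=True)
class FractalModel:
    """Diffusion–mass–fractal-dimension relation D = C·M^(−1/d_F)."""

    C: float = _FRACTAL_C_DEFAULT
    d_F: float = 1.5
    M: float = _HST5_MASS

    def __post_init__(self) -> None:
        if not (1.0 < self.d_F <= 3.0):
            raise ValueError("d_F must lie in (1, 3]")
        if self.C <= 0 or self.M <= 0:
            raise ValueError("C and M must be positive")


def fractal_predict(model: FractalModel) -> float:
    """Predicted diffusion coefficient (Å²/ns) of the fractal relation."""
    return model.C * model.M ** (-1.0 / model.d_F)


def fractal_calibrate(D: float, M: float, d_F: float) -> float:
    """Family constant C from a measured diffusion coefficient, via the
    linearized form log D = log C − (1/d_F)·log M."""
    if D <= 0 or M <= 0:
        raise ValueError("D and M must be positive")
    return D * M ** (1.0 / d_F)


def fractal_dimension_from_saxs(q: np.ndarray, intensity: np.ndarray,
                                q_min: float = C.SAXS_DF_WINDOW[0],
                                q_max: float = C.SAXS_DF_WINDOW[1]) -> float:
    """Fractal dimension from the high-q SAXS power law: minus the slope of a
    linear fit of log I vs log q over [q_min, q_max]."""
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    mask = (q >= q_min) & (q <= q_max) & (intensity > 0)
    if mask.sum() < 5:
        raise ValueError("fewer than 5 positive intensity points in the fit window")
    slope, _ = np.polyfit(np.log(q[mask]), np.log(intensity[mask]), 1)
    return float(-slope)


def apply_apparent_ratio(D_t: float, ratio: float = 1.27) -> float:
    """Convert translational to apparent diffusion with a literature D/D_t
    ratio (default 1.27, measured for an IDP of comparable class)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio * D_t
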