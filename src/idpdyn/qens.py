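"""Quasi-elastic neutron scattering model and fits.

The scattering function measured on a backscattering spectrometer is modeled
as a resolution-broadened sum of Lorentzians,

    S(q, ω) = R(ω) ⊗ { β(q)·[A₀(q)·L(ω; γ) + (1 − A₀(q))·L(ω; γ + Γ)]
                        + β_s(q)·L(ω; γ_s) },

where γ = ħDq² is the Fickian center-of-mass width, Γ the jump-diffusion
internal width Γ = ħD_int q²/(1 + D_int q² τ), A₀(q) the elastic incoherent
structure factor, and the last term the solvent contribution.  All Lorentzian
widths are half-widths at half maximum in μeV.

Two fitting routes are provided: independent per-q fits followed by a γ(q)
regression, and a global ("jump-diffusion") fit sharing D, D_int, τ across
all q.  Both use weighted trust-region least squares on the width parameters
with the amplitudes eliminated exactly by non-negative linear least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from . import constants as C
from .estimates import DiffusionEstimate

__all__ = [
    "QENSSpectrum",
    "PerQFit",
    "GlobalFit",
    "SolventPolicy",
    "lorentzian",
    "fick_width",
    "jump_width",
    "model_spectrum",
    "fit_per_q",
    "extract_D_from_gamma",
    "fit_global",
    "fit_metrics",
]

HBAR = C.HBAR_UEV_NS

#: Finest ω spacing (in units of the resolution FWHM) at which the discrete
#: resolution convolution is still considered resolvable.
MIN_POINTS_PER_FWHM = 4.0


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class QENSSpectrum:
    """Reduced QENS intensities on a rectangular (q, ω) grid.

    ``intensity`` and ``sigma`` have shape (n_q, n_omega); ``resolution_fwhm``
    is the Gaussian resolution FWHM in μeV (scalar or per-q).
    """

    q_values: np.ndarray
    omega_values: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    resolution_fwhm: float | np.ndarray = 0.9

    def __post_init__(self) -> None:
        self.q_values = np.atleast_1d(np.asarray(self.q_values, dtype=float))
        self.omega_values = np.asarray(self.omega_values, dtype=float)
        self.intensity = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if self.intensity.shape != (self.q_values.size, self.omega_values.size):
            raise ValueError("intensity grid does not match q/omega axes")
        if self.sigma.shape != self.intensity.shape:
            raise ValueError("sigma grid does not match intensity grid")
        if np.any(np.diff(self.q_values) <= 0):
            raise ValueError("q_values must be strictly increasing")
        finite = np.isfinite(self.intensity)
        if np.any(self.sigma[finite] <= 0):
            raise ValueError("sigma must be positive wherever intensity is finite")

    def resolution_at(self, iq: int) -> float:
        if np.isscalar(self.resolution_fwhm):
            return float(self.resolution_fwhm)
        return float(np.asarray(self.resolution_fwhm)[iq])


@dataclass
class PerQFit:
    """Per-q fit parameters, uncertainties, and metrics."""

    q_values: np.ndarray
    beta: np.ndarray
    A0: np.ndarray
    gamma: np.ndarray
    Gamma_int: np.ndarray
    solvent_amplitude: np.ndarray
    solvent_width: np.ndarray
    gamma_err: np.ndarray
    Gamma_int_err: np.ndarray
    A0_err: np.ndarray
    gof: np.ndarray
    l1: np.ndarray
    l2: np.ndarray
    flags: list[set[str]]

    @property
    def valid(self) -> np.ndarray:
        return np.array(["failed" not in f for f in self.flags])


@dataclass
class GlobalFit:
    """Result of the simultaneous jump-diffusion fit over all q."""

    D: float
    D_int: float
    tau: float
    D_err: float
    D_int_err: float
    tau_err: float
    A0_q: np.ndarray
    beta_q: np.ndarray
    solvent_amplitude_q: np.ndarray
    solvent_width_q: np.ndarray
    covariance: np.ndarray
    gof: float
    l1: float
    l2: float
    success: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.success and (self.D <= 0 or self.D_int <= 0 or self.tau <= 0):
            raise ValueError("shared fit parameters must be positive")


@dataclass(frozen=True)
class SolventPolicy:
    """How the solvent Lorentzian is handled in fits.

    mode 'fixed-q2' (default): width fixed at ħ·D_solvent·q² with a free
    amplitude; 'fixed': width fixed at ``width`` μeV for all q; 'free': width
    fitted per q.
    """

    mode: str = "fixed-q2"
    D_solvent: float = 187.0  # Å²/ns, heavy-water self-diffusion near 298 K
    width: float = 50.0  # μeV, used by mode='fixed'

    def fixed_width(self, q: float) -> float | None:
        if self.mode == "fixed-q2":
            return HBAR * self.D_solvent * q * q
        if self.mode == "fixed":
            return self.width
        if self.mode == "free":
            return None
        raise ValueError(f"unknown solvent policy mode {self.mode!r}")


# ---------------------------------------------------------------------------
# Model building blocks
# ---------------------------------------------------------------------------

def lorentzian(x: np.ndarray | float, hwhm: float) -> np.ndarray | float:
    """Unit-area Lorentzian density (1/μeV) of half-width ``hwhm``."""
    if hwhm <= 0:
        raise ValueError("hwhm must be positive")
    return hwhm / (math.pi * (np.asarray(x) ** 2 + hwhm * hwhm))


def fick_width(D: float, q: float) -> float:
    """Fickian COM line width γ = ħDq² (μeV)."""
    if D < 0:
        raise ValueError("D must be non-negative")
    return HBAR * D * q * q


def jump_width(D_int: float, tau: float, q: float) -> float:
    """Jump-diffusion internal width Γ = ħD_int q²/(1 + D_int q² τ) (μeV);
    plateaus at ħ/τ for large q."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if D_int < 0:
        raise ValueError("D_int must be non-negative")
    x = D_int * q * q
    return HBAR * x / (1.0 + x * tau)


def _check_uniform_grid(omega: np.ndarray) -> float:
    steps = np.diff(omega)
    if steps.size == 0 or not np.allclose(steps, steps[0], rtol=1e-8):
        raise ValueError("omega grid must be uniform for the resolution convolution")
    return float(steps[0])


def _resolution_kernel(domega: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    half = int(math.ceil(8.0 * sigma / domega))
    x = np.arange(-half, half + 1) * domega
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def convolve_resolution(model: np.ndarray, omega: np.ndarray, fwhm: float) -> np.ndarray:
    """Convolve a model evaluated on a uniform ω grid with the Gaussian
    resolution.  ``fwhm = 0`` means a delta-function resolution (no-op)."""
    if fwhm == 0:
        return model
    domega = _check_uniform_grid(omega)
    if domega > fwhm / MIN_POINTS_PER_FWHM:
        raise ValueError(
            f"omega spacing {domega:.3g} μeV too coarse for resolution FWHM "
            f"{fwhm:.3g} μeV (need ≥ {MIN_POINTS_PER_FWHM:g} points per FWHM)"
        )
    kernel = _resolution_kernel(domega, fwhm)
    if model.ndim == 1:
        return signal.fftconvolve(model, kernel, mode="same")
    return signal.fftconvolve(model, kernel[None, :], mode="same", axes=-1)


def _padded_omega(omega: np.ndarray, fwhm: float) -> tuple[np.ndarray, slice]:
    """Extend the ω grid on both sides so the Gaussian kernel does not see the
    window edge; returns the extended grid and the crop slice."""
    domega = _check_uniform_grid(omega)
    if fwhm == 0:
        return omega, slice(0, omega.size)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    n_pad = int(math.ceil(8.0 * sigma / domega))
    left = omega[0] - domega * np.arange(n_pad, 0, -1)
    right = omega[-1] + domega * np.arange(1, n_pad + 1)
    return np.concatenate([left, omega, right]), slice(n_pad, n_pad + omega.size)


def _basis(omega: np.ndarray, fwhm: float, widths: list[float]) -> np.ndarray:
    """Resolution-convolved unit-area Lorentzians of the given HWHMs,
    evaluated on ``omega`` (columns)."""
    ext, crop = _padded_omega(omega, fwhm)
    cols = np.stack([lorentzian(ext, w) for w in widths], axis=0)
    conv = convolve_resolution(cols, ext, fwhm)
    return conv[:, crop].T


def model_spectrum(omega: np.ndarray, resolution_fwhm: float, *,
                   beta: float, A0: float, gamma: float, Gamma_int: float,
                   solvent_amplitude: float = 0.0,
                   solvent_width: float = 50.0) -> np.ndarray:
    """Evaluate the full single-q model on the ω grid (μeV⁻¹ units).

    The internal line carries width γ + Γ (internal motion superimposed on
    center-of-mass diffusion).
    """
    if gamma <= 0 or Gamma_int < 0:
        raise ValueError("widths must be positive")
    if not (0.0 <= A0 <= 1.0):
        raise ValueError("A0 must lie in [0, 1]")
    widths = [gamma, gamma + Gamma_int]
    amps = [beta * A0, beta * (1.0 - A0)]
    if solvent_amplitude != 0.0:
        widths.append(solvent_width)
        amps.append(solvent_amplitude)
    B = _basis(np.asarray(omega, dtype=float), resolution_fwhm, widths)
    return B @ np.asarray(amps)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def fit_metrics(y_exp: np.ndarray, y_fit: np.ndarray, sigma: np.ndarray,
                n_params: int) -> tuple[float, float, float]:
    """Reduced χ² goodness-of-fit, mean absolute deviation (L1), and mean
    squared deviation (L2)."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_fit = np.asarray(y_fit, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if y_exp.shape != y_fit.shape or y_exp.shape != sigma.shape:
        raise ValueError("inputs must have equal shapes")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    n = y_exp.size
    if n <= n_params:
        raise ValueError("goodness-of-fit undefined: #points <= #parameters")
    resid = y_exp - y_fit
    gof = float(np.sum((resid / sigma) ** 2) / (n - n_params))
    return gof, float(np.mean(np.abs(resid))), float(np.mean(resid**2))


# ---------------------------------------------------------------------------
# Weighted NNLS amplitude elimination
# ---------------------------------------------------------------------------

def _solve_amplitudes(B: np.ndarray, y: np.ndarray, w: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative weighted least squares; returns (amplitudes, residuals)."""
    Bw = B * w[:, None]
    yw = y * w
    amps, _ = optimize.nnls(Bw, yw)
    return amps, Bw @ amps - yw


def _jitter_factors(n_starts: int, n_params: int, seed: int) -> np.ndarray:
    """Multiplicative jitter for multi-start optimization; first start is
    unjittered."""
    rng = np.random.default_rng(seed)
    f = np.exp(rng.normal(0.0, 0.6, size=(n_starts, n_params)))
    f[0] = 1.0
    return f


# ---------------------------------------------------------------------------
# Per-q fit
# ---------------------------------------------------------------------------

def _halfwidth_guess(omega: np.ndarray, y: np.ndarray) -> float:
    """Crude HWHM estimate of a peaked curve from its half-maximum crossing."""
    ymax = float(np.max(y))
    above = omega[y >= 0.5 * ymax]
    if above.size < 2:
        return max(0.5, float(omega[-1] - omega[0]) / 10.0)
    return max(0.25 * float(above[-1] - above[0]), 0.05)


def fit_per_q(spectrum: QENSSpectrum,
              solvent_policy: SolventPolicy = SolventPolicy(),
              n_starts: int = 5, seed: int = 0) -> PerQFit:
    """Fit the single-q model independently at every q (weights 1/σ²).

    Non-convergence or degeneracy at one q flags that slice only.  The
    internal width is flagged unidentifiable when the internal line carries
    less than 0.1% of the protein amplitude (e.g. a pure-elastic spectrum with
    A₀ = 1).
    """
    omega = spectrum.omega_values
    if omega.size < 8:
        raise ValueError("need at least 8 omega points per q")
    nq = spectrum.q_values.size
    out = {k: np.full(nq, np.nan) for k in
           ("beta", "A0", "gamma", "Gamma_int", "s_amp", "s_width",
            "gamma_err", "Gamma_err", "A0_err", "gof", "l1", "l2")}
    flags: list[set[str]] = [set() for _ in range(nq)]

    for iq, q in enumerate(spectrum.q_values):
        y = spectrum.intensity[iq]
        sig = spectrum.sigma[iq]
        w = 1.0 / sig
        fwhm = spectrum.resolution_at(iq)
        fixed_sw = solvent_policy.fixed_width(q)
        free_sw = fixed_sw is None
        g0 = max(_halfwidth_guess(omega, y), 0.05)
        lb_len = 3 if free_sw else 2
        lb = [1e-4] * lb_len
        ub = [20.0 * float(omega[-1])] * lb_len

        def resid(p: np.ndarray) -> np.ndarray:
            widths = [p[0], p[0] + p[1], p[2] if free_sw else fixed_sw]
            B = _basis(omega, fwhm, widths)
            return _solve_amplitudes(B, y, w)[1]

        # One deterministic start per internal-width scale: the varpro cost
        # surface has flat basins where the two protein columns degenerate
        # (Γ → 0) or an amplitude hits the NNLS boundary, so starts must span
        # well-separated Γ values rather than cluster around one guess.
        starts: list[np.ndarray] = []
        for fG in (0.3, 1.0, 3.0, 8.0):
            cands = [[fg * g0, fG * g0] + ([50.0] if free_sw else [])
                     for fg in (0.5, 1.0, 2.0)]
            costs = [float(resid(np.asarray(cd)) @ resid(np.asarray(cd)))
                     for cd in cands]
            starts.append(np.asarray(cands[int(np.argmin(costs))]))
        jitters = _jitter_factors(max(n_starts, 1), starts[0].size,
                                  seed + 1000 * iq)
        start_list = [np.clip(s, lb, ub) for s in starts]
        start_list += [np.clip(starts[0] * f, lb, ub)
                       for f in jitters[1:max(n_starts - len(starts), 0) + 1]]

        best = None
        for x0 in start_list:
            try:
                res = optimize.least_squares(
                    resid, x0, bounds=(lb, ub), method="trf")
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            flags[iq].add("failed")
            continue

        p = best.x
        widths = [p[0], p[0] + p[1], p[2] if free_sw else fixed_sw]
        B = _basis(omega, fwhm, widths)
        amps, _ = _solve_amplitudes(B, y, w)
        beta = amps[0] + amps[1]
        a0 = amps[0] / beta if beta > 0 else np.nan
        if beta <= 0:
            flags[iq].add("failed")
            continue
        if min(amps[0], amps[1]) / beta < 1e-3:
            # one protein line carries no weight: the (γ, Γ) split is not
            # determined by the data (e.g. a purely elastic protein term)
            flags[iq].add("internal_unidentifiable")

        n_lin = 3
        n_nl = len(p)
        yfit = B @ amps
        gof, l1, l2 = fit_metrics(y, yfit, sig, n_lin + n_nl)
        cov = _covariance(omega, fwhm, widths, amps, w,
                          nonlinear_cols=_perq_nl_cols(omega, fwhm, p, amps, free_sw,
                                                       fixed_sw))
        # parameter order in cov: [gamma, Gamma, (sw)], then amplitudes
        g_err = math.sqrt(max(cov[0, 0], 0.0)) if cov is not None else np.nan
        G_err = math.sqrt(max(cov[1, 1], 0.0)) if cov is not None else np.nan
        a0_err = _a0_error(cov, amps, n_nl) if cov is not None else np.nan

        out["beta"][iq] = beta
        out["A0"][iq] = min(max(a0, 0.0), 1.0)
        out["gamma"][iq] = p[0]
        out["Gamma_int"][iq] = p[1]
        out["s_amp"][iq] = amps[2]
        out["s_width"][iq] = widths[2]
        out["gamma_err"][iq] = g_err
        out["Gamma_err"][iq] = G_err
        out["A0_err"][iq] = a0_err
        out["gof"][iq], out["l1"][iq], out["l2"][iq] = gof, l1, l2

    return PerQFit(
        q_values=spectrum.q_values, beta=out["beta"], A0=out["A0"],
        gamma=out["gamma"], Gamma_int=out["Gamma_int"],
        solvent_amplitude=out["s_amp"], solvent_width=out["s_width"],
        gamma_err=out["gamma_err"], Gamma_int_err=out["Gamma_err"],
        A0_err=out["A0_err"], gof=out["gof"], l1=out["l1"], l2=out["l2"],
        flags=flags,
    )


def _perq_nl_cols(omega, fwhm, p, amps, free_sw, fixed_sw):
    """Finite-difference model derivatives w.r.t. the nonlinear widths."""

    def model_of(pv):
        widths = [pv[0], pv[0] + pv[1], pv[2] if free_sw else fixed_sw]
        return _basis(omega, fwhm, widths) @ amps

    return _fd_jacobian(model_of, np.asarray(p, dtype=float))


def _fd_jacobian(fun, p: np.ndarray, rel: float = 1e-5) -> np.ndarray:
    f0 = fun(p)
    cols = []
    for i in range(p.size):
        h = rel * max(abs(p[i]), 1e-3)
        pp = p.copy()
        pp[i] += h
        cols.append((fun(pp) - f0) / h)
    return np.stack(cols, axis=1)


def _covariance(omega, fwhm, widths, amps, w, nonlinear_cols) -> np.ndarray | None:
    B = _basis(omega, fwhm, widths)
    J = np.concatenate([nonlinear_cols, B], axis=1) * w[:, None]
    JtJ = J.T @ J
    try:
        return np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        try:
            return np.linalg.pinv(JtJ)
        except np.linalg.LinAlgError:
            return None


def _a0_error(cov: np.ndarray, amps: np.ndarray, n_nl: int) -> float:
    """Delta-method uncertainty of A0 = a1/(a1+a2)."""
    a1, a2 = amps[0], amps[1]
    s = a1 + a2
    if s <= 0:
        return np.nan
    g = np.zeros(cov.shape[0])
    g[n_nl] = a2 / s**2
    g[n_nl + 1] = -a1 / s**2
    return float(math.sqrt(max(g @ cov @ g, 0.0)))


# ---------------------------------------------------------------------------
# γ(q) → D
# ---------------------------------------------------------------------------

def extract_D_from_gamma(q_values: np.ndarray, gamma: np.ndarray,
                         gamma_err: np.ndarray | None = None,
                         valid: np.ndarray | None = None) -> DiffusionEstimate:
    """Weighted through-origin regression of γ(q) against ħq²; the slope is
    the apparent diffusion coefficient in Å²/ns."""
    q_values = np.asarray(q_values, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if gamma_err is None:
        gamma_err = np.ones_like(gamma)
    gamma_err = np.asarray(gamma_err, dtype=float)
    mask = np.isfinite(gamma) & np.isfinite(gamma_err) & (gamma_err >= 0)
    if valid is not None:
        mask &= np.asarray(valid, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("no valid (q, gamma) points")
    x = HBAR * q_values[mask] ** 2
    y = gamma[mask]
    err = np.where(gamma_err[mask] > 0, gamma_err[mask], 1.0)
    wgt = 1.0 / err**2
    sxx = float(np.sum(wgt * x * x))
    slope = float(np.sum(wgt * x * y)) / sxx
    return DiffusionEstimate(
        value=slope, uncertainty=math.sqrt(1.0 / sxx), method="per-q",
    )


# ---------------------------------------------------------------------------
# Global jump-diffusion fit
# ---------------------------------------------------------------------------

def fit_global(spectrum: QENSSpectrum,
               solvent_policy: SolventPolicy = SolventPolicy(),
               n_starts: int = 5, seed: int = 0) -> GlobalFit:
    """Simultaneous weighted fit over the full (q, ω) grid with shared
    D, D_int, τ and per-q amplitudes (Fickian COM width + jump-diffusion
    internal width imposed)."""
    nq = spectrum.q_values.size
    if nq < 4:
        raise ValueError("global fit requires at least 4 q slices")
    omega = spectrum.omega_values
    qs = spectrum.q_values
    Y = spectrum.intensity
    W = 1.0 / spectrum.sigma
    fixed_sw = [solvent_policy.fixed_width(q) for q in qs]
    free_sw = fixed_sw[0] is None

    # seed the shared parameters from crude per-q half-widths
    g_est = np.array([_halfwidth_guess(omega, Y[i]) for i in range(nq)])
    D0 = float(np.median(g_est / (HBAR * qs**2)))
    D0 = min(max(D0, 0.1), 1e3)
    x0 = [D0, 1.5 * D0, 0.02] + ([50.0] * nq if free_sw else [])
    lb = [1e-3, 1e-3, 1e-5] + ([1e-2] * nq if free_sw else [])
    ub = [1e4, 1e4, 10.0] + ([2e4] * nq if free_sw else [])

    def q_widths(p: np.ndarray, iq: int) -> list[float]:
        D, Di, tau = p[0], p[1], p[2]
        g = fick_width(D, qs[iq])
        G = jump_width(Di, tau, qs[iq])
        sw = p[3 + iq] if free_sw else fixed_sw[iq]
        return [g, g + G, sw]

    def residuals_and_amps(p: np.ndarray):
        res = []
        amps_all = np.empty((nq, 3))
        for iq in range(nq):
            B = _basis(omega, spectrum.resolution_at(iq), q_widths(p, iq))
            amps, r = _solve_amplitudes(B, Y[iq], W[iq])
            amps_all[iq] = amps
            res.append(r)
        return np.concatenate(res), amps_all

    def resid(p: np.ndarray) -> np.ndarray:
        return residuals_and_amps(p)[0]

    best = None
    for fac in _jitter_factors(n_starts, len(x0), seed):
        try:
            res = optimize.least_squares(
                resid, np.clip(np.asarray(x0) * fac, lb, ub),
                bounds=(lb, ub), method="trf", x_scale="jac")
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return GlobalFit(
            D=np.nan, D_int=np.nan, tau=np.nan, D_err=np.nan, D_int_err=np.nan,
            tau_err=np.nan, A0_q=np.full(nq, np.nan), beta_q=np.full(nq, np.nan),
            solvent_amplitude_q=np.full(nq, np.nan),
            solvent_width_q=np.full(nq, np.nan), covariance=np.empty((0, 0)),
            gof=np.nan, l1=np.nan, l2=np.nan, success=False,
            message="optimizer did not converge from any start",
        )

    p = best.x
    _, amps_all = residuals_and_amps(p)
    beta_q = amps_all[:, 0] + amps_all[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        A0_q = np.where(beta_q > 0, amps_all[:, 0] / beta_q, np.nan)
    A0_q = np.clip(A0_q, 0.0, 1.0)
    sw_q = np.array([q_widths(p, iq)[2] for iq in range(nq)])

    # metrics over the full grid
    yfit = np.vstack([
        _basis(omega, spectrum.resolution_at(iq), q_widths(p, iq)) @ amps_all[iq]
        for iq in range(nq)
    ])
    n_params = len(p) + 3 * nq
    gof, l1, l2 = fit_metrics(Y.ravel(), yfit.ravel(),
                              spectrum.sigma.ravel(), n_params)

    cov = _global_covariance(spectrum, p, amps_all, q_widths)
    nshared = len(p)
    errs = [math.sqrt(max(cov[i, i], 0.0)) for i in range(3)] if cov is not None \
        else [np.nan] * 3

    return GlobalFit(
        D=float(p[0]), D_int=float(p[1]), tau=float(p[2]),
        D_err=errs[0], D_int_err=errs[1], tau_err=errs[2],
        A0_q=A0_q, beta_q=beta_q, solvent_amplitude_q=amps_all[:, 2],
        solvent_width_q=sw_q,
        covariance=cov[:nshared, :nshared] if cov is not None else np.empty((0, 0)),
        gof=gof, l1=l1, l2=l2, success=True, message=best.message,
    )


def _global_covariance(spectrum, p, amps_all, q_widths) -> np.ndarray | None:
    """Covariance from the full Jacobian (shared params + all amplitudes)."""
    omega = spectrum.omega_values
    nq = spectrum.q_values.size
    nw = omega.size
    nsh = len(p)

    def stacked_model(pv):
        return np.concatenate([
            _basis(omega, spectrum.resolution_at(iq), q_widths(pv, iq)) @ amps_all[iq]
            for iq in range(nq)
        ])

    J_shared = _fd_jacobian(stacked_model, np.asarray(p, dtype=float))
    w = (1.0 / spectrum.sigma).ravel()
    cols = [J_shared * w[:, None]]
    amp_cols = np.zeros((nq * nw, 3 * nq))
    for iq in range(nq):
        B = _basis(omega, spectrum.resolution_at(iq), q_widths(p, iq))
        amp_cols[iq * nw:(iq + 1) * nw, 3 * iq:3 * iq + 3] = \
            B * w[iq * nw:(iq + 1) * nw, None]
    cols.append(amp_cols)
    J = np.concatenate(cols, axis=1)
    JtJ = J.T @ J
    try:
        return np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(JtJ)
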