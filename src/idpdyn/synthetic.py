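"""Synthetic-data generators with known ground truth.

Every downstream stage of the package — QENS fitting, diffusion and EISF
analysis, viscosity estimation — can be exercised on data produced here,
where the true parameters are known exactly.  Generators are pure functions
of their truth records (including the seed): identical inputs give bitwise
identical outputs.

Seed scheme: a single global integer seed is expanded into independent
per-stream generators with ``numpy.random.SeedSequence(seed, spawn_key=(k,))``
where k is the documented stream index of each generator (spectrum 0,
Brownian chains 1, confined hydrogens 2, pressure series 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import spherical_jn

from . import constants as C
from .qens import QENSSpectrum, _basis
from .trajectory import ChainEnsembleTrajectory

__all__ = [
    "SpectrumTruth",
    "BrownianSystemTruth",
    "PressureSeriesTruth",
    "PressureSeries",
    "sphere_eisf",
    "generate_spectrum",
    "generate_brownian_chains",
    "generate_confined_hydrogens",
    "generate_pressure_series",
]

_STREAMS = {"spectrum": 0, "brownian": 1, "confined": 2, "pressure": 3}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Per-stream generator derived from the single global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def default_q_grid() -> np.ndarray:
    """Instrument-like momentum-transfer grid: 0.2–1.8 Å⁻¹ in 16 steps."""
    return np.linspace(0.2, 1.8, 16)


def default_omega_grid() -> np.ndarray:
    """Energy-transfer grid ±30 μeV at 0.2 μeV spacing — fine enough to
    resolve the 0.9 μeV FWHM resolution with >4 points per FWHM."""
    return np.arange(-30.0, 30.0 + 1e-9, 0.2)


def sphere_eisf(q: np.ndarray, a: float) -> np.ndarray:
    """Closed-form EISF of diffusion confined to a sphere of radius a:
    [3·j₁(qa)/(qa)]²."""
    x = np.asarray(q, dtype=float) * a
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = (3.0 * spherical_jn(1, x[nz]) / x[nz]) ** 2
    return out


# ---------------------------------------------------------------------------
# QENS spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumTruth:
    """Ground truth of a synthetic QENS spectrum.

    The noiseless model at each q is
    β(q)·[A₀(q)L(γ) + (1−A₀(q))L(γ+Γ)] + β_s(q)·L(γ_s) convolved with a
    Gaussian resolution, with γ = ħ·D_apparent·q² and Γ the jump-diffusion
    width from (D_int, τ).  A₀(q) follows the named EISF shape.

    Amplitudes are in detector-count-like units: the default β = 100 puts the
    elastic peak at O(10²–10³) so the counting-statistics noise model
    σ = noise_scale·√I gives percent-level relative errors at the strongest
    channels, as on a well-measured backscattering spectrum.
    """

    D_apparent: float = 16.8          # Å²/ns (measured value at 50 mg/mL, 298 K)
    D_int: float = 30.0               # Å²/ns
    tau: float = 0.02                 # ns
    eisf_model: str = "sphere"        # "sphere" (radius a) or "constant"
    eisf_radius: float = 1.2          # Å, confinement radius of the sphere EISF
    eisf_constant: float = 0.7        # used when eisf_model == "constant"
    beta_q: float | np.ndarray = 100.0
    solvent_amplitude: float | np.ndarray = 5.0
    solvent_width: float = 50.0       # μeV
    resolution_fwhm: float = 0.9      # μeV
    q_grid: np.ndarray = field(default_factory=default_q_grid)
    omega_grid: np.ndarray = field(default_factory=default_omega_grid)
    noise_scale: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.omega_grid = np.asarray(self.omega_grid, dtype=float)
        for name in ("D_apparent", "D_int", "tau", "resolution_fwhm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.solvent_width <= 0:
            raise ValueError("solvent_width must be strictly positive")
        if np.any(np.diff(self.q_grid) <= 0) or self.q_grid[0] < 0.05 \
                or self.q_grid[-1] > 3.0:
            raise ValueError("q_grid must be strictly increasing within [0.05, 3.0]")
        if not np.allclose(self.omega_grid, -self.omega_grid[::-1], atol=1e-9):
            raise ValueError("omega_grid must be symmetric about 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")

    def A0(self) -> np.ndarray:
        if self.eisf_model == "sphere":
            return sphere_eisf(self.q_grid, self.eisf_radius)
        if self.eisf_model == "constant":
            return np.full(self.q_grid.size, float(self.eisf_constant))
        raise ValueError(f"unknown eisf_model {self.eisf_model!r}")

    def noiseless_model(self) -> np.ndarray:
        """The resolution-convolved model on the (q, ω) grid."""
        from .qens import fick_width, jump_width

        beta = np.broadcast_to(np.asarray(self.beta_q, dtype=float), self.q_grid.shape)
        s_amp = np.broadcast_to(
            np.asarray(self.solvent_amplitude, dtype=float), self.q_grid.shape)
        a0 = self.A0()
        out = np.empty((self.q_grid.size, self.omega_grid.size))
        for i, q in enumerate(self.q_grid):
            g = fick_width(self.D_apparent, q)
            G = jump_width(self.D_int, self.tau, q)
            B = _basis(self.omega_grid, self.resolution_fwhm,
                       [g, g + G, self.solvent_width])
            out[i] = B @ np.array([beta[i] * a0[i], beta[i] * (1 - a0[i]), s_amp[i]])
        return out


def generate_spectrum(truth: SpectrumTruth) -> QENSSpectrum:
    """Forward-model a QENS spectrum and add counting-statistics-like noise.

    The noise is Gaussian with standard deviation noise_scale·√(model), added
    pointwise; the reported uncertainties equal that standard deviation.
    Refuses ω grids coarser than resolution_fwhm/4.
    """
    domega = float(np.diff(truth.omega_grid)[0])
    if domega > truth.resolution_fwhm / 4.0:
        raise ValueError(
            "omega grid coarser than resolution_fwhm/4: convolution unresolvable")
    model = truth.noiseless_model()
    sigma = truth.noise_scale * np.sqrt(np.maximum(model, 0.0))
    if truth.noise_scale > 0:
        rng = stream_rng(truth.seed, "spectrum")
        intensity = model + rng.normal(0.0, 1.0, size=model.shape) * sigma
        sigma_rep = np.where(sigma > 0, sigma, np.min(sigma[sigma > 0]))
    else:
        intensity = model
        sigma_rep = np.full_like(model, 1e-6)
    return QENSSpectrum(
        q_values=truth.q_grid, omega_values=truth.omega_grid,
        intensity=intensity, sigma=sigma_rep,
        resolution_fwhm=truth.resolution_fwhm)


# ---------------------------------------------------------------------------
# Brownian chain ensembles
# ---------------------------------------------------------------------------

@dataclass
class BrownianSystemTruth:
    """Ground truth for independent Brownian chain centers of mass in a
    periodic cubic box: per-step displacement variance 2·D_t·dt per Cartesian
    component."""

    n_chains: int = 10
    D_t: float = 15.0     # Å²/ns
    box_edge: float = 100.0  # Å
    dt: float = 0.1       # ns
    n_steps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_edge <= 0 or self.dt <= 0:
            raise ValueError("box_edge and dt must be positive")
        if self.D_t < 0 or self.n_chains < 1:
            raise ValueError("invalid truth parameters")


def generate_brownian_chains(truth: BrownianSystemTruth) -> ChainEnsembleTrajectory:
    """Isotropic Gaussian random walks for each chain COM, wrapped into the
    periodic box.  One particle of unit mass represents each chain."""
    if truth.n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    rng = stream_rng(truth.seed, "brownian")
    std = math.sqrt(2.0 * truth.D_t * truth.dt)
    start = rng.uniform(0.0, truth.box_edge, size=(1, truth.n_chains, 3))
    steps = rng.normal(0.0, std, size=(truth.n_steps - 1, truth.n_chains, 3)) \
        if std > 0 else np.zeros((truth.n_steps - 1, truth.n_chains, 3))
    paths = np.concatenate([start, start + np.cumsum(steps, axis=0)], axis=0)
    box = np.full(3, truth.box_edge)
    return ChainEnsembleTrajectory(
        times=np.arange(truth.n_steps) * truth.dt,
        coords=np.mod(paths, box),
        box=box,
        chain_ids=np.arange(truth.n_chains),
        masses=np.ones(truth.n_chains),
    )


# ---------------------------------------------------------------------------
# Sphere-confined internal motion
# ---------------------------------------------------------------------------

def generate_confined_hydrogens(n_atoms: int, a: float, D_loc: float, dt: float,
                                n_steps: int, seed: int = 0,
                                ) -> ChainEnsembleTrajectory:
    """Reflected Brownian motion of ``n_atoms`` hydrogens, each inside its own
    fixed sphere of radius ``a`` (Å), local diffusivity ``D_loc`` (Å²/ns).

    The equilibrium distribution is uniform over the sphere volume and the
    trajectory's EISF approaches [3j₁(qa)/(qa)]².  Sphere centers sit on a
    wide lattice so chains (one atom each) never interact.  Refuses steps
    larger than a/5, where the radial reflection scheme breaks down.
    """
    if a <= 0 or D_loc < 0:
        raise ValueError("a must be positive and D_loc non-negative")
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    std = math.sqrt(2.0 * D_loc * dt)
    if std > a / 5.0:
        raise ValueError(
            f"rms step {std:.3g} Å exceeds a/5 = {a / 5:.3g} Å: reduce D_loc·dt")
    rng = stream_rng(seed, "confined")
    # start uniformly inside the sphere
    pos = rng.normal(size=(n_atoms, 3))
    pos *= (a * rng.uniform(size=(n_atoms, 1)) ** (1 / 3)
            / np.linalg.norm(pos, axis=1, keepdims=True))
    frames = np.empty((n_steps, n_atoms, 3))
    frames[0] = pos
    for t in range(1, n_steps):
        pos = pos + rng.normal(0.0, std, size=(n_atoms, 3)) if std > 0 else pos
        r = np.linalg.norm(pos, axis=1, keepdims=True)
        outside = (r > a).ravel()
        if outside.any():
            # radial reflection about the spherical boundary
            pos[outside] *= (2.0 * a - r[outside]) / r[outside]
        frames[t] = pos
    # offset each atom's sphere center so atoms are spatially distinct chains
    spacing = 10.0 * a
    centers = (np.arange(n_atoms)[:, None] * np.array([spacing, 0.0, 0.0])
               + 0.5 * spacing)
    coords = frames + centers[None, :, :]
    box_edge = spacing * (n_atoms + 1)
    return ChainEnsembleTrajectory(
        times=np.arange(n_steps) * dt,
        coords=coords,
        box=np.full(3, box_edge),
        chain_ids=np.arange(n_atoms),
        masses=np.ones(n_atoms),
        elements=np.array(["H"] * n_atoms),
    )


# ---------------------------------------------------------------------------
# Pressure-tensor series (Ornstein–Uhlenbeck)
# ---------------------------------------------------------------------------

@dataclass
class PressureSeriesTruth:
    """Ground truth of a stationary Gaussian (Ornstein–Uhlenbeck) off-diagonal
    pressure series whose analytic Green–Kubo viscosity equals eta_target:
    η = V·σ²·τ_c/(k_B T) with σ² the process variance."""

    eta_target: float = 0.85      # mPa·s
    correlation_time: float = 1.0  # ps
    volume: float = 100.0          # nm³
    temperature: float = 300.0     # K
    dt: float = 0.2                # ps
    n_steps: int = 1_000_000
    n_components: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.eta_target, self.correlation_time, self.volume,
               self.temperature, self.dt) < 0:
            raise ValueError("all truth fields must be non-negative")

    @property
    def sigma_bar(self) -> float:
        """Process standard deviation in bar implied by the target viscosity."""
        kT = C.KB_J_PER_K * self.temperature
        var_si = self.eta_target * C.MPAS_TO_PAS * kT / (
            self.volume * 1e-27 * self.correlation_time * 1e-12)  # Pa²
        return math.sqrt(var_si) / 1e5


@dataclass
class PressureSeries:
    """Time-stamped off-diagonal pressure samples (bar) with metadata."""

    times: np.ndarray       # ps
    components: np.ndarray  # (n_steps, n_components), bar
    volume: float           # nm³
    temperature: float      # K

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def generate_pressure_series(truth: PressureSeriesTruth) -> PressureSeries:
    """Exact-discretization Ornstein–Uhlenbeck sampling of the off-diagonal
    pressure components.  Refuses dt ≥ correlation_time (undersampled)."""
    if truth.dt >= truth.correlation_time:
        raise ValueError("dt must be smaller than the correlation time")
    rng = stream_rng(truth.seed, "pressure")
    a = math.exp(-truth.dt / truth.correlation_time)
    sig = truth.sigma_bar
    innov_std = sig * math.sqrt(1.0 - a * a)
    from scipy.signal import lfilter

    comps = np.empty((truth.n_steps, truth.n_components))
    for k in range(truth.n_components):
        x0 = rng.normal(0.0, sig) if sig > 0 else 0.0
        noise = rng.normal(0.0, innov_std, size=truth.n_steps) \
            if innov_std > 0 else np.zeros(truth.n_steps)
        noise[0] = x0
        comps[:, k] = lfilter([1.0], [1.0, -a], noise)
    return PressureSeries(
        times=np.arange(truth.n_steps) * truth.dt,
        components=comps,
        volume=truth.volume,
        temperature=truth.temperature,
    )
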