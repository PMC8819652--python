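# Methods

`idpdyn` implements the analysis chain used to study the diffusion of a
small, self-crowded intrinsically disordered protein (the 24-residue,
3.036 kDa peptide Histatin 5) with quasi-elastic neutron scattering (QENS)
and molecular-dynamics-style trajectories.  This note records the models,
the default parameters and why they were chosen, what the synthetic data do
and do not emulate, and the numerical choices that matter.

## Scattering model and fits

The measured scattering function is modeled as

S(q, ω) = R(ω) ⊗ { β(q)·[A₀(q)·L(ω; γ) + (1 − A₀(q))·L(ω; γ + Γ)]
                    + β_s(q)·L(ω; γ_s) },

with L a unit-area Lorentzian parametrized by its half width at half
maximum, R a Gaussian resolution of 0.9 μeV FWHM (a backscattering
spectrometer near its Si(111) elastic line), γ = ħDq² the Fickian
center-of-mass (COM) width, and Γ = ħD_int q²/(1 + D_int q²τ) the
jump-diffusion internal width with residence time τ (high-q plateau ħ/τ).
A₀(q) is the elastic incoherent structure factor (EISF).  HWHM convention:
with γ = ħDq², the measured apparent D values are reproduced directly; an
FWHM convention would rescale all widths by 2.

Two fitting routes are provided, mirroring the two experimental analyses:

* **per-q** — every q slice fitted independently; D then comes from a
  weighted through-origin regression of γ(q) on ħq².
* **global ("jump-diffusion")** — one simultaneous fit of all slices with
  shared (D, D_int, τ) and free per-q amplitudes.

Both exploit the model's partial linearity: for fixed widths the spectrum
is linear in the three amplitudes (elastic, internal, solvent), which are
eliminated exactly by non-negative weighted least squares (variable
projection).  The remaining 2-dimensional (per-q) or 3-dimensional (global)
width space is minimized by bounded trust-region least squares from
multiple starts: deterministic starts spanning well-separated internal
widths (the variable-projection surface has flat basins where the two
protein columns degenerate or an amplitude sits on the non-negativity
boundary) plus seeded jittered starts; ties are broken by lowest cost.
Parameter covariances come from the full Jacobian (finite differences for
widths, the convolved basis itself for amplitudes); the A₀ uncertainty uses
the delta method on the amplitude ratio.  A₀ is an amplitude ratio of
non-negative quantities and therefore bounded to [0, 1] by construction.

**Solvent policy.**  The solvent width can be fixed from a known solvent
diffusion coefficient as ħD_solv q² (default, D_solv = 187 Å²/ns ≈ heavy
water near 298 K), fixed at a constant value, or fitted freely per q.  The
published analysis does not state its choice; the fixed-width default is
the conservative one for narrow energy windows.

**Fit metrics.**  Reduced χ² (gof), mean absolute deviation (L1) and mean
squared deviation (L2) are reported per fit; comparing L1 and L2 exposes
isolated badly-fit channels.

**Convolution.**  The resolution convolution is a discrete FFT convolution
on a uniform ω grid extended by 8 Gaussian σ on both sides, which is
spectrally accurate (the Fourier transform of the Lorentzian–Gaussian
product decays exponentially); it conserves integrated flux on the analysis
window to better than 1e-3 and matches the analytic Voigt profile to 1e-5
relative.  Grids coarser than FWHM/4 are refused.  The closed-form Voigt
profile is used only as a test oracle, never in the fit path.

**Identifiability.**  Two genuine degeneracies are surfaced rather than
hidden.  (i) If either protein line carries < 0.1% of the protein
amplitude, the (γ, Γ) split is undetermined and the slice is flagged
`internal_unidentifiable` (e.g. a purely elastic protein term).  (ii) When
the COM width exceeds the energy window (ħDq² > 30 μeV, i.e. q ≳ 1.3 Å⁻¹
at D ≈ 17 Å²/ns), the per-q amplitude decomposition becomes practically
unidentifiable at realistic counting noise: reduced χ² stays near 1 while
A₀ wanders.  This is physics, not an optimizer defect, and it is why the
global fit is the preferred route for D while per-q EISF extraction is
reliable only for slow diffusion (narrow elastic line).  The Monte-Carlo
EISF recovery test therefore runs at D = 2.5 Å²/ns, the measured
low-temperature apparent diffusion, where A₀ is identifiable.

## Hydrodynamics

* **Viscosity.**  Light water uses the Kestin-form correlation
  (log₁₀-ratio polynomial anchored at η(20 °C) = 1.0016 mPa·s, good to
  ~0.1% over 0–110 °C).  Heavy water is obtained by the thermal-offset
  construction from the isotope-viscosity literature:
  η_D2O(T) = √(M_D2O/M_H2O) · η_H2O(T − 6.498 K), which reproduces
  tabulated D₂O viscosities to well under 1% near ambient (1.0961 vs
  1.095–1.097 mPa·s at 298.15 K) and gives an H₂O/D₂O ratio of 0.811 at
  298 K.  Validity is restricted to 270–370 K.  Salt corrections use the
  Goldsack–Franchetto functional form η/η₀ = exp(E·X)/(1 + V·X) in the
  salt mole fraction X; the NaCl parameters (E = 4.72, V = 0) are
  calibrated against Jones–Dole/CRC relative viscosities at 25 °C
  (η_r ≈ 1.014 at 0.15 M), adequate for the ≤ 1 M range used here.
* **Stokes–Einstein / Einstein–Smoluchowski.**  R = k_BT/(6πηD) for the
  effective hydrodynamic radius of an apparent D (the "pseudo-hydrodynamic"
  radius, since the measured D mixes translation and rotation), and
  D_r = k_BT/(8πηR³) for rotational diffusion of a sphere.
* **IDP R_g ↔ R_h.**  The empirical disordered-chain relation
  R_g/R_h = α₁(R_g − α₂N^0.33)/(N^0.6 − N^0.33) + α₃ with α₁ = 0.216 Å⁻¹,
  α₂ = 4.06 Å, α₃ = 0.821; the inverse is solved by bracketed Brent
  iteration (unique on the physical branch).
* **Perrin friction.**  Spheroid translational friction uses the closed
  Perrin forms (prolate: R_eq = √(a²−b²)/ln((a+√(a²−b²))/b); oblate with
  arctan); rotational friction uses the general ellipsoid integrals
  χ, α_i evaluated by adaptive quadrature, with the closed forms acting as
  an independent cross-check in the tests.  The reported rotational D is
  the orientation average over the three principal axes.
* **Apparent diffusion from (D_t, D_r).**  The incoherent spectrum of a
  rigid rotor–translator with radial hydrogen density ρ_H(r) is the
  multipole sum Σ_l B_l(q)·L(ħ(D_t q² + l(l+1)D_r)) with
  B_l(q) = (2l+1)∫ρ_H(r) j_l²(qr) dr, truncated once the cumulative weight
  exceeds 1 − 1e-4 (error if not reached by l = 100).  The "apparent width"
  is defined operationally, as in the experimental analysis: the half-width
  of the best single-Lorentzian least-squares fit over the instrument
  window, regressed against ħq².  An amplitude-weighted mean of widths is
  *not* used; a brute-force fit oracle pins the choice.  Parametric
  profiles (uniform sphere, point) replace the external SAXS-derived P(r),
  which is not redistributable; conclusions that depend on the exact
  profile shape should be rechecked with a measured profile.
* **Volume fractions.**  φ = c·ν_p (concentration per solution volume,
  default; ν_p = 0.7023 mL/g) or φ = c·ν_p/(1 + c·ν_p); the hydrodynamic
  volume fraction is φ_h = (R_h/R_g)³φ, and the hydration-shell variant
  uses R_h = R_g + 5.5 Å.
* **Crowding scaling.**  Charged-sphere short-time laws
  D_t(φ)/D_t(0) = 1 − a_t φ^{4/3} (a_t = 2.5) and
  D_r(φ)/D_r(0) = 1 − a_r φ² (a_r = 1.3); exponents and prefactors are
  overridable.  Validity is limited to small φ (factor must stay positive)
  and, more fundamentally, to roughly spherical particles.
* **Fractal relation.**  D = C·M^{−1/d_F} with the family constant
  C = 10353 (Å²/ns·Da^{1/d_F}) calibrated on an α-synuclein QENS + SAXS
  pair; d_F comes from the −slope of log I vs log q over the 2.0–2.8 Å⁻¹
  SAXS window.  The prediction is extremely steep in d_F (a 0.05 change
  moves D by ~10 Å²/ns), so the slope window and buffer subtraction
  dominate its uncertainty.

## Trajectory analysis

* **Unwrapping** applies minimum-image continuity between consecutive
  frames and refuses inter-frame displacements ≥ L/2 (undersampled).
* **MSD** is time- and origin-averaged via the FFT identity (all origins);
  a naive double-loop implementation is kept in the tests as the oracle.
  Diffusion is the slope/6 of a straight line fitted on the 0–4.6 ns
  window — the coherence time implied by a 0.9 μeV FWHM resolution — with
  R² reported and values below 0.99 flagged non-linear.  Ensemble values
  average all chains and replicates; the spread across chains is the
  quoted uncertainty.
* **Finite-size correction** adds k_BTξ/(6πηL) (simple cubic
  ξ = 2.837297).  For trajectories run in a rhombic dodecahedron the FCC
  constant applies: from the FCC lattice drag coefficient,
  ξ_FCC = 1.7917·(4π/3)^{1/3} = 2.888207 per lattice point; the helper
  takes L as the edge of the enclosing cubic cell (4 lattice points) and
  rescales by 4^{1/3}.  The same construction applied to the simple-cubic
  coefficient reproduces the standard 2.8373, which fixes the convention.
  The effective-L definition is stated by the upstream analysis only in
  words; treat FCC-corrected values as sensitive to that reading.
* **Isotope rescaling** multiplies simulated (H₂O) coefficients by
  η_H2O(T)/η_D2O(T) (≈ 0.81 at 298 K).  Finite-size, isotope and crowding
  corrections are idempotent-guarded through provenance flags on
  `DiffusionEstimate`.
* **Viscosity** from off-diagonal pressure series uses the
  Einstein–Helfand relation: η = V/(2k_BT) × slope of ⟨(∫₀ᵗP dt′)²⟩,
  averaged over independent components.  The slope window defaults to
  0.05–0.5% of the series length — far above the pressure correlation
  time for any series long enough to satisfy the estimator's precondition,
  yet short enough that the Helfand displacement is well averaged (its
  variance grows with lag).  The window is in the estimator's signature
  and flagged in its docstring.
* **Clustering** builds the pairwise minimum Cα–Cα distance matrix under
  the minimum-image convention (all particles for synthetic point chains)
  and takes connected components of the ≤-cutoff graph at 6 and 7 Å;
  singletons are not clusters.  Reported statistics (cluster count, chains
  participating, largest cluster) are per-frame and summarized as time
  averages.
* **Size distributions.**  Per-frame mass-weighted R_g; per-snapshot D_t
  via the IDP relation plus Stokes–Einstein, reported as a mean-one
  ("reduced") distribution so that shape and size heterogeneity can be
  compared across methods.
* **EISF** is A₀(q) = ⟨|⟨exp(iq·r)⟩_t|²⟩ over incoherent scatterers
  (hydrogens when elements are present, all particles otherwise) and
  uniformly sampled directions (seeded, 64 by default).  COM removal is ON
  by default: the experimental A₀ rides on a separate COM Lorentzian, so
  the internal-motion EISF must not contain COM diffusion.  The estimator
  carries a positive O(τ_corr/T_traj) bias from the squared finite-time
  average; trajectories several hundred relaxation times long keep it
  below 0.01.

## Synthetic data: what it emulates, what it does not

The generators provide every input with known ground truth: instrument-like
spectra (q = 0.2–1.8 Å⁻¹ in 16 steps, ω = ±30 μeV at 0.2 μeV spacing,
0.9 μeV FWHM Gaussian resolution), Brownian chain COMs in a periodic box
(displacement variance 2D_t·dt per component), reflected Brownian motion in
spheres (closed-form EISF [3j₁(qa)/(qa)]² as oracle), and Ornstein–
Uhlenbeck pressure series whose Green–Kubo viscosity is analytic
(η = Vσ²τ_c/k_BT).  A single global seed expands into independent streams
via `SeedSequence(seed, spawn_key=(stream,))`; all generators are bitwise
reproducible.

Deliberate simplifications: spectrum noise is Gaussian with
σ = noise_scale·√I (counting statistics on reduced data; real reduction
pipelines propagate more structure), amplitudes are in detector-count-like
units (default β = 100, putting percent-level relative noise at the
strongest channels for noise_scale = 0.02); Brownian chains do not
interact (cluster statistics are exercised on constructed configurations);
the sphere-confined fixture has an O(√(D_loc·dt)) wall bias from the radial
reflection scheme (kept ≲ 1% by the step-size guard and small steps in
equilibrium tests); the ω grid default is 0.2 μeV (a 0.25 μeV grid would
violate the FWHM/4 sampling rule the convolution enforces).  Passing tests
demonstrate estimator correctness under these idealized conditions, not
the systematics of real reduced data (absorption corrections, multiple
scattering, detector efficiency), which are out of scope.

## Known limitations

* The internal-motion parameters (D_int, τ) of the global fit are weakly
  identified on a ±30 μeV window when ħ/τ ≈ 33 μeV sits at its edge: at
  percent-level counting noise their sampling distributions are broad,
  correlated and right-skewed, so finite-noise maximum-likelihood bias of
  order +25% in τ (well within each fit's own 1σ) remains even though D is
  unbiased to a fraction of a percent.  Longer counting, a wider window or
  an informative prior on τ are the physical remedies; the package reports
  honest covariances instead of debiasing.
* Per-q EISF extraction is only meaningful where the elastic line is
  narrower than the window (see Identifiability above).
* The D₂O viscosity construction is accurate near ambient; below ~278 K
  its offset form inherits the light-water correlation's extrapolation
  error.
* Geometric models (sphere, spheroid, uniform hydrogen profile) are
  idealizations of a fluctuating disordered chain; the package treats them
  as comparison baselines, not as structural claims.
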