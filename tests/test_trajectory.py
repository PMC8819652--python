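"""Trajectory analysis: unwrapping, MSD/diffusion, corrections, clustering,
R_g, and EISF."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from idpdyn import constants as C
from idpdyn.estimates import DiffusionEstimate

from idpdyn.synthetic import (
    BrownianSystemTruth,
    generate_brownian_chains,
    generate_confined_hydrogens,
    sphere_eisf,
)
from idpdyn.trajectory import (
    ChainEnsembleTrajectory,
    FiniteSizeParams,
    cluster_chains,
    diffusion_autocorrelation,
    dt_distribution_from_rg,
    eisf_from_trajectory,
    fit_diffusion,
    isotope_rescale,
    min_chain_distance,
    msd,
    rg_series,
    unwrap,
    wrap,
    yeh_hummer_correct,
    yeh_hummer_term,
)


def _single_chain(coords, box=1000.0, dt=0.1, masses=None):
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    return ChainEnsembleTrajectory(
        times=np.arange(coords.shape[0]) * dt,
        coords=coords,
        box=np.full(3, box),
        chain_ids=np.zeros(n_atoms, dtype=int),
        masses=np.ones(n_atoms) if masses is None else np.asarray(masses),
    )


def _msd_naive(com):
    n = com.shape[0]
    out = np.zeros(n)
    for k in range(1, n):
        out[k] = np.mean(((com[k:] - com[:n - k]) ** 2).sum(axis=1))
    return out


class TestUnwrap:
    def test_continuous_trajectory_unchanged(self):
        coords = np.cumsum(np.full((20, 1, 3), 0.5), axis=0)
        traj = _single_chain(coords, box=1000.0)
        assert np.allclose(unwrap(traj).coords, coords)

    def test_single_boundary_crossing(self):
        x = np.array([9.0, 9.6, 0.2, 0.8]) % 10.0
        coords = np.zeros((4, 1, 3))
        coords[:, 0, 0] = x
        traj = _single_chain(coords, box=10.0)
        un = unwrap(traj).coords[:, 0, 0]
        assert np.allclose(un, [9.0, 9.6, 10.2, 10.8])

    def test_wrap_unwrap_wrap_idempotent(self):
        traj = generate_brownian_chains(BrownianSystemTruth(seed=1))
        w1 = wrap(unwrap(wrap(traj)))
        assert np.allclose(w1.coords, wrap(traj).coords, atol=1e-9)

    def test_undersampled_jump_rejected(self):
        coords = np.zeros((2, 1, 3))
        coords[1, 0, 0] = 5.0  # exactly L/2
        with pytest.raises(ValueError):
            unwrap(_single_chain(coords, box=10.0))


class TestMSD:
    def test_linear_drift_gives_quadratic_msd(self):
        t = np.arange(50) * 0.1
        coords = np.zeros((50, 1, 3))
        coords[:, 0, 0] = 2.0 * t
        lags, curve = msd(_single_chain(coords), 0)
        assert np.allclose(curve, (2.0 * lags) ** 2, atol=1e-9)

    def test_static_chain_zero(self):
        coords = np.ones((30, 1, 3))
        _, curve = msd(_single_chain(coords), 0)
        assert np.allclose(curve, 0.0, atol=1e-12)

    def test_matches_naive_double_loop_oracle(self, brownian_replicates):
        traj = brownian_replicates[0]
        for chain in traj.chains[:3]:
            _, curve = msd(traj, chain)
            assert np.allclose(curve, _msd_naive(traj.com(chain)),
                               rtol=1e-10, atol=1e-8)

    def test_max_lag_beyond_length_rejected(self):
        traj = _single_chain(np.zeros((10, 1, 3)), dt=0.1)
        with pytest.raises(ValueError):
            msd(traj, 0, max_lag=5.0)


class TestFitDiffusion:
    def test_exact_einstein_input(self):
        lags = np.linspace(0, 4.6, 24)
        est = fit_diffusion(lags, 6.0 * 3.2 * lags)
        assert est.value == pytest.approx(3.2, rel=1e-12)
        assert est.r_squared == pytest.approx(1.0)
        assert "nonlinear" not in est.flags

    def test_quadratic_msd_flagged_nonlinear(self):
        lags = np.linspace(0, 4.6, 24)
        est = fit_diffusion(lags, 10.0 * lags**2)
        assert "nonlinear" in est.flags

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            fit_diffusion(np.linspace(10, 20, 30), np.ones(30), window=(0, 4.6))


class TestCorrections:
    def test_correction_vanishes_for_large_box(self):
        p = FiniteSizeParams.cubic(L=1e9, eta=0.85, T=300.0)
        assert yeh_hummer_term(p) == pytest.approx(0.0, abs=1e-6)

    def test_correction_term_value(self):
        """kT·ξ/(6πηL) ≈ 7.3 Å²/ns for a 100 Å box of 0.85 mPa·s at 300 K."""
        p = FiniteSizeParams.cubic(L=100.0, eta=0.85, T=300.0)
        assert yeh_hummer_term(p) == pytest.approx(7.34, abs=0.01)

    def test_rhombic_dodecahedron_mode_substitutes_constants(self):
        cub = FiniteSizeParams.cubic(L=100.0, eta=0.85, T=300.0)
        fcc = FiniteSizeParams.rhombic_dodecahedron(L_cell=100.0, eta=0.85,
                                                    T=300.0)
        assert fcc.xi == pytest.approx(C.XI_FCC * 4 ** (1 / 3))
        assert yeh_hummer_term(fcc) > yeh_hummer_term(cub)

    def test_finite_size_removes_designed_L_dependence(self):
        """Estimates biased by the analytic −kTξ/(6πηL) term at L and 2L
        agree after correction."""
        D_true, eta, T = 15.0, 0.85, 300.0
        for L in (80.0, 160.0):
            p = FiniteSizeParams.cubic(L=L, eta=eta, T=T)
            d_pbc = D_true - yeh_hummer_term(p)
            assert yeh_hummer_correct(d_pbc, p) == pytest.approx(D_true,
                                                                 rel=1e-12)

    def test_isotope_ratio_below_one_everywhere(self):
        for T in np.linspace(278, 340, 15):
            assert isotope_rescale(1.0, T) < 1.0

    def test_isotope_ratio_at_298(self):
        assert 0.81 <= isotope_rescale(1.0, 298.0) <= 0.82

    def test_double_application_guarded(self):
        est = DiffusionEstimate(value=10.0, method="msd")
        once = isotope_rescale(est, 298.0)
        assert "isotope_rescaled" in once.corrections
        with pytest.raises(ValueError):
            isotope_rescale(once, 298.0)


class TestViscosityEstimator:
    def test_sign_flip_invariance(self):
        from idpdyn.synthetic import PressureSeriesTruth, generate_pressure_series
        from idpdyn.trajectory import viscosity_from_pressure

        s = generate_pressure_series(PressureSeriesTruth(n_steps=100_000, seed=3))
        e1, _ = viscosity_from_pressure(s.components, s.volume, s.temperature, s.dt)
        e2, _ = viscosity_from_pressure(-s.components, s.volume, s.temperature, s.dt)
        assert e1 == pytest.approx(e2, rel=1e-12)


class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(0)
        c = diffusion_autocorrelation(rng.normal(size=500))
        assert c[0] == pytest.approx(1.0)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(1)
        c = diffusion_autocorrelation(rng.normal(size=10_000))
        assert np.max(np.abs(c[1:20])) < 0.05

    def test_ar1_closed_form(self):
        rho, n = 0.8, 40_000
        rng = np.random.default_rng(2)
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        c = diffusion_autocorrelation(x)
        ks = np.arange(1, 8)
        assert np.allclose(c[ks], rho**ks, atol=4.0 / math.sqrt(n) * 3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            diffusion_autocorrelation(np.ones(100))


def _frame_traj(positions, box, chain_ids):
    positions = np.asarray(positions, dtype=float)[None, :, :]
    return ChainEnsembleTrajectory(
        times=np.array([0.0]), coords=positions, box=np.asarray(box),
        chain_ids=np.asarray(chain_ids),
        masses=np.ones(positions.shape[1]))


class TestMinChainDistance:
    def test_two_point_chains_direct(self):
        traj = _frame_traj([[1, 1, 1], [4, 5, 1]], [100.0] * 3, [0, 1])
        d = min_chain_distance(traj, 0)
        assert d[0, 1] == pytest.approx(5.0)

    def test_minimum_image_across_boundary(self):
        traj = _frame_traj([[0.5, 0, 0], [9.5, 0, 0]], [10.0] * 3, [0, 1])
        assert min_chain_distance(traj, 0)[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(3)
        L = 20.0
        pos = rng.uniform(0, L, size=(50, 3))
        cid = np.repeat(np.arange(10), 5)
        traj = _frame_traj(pos, [L] * 3, cid)
        d = min_chain_distance(traj, 0)
        for i in range(10):
            for j in range(i + 1, 10):
                best = np.inf
                for a in pos[cid == i]:
                    for b in pos[cid == j]:
                        dd = a - b
                        dd -= L * np.round(dd / L)
                        best = min(best, float(np.linalg.norm(dd)))
                assert d[i, j] == pytest.approx(best)

    def test_single_chain_rejected(self):
        traj = _frame_traj([[0, 0, 0]], [10.0] * 3, [0])
        with pytest.raises(ValueError):
            min_chain_distance(traj, 0)


class TestClusterChains:
    def test_simple_pair(self):
        d = np.array([[0.0, 5.0], [5.0, 0.0]])
        st_ = cluster_chains(d, cutoff=6.0)
        assert st_.n_clusters == 1
        assert st_.n_participating == 2
        assert st_.largest == 2

    def test_transitivity(self):
        d = np.array([[0, 5, 20], [5, 0, 5], [20, 5, 0]], dtype=float)
        st_ = cluster_chains(d, cutoff=6.0)
        assert st_.n_clusters == 1
        assert st_.largest == 3

    def test_singletons_not_counted(self):
        d = np.full((4, 4), 50.0)
        np.fill_diagonal(d, 0.0)
        st_ = cluster_chains(d, cutoff=6.0)
        assert st_.n_clusters == 0
        assert st_.largest == 0

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        pos = rng.uniform(0, 30, size=(n, 3))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        for cutoff in (6.0, 7.0):
            st_ = cluster_chains(d, cutoff)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    if d[i, j] <= cutoff:
                        parent[find(i)] = find(j)
            roots = {}
            for i in range(n):
                roots.setdefault(find(i), []).append(i)
            sizes = sorted(len(v) for v in roots.values() if len(v) >= 2)
            assert st_.n_clusters == len(sizes)
            assert st_.n_participating == sum(sizes)
            assert st_.largest == (max(sizes) if sizes else 0)

    def test_invariant_under_relabeling_and_translation(self):
        rng = np.random.default_rng(11)
        pos = rng.uniform(0, 30, size=(6, 3))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        perm = rng.permutation(6)
        d_perm = d[np.ix_(perm, perm)]
        a, b = cluster_chains(d, 7.0), cluster_chains(d_perm, 7.0)
        assert (a.n_clusters, a.n_participating, a.largest) == \
            (b.n_clusters, b.n_participating, b.largest)
        shifted = np.linalg.norm((pos + 5.0)[:, None] - (pos + 5.0)[None, :],
                                 axis=-1)
        c = cluster_chains(shifted, 7.0)
        assert (a.n_clusters, a.n_participating, a.largest) == \
            (c.n_clusters, c.n_participating, c.largest)


class TestRg:
    def test_single_particle_zero(self):
        traj = _single_chain(np.zeros((5, 1, 3)))
        assert np.allclose(rg_series(traj, 0), 0.0)

    def test_two_unit_masses(self):
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = 4.0
        traj = _single_chain(coords)
        assert np.allclose(rg_series(traj, 0), 2.0)

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(4, 12, 3))
        masses = rng.uniform(1, 15, 12)
        traj = _single_chain(coords, masses=masses)
        rg = rg_series(traj, 0)
        for t in range(4):
            com = np.average(coords[t], axis=0, weights=masses)
            expected = math.sqrt(np.average(
                ((coords[t] - com) ** 2).sum(axis=1), weights=masses))
            assert rg[t] == pytest.approx(expected, rel=1e-12)


class TestDtDistribution:
    def test_constant_rg_gives_point_mass_at_one(self, ctx_298):
        red = dt_distribution_from_rg(np.full(50, 13.0), 24, ctx_298)
        assert np.allclose(red, 1.0)

    def test_reduced_mean_is_one(self, ctx_298):
        rng = np.random.default_rng(5)
        red = dt_distribution_from_rg(rng.uniform(10, 16, 200), 24, ctx_298)
        assert red.mean() == pytest.approx(1.0, rel=1e-12)

    def test_shape_noise_broadens_distribution(self, ctx_298):
        """A diffusion series carrying extra shape heterogeneity on top of the
        size-derived one has the wider reduced distribution."""
        rng = np.random.default_rng(6)
        rg = rng.uniform(11, 15, 500)
        red_size = dt_distribution_from_rg(rg, 24, ctx_298)
        extra = red_size * np.exp(rng.normal(0, 0.15, rg.size))
        red_extra = extra / extra.mean()
        assert red_extra.std() > red_size.std()


class TestEISF:
    def test_static_structure_gives_unity(self):
        rng = np.random.default_rng(7)
        coords = np.repeat(rng.uniform(0, 5, size=(1, 20, 3)), 10, axis=0)
        traj = ChainEnsembleTrajectory(
            times=np.arange(10) * 0.1, coords=coords, box=np.full(3, 100.0),
            chain_ids=np.zeros(20, dtype=int), masses=np.ones(20),
            elements=np.array(["H"] * 20))
        a0 = eisf_from_trajectory(traj, np.array([0.3, 0.9, 1.8]),
                                  remove_com=False)
        assert np.allclose(a0, 1.0, atol=1e-12)

    def test_sphere_confined_matches_closed_form(self):
        traj = generate_confined_hydrogens(100, a=2.0, D_loc=5.0, dt=0.01,
                                           n_steps=4000, seed=8)
        q = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        a0 = eisf_from_trajectory(traj, q, n_orientations=32, remove_com=False)
        assert np.max(np.abs(a0 - sphere_eisf(q, 2.0))) < 0.02

    def test_values_bounded_and_decreasing_for_sphere(self):
        traj = generate_confined_hydrogens(60, a=2.0, D_loc=5.0, dt=0.01,
                                           n_steps=2000, seed=9)
        q = np.linspace(0.3, 2.4, 8)
        a0 = eisf_from_trajectory(traj, q, n_orientations=24, remove_com=False)
        assert np.all((a0 >= 0) & (a0 <= 1))
        assert np.all(np.diff(a0) < 0.02)

    def test_free_diffusion_decays_to_zero(self):
        traj = generate_brownian_chains(
            BrownianSystemTruth(n_chains=40, D_t=15.0, box_edge=1e5,
                                dt=0.1, n_steps=800, seed=10))
        traj = unwrap(traj)
        a0 = eisf_from_trajectory(traj, np.array([1.0]), selection="all",
                                  remove_com=False, n_orientations=16)
        assert a0[0] < 0.05

    def test_empty_selection_rejected(self):
        traj = _single_chain(np.zeros((5, 2, 3)))
        traj.elements = np.array(["C", "C"])
        with pytest.raises(ValueError):
            eisf_from_trajectory(traj, np.array([1.0]), selection="hydrogen")
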