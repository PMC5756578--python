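"""Particle simulator: sampling, link process, forces, stepping, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from springnet import micro
from springnet.params import ModelParams


def _p(ell=0.3, D=0.003, **kw):
    return ModelParams(D=D, ell=ell, **kw)


class TestSampling:
    def test_reproducible_under_seed(self):
        cfg = micro.MicroConfig(N=500, seed=3)
        p = _p()
        a = micro.sample_initial(0.01, cfg, p)
        b = micro.sample_initial(0.01, cfg, p)
        assert np.array_equal(a.positions, b.positions)

    def test_uniform_sampling_passes_ks(self):
        cfg = micro.MicroConfig(N=10_000, seed=5)
        x = micro.sample_initial(0.0, cfg, _p()).positions
        res = stats.kstest(x, stats.uniform(loc=-3.0, scale=6.0).cdf)
        assert res.pvalue > 0.01

    def test_cosine_perturbation_shifts_first_moment(self):
        # E[cos(pi X / L)] = delta * L under f0
        delta, N = 0.05, 100_000
        cfg = micro.MicroConfig(N=N, seed=8)
        x = micro.sample_initial(delta, cfg, _p()).positions
        m = np.mean(np.cos(np.pi * x / 3.0))
        sigma = np.sqrt(0.5 / N)
        assert abs(m - delta * 3.0) < 4 * sigma


class TestLinks:
    def test_initial_link_count(self):
        cfg = micro.MicroConfig(N=1000, epsilon=1.0, xi_init=0.1, seed=1)
        p = _p()
        state = micro.sample_initial(0.0, cfg, p)
        links = micro.initialize_links(state, cfg, p)
        assert links.K == 100
        d = np.abs(state.positions[:, None] - state.positions[None, :])
        d = np.minimum(d, 6.0 - d)
        assert all(d[i, j] <= p.R for i, j in links.pairs)

    def test_zero_initial_fraction(self):
        cfg = micro.MicroConfig(N=100, epsilon=1.0, xi_init=0.0, seed=1)
        p = _p()
        state = micro.sample_initial(0.0, cfg, p)
        assert micro.initialize_links(state, cfg, p).K == 0

    def test_stationary_link_probability_matches_two_state_chain(self):
        # N = 5 particles pinned inside one detection radius: each pair is an
        # independent two-state chain with per-sweep flip probabilities
        # (P_f, P_d); the empirical link fraction must match
        # P_f / (P_f + P_d) ~= nu_f / (nu_f + nu_d (N-1)) = 1/5
        N, eps, dt = 5, 1.0, 0.05
        p = _p()
        cfg = micro.MicroConfig(N=N, epsilon=eps, seed=0)
        state = micro.ParticleState(positions=np.linspace(-0.2, 0.2, N))
        rng = np.random.default_rng(12)
        links = micro.LinkSet()
        n_sweeps, burn = 30_000, 2_000
        occupancy = 0.0
        for sweep in range(n_sweeps):
            links = micro.update_links(links, state, dt, cfg, p, rng)
            if sweep >= burn:
                occupancy += links.K
        n_pairs = N * (N - 1) / 2
        frac = occupancy / ((n_sweeps - burn) * n_pairs)
        p_f = 1.0 - np.exp(-p.nu_f * dt / ((N - 1) * eps**2))
        p_d = 1.0 - np.exp(-p.nu_d * dt / eps**2)
        exact = p_f / (p_f + p_d)
        assert exact == pytest.approx(1.0 / N, rel=0.03)  # chain ~ kinetic ratio
        assert frac == pytest.approx(exact, abs=0.02)

    def test_strong_destruction_empties_links(self):
        N, eps = 6, 0.05
        p = _p()
        cfg = micro.MicroConfig(N=N, epsilon=eps, seed=0)
        state = micro.ParticleState(positions=np.linspace(-0.2, 0.2, N))
        links = micro.LinkSet()
        for i in range(N):
            for j in range(i + 1, N):
                links.add(i, j)
        rng = np.random.default_rng(3)
        # nu_d dt / eps^2 >> 1 and creation suppressed by pairs factor
        p_f, p_d = micro._event_probabilities(10.0, N, eps, p)
        assert p_d > 0.999999
        survivors = sum(1 for (i, j) in links.pairs if rng.random() >= p_d)
        assert survivors == 0

    def test_creation_probability_small_dt_expansion(self):
        N, eps = 10, 0.5
        p = _p()
        for dt in (1e-4, 1e-5):
            p_f, _ = micro._event_probabilities(dt, N, eps, p)
            linear = p.nu_f * dt / ((N - 1) * eps**2)
            assert p_f == pytest.approx(linear, rel=1e-3)


class TestForces:
    def test_linked_pair_at_rest_length(self):
        p = _p(ell=0.3)
        cfg = micro.MicroConfig(N=2, epsilon=1.0)
        state = micro.ParticleState(positions=np.array([0.0, 0.3]))
        links = micro.LinkSet(pairs={(0, 1)})
        assert np.allclose(micro.forces(state, links, cfg, p), 0.0)

    def test_compressed_pair_repels(self):
        p = _p(ell=0.3)
        cfg = micro.MicroConfig(N=2, epsilon=1.0)
        state = micro.ParticleState(positions=np.array([0.0, 0.15]))
        links = micro.LinkSet(pairs={(0, 1)})
        drift = micro.forces(state, links, cfg, p)
        assert drift[0] < 0 < drift[1]  # pushes apart

    def test_meanfield_three_body_hand_computed(self):
        p = _p(ell=0.3)
        cfg = micro.MicroConfig(N=3)
        x = np.array([-0.3, 0.0, 0.4])
        state = micro.ParticleState(positions=x)
        drift = micro.forces(state, None, cfg, p)
        pref = 1.0 / 2.0  # nu_f/(nu_d (N-1))
        expected = np.zeros(3)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                d = x[i] - x[j]
                if abs(d) <= p.R:
                    expected[i] -= pref * p.kappa * (abs(d) - p.ell) * np.sign(d)
        assert np.allclose(drift, expected, atol=1e-12)

    def test_numba_driver_matches_numpy_forces(self):
        # one noiseless step of the JIT mean-field loop equals x + drift*dt
        p = _p(ell=0.3, D=0.0)
        N = 50
        rng = np.random.default_rng(17)
        x = rng.uniform(-3.0, 3.0, N)
        cfg = micro.MicroConfig(N=N, dt_max=0.01, delta_step=1e6)
        drift = micro.forces(micro.ParticleState(positions=x.copy()), None, cfg, p)
        saved = np.empty((1, N))
        micro._drive_meanfield(x.copy(), 3.0, p.R, p.ell, p.kappa,
                               1.0 / (N - 1), 0.0, 0.01, 1e6,
                               np.array([0.01]), saved, 0)
        expected = micro._wrap(x + drift * 0.01, 3.0)
        assert np.allclose(saved[0], expected, atol=1e-12)


class TestStep:
    def test_no_noise_no_links_stays_put(self):
        p = _p(D=0.0, ell=0.3)
        cfg = micro.MicroConfig(N=4, epsilon=1.0)
        state = micro.ParticleState(positions=np.array([-2.0, -1.0, 1.0, 2.0]))
        links = micro.LinkSet()
        new, _ = micro.step(state, links, cfg, p, np.random.default_rng(0), dt=0.01)
        assert np.allclose(new.positions, state.positions)

    def test_diffusive_displacement_variance(self):
        p = _p(D=0.01, ell=0.3)
        N, dt = 10_000, 0.05
        cfg = micro.MicroConfig(N=N)
        x0 = np.linspace(-2.9, 2.9, N)
        state = micro.ParticleState(positions=x0.copy())
        # mean-field forces vanish for a uniform lattice (pair symmetry),
        # so displacements are pure noise
        new, _ = micro.step(state, None, cfg, p, np.random.default_rng(4), dt=dt)
        disp = micro._min_image(new.positions - x0, 3.0)
        var = np.var(disp)
        assert var == pytest.approx(2 * p.D * dt, rel=0.05)

    def test_linked_pair_relaxes_to_rest_length(self):
        # deterministic two-body dynamics: s(t) = ell + (s0 - ell) e^(-2 kappa t)
        p = _p(D=0.0, ell=0.3)
        cfg = micro.MicroConfig(N=2, epsilon=1.0)
        links = micro.LinkSet(pairs={(0, 1)})
        state = micro.ParticleState(positions=np.array([0.0, 0.6]))
        dt, T = 1e-4, 1.0
        for _ in range(int(T / dt)):
            drift = micro.forces(state, links, cfg, p)
            state = micro.ParticleState(
                positions=state.positions + drift * dt, time=state.time + dt)
        sep = state.positions[1] - state.positions[0]
        exact = 0.3 + 0.3 * np.exp(-2 * p.kappa * T)
        assert sep == pytest.approx(exact, abs=1e-3)

    def test_adaptive_dt_caps(self):
        cfg = micro.MicroConfig(N=10, dt_max=0.05, delta_step=0.1)
        p = _p()
        assert micro.adaptive_dt(np.zeros(10), cfg, p) == 0.05
        assert micro.adaptive_dt(np.full(10, 10.0), cfg, p) == pytest.approx(0.01)
        cfg_eps = micro.MicroConfig(N=10, dt_max=0.05, epsilon=0.1)
        assert micro.adaptive_dt(np.zeros(10), cfg_eps, p) == pytest.approx(1e-3)


class TestDensityAndRecentering:
    def test_single_bin_carries_all_mass(self):
        f = micro.estimate_density(np.full(100, 0.1), 10, 3.0)
        assert f.values.max() == pytest.approx(1.0 / f.dx)
        assert np.count_nonzero(f.values) == 1

    def test_unit_mass(self, rng):
        f = micro.estimate_density(rng.uniform(-3, 3, 777), 64, 3.0)
        assert f.mass == pytest.approx(1.0, abs=1e-12)

    def test_uniform_sample_within_binomial_bands(self):
        rng = np.random.default_rng(9)
        N, nb = 200_000, 30
        f = micro.estimate_density(rng.uniform(-3, 3, N), nb, 3.0)
        p_bin = 1.0 / nb
        sigma = np.sqrt(N * p_bin * (1 - p_bin)) / (N * f.dx)
        assert np.all(np.abs(f.values - 1.0 / 6.0) < 4 * sigma)

    def test_recenter_moves_cluster_to_origin(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1.0, 0.2, 2000)
        y = micro.recenter(x, 3.0)
        assert abs(np.mean(y)) < 0.05

    def test_recenter_idempotent(self):
        rng = np.random.default_rng(2)
        x = micro._wrap(rng.normal(1.0, 0.3, 500), 3.0)
        once = micro.recenter(x, 3.0)
        twice = micro.recenter(once, 3.0)
        assert np.allclose(once, twice, atol=1e-10)

    def test_recenter_unwraps_boundary_cluster(self):
        rng = np.random.default_rng(6)
        x = micro._wrap(rng.normal(3.0, 0.2, 2000), 3.0)  # straddles +-L
        y = micro.recenter(x, 3.0)
        assert abs(np.mean(y)) < 0.05
        assert np.std(y) < 0.3  # cluster reassembled, not split

    def test_recentered_circular_mean_is_zero(self):
        rng = np.random.default_rng(11)
        x = micro._wrap(rng.normal(-2.5, 0.4, 1000), 3.0)
        y = micro.recenter(x, 3.0)
        phase = np.angle(np.sum(np.exp(1j * np.pi * y / 3.0)))
        assert abs(phase) < 1e-10


class TestRun:
    def test_identical_seeds_identical_trajectories(self):
        p = _p(ell=0.4725, D=0.003)
        cfg = micro.MicroConfig(N=200, seed=21, n_replicates=2)
        a = micro.run(cfg, p, delta=0.01, save_times=[1.0])
        b = micro.run(cfg, p, delta=0.01, save_times=[1.0])
        assert np.array_equal(a.mean_density, b.mean_density)
        assert np.array_equal(a.Q, b.Q)

    def test_pure_diffusion_stays_uniform(self):
        # kappa -> no force path: use ell=0 and R tiny so no pair interacts
        p = ModelParams(D=0.01, ell=0.0, R=1e-4, L=3.0)
        cfg = micro.MicroConfig(N=2000, seed=13, n_replicates=4, T_f=5.0)
        res = micro.run(cfg, p, delta=0.0)
        # noise floor of Q at this N is O(1/sqrt(N))
        assert np.mean(res.Q) < 3.0 / np.sqrt(cfg.N)

    def test_finite_epsilon_smoke(self):
        p = _p(ell=0.3, D=0.01)
        cfg = micro.MicroConfig(N=60, epsilon=0.5, seed=2, n_replicates=1,
                                T_f=0.5)
        res = micro.run(cfg, p, delta=0.0)
        assert res.mean_density.shape == (cfg.n_bins,)
        assert np.all(np.isfinite(res.mean_density))
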