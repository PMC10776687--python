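import numpy as np
import pandas as pd
import pytest

from occlusim import thermal_energy
from occlusim import msm
from occlusim import synthetic as sw

KT310 = thermal_energy(310.0)


def _ou(tau, n, rng):
    phi = np.exp(-1.0 / tau)
    x = np.zeros(n)
    noise = rng.standard_normal(n) * np.sqrt(1 - phi ** 2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + noise[i]
    return x


class TestTICA:
    def test_single_feature_standardized(self):
        rng = np.random.default_rng(0)
        x = _ou(50, 30000, rng)
        table = pd.DataFrame({"time_ns": np.arange(30000, dtype=float),
                              "f": x})
        model = msm.fit_tica([table], lag_ns=10)
        proj = model.transform(table)[:, 0]
        assert proj.var() == pytest.approx(1.0, rel=0.02)
        assert abs(np.corrcoef(proj, x)[0, 1]) == pytest.approx(1.0, abs=1e-9)
        # eigenvalue ~ lag-10 autocorrelation of an OU with tau = 50
        assert model.eigenvalues[0] == pytest.approx(np.exp(-10 / 50), abs=0.03)

    def test_ou_eigenvalue_closed_form(self):
        rng = np.random.default_rng(1)
        x = _ou(100, 60000, rng)
        model = msm.fit_tica([x[:, None]], lag_ns=25)
        assert model.eigenvalues[0] == pytest.approx(np.exp(-25 / 100), abs=0.04)

    def test_rotated_ou_pair_recovers_slow_process(self):
        rng = np.random.default_rng(2)
        slow, fast = _ou(100, 40000, rng), _ou(10, 40000, rng)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        Z = np.column_stack([slow, fast]) @ R.T
        model = msm.fit_tica([Z], lag_ns=20)
        ic1 = model.transform(Z)[:, 0]
        assert abs(np.corrcoef(ic1, slow)[0, 1]) >= 0.9
        assert (model.eigenvalues <= 1 + 1e-6).all()

    def test_short_trajectories_skipped_then_error(self):
        rng = np.random.default_rng(3)
        good = rng.normal(size=(500, 2))
        short = rng.normal(size=(5, 2))
        with pytest.warns(UserWarning, match="skipped"):
            msm.fit_tica([good, short], lag_ns=10)
        with pytest.raises(ValueError, match="shorter than the lag"):
            msm.fit_tica([short], lag_ns=10)

    def test_lag_must_divide_frame_spacing(self):
        table = pd.DataFrame({"time_ns": np.arange(100) * 0.5,
                              "f": np.random.default_rng(4).normal(size=100)})
        with pytest.raises(ValueError, match="multiple"):
            msm.fit_tica([table], lag_ns=0.75)

    def test_hash_stable(self):
        Z = np.random.default_rng(5).normal(size=(200, 2))
        assert msm.fit_tica([Z], lag_ns=5).hash() == msm.fit_tica([Z], lag_ns=5).hash()


class TestDiscretize:
    def test_zero_inertia_with_k_equal_points(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [5, 5]])
        disc = msm.discretize([pts], k=4, seed=0)
        assert disc.inertia == pytest.approx(0.0, abs=1e-12)

    def test_two_blobs(self):
        rng = np.random.default_rng(1)
        a = rng.normal(loc=(0, 0), scale=0.1, size=(500, 2))
        b = rng.normal(loc=(5, 5), scale=0.1, size=(500, 2))
        disc = msm.discretize([np.vstack([a, b])], k=2, seed=0)
        centers = disc.centers[np.argsort(disc.centers[:, 0])]
        se = 0.1 / np.sqrt(500)
        assert np.abs(centers[0] - a.mean(axis=0)).max() < 3 * se
        assert np.abs(centers[1] - b.mean(axis=0)).max() < 3 * se

    def test_deterministic(self):
        pts = np.random.default_rng(2).normal(size=(1000, 2))
        d1 = msm.discretize([pts], k=10, seed=3)
        d2 = msm.discretize([pts], k=10, seed=3)
        assert (d1.dtrajs[0] == d2.dtrajs[0]).all()

    def test_k_exceeding_frames(self):
        with pytest.raises(ValueError, match="exceeds"):
            msm.discretize([np.zeros((3, 2))], k=5, seed=0)


class TestEstimateMSM:
    def test_symmetric_counts_closed_form(self):
        T, pi = msm._reversible_mle(np.array([[8.0, 2.0], [2.0, 8.0]]))
        assert np.allclose(T, [[0.8, 0.2], [0.2, 0.8]], atol=1e-12)
        assert np.allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_recovers_generating_matrix(self, three_state_chain):
        T, pi, traj = three_state_chain
        model = msm.estimate_msm([traj], lag_ns=1, dt_ns=1)
        assert np.abs(model.transition_matrix - T).max() < 0.02
        assert np.abs(model.stationary - pi).max() < 0.02

    def test_reversible_invariants(self, three_state_chain):
        _, _, traj = three_state_chain
        model = msm.estimate_msm([traj], lag_ns=2, dt_ns=1)
        T, pi = model.transition_matrix, model.stationary
        assert np.abs(pi @ T - pi).max() < 1e-8
        flux = pi[:, None] * T
        assert np.abs(flux - flux.T).max() < 1e-8
        ev = model.eigenvalues()
        assert np.abs(np.imag(ev)).max() < 1e-10
        assert np.real(ev[0]) == pytest.approx(1.0, abs=1e-10)

    def test_disconnected_blocks_keep_larger(self):
        d = np.array([0] * 10 + [1] * 30 + [0] * 0 + [2, 3] * 40)
        # states {0,1} never connect to {2,3}
        d = np.concatenate([[0, 1] * 10, [2, 3] * 40])
        with pytest.warns(UserWarning, match="dropping"):
            model = msm.estimate_msm([d], lag_ns=1, dt_ns=1)
        assert set(model.active_set) == {2, 3}

    def test_no_connected_set(self):
        with pytest.raises(ValueError, match="connected"):
            msm.estimate_msm([np.zeros(50, dtype=int)], lag_ns=1, dt_ns=1)

    def test_lag_not_multiple_of_stride(self):
        with pytest.raises(ValueError, match="multiple"):
            msm.estimate_msm([np.array([0, 1] * 50)], lag_ns=2.5, dt_ns=1)

    def test_nonreversible_option(self, three_state_chain):
        T, _, traj = three_state_chain
        model = msm.estimate_msm([traj], lag_ns=1, dt_ns=1, reversible=False)
        assert np.abs(model.transition_matrix - T).max() < 0.02


class TestImpliedTimescales:
    def test_arithmetic(self):
        # lambda2 = 0.6 at tau = 25 ns -> t2 = -25/ln 0.6 = 48.94 ns
        counts = np.array([[80.0, 20.0], [20.0, 80.0]])
        T, pi = msm._reversible_mle(counts)
        model = msm.MSMModel(25.0, 25.0, counts, np.array([0, 1]), T, pi, True)
        assert model.timescales(1)[0] == pytest.approx(-25 / np.log(0.6), rel=1e-9)
        assert model.timescales(1)[0] == pytest.approx(48.94, abs=0.01)

    def test_markovian_chain_flat_and_matches_generator(self, three_state_chain):
        T, _, traj = three_state_chain
        lam2 = np.sort(np.real(np.linalg.eigvals(T)))[-2]
        ref = -1.0 / np.log(lam2)
        its = msm.implied_timescales([traj], lags=[1, 2, 5, 10], n_timescales=2)
        t2 = its.timescales[:, 0]
        assert np.all(np.abs(t2 - ref) / ref < 0.10)

    def test_negative_eigenvalue_masked(self):
        d = np.array([0, 1] * 2000)  # period-2 chain, lambda2 = -1
        its = msm.implied_timescales([d], lags=[1], n_timescales=1)
        assert np.isnan(its.timescales[0, 0])

    def test_bootstrap_bands(self, three_state_chain):
        _, _, traj = three_state_chain
        half = len(traj) // 2
        its = msm.implied_timescales([traj[:half], traj[half:]], lags=[1, 2],
                                     n_timescales=1, n_boot=10, seed=0)
        assert its.lower is not None and (its.upper >= its.lower).all()


class TestCKTest:
    def test_factor_one_identity(self, three_state_chain):
        _, _, traj = three_state_chain
        model = msm.estimate_msm([traj], lag_ns=1, dt_ns=1)
        ck = msm.ck_test(model, [traj], factors=(1, 2), n_boot=5, seed=0)
        assert np.allclose(ck.predicted[:, 0], ck.estimated[:, 0], atol=1e-12)

    def test_markovian_passes(self, three_state_chain):
        _, _, traj = three_state_chain
        model = msm.estimate_msm([traj], lag_ns=1, dt_ns=1)
        ck = msm.ck_test(model, [traj], factors=(1, 2, 3, 4, 5), n_boot=20, seed=1)
        assert ck.passes(n_sd=2.0)

    def test_lumped_chain_fails(self):
        hidden = np.array([[0.99, 0.01, 0.0],
                           [0.05, 0.80, 0.15],
                           [0.0, 0.10, 0.90]])
        h = sw.simulate_discrete_chain(hidden, 100_000, seed=11)
        obs = np.where(h == 2, 1, 0)
        model = msm.estimate_msm([obs], lag_ns=1, dt_ns=1)
        ck = msm.ck_test(model, [obs], factors=(1, 2, 3, 4, 5), n_boot=20, seed=1)
        assert not ck.passes(n_sd=2.0)
        dev = np.abs(ck.predicted - ck.estimated) / np.maximum(ck.estimated_sd, 0.01)
        assert np.nanmax(dev[:, 2:]) > 2.0  # violation at factor >= 3

    def test_excessive_factor_dropped(self):
        d = np.array([0, 0, 1, 1] * 10)
        model = msm.estimate_msm([d], lag_ns=1, dt_ns=1)
        with pytest.warns(UserWarning, match="dropped"):
            ck = msm.ck_test(model, [d], factors=(1, 100), n_boot=2, seed=0)
        assert list(ck.factors) == [1]


def _toy_model(pi, lag_ns=25.0):
    k = len(pi)
    pi = np.asarray(pi, float)
    T = np.tile(pi, (k, 1))  # rank-one chain with stationary pi
    counts = np.outer(pi, pi) * 1000
    return msm.MSMModel(lag_ns, lag_ns, counts, np.arange(k), T, pi, True)


class TestFreeEnergySurface:
    def _disc(self, centers):
        centers = np.asarray(centers, float)
        return msm.Discretization(centers, [np.arange(len(centers))], 0.0, 0)

    def test_equal_mass_zero_delta_g(self):
        model = _toy_model([0.5, 0.5])
        disc = self._disc([[-1, 0], [1, 0]])
        grid = (np.array([-2.0, 0.0, 2.0]), np.array([-1.0, 1.0]))
        surf = msm.free_energy_surface(model, disc, grid)
        assert surf.g[0, 0] == surf.g[1, 0] == 0.0

    def test_80_20_delta_g(self):
        # dG = kT ln 4 = 2.5775 * ln 4 = 3.573 kJ/mol at 310 K
        model = _toy_model([0.8, 0.2])
        disc = self._disc([[-1, 0], [1, 0]])
        grid = (np.array([-2.0, 0.0, 2.0]), np.array([-1.0, 1.0]))
        surf = msm.free_energy_surface(model, disc, grid, temperature_k=310.0)
        assert surf.g[1, 0] - surf.g[0, 0] == pytest.approx(KT310 * np.log(4),
                                                            rel=1e-9)
        assert surf.g[1, 0] == pytest.approx(3.573, abs=2e-3)

    def test_microstates_summed_into_bin(self):
        model = _toy_model([0.3, 0.2, 0.5])
        disc = self._disc([[-1, 0], [-1.1, 0.1], [1, 0]])
        grid = (np.array([-2.0, 0.0, 2.0]), np.array([-1.0, 1.0]))
        surf = msm.free_energy_surface(model, disc, grid)
        w = np.exp(-surf.g / surf.kt)
        w /= w.sum()
        assert w[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_single_occupied_bin_valid(self):
        model = _toy_model([1.0 - 1e-12, 1e-12])
        disc = self._disc([[0.5, 0], [0.4, 0]])
        grid = (np.array([0.0, 1.0]), np.array([-1.0, 1.0]))
        surf = msm.free_energy_surface(model, disc, grid)
        assert surf.g[0, 0] == 0.0

    def test_centre_outside_grid_rejected(self):
        model = _toy_model([0.5, 0.5])
        disc = self._disc([[-5, 0], [1, 0]])
        grid = (np.array([-2.0, 0.0, 2.0]), np.array([-1.0, 1.0]))
        with pytest.raises(ValueError, match="outside"):
            msm.free_energy_surface(model, disc, grid)

    def test_kt_at_310(self):
        assert KT310 == pytest.approx(2.5775, abs=1e-4)


class TestBootstrapSurface:
    def _setup(self):
        rng = np.random.default_rng(0)
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        dtrajs = [sw.simulate_discrete_chain(T, 2000, seed=s) for s in range(6)]
        centers = np.array([[-1.0, 0.0], [1.0, 0.0]])
        disc = msm.Discretization(centers, dtrajs, 0.0, 0)
        grid = (np.array([-2.0, 0.0, 2.0]), np.array([-1.0, 1.0]))
        return dtrajs, disc, grid

    def test_identical_trajectories_zero_sd(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        d = sw.simulate_discrete_chain(T, 2000, seed=1)
        dtrajs = [d.copy() for _ in range(5)]
        disc = msm.Discretization(np.array([[-1.0, 0], [1.0, 0]]), dtrajs, 0.0, 0)
        grid = (np.array([-2.0, 0.0, 2.0]), np.array([-1.0, 1.0]))
        out = msm.bootstrap_surface(dtrajs, disc, grid, lag_ns=1, dt_ns=1,
                                    n_boot=5, seed=2)
        assert np.nanmax(out["sd"].g) == pytest.approx(0.0, abs=1e-12)

    def test_sd_nonnegative_and_mean_consistent(self):
        dtrajs, disc, grid = self._setup()
        out = msm.bootstrap_surface(dtrajs, disc, grid, lag_ns=1, dt_ns=1,
                                    n_boot=25, seed=3)
        assert (out["sd"].g[~out["sd"].mask] >= 0).all()
        full = msm.free_energy_surface(
            msm.estimate_msm(dtrajs, lag_ns=1, dt_ns=1), disc, grid)
        occupied = ~full.mask
        dev = np.abs(out["mean"].g - full.g)[occupied]
        assert np.nanmax(dev) < 0.3 * full.kt

    def test_requires_multiple_trajectories(self):
        dtrajs, disc, grid = self._setup()
        with pytest.raises(ValueError, match=">= 2"):
            msm.bootstrap_surface(dtrajs[:1], disc, grid, lag_ns=1, dt_ns=1,
                                  n_boot=5, seed=0)
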