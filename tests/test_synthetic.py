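import numpy as np
import pytest

from occlusim import thermal_energy
from occlusim import synthetic as sw

KT = thermal_energy()


class TestDiscreteChain:
    def test_identity_matrix_is_absorbing(self):
        seq = sw.simulate_discrete_chain(np.eye(3), 500, seed=0, start=1)
        assert (seq == 1).all()

    def test_empirical_transition_frequencies(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        seq = sw.simulate_discrete_chain(T, 200_000, seed=1)
        emp = np.zeros((2, 2))
        np.add.at(emp, (seq[:-1], seq[1:]), 1.0)
        emp /= emp.sum(axis=1, keepdims=True)
        assert np.abs(emp - T).max() < 0.005

    def test_stationary_occupancy_two_thirds(self):
        # pi T = pi solved by hand for [[0.9,0.1],[0.2,0.8]] -> pi = (2/3, 1/3)
        seq = sw.simulate_discrete_chain(np.array([[0.9, 0.1], [0.2, 0.8]]),
                                         200_000, seed=2)
        assert abs((seq == 0).mean() - 2 / 3) < 0.01

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sw.simulate_discrete_chain(np.array([[0.9, 0.2], [0.2, 0.8]]), 10, 0)
        with pytest.raises(ValueError, match=">= 0"):
            sw.simulate_discrete_chain(np.array([[1.1, -0.1], [0.2, 0.8]]), 10, 0)

    def test_reproducible(self):
        T = np.array([[0.5, 0.5], [0.5, 0.5]])
        a = sw.simulate_discrete_chain(T, 1000, seed=3)
        b = sw.simulate_discrete_chain(T, 1000, seed=3)
        assert (a == b).all()


class TestPotential:
    def test_invariants(self):
        with pytest.raises(ValueError):
            sw.Well((0, 0), -1.0, (0.3, 0.3))
        with pytest.raises(ValueError):
            sw.Well((0, 0), 1.0, (0.3, 0.0))
        with pytest.raises(ValueError):
            sw.PotentialSpec(wells=())

    def test_gradient_matches_finite_difference(self):
        pot = sw.default_profile("5HT").potential()
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 2))
        eps = 1e-6
        for d in range(2):
            step = np.zeros(2)
            step[d] = eps
            num = (pot.energy(x + step) - pot.energy(x - step)) / (2 * eps)
            assert np.allclose(pot.gradient(x)[:, d], num, atol=1e-5)


class TestLangevin:
    def test_harmonic_well_equipartition(self):
        # U = c x^2 -> per-axis variance kT/(2c)
        pot = sw.PotentialSpec(wells=(sw.Well((0, 0), 1e-9, (10, 10)),),
                               confinement=5.0)
        traj = sw.simulate_langevin(pot, 200_000, dt=0.002, diffusion=0.5, seed=3)
        expected = pot.kt / (2 * 5.0)
        assert np.allclose(traj.coords.var(axis=0), expected, rtol=0.05)

    def test_two_equal_wells_symmetric_occupancy(self):
        pot = sw.PotentialSpec(wells=(sw.Well((-1, 0), 8.0, (0.35, 0.35)),
                                      sw.Well((1, 0), 8.0, (0.35, 0.35))),
                               confinement=2.0)
        traj = sw.simulate_langevin(pot, 150_000, dt=0.01, diffusion=0.5,
                                    seed=4, substeps=2)
        p = (traj.coords[:, 0] > 0).mean()
        assert abs(p - 0.5) < 0.1

    def test_boltzmann_occupancy_ratio_two_kt(self):
        # equal-depth wells offset by confinement: dU between minima = 2 kT
        conf = 4.0
        r2 = float(np.sqrt(1.0 + 2 * KT / conf))
        pot = sw.PotentialSpec(wells=(sw.Well((-1.0, 0.0), 12.0, (0.3, 0.3)),
                                      sw.Well((r2, 0.0), 12.0, (0.3, 0.3))),
                               confinement=conf)
        traj = sw.simulate_langevin(pot, 250_000, dt=0.02, diffusion=0.5,
                                    seed=5, substeps=4)  # 1e6 integration steps
        x = traj.coords[:, 0]
        mid = 0.5 * (r2 - 1.0)
        ratio = (x < mid).mean() / (x > mid).mean()
        # oracle expectation from Boltzmann inversion of the same potential
        grid = (np.linspace(-2.6, 3.2, 120), np.linspace(-1.8, 1.8, 80))
        oracle = sw.analytic_surface(pot, grid=grid, integrate=True)
        w = np.exp(-oracle.g / KT)
        w /= w.sum()
        xs = oracle.x_centers
        expected = w[xs < mid].sum() / w[xs > mid].sum()
        assert ratio == pytest.approx(expected, rel=0.15)

    def test_equilibrium_histogram_matches_boltzmann(self):
        # per occupied bin (weight > 1e-3) within 0.3 kT at 1e6 steps
        conf = 4.0
        r2 = float(np.sqrt(1.0 + 2 * KT / conf))
        pot = sw.PotentialSpec(wells=(sw.Well((-1.0, 0.0), 12.0, (0.3, 0.3)),
                                      sw.Well((r2, 0.0), 12.0, (0.3, 0.3))),
                               confinement=conf)
        coords = np.vstack([
            sw.simulate_langevin(pot, 50_000, dt=0.02, diffusion=0.5,
                                 seed=60 + i, substeps=4).coords
            for i in range(10)])
        grid = (np.linspace(-2.8, 3.4, 21), np.linspace(-2.0, 2.0, 15))
        hist, _, _ = np.histogram2d(coords[:, 0], coords[:, 1], bins=grid)
        w = hist / hist.sum()
        oracle = sw.analytic_surface(pot, grid=grid, integrate=True)
        sel = w > 1e-3
        g = -KT * np.log(np.where(sel, w, 1.0))
        g -= g[sel].min()
        assert np.abs(g - oracle.g)[sel].max() < 0.3 * KT

    def test_determinism(self):
        pot = sw.default_profile("P5HT").potential()
        a = sw.simulate_langevin(pot, 500, dt=0.01, diffusion=0.5, seed=9)
        b = sw.simulate_langevin(pot, 500, dt=0.01, diffusion=0.5, seed=9)
        assert (a.coords == b.coords).all()

    def test_coarse_step_warns(self):
        pot = sw.PotentialSpec(wells=(sw.Well((0, 0), 50.0, (0.05, 0.05)),),
                               confinement=2.0)
        with pytest.warns(RuntimeWarning, match="too coarse"):
            sw.simulate_langevin(pot, 10, dt=1.0, diffusion=1.0, seed=0)

    def test_divergence_names_step(self):
        pot = sw.PotentialSpec(wells=(sw.Well((0, 0), 1.0, (0.3, 0.3)),),
                               confinement=1e12)
        with pytest.warns(RuntimeWarning), np.errstate(over="ignore"), \
                pytest.raises(RuntimeError, match="step"):
            sw.simulate_langevin(pot, 100, dt=1.0, diffusion=1.0, seed=0,
                                 x0=(5.0, 5.0))

    def test_bad_args(self):
        pot = sw.default_profile("apo").potential()
        with pytest.raises(ValueError):
            sw.simulate_langevin(pot, 1, dt=0.01, diffusion=0.5, seed=0)
        with pytest.raises(ValueError):
            sw.simulate_langevin(pot, 10, dt=-0.01, diffusion=0.5, seed=0)


class TestEmission:
    def test_oo_centre_hits_oo_endpoint(self):
        profile = sw.default_profile("5HT")
        traj = sw.LatentTrajectory(
            np.array([profile.oo_center, profile.oo_center]), dt=0.5, seed=0,
            profile=profile)
        table = sw.emit_features(traj, noise_sigma=0.0)
        assert table["tm6a_tm9up_nm"].iloc[0] == pytest.approx(1.75)
        assert table["tm1b_tm9up_nm"].iloc[0] == pytest.approx(1.45)

    def test_oc_centre_strong_interaction(self):
        profile = sw.default_profile("5HT")
        traj = sw.LatentTrajectory(
            np.array([profile.oc_center, profile.oc_center]), dt=0.5, seed=0,
            profile=profile)
        table = sw.emit_features(traj, noise_sigma=0.0)
        assert table["e_f335_kjmol"].iloc[0] == pytest.approx(-35.0)
        assert table["e_f335_kjmol"].iloc[0] < -20.0

    def test_energy_distance_correlation(self):
        profile = sw.default_profile("5HT")
        traj = sw.simulate_langevin(profile.potential(), 20_000, dt=0.02,
                                    diffusion=0.5, seed=11, substeps=4)
        traj.profile = profile
        table = sw.emit_features(traj, noise_sigma=0.02, seed=1)
        r = np.corrcoef(table["e_f335_kjmol"], table["tm6a_tm9up_nm"])[0, 1]
        assert r > 0.8

    def test_inner_gate_widens_with_occlusion(self):
        # emitted endpoints: inner-gate OC > OO, outer-gate OO > OC
        means = sw.DEFAULT_EMISSION_MEANS
        for obs in ("d87_f268_nm", "d87_v281_nm", "f268_y289_nm"):
            assert means[obs][1] > means[obs][0]
        for obs in ("tm6a_tm9up_nm", "tm1b_tm9up_nm"):
            assert means[obs][0] > means[obs][1]

    def test_missing_emission_mean_listed(self):
        profile = sw.default_profile("5HT")
        traj = sw.LatentTrajectory(np.zeros((3, 2)), dt=0.5, seed=0,
                                   profile=profile)
        with pytest.raises(KeyError, match="not_an_observable"):
            sw.emit_features(traj, observables=["not_an_observable"])


class TestEnsemble:
    def test_replica_count_and_distinctness(self):
        tables = sw.make_ligand_ensemble(sw.default_profile("B5HT"), 4, 200,
                                         seed=0, substeps=10)
        assert len(tables) == 4
        for i in range(4):
            for j in range(i + 1, 4):
                assert not tables[i].equals(tables[j])

    def test_master_seed_determinism(self):
        profile = sw.default_profile("5HT")
        a = sw.make_ligand_ensemble(profile, 3, 150, seed=5, substeps=10)
        b = sw.make_ligand_ensemble(profile, 3, 150, seed=5, substeps=10)
        for ta, tb in zip(a, b):
            assert ta.equals(tb)

    def test_5ht_visits_occluded_basin(self, small_5ht_ensemble):
        _, tables = small_5ht_ensemble
        # at least one replica reaches the occluded gate distance range
        reached = any((t["tm6a_tm9up_nm"] < 1.40).any() for t in tables)
        assert reached

    def test_depth_ordering_encodes_landscape(self):
        p = {name: sw.default_profile(name) for name in sw.LIGAND_NAMES}
        assert p["5HT"].oc_depth > p["5HT"].oo_depth
        assert p["B5HT"].oo_depth > p["B5HT"].oc_depth
        assert p["COC"].oo_depth > p["COC"].oc_depth
        assert p["M5HT"].oo_depth > p["M5HT"].oc_depth
        assert p["P5HT"].oc_depth == pytest.approx(p["P5HT"].oo_depth, rel=0.1)


class TestPatchClamp:
    def test_zero_concentration_flat_zero(self):
        rates = sw.REFERENCE_RATES["5HT"]
        trace = sw.simulate_patch_clamp(rates, {"mode": "peak_0mV",
                                                "concentration_um": 0.0})
        assert np.allclose(trace.current, 0.0)

    def test_saturating_peak_is_exact_monoexponential(self):
        rates = sw.REFERENCE_RATES["5HT"]
        sat = 1000.0 * rates.k_flip / rates.K_on
        trace = sw.simulate_patch_clamp(
            rates, {"mode": "peak_0mV", "concentration_um": sat,
                    "amplitude": 2.0})
        amp = trace.current[0]
        model = amp * np.exp(-rates.k_flip * trace.time)
        assert np.abs(trace.current - model).max() < 1e-10

    def test_recovery_amplitude_sequence(self):
        rates = sw.REFERENCE_RATES["5HT"]  # K_off = 0.55 s^-1
        washes = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        amps = sw.recovery_amplitudes(rates, washes)
        assert np.allclose(amps, 1.0 - np.exp(-0.55 * washes))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="concentration"):
            sw.simulate_patch_clamp(sw.REFERENCE_RATES["5HT"],
                                    {"mode": "peak_0mV", "concentration_um": -1})

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            sw.simulate_patch_clamp(sw.REFERENCE_RATES["5HT"],
                                    {"mode": "sideways", "concentration_um": 1})

    def test_trace_invariants(self):
        rates = sw.REFERENCE_RATES["P5HT"]
        trace = sw.simulate_patch_clamp(
            rates, {"mode": "peak_recovery", "concentration_um": 10.0,
                    "wash_intervals_s": [0.5, 1, 2]}, noise_sigma=0.01, seed=1)
        assert (np.diff(trace.time) > 0).all()
        assert len(trace.protocol["pulse_windows"]) == 4

    def test_rates_positivity(self):
        with pytest.raises(ValueError, match="K_off"):
            sw.TransportRates(1.0, 1.0, -0.1, 0.1, 1.0)


class TestAnalyticSurface:
    def test_single_well_minimum_zero_at_centre(self):
        pot = sw.PotentialSpec(wells=(sw.Well((0.5, -0.25), 10.0, (0.3, 0.3)),),
                               confinement=0.0)
        grid = (np.linspace(-1.0, 2.0, 61), np.linspace(-1.75, 1.25, 61))
        surf = sw.analytic_surface(pot, grid=grid)
        i, j = np.unravel_index(np.argmin(surf.g), surf.g.shape)
        assert surf.g[i, j] == 0.0
        assert abs(surf.x_centers[i] - 0.5) < 0.05
        assert abs(surf.y_centers[j] + 0.25) < 0.05

    def test_two_well_depth_difference(self):
        # depths 10 and 8 kJ/mol, no confinement -> dG between minima = 2
        pot = sw.PotentialSpec(wells=(sw.Well((-1, 0), 10.0, (0.3, 0.3)),
                                      sw.Well((1, 0), 8.0, (0.3, 0.3))),
                               confinement=0.0)
        grid = (np.arange(-2.05, 2.06, 0.1), np.arange(-1.05, 1.06, 0.1))
        surf = sw.analytic_surface(pot, grid=grid)
        xi1 = np.argmin(np.abs(surf.x_centers + 1))
        xi2 = np.argmin(np.abs(surf.x_centers - 1))
        yj = np.argmin(np.abs(surf.y_centers))
        assert surf.g[xi2, yj] - surf.g[xi1, yj] == pytest.approx(2.0, abs=1e-9)

    def test_grid_refinement_converges(self):
        pot = sw.PotentialSpec(wells=(sw.Well((0, 0), 5.0, (0.5, 0.5)),),
                               confinement=1.0)
        coarse = sw.analytic_surface(pot, bins=100)
        fine = sw.analytic_surface(
            pot, grid=(np.linspace(coarse.x_edges[0], coarse.x_edges[-1], 201),
                       np.linspace(coarse.y_edges[0], coarse.y_edges[-1], 201)))
        # every coarse bin contains a 2x2 block of fine bins
        block = fine.g.reshape(100, 2, 100, 2).mean(axis=(1, 3))
        assert np.abs(block - coarse.g).max() < 0.1

    def test_uncovering_grid_rejected(self):
        pot = sw.PotentialSpec(wells=(sw.Well((0, 0), 5.0, (0.5, 0.5)),))
        grid = (np.linspace(-1, 1, 11), np.linspace(-1, 1, 11))
        with pytest.raises(ValueError, match="3 sigma"):
            sw.analytic_surface(pot, grid=grid)
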