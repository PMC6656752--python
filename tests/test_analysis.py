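"""Density, RDF, nearest-neighbour, MSD and solubility observables."""

import math

import numpy as np
import pytest

from radonsol.analysis import (
    count_dissolved_radon,
    mass_density,
    msd_diffusion,
    nearest_neighbour_distance,
    radial_distribution,
    solubility,
)
from radonsol.constants import N_AVOGADRO
from radonsol.engine.system import ParamSystem, SystemState, Trajectory
from radonsol.forcefield import radon_topology, water_topology


def _static_trajectory(system, positions, box, n_frames=4):
    traj = Trajectory(system=system)
    for k in range(n_frames):
        st = SystemState(positions, np.zeros_like(positions), np.asarray(box))
        traj.add_frame(float(k), st)
        rho = system.total_mass / st.volume / (N_AVOGADRO * 1e-21)
        traj.log(float(k), 298.0, 1.0, st.volume, 0.0, 0.0, rho)
    return traj


class TestMassDensity:
    def test_static_radon_frame_closed_form(self):
        """100 Rn in a fixed 10x10x10 nm box: rho = 100*222/(N_A * 1e-18 cm^3)."""
        system = ParamSystem([(radon_topology(), 100)])
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 10, (100, 3))
        traj = _static_trajectory(system, pos, [10.0, 10.0, 10.0])
        rho, _ = mass_density(traj)
        expected = 100 * 222.0176 / N_AVOGADRO / 1e-18  # 1000 nm^3 = 1e-18 cm^3
        assert rho == pytest.approx(expected, rel=1e-6)

    def test_empty_window_rejected(self):
        system = ParamSystem([(radon_topology(), 1)])
        traj = _static_trajectory(system, np.zeros((1, 3)), [5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            mass_density(traj, window=(100.0, 200.0))


class TestRadialDistribution:
    def test_ideal_gas_is_flat(self):
        system = ParamSystem([(radon_topology(), 400)])
        rng = np.random.default_rng(1)
        frames = [SystemState(rng.uniform(0, 8, (400, 3)),
                              np.zeros((400, 3)), np.full(3, 8.0))
                  for _ in range(8)]
        idx = np.arange(400)
        df = radial_distribution(frames, None, idx, idx, dr=0.1)
        inner = df[(df.r > 1.0) & (df.r < 3.5)]
        assert np.allclose(inner.g, 1.0, atol=0.1)

    def test_rdf_counts_integrate_to_n_minus_one(self):
        """4 pi rho int g r^2 dr over the half-box sphere ~ fraction of
        particles in that sphere (ideal gas)."""
        system = ParamSystem([(radon_topology(), 300)])
        rng = np.random.default_rng(2)
        frames = [SystemState(rng.uniform(0, 6, (300, 3)),
                              np.zeros((300, 3)), np.full(3, 6.0))
                  for _ in range(10)]
        idx = np.arange(300)
        df = radial_distribution(frames, None, idx, idx, dr=0.05)
        rho = 300 / 6.0**3
        integral = 4 * math.pi * rho * np.trapezoid(
            df.g * df.r**2, df.r)
        expected = 299 * (4 / 3 * math.pi * 3.0**3) / 6.0**3
        assert integral == pytest.approx(expected, rel=0.05)

    def test_excluded_volume_hole_in_dense_fluid(self):
        """A minimized radon liquid shows g(r) = 0 inside the hard core."""
        from radonsol.engine import MDConfig
        from radonsol.synthetic import BoxRecipe, build_box

        cfg = MDConfig(cutoff=0.8, switch_start=0.7, ensemble="nvt")
        system, state = build_box(
            BoxRecipe({"radon": 64}, target_density=4.4, seed=3), config=cfg)
        idx = np.arange(64)
        df = radial_distribution([state], None, idx, idx, dr=0.02)
        core = df[df.r < 0.8 * 0.453]
        assert np.all(core.g == 0.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radial_distribution([SystemState(np.zeros((1, 3)),
                                             np.zeros((1, 3)),
                                             np.full(3, 5.0))],
                                None, np.array([]), np.array([0]))

    def test_rmax_capped_at_half_box(self):
        st = SystemState(np.zeros((2, 3)), np.zeros((2, 3)), np.full(3, 4.0))
        with pytest.raises(ValueError):
            radial_distribution([st], None, np.array([0]), np.array([1]),
                                r_max=3.0)


class TestNearestNeighbour:
    def test_two_fixed_atoms(self):
        system = ParamSystem([(radon_topology(), 2)])
        pos = np.array([[0.0, 0, 0], [0.3, 0, 0]])
        st = SystemState(pos, np.zeros_like(pos), np.full(3, 5.0))
        assert nearest_neighbour_distance([st], system, [0, 1]) == pytest.approx(0.3)

    def test_cubic_lattice_spacing(self):
        a = 0.41
        n = 4
        pts = np.array([(i * a, j * a, k * a) for i in range(n)
                        for j in range(n) for k in range(n)])
        system = ParamSystem([(radon_topology(), len(pts))])
        st = SystemState(pts, np.zeros_like(pts), np.full(3, n * a))
        r = nearest_neighbour_distance([st], system, np.arange(len(pts)))
        assert r == pytest.approx(a, rel=1e-9)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        n = 40
        pts = rng.uniform(0, 3, (n, 3))
        system = ParamSystem([(radon_topology(), n)])
        box = np.full(3, 3.0)
        st = SystemState(pts, np.zeros_like(pts), box)
        ours = nearest_neighbour_distance([st], system, np.arange(n))
        mins = []
        for i in range(n):
            best = np.inf
            for j in range(n):
                if i == j:
                    continue
                d = pts[i] - pts[j]
                d -= box * np.round(d / box)
                best = min(best, np.linalg.norm(d))
            mins.append(best)
        assert ours == pytest.approx(np.mean(mins), rel=1e-12)

    def test_single_molecule_rejected(self):
        system = ParamSystem([(radon_topology(), 1)])
        st = SystemState(np.zeros((1, 3)), np.zeros((1, 3)), np.full(3, 5.0))
        with pytest.raises(ValueError):
            nearest_neighbour_distance([st], system, [0])


class TestMSDDiffusion:
    @staticmethod
    def _random_walk_traj(d_target, n_atoms=40, n_frames=200, dt=0.1, seed=7):
        system = ParamSystem([(radon_topology(), n_atoms)])
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, math.sqrt(2 * d_target * dt),
                           (n_frames, n_atoms, 3))
        pos = np.cumsum(steps, axis=0)
        traj = Trajectory(system=system)
        for k in range(n_frames):
            traj.add_frame(k * dt, SystemState(pos[k], np.zeros((n_atoms, 3)),
                                               np.full(3, 100.0)))
        return traj

    def test_immobile_particles_have_zero_diffusion(self):
        system = ParamSystem([(radon_topology(), 5)])
        traj = Trajectory(system=system)
        pos = np.random.default_rng(0).uniform(0, 5, (5, 3))
        for k in range(50):
            traj.add_frame(k * 0.1, SystemState(pos, np.zeros_like(pos),
                                                np.full(3, 10.0)))
        d, _ = msd_diffusion(traj, np.arange(5), (0.5, 2.0))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_overdamped_random_walk_matches_closed_form(self):
        d_target = 1.5e-3
        traj = self._random_walk_traj(d_target)
        d, d_err = msd_diffusion(traj, np.arange(40), (1.0, 8.0))
        assert d == pytest.approx(d_target, rel=0.15)

    def test_window_beyond_trajectory_rejected(self):
        traj = self._random_walk_traj(1e-3, n_frames=50)
        with pytest.raises(ValueError):
            msd_diffusion(traj, np.arange(40), (1.0, 100.0))


class TestDissolvedRadon:
    @staticmethod
    def _water_radon_frame():
        from radonsol.engine import MDConfig
        from radonsol.synthetic import BoxRecipe, build_box

        cfg = MDConfig(cutoff=0.7, switch_start=0.6, ensemble="nvt")
        return build_box(BoxRecipe({"water": 100, "radon": 3}, seed=8),
                         config=cfg)

    def test_no_radon_gives_zero(self):
        system, state = ParamSystem([(water_topology(), 8)]), None
        from radonsol.synthetic import BoxRecipe, build_box
        system, state = build_box(BoxRecipe({"water": 8}, seed=1),
                                  minimize=False)
        count, c = count_dissolved_radon(state, system)
        assert count == 0 and c == 0.0

    def test_radon_inside_bulk_liquid_counts_as_dissolved(self):
        system, state = self._water_radon_frame()
        count, c = count_dissolved_radon(state, system)
        assert count == 3
        assert c > 0

    def test_criterion_monotonicity(self):
        """Count never increases with stricter neighbour threshold and never
        decreases with larger capture radius."""
        system, state = self._water_radon_frame()
        counts_k = [count_dissolved_radon(state, system, min_neighbours=k)[0]
                    for k in (1, 2, 4, 8, 16)]
        assert all(a >= b for a, b in zip(counts_k, counts_k[1:]))
        counts_r = [count_dissolved_radon(state, system, r_c=r)[0]
                    for r in (0.3, 0.5, 0.7, 0.9)]
        assert all(a <= b for a, b in zip(counts_r, counts_r[1:]))


class TestSolubility:
    def test_published_water_arithmetic(self):
        res = solubility(6.451e-4, 9.36e-3)
        assert round(res.value, 2) == 0.07
        assert res.value == pytest.approx(0.0689, abs=5e-4)

    def test_published_hexane_arithmetic(self):
        res = solubility(1.333e-2, 9.36e-3)
        assert round(res.value, 2) == 1.42

    def test_zero_concentration(self):
        assert solubility(0.0, 9.36e-3).value == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            solubility(1.0, 0.0)

    def test_homogeneity(self):
        base = solubility(2.0e-3, 9.36e-3).value
        for k in (0.5, 2.0, 7.3):
            assert solubility(k * 2.0e-3, 9.36e-3).value == pytest.approx(
                k * base, rel=1e-12)

    def test_error_propagation_quadrature(self):
        res = solubility(1.0, 2.0, 0.1, 0.2)
        expected = 0.5 * math.sqrt(0.1**2 + 0.1**2)
        assert res.stderr == pytest.approx(expected)
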