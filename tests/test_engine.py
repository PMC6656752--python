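"""MD engine: potentials, forces, Ewald, integrator, constraints, barostat."""

import math

import numpy as np
import pytest

from radonsol.constants import COULOMB, KB, KJ_PER_KCAL
from radonsol.engine import (
    MDConfig,
    ParamSystem,
    SystemState,
    constrain_rigid_water,
    lj_pair_energy,
    maxwell_boltzmann_velocities,
    run_md,
    total_energy_forces,
)
from radonsol.engine.md import EngineError, ForceField
from radonsol.forcefield import (
    PairParams,
    ion_topology,
    mix_pair_params,
    radon_topology,
    standard_parameter_table,
    water_topology,
)
from radonsol.synthetic import BoxRecipe, build_box


@pytest.fixture(scope="module")
def table():
    return standard_parameter_table()


def _random_water_ion_box(seed=3):
    """Small neutral box with water, radon and an ion pair (all force terms)."""
    wat = water_topology()
    system = ParamSystem([(wat, 8), (radon_topology(), 2),
                          (ion_topology("Na"), 1), (ion_topology("Cl"), 1)])
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.2, 1.4, 3)
    centers = [(x, y, z) for x in grid for y in grid for z in grid]
    pos = np.vstack([wat.coords0 + np.array(centers[i]) for i in range(8)]
                    + [np.array([centers[8 + k]]) for k in range(4)])
    pos += rng.normal(0, 0.01, pos.shape)
    state = SystemState(pos, np.zeros_like(pos), np.full(3, 1.6))
    return system, state


class TestLJPairEnergy:
    def test_root_at_sigma(self):
        assert lj_pair_energy(PairParams(0.541, 0.453), 0.453) == pytest.approx(0.0)

    def test_minimum_at_rmin(self):
        p = PairParams(0.541, 0.453)
        r_min = 2 ** (1 / 6) * 0.453
        assert lj_pair_energy(p, r_min) == pytest.approx(-0.541, rel=1e-12)

    def test_radon_pair_hand_evaluation(self, table):
        p = mix_pair_params(table["Rn"], table["Rn"])
        r = 0.6
        sr6 = (0.453 / r) ** 6
        expected = 4 * 0.541 * (sr6**2 - sr6)
        assert lj_pair_energy(p, r) == pytest.approx(expected, rel=1e-12)

    def test_zero_beyond_cutoff(self):
        assert lj_pair_energy(PairParams(1.0, 0.4), 1.6) == 0.0

    def test_switching_is_continuous_at_boundaries(self):
        p = PairParams(0.3, 0.9)
        for r0 in (1.2, 1.5):
            below = lj_pair_energy(p, r0 - 1e-9)
            above = lj_pair_energy(p, r0 + 1e-9)
            assert below == pytest.approx(above, abs=1e-7)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            lj_pair_energy(PairParams(1.0, 0.4), 0.0)


class TestEnergyForces:
    def test_isolated_pair_beyond_cutoff_is_inert(self):
        system = ParamSystem([(radon_topology(), 2)])
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        state = SystemState(pos, np.zeros((2, 3)), np.full(3, 8.0))
        e, f = total_energy_forces(state, system,
                                   MDConfig(cutoff=1.5, switch_start=1.2))
        assert e == 0.0
        assert np.all(f == 0.0)

    def test_neighbour_list_matches_brute_force_lj(self):
        """Engine energy (pair list + switching) equals an independent
        all-pairs evaluation on random radon boxes."""
        cfg = MDConfig(cutoff=1.0, switch_start=0.8, ensemble="nvt")
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 60
            system = ParamSystem([(radon_topology(), n)])
            pos = rng.uniform(0, 3.0, (n, 3))
            box = np.full(3, 3.0)
            state = SystemState(pos, np.zeros((n, 3)), box)
            e, _ = total_energy_forces(state, system, cfg)
            p = PairParams(0.541, 0.453)
            e_ref = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    d = pos[i] - pos[j]
                    d -= box * np.round(d / box)
                    e_ref += lj_pair_energy(p, float(np.linalg.norm(d)),
                                            cfg.cutoff, cfg.switch_start)
            assert e == pytest.approx(e_ref, rel=1e-8)

    def test_forces_are_exact_gradient(self):
        """Central finite differences of the energy match the forces on a
        random box exercising LJ, Ewald, exclusions and constraints."""
        system, state = _random_water_ion_box()
        cfg = MDConfig(cutoff=0.7, switch_start=0.6, ensemble="nvt",
                       ewald_accuracy=1e-6)
        ff = ForceField(system, cfg, use_tail_correction=False)
        fr = ff.compute(state)
        eps = 2e-6
        for (i, ax) in [(0, 0), (3, 1), (11, 2), (24, 0), (26, 2), (27, 1)]:
            sp = state.copy()
            sp.positions[i, ax] += eps
            sm = state.copy()
            sm.positions[i, ax] -= eps
            f_num = -(ff.compute(sp).e_pot - ff.compute(sm).e_pot) / (2 * eps)
            assert f_num == pytest.approx(fr.forces[i, ax],
                                          rel=1e-5, abs=1e-4)

    def test_newtons_third_law(self):
        system, state = _random_water_ion_box()
        cfg = MDConfig(cutoff=0.7, switch_start=0.6, ensemble="nvt")
        _, forces = total_energy_forces(state, system, cfg)
        assert np.abs(forces.sum(axis=0)).max() < 1e-9

    def test_translation_invariance(self):
        system, state = _random_water_ion_box()
        cfg = MDConfig(cutoff=0.7, switch_start=0.6, ensemble="nvt")
        e0, _ = total_energy_forces(state, system, cfg)
        shifted = state.copy()
        shifted.positions += np.array([0.71, -1.13, 3.37])
        e1, _ = total_energy_forces(shifted, system, cfg)
        assert e1 == pytest.approx(e0, rel=1e-10)

    def test_madelung_constant_of_rock_salt(self):
        """Ewald total Coulomb energy of a perfect NaCl lattice reproduces
        the Madelung constant to 6 digits."""
        a = 0.28
        n = 4
        sites = [((i + j + k) % 2, (i * a, j * a, k * a))
                 for i in range(n) for j in range(n) for k in range(n)]
        na = [p for t, p in sites if t == 0]
        cl = [p for t, p in sites if t == 1]
        system = ParamSystem([(ion_topology("Na"), len(na)),
                              (ion_topology("Cl"), len(cl))])
        state = SystemState(np.array(na + cl), np.zeros((n**3, 3)),
                            np.full(3, n * a))
        cfg = MDConfig(cutoff=0.55, switch_start=0.5, ensemble="nvt",
                       ewald_accuracy=1e-7)
        fr = ForceField(system, cfg, use_tail_correction=False).compute(state)
        e_coul = (fr.components["coul_real"] + fr.components["coul_recip"]
                  + fr.components["coul_self"])
        madelung = -e_coul * 2 * a / (n**3 * COULOMB)
        assert madelung == pytest.approx(1.747565, abs=2e-6)

    def test_non_neutral_box_with_ewald_rejected(self):
        system = ParamSystem([(ion_topology("Na"), 2)])
        cfg = MDConfig(cutoff=0.7, switch_start=0.6)
        with pytest.raises(EngineError):
            ForceField(system, cfg)


class TestConstraints:
    def test_distorted_water_restored_exactly(self):
        system = ParamSystem([(water_topology(), 1)])
        good = water_topology().coords0 + 1.0
        state = SystemState(good + np.random.default_rng(0).normal(0, 0.02, (3, 3)),
                            np.zeros((3, 3)), np.full(3, 5.0))
        constrain_rigid_water(system, state)
        d01 = np.linalg.norm(state.positions[0] - state.positions[1])
        d02 = np.linalg.norm(state.positions[0] - state.positions[2])
        assert d01 == pytest.approx(0.1, abs=1e-9)
        assert d02 == pytest.approx(0.1, abs=1e-9)

    def test_rigid_geometry_preserved_along_trajectory(self):
        """O-H distances stay within 1e-6 nm of the model geometry over a
        thermalized run."""
        cfg_b = MDConfig(cutoff=0.45, switch_start=0.40, ensemble="nvt")
        system, state = build_box(BoxRecipe({"water": 27}, seed=5),
                                  config=cfg_b)
        rng = np.random.default_rng(1)
        state.velocities = maxwell_boltzmann_velocities(system, 298, rng,
                                                        state.positions)
        cfg = MDConfig(cutoff=0.45, switch_start=0.40, ensemble="nvt", seed=2,
                       n_steps=500, snapshot_every=50)
        traj = run_md(system, state, cfg)
        worst = 0.0
        for st in traj.frames:
            d = np.linalg.norm(st.positions[system.con_idx[:, 0]]
                               - st.positions[system.con_idx[:, 1]], axis=1)
            worst = max(worst, float(np.abs(d - system.con_d).max()))
        assert worst < 1e-6


class TestIntegrator:
    def test_zero_steps_returns_initial_frame_only(self):
        system, state = _random_water_ion_box()
        cfg = MDConfig(cutoff=0.7, switch_start=0.6, ensemble="nvt", n_steps=0)
        traj = run_md(system, state, cfg)
        assert len(traj) == 1
        assert traj.times == [0.0]

    def test_identical_seeds_are_bit_identical(self):
        cfg_b = MDConfig(cutoff=0.45, switch_start=0.40, ensemble="nvt")
        system, state = build_box(BoxRecipe({"water": 27}, seed=3),
                                  config=cfg_b)
        cfg = MDConfig(cutoff=0.45, switch_start=0.40, ensemble="npt", seed=42,
                       n_steps=60)
        a = run_md(system, state, cfg)
        b = run_md(system, state, cfg)
        assert np.array_equal(a.frames[-1].positions, b.frames[-1].positions)
        assert a.thermo.equals(b.thermo)

    def test_harmonic_oscillator_energy_conservation(self):
        """gamma = 0 (NVE): a bonded diatomic keeps its energy to better than
        1e-4 relative over 1e5 velocity-Verlet steps."""
        from radonsol.forcefield import hexane_topology

        # use one hexane C-C bond as the spring: build a 2-site molecule
        import radonsol.forcefield as ffmod

        topo = ffmod.MoleculeTopology(
            "diatomic", ["C_b", "C_b"], np.zeros(2),
            np.array([[0.0, 0, 0], [0.16, 0, 0]]), bonds=[(0, 1)]).finalize()
        system = ParamSystem([(topo, 1)])
        state = SystemState(topo.coords0 + 2.0, np.zeros((2, 3)),
                            np.full(3, 4.0))
        cfg = MDConfig(cutoff=1.0, switch_start=0.9, ensemble="nve",
                       langevin_gamma=0.0, n_steps=100_000, log_every=1000,
                       snapshot_every=0)
        traj = run_md(system, state, cfg)
        th = traj.thermo
        e = th.e_pot + th.e_kin
        # compare segment means so the bounded O(dt^2) oscillation of the
        # shadow Hamiltonian does not mask the (absent) secular drift
        first = e.iloc[: len(e) // 10].mean()
        last = e.iloc[-len(e) // 10:].mean()
        assert abs(last - first) / max(abs(first), 1e-3) < 1e-4

    def test_water_box_nve_energy_drift(self):
        """Full force field (Ewald + constraints): relative drift of the
        total energy stays small over a 10 ps NVE run."""
        cfg_b = MDConfig(cutoff=0.45, switch_start=0.40, ensemble="nvt")
        system, state = build_box(BoxRecipe({"water": 27}, seed=5),
                                  config=cfg_b)
        rng = np.random.default_rng(4)
        state.velocities = maxwell_boltzmann_velocities(system, 150, rng,
                                                        state.positions)
        cfg = MDConfig(cutoff=0.45, switch_start=0.40, ensemble="nve", seed=2,
                       n_steps=10_000, log_every=100, snapshot_every=0,
                       ewald_accuracy=1e-6)
        traj = run_md(system, state, cfg)
        th = traj.thermo
        e = th.e_pot + th.e_kin
        drift = abs(e.iloc[-1] - e.iloc[0]) / abs(e.iloc[0])
        assert drift < 1e-3

    def test_free_particle_equipartition(self):
        """Long Langevin run of non-interacting atoms: velocity variance
        matches kT/m within 3 standard errors."""
        n = 600
        system = ParamSystem([(radon_topology(), n)])
        rng = np.random.default_rng(1)
        state = SystemState(rng.uniform(0, 300, (n, 3)), np.zeros((n, 3)),
                            np.full(3, 300.0))
        state.velocities = maxwell_boltzmann_velocities(system, 298, rng)
        cfg = MDConfig(cutoff=1.0, switch_start=0.9, ensemble="nvt", seed=7,
                       langevin_gamma=20.0, n_steps=12_000, log_every=20,
                       snapshot_every=0)
        traj = run_md(system, state, cfg)
        temps = traj.thermo.temperature_K.iloc[100:]
        # ~1/gamma correlation time -> nearly independent samples at 20 fs
        se = temps.std() / math.sqrt(len(temps) / 3.0)
        assert abs(temps.mean() - 298.0) < 3 * se

    def test_free_particle_langevin_diffusion(self):
        """D of a free Langevin particle approaches kT/(m gamma)."""
        from radonsol.analysis import msd_diffusion

        n = 400
        system = ParamSystem([(radon_topology(), n)])
        rng = np.random.default_rng(2)
        state = SystemState(rng.uniform(0, 500, (n, 3)), np.zeros((n, 3)),
                            np.full(3, 500.0))
        state.velocities = maxwell_boltzmann_velocities(system, 298, rng)
        gamma = 20.0
        cfg = MDConfig(cutoff=1.0, switch_start=0.9, ensemble="nvt", seed=9,
                       langevin_gamma=gamma, n_steps=20_000, log_every=500,
                       snapshot_every=100, timestep_fs=2.0)
        traj = run_md(system, state, cfg)
        d, d_err = msd_diffusion(traj, np.arange(n), (5.0, 18.0))
        mass = 222.0176
        d_expected = KB * KJ_PER_KCAL * 298.0 / (mass * gamma)
        assert d == pytest.approx(d_expected, rel=0.1)

    def test_nonfinite_energy_aborts_with_diagnostics(self):
        system = ParamSystem([(radon_topology(), 2)])
        pos = np.zeros((2, 3))  # exact overlap: undefined pair energy
        state = SystemState(pos, np.zeros((2, 3)), np.full(3, 8.0))
        cfg = MDConfig(cutoff=1.5, switch_start=1.2, ensemble="nvt",
                       n_steps=50)
        with pytest.raises((EngineError, FloatingPointError, ValueError)):
            run_md(system, state, cfg)


class TestBarostat:
    def test_lj_gas_mean_pressure_at_target(self):
        """NPT radon gas: the mean instantaneous pressure sits at 1 bar
        within the statistical error of the run."""
        system, state = build_box(
            BoxRecipe({"radon": 100}, geometry="pure_gas",
                      target_density=9.36e-3, seed=11),
            config=MDConfig(cutoff=1.5, switch_start=1.2, ensemble="nvt"))
        rng = np.random.default_rng(3)
        state.velocities = maxwell_boltzmann_velocities(system, 298, rng)
        cfg = MDConfig(cutoff=1.5, switch_start=1.2, ensemble="npt", seed=13,
                       n_steps=30_000, langevin_gamma=2.0,
                       compressibility_per_bar=1.0, barostat_tau_ps=1.0,
                       log_every=50, snapshot_every=0, neighbor_skin=0.5)
        traj = run_md(system, state, cfg)
        th = traj.thermo
        p = th.pressure_bar.iloc[len(th) // 3:]
        se = p.std() / math.sqrt(len(p) / 10.0)
        assert abs(p.mean() - 1.0) < max(3 * se, 0.15)

    def test_box_collapse_raises(self):
        system, state = _random_water_ion_box()
        cfg = MDConfig(cutoff=0.7, switch_start=0.6)
        state.box[:] = 1.3  # below twice the cutoff
        with pytest.raises(EngineError):
            ForceField(system, cfg).compute(state)
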