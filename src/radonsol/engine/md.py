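"""Force evaluation, BAOAB Langevin integration, barostat, run driver.

The integrator is the BAOAB splitting of Langevin dynamics (kick/drift/
Ornstein-Uhlenbeck/drift/kick); with gamma = 0 it reduces exactly to velocity
Verlet.  Rigid water is handled by SHAKE position projections and RATTLE
velocity projections after every sub-step (g-BAOAB).  Constant pressure uses
an overdamped Langevin barostat (stochastic cell rescaling) acting on
molecule centres of mass, with the molecular-virial instantaneous pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .. import constants
from ..constants import BAR, COULOMB, KB, KJ_PER_KCAL
from . import kernels
from .system import MDConfig, ParamSystem, SystemState, Trajectory


class EngineError(RuntimeError):
    """Raised when a run becomes unphysical; carries the offending state."""

    def __init__(self, message, state: SystemState | None = None):
        super().__init__(message)
        self.state = state


@dataclass
class ForceResult:
    e_pot: float
    forces: np.ndarray
    virial_mol: float        # molecular virial incl. tail, kcal/mol
    components: dict


def lj_pair_energy(pair, r: float, cutoff: float = 1.5,
                   switch_start: float = 1.2) -> float:
    """Switched Lennard-Jones energy U = 4 eps (sigma^12/r^12 - sigma^6/r^6)
    of one pair at separation r (nm), multiplied by the C1 switching factor
    between switch_start and cutoff and zero beyond the cutoff."""
    if r <= 0:
        raise ValueError("r must be > 0")
    if r >= cutoff:
        return 0.0
    sr6 = (pair.sigma / r) ** 6
    u = 4.0 * pair.epsilon * (sr6 * sr6 - sr6)
    if r > switch_start:
        rc2, rs2, r2 = cutoff**2, switch_start**2, r * r
        u *= (rc2 - r2) ** 2 * (rc2 + 2 * r2 - 3 * rs2) / (rc2 - rs2) ** 3
    return u


# ---------------------------------------------------------------------------
# Ewald setup and LJ tail corrections


def ewald_parameters(cutoff: float, box: np.ndarray, accuracy: float = 1e-5):
    """Splitting parameter and half-space k-vector list for the current box.

    alpha is set so erfc(alpha rc) ~ accuracy at the cutoff; the reciprocal
    sum keeps k below the matching Gaussian cutoff.
    """
    s = math.sqrt(-math.log(accuracy))
    alpha = s / cutoff  # erfc(s) ~ accuracy/(s sqrt(pi)) at the cutoff
    kcut = 2.0 * alpha * s
    nmax = np.maximum(1, np.ceil(kcut * box / (2.0 * math.pi)).astype(int))
    nx, ny, nz = np.meshgrid(np.arange(0, nmax[0] + 1),
                             np.arange(-nmax[1], nmax[1] + 1),
                             np.arange(-nmax[2], nmax[2] + 1), indexing="ij")
    n = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], axis=1)
    # half space: nx > 0, or nx == 0 and ny > 0, or nx == ny == 0 and nz > 0
    half = ((n[:, 0] > 0)
            | ((n[:, 0] == 0) & (n[:, 1] > 0))
            | ((n[:, 0] == 0) & (n[:, 1] == 0) & (n[:, 2] > 0)))
    k2 = np.sum((2.0 * math.pi * n / box) ** 2, axis=1)
    keep = half & (k2 <= kcut * kcut)
    return alpha, np.ascontiguousarray(n[keep], dtype=np.int32)


def lj_tail_integrals(system: ParamSystem, cutoff: float, switch_start: float):
    """sum_{ab} N_a N_b of the missing-energy and missing-virial integrals
    beyond the switching region, for homogeneous-fluid tail corrections.

    Returns (IE, IW) with E_tail = 2 pi IE / V and W_tail = 2 pi IW / V
    (so P_tail = W_tail / (3 V)).
    """
    rc, rs = cutoff, switch_start
    r = np.linspace(rs, 6.0 * rc, 4000)
    rc2, rs2 = rc * rc, rs * rs
    s = np.where(r < rc,
                 (rc2 - r**2) ** 2 * (rc2 + 2 * r**2 - 3 * rs2) / (rc2 - rs2) ** 3,
                 0.0)
    dsdr = np.where(r < rc,
                    12.0 * r * (rc2 - r**2) * (rs2 - r**2) / (rc2 - rs2) ** 3,
                    0.0)
    IE = 0.0
    IW = 0.0
    counts = system.type_counts
    for a in range(len(counts)):
        for b in range(len(counts)):
            eps = system.eps_table[a, b]
            if eps == 0.0 or counts[a] == 0 or counts[b] == 0:
                continue
            sig = system.sig_table[a, b]
            sr6 = (sig / r) ** 6
            u = 4.0 * eps * (sr6**2 - sr6)
            dudr = -24.0 * eps * (2.0 * sr6**2 - sr6) / r
            u_miss = (1.0 - s) * u
            dumiss = (1.0 - s) * dudr - dsdr * u
            w_miss = -r * dumiss
            IE += counts[a] * counts[b] * np.trapezoid(u_miss * r**2, r)
            IW += counts[a] * counts[b] * np.trapezoid(w_miss * r**2, r)
    return float(IE), float(IW)


class ForceField:
    """Caches neighbour list, Ewald vectors and tail integrals for one run."""

    def __init__(self, system: ParamSystem, config: MDConfig,
                 use_tail_correction: bool = True):
        self.system = system
        self.config = config
        self.use_ewald = system.has_charges
        if self.use_ewald and not system.is_neutral:
            raise EngineError(
                f"Ewald electrostatics requires a neutral box "
                f"(total charge {system.total_charge:.3g} e)")
        self.rlist = config.cutoff + config.neighbor_skin
        self.pairs = None
        self._pairs_ref = None
        self._ewald_box = None
        self.alpha = 0.0
        self.kint = np.zeros((0, 3), dtype=np.int32)
        if use_tail_correction:
            self.tail_ie, self.tail_iw = lj_tail_integrals(
                system, config.cutoff, config.switch_start)
        else:
            self.tail_ie = self.tail_iw = 0.0
        if self.use_ewald:
            self.e_self_coeff = -COULOMB / math.sqrt(math.pi) * float(
                np.sum(system.charge**2))
        else:
            self.e_self_coeff = 0.0

    def _update_pairs(self, state: SystemState):
        rebuild = self.pairs is None
        if not rebuild:
            d2 = kernels.max_displacement2(state.positions, self._pairs_ref,
                                           state.box)
            rebuild = d2 > (0.5 * self.config.neighbor_skin) ** 2
        if rebuild:
            self.pairs = kernels.build_pairs(
                state.positions, state.box, self.rlist**2,
                self.system.excl_ptr, self.system.excl_j)
            self._pairs_ref = state.positions.copy()

    def _update_ewald(self, box: np.ndarray):
        if (self._ewald_box is None
                or np.any(np.abs(box / self._ewald_box - 1.0) > 0.01)):
            self.alpha, self.kint = ewald_parameters(
                self.config.cutoff, box, self.config.ewald_accuracy)
            self._ewald_box = box.copy()

    def compute(self, state: SystemState) -> ForceResult:
        sysm = self.system
        cfg = self.config
        if np.min(state.box) < 2.0 * cfg.cutoff:
            raise EngineError(
                f"box edge {np.min(state.box):.3f} nm below twice the cutoff",
                state)
        self._update_pairs(state)
        if self.use_ewald:
            self._update_ewald(state.box)
        _, dcm = sysm.com_offsets(state.positions)
        forces = np.zeros_like(state.positions)
        try:
            e_lj, e_cr, w_pair = kernels.pair_forces(
                state.positions, state.box, self.pairs, sysm.type_index,
                sysm.eps_table, sysm.sig_table, sysm.charge, dcm,
                cfg.cutoff, cfg.switch_start,
                self.alpha if self.use_ewald else 0.0,
                COULOMB, self.use_ewald, forces)
        except ZeroDivisionError as exc:
            raise EngineError("coincident sites: pair distance is zero",
                              state) from exc
        comp = {"lj": e_lj, "coul_real": e_cr}
        w_mol = w_pair
        if self.use_ewald:
            frec = np.zeros_like(forces)
            e_rec, w_rec_atomic = kernels.ewald_recip(
                state.positions, sysm.charge, state.box, self.kint,
                self.alpha, COULOMB, frec)
            forces += frec
            w_mol += w_rec_atomic - float(np.sum(frec * dcm))
            e_self = self.e_self_coeff * self.alpha
            e_excl = kernels.excluded_coulomb(
                state.positions, sysm.excl_pairs, sysm.charge, self.alpha,
                COULOMB, forces)
            comp.update(coul_recip=e_rec, coul_self=e_self, coul_excl=e_excl)
        if len(sysm.bond_k):
            comp["bond"] = kernels.bond_forces(
                state.positions, sysm.bond_idx, sysm.bond_k, sysm.bond_b0,
                forces)
        if len(sysm.angle_k):
            comp["angle"] = kernels.angle_forces(
                state.positions, sysm.angle_idx, sysm.angle_k, sysm.angle_t0,
                forces)
        if len(sysm.dihedral_k):
            comp["dihedral"] = kernels.dihedral_forces(
                state.positions, sysm.dihedral_idx, sysm.dihedral_k,
                sysm.dihedral_n, sysm.dihedral_d, forces)
        v = state.volume
        e_tail = 2.0 * math.pi * self.tail_ie / v
        w_tail = 2.0 * math.pi * self.tail_iw / v
        comp["tail"] = e_tail
        e_pot = float(sum(comp.values()))
        if not math.isfinite(e_pot):
            raise EngineError("non-finite potential energy", state)
        return ForceResult(e_pot, forces, w_mol + w_tail, comp)


def total_energy_forces(state: SystemState, system: ParamSystem,
                        config: MDConfig):
    """(potential energy, forces) for one configuration -- thin wrapper used
    by tests and analyses; forces are the exact negative gradient of the
    implemented energy."""
    fr = ForceField(system, config, use_tail_correction=False).compute(state)
    return fr.e_pot, fr.forces


# ---------------------------------------------------------------------------
# constraints (SHAKE / RATTLE for rigid water)


def shake_positions(system: ParamSystem, pos: np.ndarray, ref: np.ndarray,
                    tol: float = 1e-10, max_iter: int = 25):
    """Project ``pos`` onto the constraint manifold (batched Newton-SHAKE).

    Corrections act along the reference (pre-step) bond vectors, per the
    standard SHAKE convention; each Newton iteration solves the exact 3x3
    coupled system per molecule, so convergence is quadratic.
    """
    if system.n_constraints == 0:
        return pos
    ci, cj, d0, wi, wj, factor = system.constraint_clusters
    rref = ref[ci] - ref[cj]                      # (nm, 3, 3) bond vectors
    for _ in range(max_iter):
        d = pos[ci] - pos[cj]
        sigma = (d * d).sum(axis=2) - d0**2       # (nm, 3)
        if float(np.max(np.abs(sigma))) < tol:
            break
        # d sigma_k / d g_l = -2 (d_k . r_l) factor_kl
        M = 2.0 * np.einsum("mkx,mlx->mkl", d, rref) * factor
        g = np.linalg.solve(M, sigma[:, :, None])[:, :, 0]
        corr = g[:, :, None] * rref               # (nm, 3, 3)
        for l in range(3):  # indices are unique within each slot
            pos[ci[:, l]] -= corr[:, l] * wi[:, l, None]
            pos[cj[:, l]] += corr[:, l] * wj[:, l, None]
    else:
        raise EngineError("SHAKE failed to converge")
    return pos


def rattle_velocities(system: ParamSystem, pos: np.ndarray, vel: np.ndarray):
    """Project velocities onto the constraint tangent space.

    The velocity-level constraints are linear in the multipliers, so one
    batched 3x3 solve per molecule is exact.
    """
    if system.n_constraints == 0:
        return vel
    ci, cj, d0, wi, wj, factor = system.constraint_clusters
    d = pos[ci] - pos[cj]
    dv = vel[ci] - vel[cj]
    c = (d * dv).sum(axis=2)
    M = np.einsum("mkx,mlx->mkl", d, d) * factor
    g = np.linalg.solve(M, c[:, :, None])[:, :, 0]
    corr = g[:, :, None] * d
    for l in range(3):  # indices are unique within each slot
        vel[ci[:, l]] -= corr[:, l] * wi[:, l, None]
        vel[cj[:, l]] += corr[:, l] * wj[:, l, None]
    return vel


def constrain_rigid_water(system: ParamSystem, state: SystemState) -> SystemState:
    """Restore exact rigid geometry (positions and velocities) of all
    constrained molecules; no-op for unconstrained systems."""
    ref = state.positions.copy()
    shake_positions(system, state.positions, ref)
    rattle_velocities(system, state.positions, state.velocities)
    return state


# ---------------------------------------------------------------------------
# thermodynamics helpers


def kinetic_energy(system: ParamSystem, state: SystemState) -> float:
    return constants.kinetic_energy(system.mass, state.velocities)


def instantaneous_pressure_bar(system: ParamSystem, state: SystemState,
                               virial_mol: float) -> float:
    """Molecular-virial pressure: COM kinetic part + intermolecular virial."""
    com_v = np.zeros((system.n_mol, 3))
    mv = state.velocities * system.mass[:, None]
    for ax in range(3):
        com_v[:, ax] = np.bincount(system.mol_index, weights=mv[:, ax],
                                   minlength=system.n_mol)
    com_v /= system.mol_mass[:, None]
    k_trans = 0.5 * float(np.sum(system.mol_mass * np.sum(com_v**2, axis=1))) \
        / KJ_PER_KCAL
    p_internal = (2.0 * k_trans + virial_mol) / (3.0 * state.volume)
    return p_internal / BAR


def maxwell_boltzmann_velocities(system: ParamSystem, temperature: float,
                                 rng: np.random.Generator,
                                 positions: np.ndarray | None = None):
    """Seeded Maxwell-Boltzmann velocities; net momentum removed and, when
    constraints exist, projected onto the constraint tangent space."""
    sigma = np.sqrt(KB * KJ_PER_KCAL * temperature / system.mass)
    vel = rng.standard_normal((system.n_sites, 3)) * sigma[:, None]
    vel -= np.sum(vel * system.mass[:, None], axis=0) / system.total_mass
    if system.n_constraints and positions is not None:
        rattle_velocities(system, positions, vel)
    return vel


# ---------------------------------------------------------------------------
# barostat


def cell_rescale_step(system: ParamSystem, state: SystemState,
                      config: MDConfig, p_inst_bar: float, dt_ps: float,
                      rng: np.random.Generator):
    """One overdamped-Langevin (stochastic cell rescaling) barostat update.

    d(lnV) = (beta/tau) (P - P_ext) dt + sqrt(2 kB T beta dt / (V tau)) xi,
    applied to molecule COMs so intramolecular geometry is untouched.
    """
    beta = config.compressibility_per_bar / BAR  # (kcal/mol/nm^3)^-1
    tau = config.barostat_tau_ps
    kt = KB * config.temperature
    v = state.volume
    dp = (p_inst_bar - config.pressure_bar) * BAR
    x = (beta / tau) * dp * dt_ps \
        + math.sqrt(2.0 * kt * beta * dt_ps / (v * tau)) * rng.standard_normal()
    # guard against pathological early-run pressure spikes
    x = float(np.clip(x, -0.05, 0.05))
    mu = math.exp(x / 3.0)
    com, dcm = system.com_offsets(state.positions)
    state.positions[:] = com[system.mol_index] * mu + dcm
    state.box *= mu
    if np.min(state.box) < 2.0 * config.cutoff:
        raise EngineError("barostat collapsed the box below twice the cutoff",
                          state)
    # COM velocities scale inversely; internal velocities untouched
    com_v = np.zeros((system.n_mol, 3))
    mv = state.velocities * system.mass[:, None]
    for ax in range(3):
        com_v[:, ax] = np.bincount(system.mol_index, weights=mv[:, ax],
                                   minlength=system.n_mol)
    com_v /= system.mol_mass[:, None]
    state.velocities += com_v[system.mol_index] * (1.0 / mu - 1.0)
    return state


# ---------------------------------------------------------------------------
# integrator and run driver


def langevin_step(system: ParamSystem, state: SystemState, forces: np.ndarray,
                  config: MDConfig, forcefield: ForceField,
                  rng: np.random.Generator):
    """One BAOAB step; returns the ForceResult at the new positions.

    With gamma = 0 the O-step is the identity and the scheme reduces to
    velocity Verlet (plus SHAKE/RATTLE when constraints are present).
    """
    dt = config.timestep_ps
    h = 0.5 * dt
    m = system.mass[:, None]
    acc = forces * (KJ_PER_KCAL / m)
    vel = state.velocities
    pos = state.positions
    constrained = system.n_constraints > 0
    # B
    vel += h * acc
    if constrained:
        rattle_velocities(system, pos, vel)
    # A
    ref = pos.copy()
    pos += h * vel
    if constrained:
        unconstrained = pos.copy()
        shake_positions(system, pos, ref)
        vel += (pos - unconstrained) / h
    # O
    gamma = 0.0 if config.ensemble == "nve" else config.langevin_gamma
    if gamma > 0.0:
        c1 = math.exp(-gamma * dt)
        sigma = np.sqrt((1.0 - c1 * c1) * KB * KJ_PER_KCAL
                        * config.temperature / system.mass)
        vel *= c1
        vel += sigma[:, None] * rng.standard_normal(vel.shape)
        if constrained:
            rattle_velocities(system, pos, vel)
    # A
    ref = pos.copy()
    pos += h * vel
    if constrained:
        unconstrained = pos.copy()
        shake_positions(system, pos, ref)
        vel += (pos - unconstrained) / h
    # B with new forces
    fr = forcefield.compute(state)
    vel += h * fr.forces * (KJ_PER_KCAL / m)
    if constrained:
        rattle_velocities(system, pos, vel)
    return fr


def run_md(system: ParamSystem, state: SystemState, config: MDConfig,
           trajectory: Trajectory | None = None,
           rng: np.random.Generator | None = None) -> Trajectory:
    """Integrate ``config.n_steps`` steps; reproducible from ``config.seed``.

    Returns a :class:`Trajectory` with the initial frame, periodic snapshots
    and a dense thermo log.  Aborts with :class:`EngineError` (carrying the
    offending frame) if the energy turns non-finite.
    """
    rng = rng or np.random.default_rng(config.seed)
    ff = ForceField(system, config)
    traj = trajectory or Trajectory(system=system)
    state = state.copy()
    if system.n_constraints:
        constrain_rigid_water(system, state)
    fr = ff.compute(state)
    t = 0.0
    traj.add_frame(t, state)
    _log(traj, system, state, config, fr, t)
    for step in range(1, config.n_steps + 1):
        fr = langevin_step(system, state, fr.forces, config, ff, rng)
        t = step * config.timestep_ps
        if not math.isfinite(fr.e_pot):
            raise EngineError(f"non-finite energy at step {step}", state)
        if (config.ensemble == "npt"
                and step % config.barostat_every == 0):
            p_inst = instantaneous_pressure_bar(system, state, fr.virial_mol)
            cell_rescale_step(system, state, config, p_inst,
                              config.barostat_every * config.timestep_ps, rng)
            fr = ff.compute(state)
        if step % config.log_every == 0:
            _log(traj, system, state, config, fr, t)
        if config.snapshot_every and step % config.snapshot_every == 0:
            traj.add_frame(t, state)
    return traj


def _log(traj, system, state, config, fr, t):
    ekin = kinetic_energy(system, state)
    temp = constants.instantaneous_temperature(ekin, system.n_dof)
    p = instantaneous_pressure_bar(system, state, fr.virial_mol)
    rho = constants.mass_density_gcm3(system.total_mass, state.volume)
    traj.log(t, temp, p, state.volume, fr.e_pot, ekin, rho)


def minimize_energy(system: ParamSystem, state: SystemState, config: MDConfig,
                    max_steps: int = 200, step0: float = 5e-4,
                    fmax_tol: float = 50.0) -> SystemState:
    """Adaptive steepest-descent minimization (SHAKE-projected for rigid
    molecules); stops when the max force drops below ``fmax_tol`` kcal/mol/nm."""
    state = state.copy()
    ff = ForceField(system, config, use_tail_correction=False)
    fr = ff.compute(state)
    step = step0
    for _ in range(max_steps):
        fmax = float(np.max(np.abs(fr.forces)))
        if fmax < fmax_tol:
            break
        disp = fr.forces * (step / fmax)
        trial = state.copy()
        trial.positions += disp
        try:
            if system.n_constraints:
                shake_positions(system, trial.positions, state.positions)
            fr_trial = ff.compute(trial)
        except EngineError:
            step *= 0.5
            continue
        if fr_trial.e_pot < fr.e_pot:
            state, fr = trial, fr_trial
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-8:
                break
    state.velocities[:] = 0.0
    return state
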