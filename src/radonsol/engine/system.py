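"""System containers: per-site parameter arrays, dynamic state, trajectory."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..forcefield import MoleculeTopology, mix_pair_params, standard_parameter_table


@dataclass
class MDConfig:
    """Run parameters.

    Defaults follow the production protocol the package models: NPT at 298 K
    and 1 bar, 1 fs timestep, Langevin coupling 1.0 1/ps, LJ switched between
    1.2 and 1.5 nm.  Desk-scale boxes (edge < 3 nm) must shorten
    cutoff/switch_start so the cutoff stays below half the box edge.
    """

    temperature: float = 298.0       # K
    pressure_bar: float = 1.0
    timestep_fs: float = 1.0
    langevin_gamma: float = 1.0      # 1/ps
    cutoff: float = 1.5              # nm
    switch_start: float = 1.2        # nm
    ensemble: str = "npt"            # nve | nvt | npt
    seed: int = 0
    n_steps: int = 0
    # overdamped Langevin barostat (stochastic cell rescaling)
    barostat_tau_ps: float = 0.5
    compressibility_per_bar: float = 4.5e-5
    barostat_every: int = 10
    # bookkeeping
    neighbor_skin: float = 0.2       # nm
    log_every: int = 20              # thermo records
    snapshot_every: int = 200        # trajectory frames
    ewald_accuracy: float = 1e-5

    def __post_init__(self):
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be > 0")
        if not 0 < self.switch_start < self.cutoff:
            raise ValueError("require 0 < switch_start < cutoff")
        if self.ensemble not in ("nve", "nvt", "npt"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")

    @property
    def timestep_ps(self) -> float:
        return self.timestep_fs * 1e-3


class ParamSystem:
    """Flattened per-site force-field arrays for one simulation box."""

    def __init__(self, molecules: list[tuple[MoleculeTopology, int]]):
        table = standard_parameter_table()
        type_names: list[str] = []
        tindex: dict[str, int] = {}
        self.molecules = molecules
        site_type, charge, mass, mol_index = [], [], [], []
        self.mol_names: list[str] = []
        self.mol_first_site: list[int] = []
        bonds, angles, dihedrals, constraints = [], [], [], []
        excl = []
        imol = 0
        offset = 0
        for topo, count in molecules:
            for t in topo.site_types:
                if t not in tindex:
                    tindex[t] = len(type_names)
                    type_names.append(t)
            for _ in range(count):
                self.mol_names.append(topo.name)
                self.mol_first_site.append(offset)
                for k, t in enumerate(topo.site_types):
                    site_type.append(tindex[t])
                    charge.append(topo.charges[k])
                    mass.append(table[t].mass)
                    mol_index.append(imol)
                for (i, j, kb, b0) in topo.bond_terms:
                    bonds.append((offset + i, offset + j, kb, b0))
                for (i, j, k, kt, th0) in topo.angle_terms:
                    angles.append((offset + i, offset + j, offset + k, kt, th0))
                for (i, j, k, l, kp, n, de) in topo.dihedral_terms:
                    dihedrals.append((offset + i, offset + j, offset + k,
                                      offset + l, kp, n, de))
                for (i, j, d0) in topo.constraints:
                    constraints.append((offset + i, offset + j, d0))
                for (i, j) in topo.excluded_pairs():
                    excl.append((offset + i, offset + j))
                offset += topo.n_sites
                imol += 1
        self.n_sites = offset
        self.n_mol = imol
        self.type_names = type_names
        self.type_index = np.array(site_type, dtype=np.int32)
        self.charge = np.array(charge, dtype=np.float64)
        self.mass = np.array(mass, dtype=np.float64)
        self.mol_index = np.array(mol_index, dtype=np.int32)
        nt = len(type_names)
        self.eps_table = np.zeros((nt, nt))
        self.sig_table = np.zeros((nt, nt))
        for a, ta in enumerate(type_names):
            for b, tb in enumerate(type_names):
                p = mix_pair_params(table[ta], table[tb])
                self.eps_table[a, b] = p.epsilon
                self.sig_table[a, b] = p.sigma
        self.bond_idx = np.array([(b[0], b[1]) for b in bonds], dtype=np.int32).reshape(-1, 2)
        self.bond_k = np.array([b[2] for b in bonds])
        self.bond_b0 = np.array([b[3] for b in bonds])
        self.angle_idx = np.array([(a[0], a[1], a[2]) for a in angles],
                                  dtype=np.int32).reshape(-1, 3)
        self.angle_k = np.array([a[3] for a in angles])
        self.angle_t0 = np.array([a[4] for a in angles])
        self.dihedral_idx = np.array([(d[0], d[1], d[2], d[3]) for d in dihedrals],
                                     dtype=np.int32).reshape(-1, 4)
        self.dihedral_k = np.array([d[4] for d in dihedrals])
        self.dihedral_n = np.array([d[5] for d in dihedrals], dtype=np.int32)
        self.dihedral_d = np.array([d[6] for d in dihedrals])
        self.con_idx = np.array([(c[0], c[1]) for c in constraints],
                                dtype=np.int32).reshape(-1, 2)
        self.con_d = np.array([c[2] for c in constraints])
        # exclusion CSR, symmetric neighbour lists sorted by j
        pairs = sorted(set(excl))
        ptr = np.zeros(self.n_sites + 1, dtype=np.int32)
        lists = [[] for _ in range(self.n_sites)]
        for i, j in pairs:
            lists[i].append(j)
            lists[j].append(i)
        flat = []
        for i in range(self.n_sites):
            lists[i].sort()
            flat.extend(lists[i])
            ptr[i + 1] = len(flat)
        self.excl_ptr = ptr
        self.excl_j = np.array(flat, dtype=np.int32)
        self.excl_pairs = np.array(pairs, dtype=np.int32).reshape(-1, 2)
        # molecule masses
        self.mol_mass = np.bincount(self.mol_index, weights=self.mass,
                                    minlength=self.n_mol)
        self.total_mass = float(self.mass.sum())
        self.total_charge = float(self.charge.sum())
        self.has_charges = bool(np.any(self.charge != 0.0))
        self.n_constraints = len(self.con_d)
        self.n_dof = 3 * self.n_sites - self.n_constraints
        # per-type site counts for tail corrections
        self.type_counts = np.bincount(self.type_index, minlength=nt)

    @property
    def is_neutral(self) -> bool:
        return abs(self.total_charge) < 1e-8

    @property
    def constraint_clusters(self):
        """Per-molecule constraint clusters (waters: 3 constraints/3 atoms)
        with the multiplier coupling factors, cached for the batched
        SHAKE/RATTLE solvers."""
        if getattr(self, "_con_clusters", None) is None:
            ci = self.con_idx[:, 0].reshape(-1, 3)
            cj = self.con_idx[:, 1].reshape(-1, 3)
            d0 = self.con_d.reshape(-1, 3)
            wi = 1.0 / self.mass[ci]
            wj = 1.0 / self.mass[cj]
            nm = ci.shape[0]
            factor = np.zeros((nm, 3, 3))
            for k in range(3):
                for l in range(3):
                    factor[:, k, l] = (
                        wi[:, k] * ((ci[:, k] == ci[:, l]).astype(float)
                                    - (ci[:, k] == cj[:, l]).astype(float))
                        - wj[:, k] * ((cj[:, k] == ci[:, l]).astype(float)
                                      - (cj[:, k] == cj[:, l]).astype(float)))
            self._con_clusters = (ci, cj, d0, wi, wj, factor)
        return self._con_clusters

    def species_mask(self, name: str) -> np.ndarray:
        """Boolean site mask for all sites belonging to molecules named ``name``."""
        mol_ok = np.array([m == name for m in self.mol_names])
        return mol_ok[self.mol_index]

    def heavy_mask(self) -> np.ndarray:
        """Sites that are not hydrogens (mass > 2 amu)."""
        return self.mass > 2.0

    def com_offsets(self, positions: np.ndarray):
        """Molecule COMs (n_mol,3) and per-site offsets r_i - R_cm(mol_i)."""
        mw = positions * self.mass[:, None]
        com = np.zeros((self.n_mol, 3))
        for ax in range(3):
            com[:, ax] = np.bincount(self.mol_index, weights=mw[:, ax],
                                     minlength=self.n_mol)
        com /= self.mol_mass[:, None]
        return com, positions - com[self.mol_index]


@dataclass
class SystemState:
    """Positions (kept unwrapped; molecules stay whole), velocities, box."""

    positions: np.ndarray   # (N,3) nm
    velocities: np.ndarray  # (N,3) nm/ps
    box: np.ndarray         # (3,) nm, orthorhombic edge lengths

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def wrapped_positions(self) -> np.ndarray:
        return self.positions - self.box * np.floor(self.positions / self.box)

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           self.box.copy())


@dataclass
class Trajectory:
    """Snapshots plus a dense thermodynamic log.

    ``thermo`` has columns time_ps, temperature_K, pressure_bar, volume_nm3,
    e_pot, e_kin (kcal/mol) and density_gcm3; frames are stored every
    ``snapshot_every`` steps with unwrapped positions (for MSD analysis).
    """

    times: list = field(default_factory=list)          # ps, one per frame
    frames: list = field(default_factory=list)         # SystemState snapshots
    thermo_records: list = field(default_factory=list)
    system: ParamSystem | None = None

    def add_frame(self, time_ps: float, state: SystemState):
        if self.times and time_ps <= self.times[-1]:
            raise ValueError("frame times must be strictly increasing")
        self.times.append(time_ps)
        self.frames.append(state.copy())

    def log(self, time_ps, temperature, pressure_bar, volume, e_pot, e_kin,
            density):
        self.thermo_records.append((time_ps, temperature, pressure_bar, volume,
                                    e_pot, e_kin, density))

    @property
    def thermo(self) -> pd.DataFrame:
        return pd.DataFrame(self.thermo_records, columns=[
            "time_ps", "temperature_K", "pressure_bar", "volume_nm3",
            "e_pot", "e_kin", "density_gcm3"])

    def __len__(self):
        return len(self.frames)
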