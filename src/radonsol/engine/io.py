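"""Plain-text trajectory and log output: XYZ, PDB snapshots, thermo CSV."""

from __future__ import annotations

from .system import ParamSystem, SystemState, Trajectory

_ELEMENT = {
    "O_W": "O", "H_W": "H", "C_e": "C", "C_b": "C", "H_e": "H", "H_b": "H",
    "C": "C", "O=C": "O", "O-H": "O", "H": "H", "CH2": "C", "CH3": "C",
    "Na": "Na", "Cl": "Cl", "Ca": "Ca", "Rn": "Rn",
}


def site_elements(system: ParamSystem) -> list[str]:
    return [_ELEMENT.get(system.type_names[t], "X") for t in system.type_index]


def write_xyz(path, system: ParamSystem, frames, times=None, wrap=True):
    """Multi-frame XYZ (positions in Angstrom, as customary for the format)."""
    elems = site_elements(system)
    if isinstance(frames, SystemState):
        frames = [frames]
    times = times if times is not None else range(len(frames))
    with open(path, "w") as fh:
        for t, st in zip(times, frames):
            pos = st.wrapped_positions() if wrap else st.positions
            fh.write(f"{system.n_sites}\n")
            fh.write(f"t={t} box_nm={st.box[0]:.5f} {st.box[1]:.5f} {st.box[2]:.5f}\n")
            for e, p in zip(elems, pos * 10.0):
                fh.write(f"{e:<2s} {p[0]:12.5f} {p[1]:12.5f} {p[2]:12.5f}\n")


def write_pdb(path, system: ParamSystem, state: SystemState):
    """Single-frame PDB snapshot with a CRYST1 box record."""
    elems = site_elements(system)
    pos = state.wrapped_positions() * 10.0
    box = state.box * 10.0
    with open(path, "w") as fh:
        fh.write(f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                 f"  90.00  90.00  90.00 P 1           1\n")
        for n, (e, p) in enumerate(zip(elems, pos), start=1):
            mol = system.mol_index[n - 1] + 1
            res = system.mol_names[mol - 1][:3].upper()
            fh.write(f"ATOM  {n % 100000:5d} {e:<4s}{res:<4s} {mol % 10000:4d}    "
                     f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00"
                     f"          {e:>2s}\n")
        fh.write("END\n")


def write_thermo_csv(path, trajectory: Trajectory):
    trajectory.thermo.to_csv(path, index=False)


def write_trajectory_xyz(path, trajectory: Trajectory):
    write_xyz(path, trajectory.system, trajectory.frames, trajectory.times)
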