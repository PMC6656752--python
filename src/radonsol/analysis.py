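"""Observables from trajectories: density, RDF, nearest-neighbour distance,
MSD diffusion, dissolved-radon concentration and the solubility S = C/D_Rn.

Standard errors use block averaging with 5 blocks unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import GCM3_TO_AMU_NM3
from .engine.system import ParamSystem, SystemState, Trajectory

N_BLOCKS = 5


@dataclass(frozen=True)
class LiquidSummary:
    """Equilibrium density and nearest-neighbour distance of one liquid."""

    species: str
    density: float                     # g/cm^3
    density_err: float
    nearest_neighbour_distance: float  # nm

    def __post_init__(self):
        if self.density <= 0 or self.nearest_neighbour_distance <= 0:
            raise ValueError("density and R must be positive")


@dataclass(frozen=True)
class SolubilityResult:
    """Concentration-specific solubility S = C / D_Rn (dimensionless when C
    and D_Rn share units, g/cm^3 in simulation or Bq/cm^3 in experiment)."""

    concentration: float
    reference_density: float
    value: float
    stderr: float = 0.0


def block_average(series: np.ndarray, n_blocks: int = N_BLOCKS):
    """(mean, standard error) via non-overlapping block averages."""
    series = np.asarray(series, dtype=float)
    if len(series) == 0:
        raise ValueError("empty series")
    mean = float(series.mean())
    if len(series) < n_blocks:
        se = (float(series.std(ddof=1) / math.sqrt(len(series)))
              if len(series) > 1 else 0.0)
        return mean, se
    blocks = np.array_split(series, n_blocks)
    bm = np.array([b.mean() for b in blocks])
    return mean, float(bm.std(ddof=1) / math.sqrt(n_blocks))


def mass_density(traj: Trajectory, window: tuple[float, float] | None = None):
    """Time-averaged mass density (g/cm^3) with block-averaged standard error.

    ``window`` is a (t_start, t_end) slice in ps over the thermo log; the
    default is the full log.
    """
    th = traj.thermo
    if window is not None:
        th = th[(th.time_ps >= window[0]) & (th.time_ps <= window[1])]
    if len(th) == 0:
        raise ValueError("empty averaging window")
    return block_average(th.density_gcm3.to_numpy())


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def radial_distribution(frames, box_or_none, ref_idx, target_idx,
                        dr: float = 0.002, r_max: float | None = None,
                        exclude_same_molecule: np.ndarray | None = None):
    """Pair correlation g(r) between two site selections.

    ``frames`` is an iterable of SystemState (or a Trajectory, whose frames
    are used).  Normalization is the standard one: shell counts divided by
    the ideal-gas expectation at the bulk density of the target selection.
    Returns a DataFrame with columns r, g.
    """
    if isinstance(frames, Trajectory):
        frames = frames.frames
    frames = list(frames)
    ref_idx = np.asarray(ref_idx)
    target_idx = np.asarray(target_idx)
    if len(ref_idx) == 0 or len(target_idx) == 0:
        raise ValueError("empty selection")
    box0 = frames[0].box
    r_max = r_max if r_max is not None else float(np.min(box0)) / 2.0
    if r_max > np.min(box0) / 2.0 + 1e-9:
        raise ValueError("r_max exceeds half the smallest box edge")
    nbins = int(math.ceil(r_max / dr))
    hist = np.zeros(nbins)
    n_frames = 0
    rho_sum = 0.0
    same = np.array_equal(ref_idx, target_idx)
    for st in frames:
        pos = st.positions
        d = pos[ref_idx][:, None, :] - pos[target_idx][None, :, :]
        d = _min_image(d, st.box)
        r = np.linalg.norm(d, axis=-1).ravel()
        if same:
            r = r[r > 1e-9]
        if exclude_same_molecule is not None:
            pair_ok = (exclude_same_molecule[ref_idx][:, None]
                       != exclude_same_molecule[target_idx][None, :]).ravel()
            r = r[pair_ok & (np.linalg.norm(d, axis=-1).ravel() > 1e-9)] \
                if same else r[pair_ok]
        hist += np.histogram(r, bins=nbins, range=(0.0, r_max))[0]
        rho_sum += len(target_idx) / st.volume
        n_frames += 1
    edges = np.linspace(0.0, r_max, nbins + 1)
    shell = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = rho_sum / n_frames
    n_pairs_expected = len(ref_idx) * shell * rho
    g = hist / (n_frames * n_pairs_expected)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return pd.DataFrame({"r": centers, "g": g})


def nearest_neighbour_distance(frames, system: ParamSystem,
                               site_idx) -> float:
    """Mean minimum intermolecular distance between selected reference sites
    (one per molecule: O for water, head carbon for acids), averaged over
    molecules and frames."""
    if isinstance(frames, Trajectory):
        frames = frames.frames
    site_idx = np.asarray(site_idx)
    if len(site_idx) < 2:
        raise ValueError("need at least two molecules selected")
    mols = system.mol_index[site_idx]
    total = 0.0
    count = 0
    for st in frames:
        pos = st.positions[site_idx]
        d = _min_image(pos[:, None, :] - pos[None, :, :], st.box)
        r = np.linalg.norm(d, axis=-1)
        r[mols[:, None] == mols[None, :]] = np.inf
        total += float(np.min(r, axis=1).sum())
        count += len(site_idx)
    return total / count


def msd(traj_frames, times, sel, max_lag_frac: float = 0.5,
        com_masses: np.ndarray | None = None):
    """Mean squared displacement with multiple time origins (50% overlap).

    Positions must be unwrapped (the engine stores them unwrapped).  With
    ``com_masses`` (one mass per site in the full system) displacements are
    measured in the system centre-of-mass frame, removing any net drift --
    essential for small boxes, where residual COM momentum otherwise adds a
    spurious ballistic term.  Returns (lag times, msd values).
    """
    if isinstance(traj_frames, Trajectory):
        times = np.asarray(traj_frames.times)
        traj_frames = traj_frames.frames
    pos = np.array([f.positions[sel] for f in traj_frames])  # (T, n, 3)
    if com_masses is not None:
        com = np.array([
            np.average(f.positions, axis=0, weights=com_masses)
            for f in traj_frames])
        pos = pos - com[:, None, :]
    nt = len(pos)
    max_lag = int(nt * max_lag_frac)
    origins = range(0, nt - max_lag, max(1, max_lag // 2))
    out = np.zeros(max_lag)
    norm = 0
    for o in origins:
        disp = pos[o:o + max_lag] - pos[o]
        out += np.mean(np.sum(disp**2, axis=-1), axis=1)
        norm += 1
    dt = times[1] - times[0]
    return np.arange(max_lag) * dt, out / norm


def msd_diffusion(traj, sel, fit_window: tuple[float, float],
                  com_masses: np.ndarray | None = None):
    """Diffusion coefficient (nm^2/ps) from the Einstein relation
    D = slope(MSD)/6, least-squares over ``fit_window`` (ps)."""
    lags, m = msd(traj, None, sel, com_masses=com_masses)
    if fit_window[1] > lags[-1] + 1e-9:
        raise ValueError("fit window longer than available lags")
    mask = (lags >= fit_window[0]) & (lags <= fit_window[1])
    if mask.sum() < 2:
        raise ValueError("fit window too narrow")
    coef, cov = np.polyfit(lags[mask], m[mask], 1, cov=True)
    return float(coef[0] / 6.0), float(math.sqrt(cov[0, 0]) / 6.0)


def count_dissolved_radon(frame: SystemState, system: ParamSystem,
                          min_neighbours: int = 4, r_c: float = 0.7,
                          liquid_density: float | None = None):
    """Dissolved-radon count and concentration C (g/cm^3) for one frame.

    A radon atom counts as dissolved when at least ``min_neighbours`` liquid
    heavy-atom sites lie within ``r_c`` nm.  C is the dissolved radon mass
    over the liquid-region volume, the latter estimated as liquid mass /
    bulk liquid density (``liquid_density``, g/cm^3; defaults to the liquid's
    reference bulk density).
    """
    from .synthetic import BULK_DENSITY_GCM3

    rn_mask = system.species_mask("radon")
    liq_mask = ~rn_mask & system.heavy_mask()
    rn_idx = np.where(rn_mask)[0]
    liq_idx = np.where(liq_mask)[0]
    if len(liq_idx) == 0:
        raise ValueError("no liquid sites in frame")
    liq_names = {m for m in system.mol_names if m != "radon"}
    if liquid_density is None:
        main = max(liq_names, key=lambda n: system.mol_names.count(n))
        liquid_density = BULK_DENSITY_GCM3.get(main, 1.0)
    liquid_mass = float(system.mass[~rn_mask].sum())
    v_liq = liquid_mass / (liquid_density * GCM3_TO_AMU_NM3)  # nm^3
    if v_liq <= 0:
        raise ValueError("zero liquid volume")
    count = 0
    if len(rn_idx):
        d = _min_image(frame.positions[rn_idx][:, None, :]
                       - frame.positions[liq_idx][None, :, :], frame.box)
        within = (np.sum(d**2, axis=-1) < r_c * r_c).sum(axis=1)
        count = int(np.sum(within >= min_neighbours))
    m_rn = system.mass[rn_mask][:1].sum() if len(rn_idx) else 222.0176
    c = count * float(m_rn) / v_liq / GCM3_TO_AMU_NM3
    return count, c


def solubility(concentration: float, reference_density: float,
               concentration_err: float = 0.0,
               reference_density_err: float = 0.0) -> SolubilityResult:
    """S = C / D_Rn with quadrature error propagation."""
    if reference_density <= 0:
        raise ValueError("reference density must be > 0")
    s = concentration / reference_density
    err = 0.0
    if concentration_err or reference_density_err:
        rel2 = 0.0
        if concentration:
            rel2 += (concentration_err / concentration) ** 2
        rel2 += (reference_density_err / reference_density) ** 2
        err = abs(s) * math.sqrt(rel2) if concentration else \
            concentration_err / reference_density
    return SolubilityResult(concentration, reference_density, s, err)


def observables_frame(rows) -> pd.DataFrame:
    """Tidy observable table (observable, value, stderr, window, seed)."""
    return pd.DataFrame(rows, columns=["observable", "value", "stderr",
                                       "window", "seed"])
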