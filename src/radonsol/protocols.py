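"""Standard desk-scale simulation protocols and table reproductions.

The protocols fix the study conditions in one place: box compositions,
thermostat/barostat settings and run lengths for the scaled-down
(10^2-10^3 molecule) reproductions of the production simulations.  Desk-scale
water boxes use a 0.85/0.75 nm cutoff/switch (half the 216-molecule box edge
caps the cutoff) with analytic LJ tail corrections; the gas box is large
enough for the production 1.5/1.2 nm values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import analysis
from .engine import MDConfig, run_md
from .synthetic import BoxRecipe, build_box

#: desk-scale liquid-box electrostatics/cutoff settings
LIQUID_CUTOFF = 0.85
LIQUID_SWITCH = 0.75


def _liquid_config(seed: int, n_steps: int, **overrides) -> MDConfig:
    kw = dict(temperature=298.0, pressure_bar=1.0, timestep_fs=1.0,
              langevin_gamma=1.0, cutoff=LIQUID_CUTOFF,
              switch_start=LIQUID_SWITCH, ensemble="npt", seed=seed,
              n_steps=n_steps, barostat_tau_ps=0.5,
              compressibility_per_bar=4.5e-5, barostat_every=10,
              log_every=20, snapshot_every=500, ewald_accuracy=1e-4)
    kw.update(overrides)
    return MDConfig(**kw)


@dataclass
class DensityRun:
    trajectory: object
    density: float       # g/cm^3
    density_err: float
    window_ps: tuple


def water_density_run(charge_factor: float = 0.0, n_water: int = 216,
                      seed: int = 0, equil_ps: float = 10.0,
                      prod_ps: float = 30.0) -> DensityRun:
    """NPT density of SPC/E water (optionally charge-scaled) at 298 K, 1 bar.

    216 molecules on a jittered lattice at 0.997 g/cm^3, minimized, then
    ``equil_ps + prod_ps`` of NPT; the density is block-averaged over the
    production window.
    """
    recipe = BoxRecipe({"water": n_water}, water_charge_factor=charge_factor,
                       seed=seed)
    cfg = _liquid_config(seed, n_steps=int((equil_ps + prod_ps) * 1000))
    system, state = build_box(recipe, config=_liquid_config(seed, 0, ensemble="nvt"))
    traj = run_md(system, state, cfg)
    window = (equil_ps, equil_ps + prod_ps)
    rho, se = analysis.mass_density(traj, window)
    return DensityRun(traj, rho, se, window)


def radon_gas_run(n_radon: int = 200, seed: int = 0, equil_ps: float = 30.0,
                  prod_ps: float = 120.0,
                  start_density: float = 9.36e-3) -> DensityRun:
    """NPT density of pure radon gas at 298 K, 1 bar.

    The gas box is ~20 nm, so the production 1.5/1.2 nm cutoff/switch is
    used directly; the barostat compressibility matches an ideal gas
    (1/P = 1 bar^-1).
    """
    recipe = BoxRecipe({"radon": n_radon}, geometry="pure_gas",
                       target_density=start_density, seed=seed)
    cfg = MDConfig(temperature=298.0, pressure_bar=1.0, cutoff=1.5,
                   switch_start=1.2, ensemble="npt", seed=seed,
                   n_steps=int((equil_ps + prod_ps) * 1000),
                   langevin_gamma=1.0, barostat_tau_ps=1.0,
                   compressibility_per_bar=1.0, barostat_every=10,
                   log_every=50, snapshot_every=2000, neighbor_skin=0.4)
    system, state = build_box(recipe, config=MDConfig(
        cutoff=1.5, switch_start=1.2, ensemble="nvt"))
    traj = run_md(system, state, cfg)
    window = (equil_ps, equil_ps + prod_ps)
    rho, se = analysis.mass_density(traj, window)
    return DensityRun(traj, rho, se, window)


def radon_in_solvent_diffusion(solvent: str, seed: int = 0,
                               n_radon: int = 8,
                               equil_ps: float = 8.0, prod_ps: float = 32.0,
                               fit_window: tuple = (2.0, 8.0)):
    """Diffusion coefficient (nm^2/ps) of radon atoms dissolved in a solvent.

    A bulk solvent box (125 waters or 25 hexanes) with ``n_radon`` radon
    atoms mixed in is equilibrated in NPT, then diffusion is measured in a
    constant-volume production run (MSD over multiple origins, Einstein
    relation over ``fit_window``).  The two boxes are of comparable edge
    length so the hydrodynamic finite-size suppression of D largely cancels
    in the hexane/water ratio.

    The production segment runs thermostat-free (NVE): Langevin friction
    adds the same per-atom drag mv*gamma in both solvents, which suppresses
    the faster hexane diffusion disproportionately and would bias the
    hexane/water ratio toward 1; microcanonical dynamics is the standard
    choice for transport coefficients.
    """
    counts = {"water": 125} if solvent == "water" else {"hexane": 25}
    counts["radon"] = n_radon
    recipe = BoxRecipe(counts, seed=seed)
    cut = dict(cutoff=0.70, switch_start=0.60)
    system, state = build_box(recipe, config=_liquid_config(seed, 0, ensemble="nvt", **cut))
    cfg_eq = _liquid_config(seed, n_steps=int(equil_ps * 1000), **cut)
    traj_eq = run_md(system, state, cfg_eq)
    state = traj_eq.frames[-1]
    # Langevin equilibration leaves a random net momentum; remove it so the
    # microcanonical production segment has no ballistic COM drift
    p_com = (state.velocities * system.mass[:, None]).sum(axis=0)
    state.velocities -= p_com / system.total_mass
    cfg_pr = _liquid_config(seed + 1, n_steps=int(prod_ps * 1000),
                            ensemble="nve", langevin_gamma=0.0,
                            snapshot_every=100, **cut)
    traj = run_md(system, state, cfg_pr)
    sel = np.where(system.species_mask("radon"))[0]
    d, d_err = analysis.msd_diffusion(traj, sel, fit_window,
                                      com_masses=system.mass)
    return d, d_err, traj


# ---------------------------------------------------------------------------
# table reproductions from the bundled reference data


def load_reference_simulation(path=None) -> pd.DataFrame:
    if path is None:
        res = resources.files("radonsol.data") / "reference_simulation.csv"
        with resources.as_file(res) as p:
            return pd.read_csv(p, comment="#")
    return pd.read_csv(path, comment="#")


def simulated_solubility_table() -> pd.DataFrame:
    """S = C / D_Rn for every liquid in the bundled reference summaries,
    normalized by the radon-gas reference density, with propagated errors."""
    df = load_reference_simulation()
    d_rn = float(df.loc[df.liquid == "radon_gas", "density"].iloc[0])
    rows = []
    for _, r in df.iterrows():
        if r.liquid == "radon_gas" or pd.isna(r.c_rn):
            continue
        res = analysis.solubility(float(r.c_rn), d_rn,
                                  float(r.c_rn_err) if not pd.isna(r.c_rn_err)
                                  else 0.0)
        rows.append((r.liquid, res.concentration, d_rn, res.value, res.stderr))
    return pd.DataFrame(rows, columns=["liquid", "c_rn", "d_rn",
                                       "solubility", "stderr"])


def experimental_solubility_table() -> pd.DataFrame:
    """Per-liquid solubility aggregates from the bundled exposure records."""
    from .decay import solubility_by_liquid

    rows = []
    for liquid, est in solubility_by_liquid().items():
        rows.append((liquid, len(est.per_run), est.aggregate, est.dispersion,
                     est.propagated_err))
    return pd.DataFrame(rows, columns=["liquid", "n_runs", "solubility",
                                       "std_dev", "propagated_err"])
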