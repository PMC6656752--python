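"""Synthetic inputs: initial molecular configurations and gamma-activity data.

Everything the pipeline consumes can be generated here with known ground
truth: bulk liquid boxes, pure radon gas boxes, liquid-droplet-in-radon-gas
configurations for solubility runs, synthetic progeny-activity time series
and synthetic exposure records for end-to-end recovery studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import GCM3_TO_AMU_NM3
from .decay import ExperimentRecord, GammaSeries, NuclideChain
from .engine import MDConfig, ParamSystem, SystemState, minimize_energy
from .forcefield import (
    TOPOLOGY_FACTORIES,
    MoleculeTopology,
    ion_topology,
    water_topology,
)

#: reference bulk densities (g/cm^3) used to size boxes; the NPT barostat
#: relaxes the volume afterwards, so these only need to be approximate.
BULK_DENSITY_GCM3 = {
    "water": 0.997,
    "hexane": 0.662,
    "butyric_acid": 1.014,
    "capric_acid": 0.921,
    "radon": 9.36e-3,
}


@dataclass
class BoxRecipe:
    """Composition and geometry of an initial configuration.

    ``counts`` maps species names (water, hexane, butyric_acid, capric_acid,
    radon, Na, Cl, Ca) to molecule counts.  ``geometry`` is ``bulk`` (single
    phase), ``pure_gas`` (low-density radon) or ``droplet_in_gas`` (liquid
    sphere surrounded by radon gas).  Box size comes from ``box_edge`` if
    given, otherwise from ``target_density`` for the condensed species (and
    ``gas_density`` for the gas fraction of droplet systems).
    """

    counts: dict[str, int]
    geometry: str = "bulk"
    box_edge: float | None = None        # nm
    target_density: float | None = None  # g/cm^3 of the liquid phase
    gas_density: float = 9.36e-3         # g/cm^3 of the radon gas phase
    water_charge_factor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")
        if self.geometry not in ("bulk", "pure_gas", "droplet_in_gas"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "droplet_in_gas":
            liquid = sum(c for s, c in self.counts.items() if s != "radon")
            if liquid == 0 or self.counts.get("radon", 0) == 0:
                raise ValueError("droplet_in_gas needs liquid and radon counts")


def _topology(name: str, water_factor: float) -> MoleculeTopology:
    if name == "water":
        return water_topology(water_factor)
    if name in ("Na", "Cl", "Ca"):
        return ion_topology(name)
    if name in TOPOLOGY_FACTORIES:
        return TOPOLOGY_FACTORIES[name]()
    raise KeyError(f"unknown species {name!r}")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def build_box(recipe: BoxRecipe, minimize: bool = True,
              config: MDConfig | None = None):
    """Build a non-overlapping initial configuration for a recipe.

    Molecules are placed on a jittered cubic lattice with random orientations
    (liquid species inside a central sphere for droplet geometries, radon on
    the remaining lattice sites) and the configuration is energy-minimized.
    Returns ``(ParamSystem, SystemState)`` with exactly the requested counts.
    """
    rng = np.random.default_rng(recipe.seed)
    species = [(s, c) for s, c in recipe.counts.items() if c > 0]
    if not species:
        raise ValueError("empty recipe")
    topos = {s: _topology(s, recipe.water_charge_factor) for s, _ in species}
    liquid_species = [(s, c) for s, c in species if s != "radon"]
    n_rn = recipe.counts.get("radon", 0)
    liquid_mass = sum(topos[s].molar_mass * c for s, c in liquid_species)

    if recipe.geometry == "droplet_in_gas":
        rho_liq = (recipe.target_density
                   or BULK_DENSITY_GCM3[liquid_species[0][0]]) * GCM3_TO_AMU_NM3
        v_liq = liquid_mass / rho_liq
        rho_gas = recipe.gas_density * GCM3_TO_AMU_NM3
        v_gas = n_rn * topos["radon"].molar_mass / rho_gas
        edge = recipe.box_edge or (v_liq + v_gas) ** (1.0 / 3.0)
        radius = (3.0 * v_liq / (4.0 * math.pi)) ** (1.0 / 3.0)
        if 2.0 * radius > 0.9 * edge:
            raise ValueError("droplet does not fit; enlarge the box")
    elif recipe.geometry == "pure_gas":
        rho = (recipe.target_density or recipe.gas_density) * GCM3_TO_AMU_NM3
        total_mass = sum(topos[s].molar_mass * c for s, c in species)
        edge = recipe.box_edge or (total_mass / rho) ** (1.0 / 3.0)
        radius = 0.0
    else:
        rho = (recipe.target_density
               or BULK_DENSITY_GCM3.get(liquid_species[0][0], 1.0)) * GCM3_TO_AMU_NM3
        total_mass = sum(topos[s].molar_mass * c for s, c in species)
        edge = recipe.box_edge or (total_mass / rho) ** (1.0 / 3.0)
        radius = 0.0
    box = np.full(3, edge)

    # lattice sites
    n_total = sum(c for _, c in species)
    if recipe.geometry == "droplet_in_gas":
        n_liq = sum(c for _, c in liquid_species)
        a_liq = (4.0 / 3.0 * math.pi * radius**3 / max(n_liq, 1)) ** (1.0 / 3.0)
        liq_sites = _sphere_lattice(radius, a_liq, n_liq, edge / 2.0)
        gas_sites = _box_lattice_outside(edge, radius + 0.35, n_rn, rng)
        site_pool = [liq_sites, gas_sites]
        species = liquid_species + [("radon", n_rn)]
    else:
        m = math.ceil(n_total ** (1.0 / 3.0))
        if edge / m < 0.22:  # tighter than any LJ contact distance
            raise RuntimeError(
                "molecule insertion failed: lattice spacing "
                f"{edge / m:.3f} nm is unphysically tight; use a larger box")
        grid = (np.arange(m) + 0.5) * (edge / m)
        pts = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1)
        pts = pts.reshape(-1, 3)
        order = rng.permutation(len(pts))[:n_total]
        site_pool = [pts[order]]

    molecules = [(topos[s], c) for s, c in species]
    system = ParamSystem(molecules)
    positions = np.zeros((system.n_sites, 3))
    jitter_scale = 0.04
    idx_site = 0
    pool_i = 0
    used = 0
    for s, count in species:
        if recipe.geometry == "droplet_in_gas" and s == "radon":
            pool_i, used = 1, 0
        topo = topos[s]
        sites = site_pool[pool_i]
        for _ in range(count):
            if used >= len(sites):
                raise RuntimeError(
                    "molecule insertion failed; use a larger box")
            center = sites[used] + rng.normal(0.0, jitter_scale, 3)
            used += 1
            rot = _random_rotation(rng)
            coords = topo.coords0 @ rot.T + center
            positions[idx_site:idx_site + topo.n_sites] = coords
            idx_site += topo.n_sites

    state = SystemState(positions, np.zeros_like(positions), box)
    if minimize:
        if config is None:
            rc = min(0.9, edge / 2.0 - 0.05)
            config = MDConfig(cutoff=rc, switch_start=0.85 * rc,
                              ensemble="nvt")
        state = minimize_energy(system, state, config)
    return system, state


def _sphere_lattice(radius, spacing, n, center):
    """First n cubic-lattice points (spacing a) inside a sphere, innermost
    first so the droplet is compact."""
    m = int(math.ceil(2 * radius / spacing)) + 2
    ax = (np.arange(m) - (m - 1) / 2.0) * spacing
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.linalg.norm(pts, axis=1)
    pts = pts[np.argsort(d)]
    if len(pts) < n:
        raise RuntimeError("sphere lattice too small")
    return pts[:n] + center


def _box_lattice_outside(edge, excluded_radius, n, rng):
    """n lattice points in the box but outside a central sphere."""
    for m in (6, 8, 10, 12, 16, 20, 26):
        grid = (np.arange(m) + 0.5) * (edge / m)
        pts = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"),
                       axis=-1).reshape(-1, 3)
        mask = np.linalg.norm(pts - edge / 2.0, axis=1) > excluded_radius
        if mask.sum() >= n:
            pts = pts[mask]
            return pts[rng.permutation(len(pts))[:n]]
    raise RuntimeError("cannot place gas molecules outside the droplet")


# ---------------------------------------------------------------------------
# synthetic gamma-spectroscopy data


@dataclass
class GammaGroundTruth:
    """Known-truth description of one synthetic activity series.

    ``a0_bq`` is the radon activity in the sample at sealing time (t = 0);
    the generated progeny series decays with the radon half-life scaled by
    the progeny's transient-equilibrium ratio.  Measurements start only
    after equilibrium (first time >= 4 h).
    """

    a0_bq: float
    times_h: np.ndarray = field(
        default_factory=lambda: 4.0 + 24.0 * np.arange(14.0))
    relative_noise: float = 0.05
    nuclide: str = "Pb214"
    seed: int = 0

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        if self.relative_noise < 0:
            raise ValueError("noise must be >= 0")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("schedule must be strictly increasing")
        if self.times_h[0] < 4.0:
            raise ValueError("first measurement must be post-equilibrium (>= 4 h)")


def gamma_series_truth(gt: GammaGroundTruth, chain: NuclideChain | None = None):
    """Noiseless activity curve (and its t=0 intercept) for a ground truth."""
    chain = chain or NuclideChain()
    lam = chain.decay_constants[0]
    ratio = chain.equilibrium_activity_ratio(gt.nuclide)
    a0 = gt.a0_bq * ratio
    return a0, a0 * np.exp(-lam * gt.times_h)


def generate_gamma_series(gt: GammaGroundTruth,
                          chain: NuclideChain | None = None) -> GammaSeries:
    """Synthetic measured series: exponential decay at the radon rate with
    Gaussian relative measurement noise; reproducible from ``gt.seed``."""
    _, truth = gamma_series_truth(gt, chain)
    rng = np.random.default_rng(gt.seed)
    sigma = gt.relative_noise * truth
    noisy = truth + (rng.standard_normal(len(truth)) * sigma
                     if gt.relative_noise > 0 else 0.0)
    return GammaSeries(gt.times_h, noisy,
                       sigma if gt.relative_noise > 0 else None, gt.nuclide)


def generate_experiment_records(s_true: float, d_rn_range=(2.0, 7.0),
                                n_runs: int = 3, noise: float = 0.05,
                                seed: int = 0,
                                liquid: str = "synthetic") -> list[ExperimentRecord]:
    """Synthetic exposure records with C_Pb ~ C_Bi ~ S_true * D_Rn.

    Ambient radon levels are drawn uniformly from ``d_rn_range``; the two
    progeny concentrations get independent Gaussian relative noise.
    """
    if s_true <= 0:
        raise ValueError("s_true must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_runs):
        d = rng.uniform(*d_rn_range)
        c = s_true * d
        c_pb = c * (1.0 + noise * rng.standard_normal())
        c_bi = c * (1.0 + noise * rng.standard_normal())
        records.append(ExperimentRecord(
            liquid, c_pb, c_bi, d,
            c_pb_err=noise * c, c_bi_err=noise * c, d_rn_err=0.0))
    return records
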