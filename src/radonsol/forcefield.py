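"""Nonbonded parameters, molecule topologies, mixing rules and charge scaling.

The molecule set is fixed by the study this package models: SPC/E water (with
optionally scaled oxygen charge), 0.9--5% salt solutions (Na+, Ca2+, Cl-),
all-atom n-hexane, united-atom butyric and capric acid, and atomic radon.

Radon is parameterized from the bulk cohesive energy of solid radon: for an
fcc LJ solid the binding energy per atom is ``U_coh/N0 = -(2.15) * 4 eps``
(2.15 is the lattice-sum factor), which fixes the well depth; sigma is chosen
to reproduce the radon gas density at ambient conditions.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: SPC/E oxygen partial charge, e
SPCE_OXYGEN_CHARGE = -0.8476
#: SPC/E O-H bond length, nm
SPCE_OH = 0.1
#: SPC/E H-O-H angle, degrees
SPCE_HOH_DEG = 109.47
#: lattice sum factor relating cohesive energy per atom to the LJ well depth
FCC_LATTICE_SUM_FACTOR = 2.15


@dataclass(frozen=True)
class LJSite:
    """One nonbonded site type: LJ well depth/diameter, partial charge, mass."""

    name: str
    epsilon: float  # kcal/mol
    sigma: float    # nm
    charge: float   # e
    mass: float     # g/mol

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError(f"{self.name}: epsilon must be >= 0")
        if self.sigma <= 0:
            raise ValueError(f"{self.name}: sigma must be > 0")
        if self.mass <= 0:
            raise ValueError(f"{self.name}: mass must be > 0")


@dataclass(frozen=True)
class PairParams:
    """Mixed LJ parameters for an unlike pair."""

    epsilon: float  # kcal/mol
    sigma: float    # nm


@dataclass(frozen=True)
class CohesiveSpec:
    """Cohesive energy per atom of the noble-gas solid and its lattice-sum factor."""

    u_coh_per_atom: float  # kcal/mol, negative for a bound solid
    lattice_sum_factor: float = FCC_LATTICE_SUM_FACTOR


@dataclass(frozen=True)
class ChargeScaling:
    """Scaling of the water oxygen partial charge: O gets ``Q0*(1+factor)``."""

    base_oxygen_charge: float = SPCE_OXYGEN_CHARGE
    factor: float = 0.0

    def __post_init__(self):
        if self.factor < -1:
            raise ValueError("scaling factor must be >= -1")

    @property
    def oxygen_charge(self) -> float:
        return self.base_oxygen_charge * (1.0 + self.factor)

    @property
    def hydrogen_charge(self) -> float:
        return -0.5 * self.oxygen_charge


@functools.cache
def standard_parameter_table() -> dict[str, LJSite]:
    """All published nonbonded site types, keyed by name.

    Values are exactly as published; masses are standard atomic masses added
    by this package. Unknown names raise ``KeyError`` on lookup.
    """
    path = resources.files("radonsol.data") / "lj_sites.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, comment="#")
    return {
        r["name"]: LJSite(r["name"], float(r.epsilon), float(r.sigma),
                          float(r.charge), float(r.mass))
        for _, r in df.iterrows()
    }


def mix_pair_params(a: LJSite, b: LJSite) -> PairParams:
    """Lorentz-Berthelot combination: arithmetic sigma, geometric epsilon."""
    return PairParams(epsilon=math.sqrt(a.epsilon * b.epsilon),
                      sigma=0.5 * (a.sigma + b.sigma))


def epsilon_from_cohesive_energy(spec: CohesiveSpec) -> float:
    """Well depth (kcal/mol) from the solid's cohesive energy per atom.

    Inverts ``u_coh = -(lattice_sum_factor) * 4 * eps``; a positive cohesive
    energy describes an unbound solid and is rejected.
    """
    if spec.lattice_sum_factor <= 0:
        raise ValueError("lattice_sum_factor must be > 0")
    if spec.u_coh_per_atom > 0:
        raise ValueError("u_coh_per_atom must be <= 0 for a bound solid")
    return -spec.u_coh_per_atom / (4.0 * spec.lattice_sum_factor)


# ---------------------------------------------------------------------------
# bonded parameters


@functools.cache
def load_bonded_parameters(path=None):
    """Bond/angle/dihedral parameter lookup tables from a packaged CSV.

    Returns a dict with keys ``bond`` ((a,b) -> (k, b0)), ``angle``
    ((a,b,c) -> (k, theta0_rad)), ``dihedral`` ((b,c) central pair ->
    (k, n, delta_rad)).  Pass ``path`` to override the packaged file.
    """
    if path is None:
        res = resources.files("radonsol.data") / "bonded_parameters.csv"
        with resources.as_file(res) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    bonds, angles, dihedrals = {}, {}, {}
    for _, r in df.iterrows():
        if r["kind"] == "bond":
            k = (float(r.p1), float(r.p2))
            bonds[(r.a, r.b)] = k
            bonds[(r.b, r.a)] = k
        elif r["kind"] == "angle":
            k = (float(r.p1), math.radians(float(r.p2)))
            angles[(r.a, r.b, r.c)] = k
            angles[(r.c, r.b, r.a)] = k
        elif r["kind"] == "dihedral":
            k = (float(r.p1), int(float(r.p2)), math.radians(float(r.p3)))
            dihedrals[(r.a, r.b)] = k
            dihedrals[(r.b, r.a)] = k
    return {"bond": bonds, "angle": angles, "dihedral": dihedrals}


# ---------------------------------------------------------------------------
# topologies


@dataclass
class MoleculeTopology:
    """Sites, charges, template geometry and bonded terms of one molecule.

    Flexible molecules carry harmonic bonds/angles and cosine dihedrals;
    rigid molecules (water) carry distance constraints instead.  ``charges``
    may deviate from the raw site-type charges where the published per-type
    values do not produce a neutral molecule (see the package methods note).
    """

    name: str
    site_types: list[str]
    charges: np.ndarray          # e, one per site
    coords0: np.ndarray          # nm, template geometry (n_sites, 3)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    rigid: bool = False
    # (i, j, k_b, b0) for flexible bonds; filled by finalize()
    bond_terms: list[tuple] = field(default_factory=list)
    # (i, j, k, k_t, theta0)
    angle_terms: list[tuple] = field(default_factory=list)
    # (i, j, k, l, k_phi, n, delta)
    dihedral_terms: list[tuple] = field(default_factory=list)
    # (i, j, d0) holonomic constraints for rigid molecules
    constraints: list[tuple] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.site_types)

    @property
    def sites(self) -> list[LJSite]:
        table = standard_parameter_table()
        return [table[t] for t in self.site_types]

    @property
    def masses(self) -> np.ndarray:
        table = standard_parameter_table()
        return np.array([table[t].mass for t in self.site_types])

    @property
    def net_charge(self) -> float:
        return float(np.sum(self.charges))

    @property
    def molar_mass(self) -> float:
        return float(np.sum(self.masses))

    def excluded_pairs(self) -> set[tuple[int, int]]:
        """Intramolecular nonbonded exclusions: 1-2 and 1-3 neighbours along
        bonds; rigid molecules exclude every intramolecular pair."""
        n = self.n_sites
        if self.rigid or not self.bonds:
            return {(i, j) for i in range(n) for j in range(i + 1, n)}
        adj = _adjacency(self.bonds, n)
        excl = set()
        for i, j in self.bonds:
            excl.add((min(i, j), max(i, j)))
        for j in range(n):
            nb = adj[j]
            for a in nb:
                for b in nb:
                    if a < b:
                        excl.add((a, b))
        return excl

    def finalize(self, params=None) -> "MoleculeTopology":
        """Derive angle/dihedral lists from connectivity and attach parameters."""
        if self.rigid:
            return self
        params = params or load_bonded_parameters()
        t = self.site_types
        self.bond_terms = []
        for i, j in self.bonds:
            key = (t[i], t[j])
            if key not in params["bond"]:
                raise KeyError(f"no bond parameters for {key}")
            kb, b0 = params["bond"][key]
            self.bond_terms.append((i, j, kb, b0))
        adj = _adjacency(self.bonds, self.n_sites)
        self.angle_terms = []
        for j in range(self.n_sites):
            nb = sorted(adj[j])
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    i, k = nb[x], nb[y]
                    key = (t[i], t[j], t[k])
                    if key in params["angle"]:
                        kt, th0 = params["angle"][key]
                        self.angle_terms.append((i, j, k, kt, th0))
        self.dihedral_terms = []
        for j, k in self.bonds:
            key = (t[j], t[k])
            if key not in params["dihedral"]:
                continue
            kphi, mult, delta = params["dihedral"][key]
            for i in adj[j]:
                if i == k:
                    continue
                for l in adj[k]:
                    if l == j or l == i:
                        continue
                    self.dihedral_terms.append((i, j, k, l, kphi, mult, delta))
        return self


def _adjacency(bonds, n):
    adj = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def water_topology(scaling: ChargeScaling | float = 0.0) -> MoleculeTopology:
    """Rigid 3-site SPC/E water, optionally with scaled partial charges.

    ``scaling`` is either a :class:`ChargeScaling` or a bare factor f, giving
    an oxygen charge ``Q0*(1+f)`` with each hydrogen at half the magnitude and
    opposite sign; the molecule is neutral for every factor and the geometry
    (O-H 0.1 nm, H-O-H 109.47 deg) never changes.
    """
    if not isinstance(scaling, ChargeScaling):
        scaling = ChargeScaling(factor=float(scaling))
    th = math.radians(SPCE_HOH_DEG)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [SPCE_OH, 0.0, 0.0],
        [SPCE_OH * math.cos(th), SPCE_OH * math.sin(th), 0.0],
    ])
    coords -= coords.mean(axis=0)
    d_hh = 2.0 * SPCE_OH * math.sin(th / 2.0)
    qo = scaling.oxygen_charge
    return MoleculeTopology(
        name="water",
        site_types=["O_W", "H_W", "H_W"],
        charges=np.array([qo, -qo / 2, -qo / 2]),
        coords0=coords,
        bonds=[(0, 1), (0, 2)],
        rigid=True,
        constraints=[(0, 1, SPCE_OH), (0, 2, SPCE_OH), (1, 2, d_hh)],
    )


def scale_water_charges(factor: float) -> MoleculeTopology:
    """Water topology with the oxygen charge scaled by ``(1+factor)``."""
    return water_topology(factor)


def radon_topology() -> MoleculeTopology:
    return MoleculeTopology("radon", ["Rn"], np.zeros(1), np.zeros((1, 3)))


def ion_topology(kind: str) -> MoleculeTopology:
    """Single-site ion (Na, Cl or Ca) carrying its formal charge."""
    site = standard_parameter_table()[kind]
    return MoleculeTopology(kind, [kind], np.array([site.charge]), np.zeros((1, 3)))


def hexane_topology() -> MoleculeTopology:
    """All-atom n-hexane (20 sites): CH3 ends (C_e/H_e), CH2 backbone (C_b/H_b).

    Published per-type LJ values; H charges set to +0.09 e so the molecule is
    neutral (2*(-0.27) + 4*(-0.18) + 14*0.09 = 0).
    """
    backbone = _zigzag(6, 0.153, 113.5)
    types = []
    coords = []
    charges = []
    bonds = []
    carbon_idx = []
    for ci in range(6):
        end = ci in (0, 5)
        carbon_idx.append(len(types))
        types.append("C_e" if end else "C_b")
        charges.append(-0.27 if end else -0.18)
        coords.append(backbone[ci])
    for ci in range(1, 6):
        bonds.append((carbon_idx[ci - 1], carbon_idx[ci]))
    for ci in range(6):
        end = ci in (0, 5)
        nbrs = [backbone[ci + 1]] if ci == 0 else (
            [backbone[ci - 1]] if ci == 5 else [backbone[ci - 1], backbone[ci + 1]])
        hs = (_methyl_hydrogens(backbone[ci], nbrs[0], 0.111) if end
              else _methylene_hydrogens(backbone[ci], nbrs[0], nbrs[1], 0.111))
        for h in hs:
            bonds.append((carbon_idx[ci], len(types)))
            types.append("H_e" if end else "H_b")
            charges.append(0.09)
            coords.append(h)
    topo = MoleculeTopology("hexane", types, np.array(charges),
                            np.array(coords) - np.mean(coords, axis=0), bonds)
    return topo.finalize()


def fatty_acid_topology(n_carbons: int, name: str | None = None) -> MoleculeTopology:
    """United-atom linear fatty acid CH3-(CH2)_{n-2}-COOH.

    Chain carbons are CH2/CH3 united sites with published LJ values; the
    carboxyl head carries the published charges (C +0.75, O= -0.55, O-H -0.61)
    completed by a standard hydroxyl hydrogen (+0.45) and a small alpha-CH2
    counter-charge (-0.04) so the molecule is neutral.
    """
    if n_carbons < 3:
        raise ValueError("need at least 3 carbons")
    n_chain = n_carbons - 1  # united-atom chain carbons, head carbon separate
    backbone = _zigzag(n_chain + 1, 0.1526, 112.4)  # chain + carboxyl C
    types, charges, coords, bonds = [], [], [], []
    for i in range(n_chain):
        types.append("CH3" if i == 0 else "CH2")
        charges.append(0.0)
        coords.append(backbone[i])
        if i > 0:
            bonds.append((i - 1, i))
    charges[-1] = -0.04  # alpha carbon
    ic = len(types)
    types.append("C")
    charges.append(0.75)
    coords.append(backbone[n_chain])
    bonds.append((ic - 1, ic))
    # carboxyl oxygens in the backbone plane, +-120 deg off the chain direction
    u = backbone[n_chain] - backbone[n_chain - 1]
    u /= np.linalg.norm(u)
    w = np.array([0.0, 0.0, 1.0])
    v = np.cross(w, u)
    co = backbone[n_chain]
    o_dbl = co + 0.1229 * (u * math.cos(math.radians(60)) + v * math.sin(math.radians(60)))
    o_sgl = co + 0.1364 * (u * math.cos(math.radians(60)) - v * math.sin(math.radians(60)))
    types.append("O=C"); charges.append(-0.55); coords.append(o_dbl)
    bonds.append((ic, ic + 1))
    types.append("O-H"); charges.append(-0.61); coords.append(o_sgl)
    bonds.append((ic, ic + 2))
    h = o_sgl + 0.096 * (o_sgl - co) / np.linalg.norm(o_sgl - co)
    types.append("H"); charges.append(0.45); coords.append(h)
    bonds.append((ic + 2, ic + 3))
    topo = MoleculeTopology(name or f"acid_C{n_carbons}", types, np.array(charges),
                            np.array(coords) - np.mean(coords, axis=0), bonds)
    return topo.finalize()


def butyric_acid_topology() -> MoleculeTopology:
    return fatty_acid_topology(4, "butyric_acid")


def capric_acid_topology() -> MoleculeTopology:
    return fatty_acid_topology(10, "capric_acid")


# ---------------------------------------------------------------------------
# geometry helpers


def _zigzag(n, b, angle_deg):
    """n points along an all-trans zigzag chain with bond b and angle angle_deg."""
    half = math.radians(angle_deg) / 2.0
    pts = np.zeros((n, 3))
    for i in range(1, n):
        pts[i, 0] = pts[i - 1, 0] + b * math.sin(half)
        pts[i, 1] = b * math.cos(half) * (i % 2)
    return pts


def _methylene_hydrogens(c, a, b, d):
    """Two H on a CH2 carbon c bonded to heavy neighbours a and b."""
    u1 = (c - a) / np.linalg.norm(c - a)
    u2 = (c - b) / np.linalg.norm(c - b)
    bisector = u1 + u2
    bisector /= np.linalg.norm(bisector)
    normal = np.cross(u1, u2)
    normal /= np.linalg.norm(normal)
    half = math.radians(109.0) / 2.0
    return [c + d * (bisector * math.cos(half) + normal * math.sin(half)),
            c + d * (bisector * math.cos(half) - normal * math.sin(half))]


def _methyl_hydrogens(c, a, d):
    """Three H on a terminal CH3 carbon c bonded to heavy neighbour a."""
    axis = (c - a) / np.linalg.norm(c - a)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    tilt = math.radians(180.0 - 109.5)
    out = []
    for k in range(3):
        phi = 2.0 * math.pi * k / 3.0
        direction = (axis * math.cos(tilt)
                     + (e1 * math.cos(phi) + e2 * math.sin(phi)) * math.sin(tilt))
        out.append(c + d * direction)
    return out


#: topology factory by liquid name, used by the box builder and CLI
TOPOLOGY_FACTORIES = {
    "water": water_topology,
    "hexane": hexane_topology,
    "butyric_acid": butyric_acid_topology,
    "capric_acid": capric_acid_topology,
    "radon": radon_topology,
}
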