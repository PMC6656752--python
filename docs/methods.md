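# Methods

`radonsol` determines the concentration-specific solubility of radon,

    S = C / D_Rn,

where `C` is the radon concentration inside a liquid and `D_Rn` the radon
density (simulation arm, g/cm³) or activity concentration (experimental arm,
Bq/cm³) of the surrounding gas.  The package implements both arms of the
combined study design it models: a desk-scale molecular-dynamics engine with
the study's force-field parameterization, and a radioactive decay-chain
pipeline that back-calculates solubility from γ-spectroscopy activity
records.

## Force field

Nonbonded sites carry Lennard-Jones parameters and fixed partial charges
(`data/lj_sites.csv`, the published per-site table, reproduced verbatim).
Unlike pairs mix by Lorentz–Berthelot rules (arithmetic σ, geometric ε).
Water is rigid 3-site SPC/E (O–H 0.1 nm, H–O–H 109.47°, Q₀ = −0.8476 e on
oxygen).  Solvent polarity experiments scale the oxygen charge by a factor
(1 + f), f = ±0.15 for the Q± waters, hydrogens always at half the opposite
charge so the molecule stays neutral at every f.

Radon is charge-free; its well depth comes from the cohesive energy of the
noble-gas solid through the fcc lattice-sum relation U_coh/N₀ = −2.15·4ε
(`epsilon_from_cohesive_energy`), and σ = 0.453 nm reproduces the ambient
radon gas density.  Since the source cohesive energy is not part of the
parameter table, the operation takes U_coh as an input; the shipped ε of
0.541 kcal/mol corresponds to U_coh/N₀ = −4.65 kcal/mol.

Two charge assignments in the published per-site table cannot produce
neutral molecules as printed: hexane hydrogens are listed as +0.009 e where
neutrality (and the source all-atom force field) requires +0.09 e, and no
hydroxyl-hydrogen charge can balance the listed united-atom CH2/CH3 charges
in the fatty acids.  `standard_parameter_table()` returns the printed values
unmodified; the molecule topologies use a minimally adjusted, neutral set:
hexane H = +0.09 e; acids keep the printed head-group charges (C +0.75,
O= −0.55, O–H −0.61), take the standard +0.45 e hydroxyl hydrogen, put
−0.04 e on the α-CH2 to close the balance, and leave the remaining chain
sites uncharged.  Bonded parameters (harmonic bonds/angles, cosine
dihedrals) are representative values from the cited all-atom and united-atom
force-field families, shipped as external-constant data
(`data/bonded_parameters.csv`) and overridable.

## MD engine

A compact periodic-boundary engine for orthorhombic boxes:

* **Pair interactions.**  LJ with NAMD-style C1 energy switching (defaults
  1.2–1.5 nm; desk-scale water boxes use 0.75–0.85 nm because the cutoff
  must stay below half the ~1.83 nm box edge) plus analytic homogeneous-fluid
  tail corrections to both energy and pressure.  Electrostatics by classical
  Ewald summation: real-space erfc interactions inside the cutoff, a
  spherically truncated reciprocal sum, self-term, and erf corrections for
  excluded intramolecular pairs.  The splitting parameter and k-space cutoff
  follow from one accuracy parameter (default 10⁻⁵; the NPT production
  protocols use 10⁻⁴, standard for biomolecular work).  The real-space erfc
  uses the Abramowitz–Stegun 7.1.26 rational approximation (absolute error
  < 1.5·10⁻⁷) with the force taken as the exact derivative of the
  approximation, so forces are the exact negative gradient of the
  implemented energy (verified to ~10⁻⁷ by finite differences) and the
  Madelung constant of rock salt is reproduced to six digits.
* **Exclusions.** 1–2 and 1–3 bonded neighbours are excluded from nonbonded
  terms, 1–4 fully included; rigid water excludes all intramolecular pairs.
* **Integrator.**  BAOAB splitting of Langevin dynamics at 1 fs with
  coupling γ = 1 ps⁻¹ (the study protocol); with γ = 0 it reduces exactly to
  velocity Verlet, which is how the NVE conservation checks run.  Initial
  velocities are Maxwell–Boltzmann from the run seed.
* **Constraints.**  Rigid water by SHAKE/RATTLE: each water contributes a
  3-constraint cluster whose multiplier equations are solved exactly per
  molecule (batched 3×3 Newton solve for positions, one linear solve for
  velocities), so constraint residuals sit at machine precision every step.
* **Pressure and barostat.**  The instantaneous pressure uses the molecular
  (group-based) virial: translational COM kinetic term plus pairwise virial
  evaluated on molecule-COM separations, plus the reciprocal-space virial
  with the standard site→COM correction.  Constraint forces therefore never
  enter the pressure.  The barostat is a first-order (overdamped) Langevin
  piston — stochastic cell rescaling of molecule COMs,
  d ln V = (β_T/τ_p)(P − P_ext) dt + √(2 k_B T β_T dt/(V τ_p)) ξ —
  which samples the NPT ensemble without a piston mass; β_T is a nominal
  compressibility (4.5·10⁻⁵ bar⁻¹ for liquids, 1 bar⁻¹ for the gas — it only
  sets the relaxation rate, not the sampled distribution) and τ_p defaults
  to 0.5 ps.  A second-order oscillating piston was deliberately not used:
  at 10²–10³ molecules the overdamped variant is markedly more robust and
  its stationary distribution is the same.
* **Neighbour list.**  Verlet list with 0.2 nm skin, rebuilt when any site
  moves more than half the skin; list energies equal brute-force all-pairs
  sums to 10⁻⁸ relative (tested).

Internal units: nm, ps, kcal/mol, elementary charge, g/mol; all conversions
live in `radonsol.constants` (note k_BT at 298 K = 0.5922 kcal/mol, and
1 kcal mol⁻¹ nm⁻³ = 69.477 bar).

## Desk-scale study conditions

The production simulations of the modelled study (9999 waters, ~10 ns) are
not desk-reproducible; `radonsol.protocols` fixes scaled-down conditions
chosen once:

* **Water densities (Q₀, Q₊):** 216 molecules started from a jittered
  lattice at 0.997 g/cm³, minimized, NPT at 298 K/1 bar, 8 ps equilibration
  + 25 ps production (6 + 16 ps in the quicker test-suite variant), density
  block-averaged (5 blocks) over production.
* **Radon gas:** 200 atoms at 1 bar in a ~20 nm box (large enough for the
  production 1.2–1.5 nm switching), 30 ps + 120 ps.
* **Radon diffusion:** 8 radon atoms in 125 waters or 25 hexanes (boxes of
  comparable edge, so hydrodynamic finite-size suppression largely cancels
  in the ratio); 8 ps NPT equilibration, then 32 ps thermostat-free (NVE)
  production with snapshots every 0.1 ps.  Two deliberate choices matter
  here: production is microcanonical because Langevin friction adds the
  same per-atom drag in both solvents and disproportionately suppresses the
  faster hexane diffusion (biasing the hexane/water ratio toward 1), and
  the MSD is evaluated in the system centre-of-mass frame with the COM
  momentum zeroed at production start, because the random net momentum left
  by Langevin equilibration otherwise adds a ballistic term comparable to
  the diffusive signal in boxes this small.  D is the Einstein-relation MSD
  slope/6 over the 2–8 ps lag window with multiple time origins (50%
  overlap).

What the scaled-down runs do and do not show: equilibrium densities and
local structure converge quickly at these sizes, so the density targets are
meaningful; absolute diffusion coefficients carry hydrodynamic finite-size
suppression (≈ 2.84 k_BT/(6πηL)), which partially cancels in the
hexane/water ratio; dissolved-radon *concentrations* equilibrate over
nanoseconds and are therefore taken from the bundled reference summaries
rather than re-simulated.

## Decay-chain arm

The chain ²²²Rn → ²¹⁸Po → ²¹⁴Pb → ²¹⁴Bi is treated as strictly linear (the
minor ²¹⁸Po → ²¹⁸At branch is ignored).  Only the parent half-life (3.8 d)
is anchored by the modelled study; progeny half-lives (3.098 min, 26.8 min,
19.9 min) are nuclide-chart constants, packaged but overridable.  Closed-form
Bateman solutions give amounts/activities for arbitrary initial inventories;
near-degenerate decay constants are ε-perturbed (10⁻⁹ relative) rather than
switched to the confluent formula.  Transient equilibrium — daughter/parent
activity ratios within 1% of their asymptotes Π λ_k/(λ_k − λ_Rn) — is
reached at ≈ 3.9 h, matching the experimental 4 h waiting period.

After equilibrium a progeny activity series decays as A(t) = A₀ e^{−λ_Rn t};
A₀ is the single linear parameter of a weighted least-squares fit (weights
1/σ², exact Gaussian standard error; unweighted with residual-variance
scaling when σ are absent).  Per exposure run, S = mean(C_Pb, C_Bi)/D_Rn;
per liquid, the estimate is the mean over runs.  Two uncertainty summaries
are reported because the underlying convention is ambiguous: the sample
standard deviation over the individual per-line values (which reproduces the
published ± values exactly) and the quadrature-propagated measurement error.

## Synthetic data

The generator module produces every input with known ground truth: lattice-
placed bulk boxes, droplet-in-gas configurations (liquid sphere centred in a
periodic cube, radon on outside lattice sites), pure gas boxes; γ-activity
series with Gaussian *relative* noise (a symmetric-error approximation to
counting statistics, matching how the reference activities are reported);
and Table-style exposure records with C ≈ S·D_Rn.  Gaussian noise means the
A₀ estimator is exactly unbiased — the Monte-Carlo calibration tests verify
the implementation, not the noise model; real spectroscopy adds Poisson
statistics, efficiency/geometry systematics and background subtraction that
the generator deliberately omits.

## Numerical choices and edge cases

* Dissolved-radon criterion: a radon atom counts as dissolved when ≥ 4
  liquid heavy-atom sites lie within 0.7 nm — chosen so bulk-liquid radon is
  always counted and gas-phase radon never is on the construction fixtures;
  both knobs are exposed.
* Nearest-neighbour distance R is the time-and-molecule mean of the minimum
  intermolecular reference-site distance (O for water, head carbon for
  acids), an interpretation: the reference summaries' R definition is not
  operationally specified, so R values are cross-checked qualitatively, not
  treated as numeric targets.
* Standard errors: block averaging with 5 blocks throughout.
* Bateman at t = 0 returns the initial amounts exactly (avoiding ~10⁻¹²
  cancellation residue).
* Degenerate inputs error loudly: non-neutral boxes with Ewald, boxes
  smaller than twice the cutoff, coincident sites, empty selections/windows,
  single-molecule nearest-neighbour queries.

## Known limitations

* Ewald is classical (O(N^1.5–2)); fine at 10²–10³ sites, no PME.
* Orthorhombic boxes only; rigid constraints only for water.
* The fatty-acid bonded parameters are representative, not re-derived; acid
  liquids are used for structure/diffusion style analyses, not for
  quantitative thermodynamics.
* Scaled-down dissolved-concentration runs would need ≥ ns to equilibrate
  partitioning; the solubility table for the simulation arm therefore flows
  from bundled reference concentrations, recomputed through the same
  S = C/D_Rn machinery used everywhere else.
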