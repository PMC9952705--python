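# Methods

## The model

`crowdpd` simulates a coarse-grained model of liquid–liquid phase
separation of intrinsically disordered proteins (IDPs) in the presence of
an inert polymeric crowding agent, using Dissipative Particle Dynamics
(DPD).  All quantities are in reduced units: lengths in the interaction
range d0, energies in kBT, masses in the bead mass m, and times in
τ = √(m d0² / kBT); all three base units are 1.

Five bead types exist.  Solvent is a single bead (W).  An IDP is a linear
sticker–spacer chain: sticky endcaps (E) and sticky internal binding
sites (F) separated by runs of inert backbone beads (B); `nBm` denotes n
binding sites separated by m backbone beads (so `6B10` has 56 beads).
The crowder `Pn` is an n-bead homopolymer of type P that interacts with
every non-solvent bead type (itself included) through a strong soft
repulsion, so it exerts only steric/entropic pressure — there is no
hydrophobic or attractive coupling anywhere in the model.

### Forces

Non-bonded beads closer than d0 interact through three soft pairwise
forces, all directed along the pair axis and summing to zero over each
pair (linear momentum is conserved exactly):

* conservative: `F_C = a_ij (1 − r/d0) r̂`,
* dissipative: `F_D = −γ (1 − r/d0)² (r̂·v_ij) r̂` with γ = 4.5 for all
  pairs,
* random: `F_R = √(2 γ kBT / dt) (1 − r/d0) ζ_ij r̂` with ζ_ij a
  symmetric, uniform, zero-mean, unit-variance variate shared by the pair
  (uniform on [−√3, √3]).

The dissipative/random pair forms the DPD thermostat; the 1/√dt scaling
makes the discretised Langevin dynamics well defined.  The conservative
amplitudes a_ij (kBT/d0) are, with ε the sticker affinity:

|       | W  | E        | B  | F        | P  |
|-------|----|----------|----|----------|----|
| **W** | 25 | 25       | 23 | 25       | 25 |
| **E** |    | 25(1−ε)  | 25 | 25(1−ε)  | 80 |
| **B** |    |          | 25 | 25       | 80 |
| **F** |    |          |    | 25(1−ε)  | 80 |
| **P** |    |          |    |          | 80 |

ε = (a_EW − a_EE)/a_EW ∈ [0, 1] measures how much more weakly stickers
repel each other than they repel solvent: ε = 0 is no net attraction,
larger ε is stronger effective sticker–sticker attraction.  E and F carry
identical interactions; the two labels exist for rendering.  The crowder
repulsion a_Px (default 80) is a separate parameter so it can be reduced
mid-run.

Bonded beads are joined by Hookean springs U = ½ k2 (r − l0)² with
k2 = 128 kBT/d0², l0 = 0.5 d0 for every bond, and consecutive bead
triples feel a bending potential U = k3 (1 − cos(φ − φ0)) with k3 = 5 kBT
and φ0 = 0 (straight chains preferred).  Bending is applied to **all**
consecutive triples of every polymer, including triples containing E/F
beads and the crowders: both molecule classes are semi-flexible, and a
uniform rule is the simplest consistent choice.  Restricting bending to
pure backbone (BBB) triples is a one-line change in
`model.MoleculeTemplate.linear`.  Bonded neighbours keep their non-bonded
DPD interactions (a common DPD convention; the soft forces make the
double-counting harmless).

### System construction

Simulations run in a periodic box (48³ d0³ at full scale) filled to an
average bead density ρ d0³ = 3: polymers are placed first, then solvent
makes up the remaining bead budget round(ρ V).  Compositions are *number
fractions*: molecules of a species over total molecules in the box,
solvent included.  This convention reproduces the reference
count↔fraction pairs exactly, e.g. 180 `6B10` + 361 `P48` in 48³ gives
fractions 0.00059 and 0.00118 (printing as 0.0006/0.0012 at 4 decimals).
The inverse map (fractions → integer counts) solves the self-consistent
system — counts depend on the solvent count, which depends on counts —
by fixed-point iteration from an all-solvent box, then rounds half-up.

Initial chain conformations are random walks with unstretched step l0
from uniformly random origins; DPD's soft potentials tolerate the
resulting overlaps, which relax within a few hundred steps.  Velocities
are Maxwell–Boltzmann at kBT = 1, shifted to zero net momentum.

### Integration

The equations of motion are advanced with the Groot–Warren modified
velocity-Verlet scheme (λ = 0.5) at dt = 0.02 τ: positions advance with
the current forces, forces are then evaluated once using predicted
velocities ṽ = v + ½ dt f, and velocities complete with the averaged
force.  The one-evaluation scheme carries the usual O(dt) kinetic
temperature bias; at dt = 0.02 the measured offset is ≈ +1%, within the
2% acceptance band of the thermostat check.  Non-finite coordinates abort
the run with a diagnostic.

Neighbour search is a linked-cell sweep: beads are binned into cells at
least d0 wide (minimum 3 per dimension; smaller boxes down to 2 d0 fall
back to an exact all-pairs path), coordinates are gathered into cell
order for cache locality, and each cell is swept against itself and half
of its 26 neighbours, applying the periodic image of the neighbouring
cell as a per-cell coordinate shift (exact minimum image without
per-pair branches).  A Verlet-list variant with a reusable skin was
implemented first and measured *slower* at ρ = 3 on one core — the list
rebuild rate at thermal speeds eats the savings — so the fused sweep is
the production path.  The all-pairs path doubles as an independent
oracle: both paths must agree bead-for-bead below 1e-10.

### Reproducibility and the thermostat noise

The random-force variate is *counter-based*: ζ_ij at step s is a
splitmix64 hash of (seed, s, min(i,j), max(i,j)) mapped to the uniform
[−√3, √3].  This construction (in the spirit of the counter-based RNGs
used by modern parallel MD codes) gives ζ_ij = ζ_ji exactly, makes the
force field a pure function of the state rather than of iteration order,
and makes runs bit-reproducible for a fixed seed on a given platform.

### Mid-run parameter schedules

A scenario may list schedule events (step, parameter, value) with
strictly increasing steps; supported parameters are the sticker affinity
ε (rebuilding the E/F amplitude group) and the crowder repulsion a_Px.
Events apply when the run reaches their step, before subsequent force
evaluations — e.g. setting ε = 0 at step 500,000 switches the sticker
attraction off for the second half, the control used to show that
crowding alone does not maintain the sticker network.

## Structural observables

Condensate structure is quantified on trajectory samples; the first half
of every run is discarded as equilibration and averages use the second
(production) half only.

* **Contact graph** — nodes are IDP molecules; an edge joins two IDPs
  when any sticky-bead pair (one bead from each) lies within the contact
  cutoff under the minimum image.
* **LEN (Largest Equilibrium Network)** — the largest connected
  component of the contact graph at each sample; ties break toward the
  component containing the lowest molecule id.  The **dense-phase
  fraction** is LEN size over total IDPs.
* **Junctions** — single-linkage clusters of all sticky beads at the
  cutoff; clusters drawing beads from ≥ 2 distinct IDPs are junctions,
  and the **junction mass** is the number of distinct IDPs meeting
  there.  Junction centres use per-dimension circular means so clusters
  spanning the periodic boundary get correct centres.
* **Junction separation** — the mean centre distance over junction pairs
  *bridged* by at least one shared IDP (a chain with sticky beads in both
  clusters): these are the network strands that set the mesh size.
  All-pairs and nearest-neighbour conventions were considered; the
  bridged convention directly reflects the strand structure.

The contact and clustering cutoff defaults to d0 = 1, the only length at
which sticky beads interact at all; it is configurable everywhere.
Absolute junction separations shift with this choice, but the
comparative statements (insensitivity to crowder concentration and
molecular weight) are robust to it.  Observables that do not exist for a
sample (fewer than two junctions, no bridged pair) propagate as NaN and
are excluded from averages — never silently recorded as zero; plots
should place such points on the abscissa.

## Parameter-grid sweeps

Phase maps are produced by sweeping two scenario parameters over an
X × Y grid.  `generate_scenarios` writes one self-contained YAML scenario
per cell named `i_j_scenario.yaml` (column i = axis 1, row j = axis 2),
with a per-cell seed (base seed + row-major index) so cells are
statistically independent and exactly reproducible; regeneration is
byte-identical.  `run_grid` executes cells with a bounded local process
pool; a failing cell records its traceback in its result slot without
aborting the grid.  `render_snapshot` draws a deterministic orthographic
projection (beads as depth-sorted discs, solvent and crowders hidden by
default, matching the usual presentation), and `montage` tiles the cell
images row-major — crowder concentration increasing rightward, IDP
concentration increasing downward in the conventional orientation.
Videos are left to external tooling; the per-cell snapshot series is the
package's output.

## Problem sizes used by the test suite

Full-scale runs (48³ ≈ 331,776 beads × 10⁶ steps ≈ 3.3 × 10¹¹
bead-steps) are HPC-scale; the engine sustains roughly 3 × 10⁶
bead-steps/s on one core, so the suite exercises the same physics at
reduced size.  The choices, fixed once after feasibility scoping:

* **Thermostat benchmark** — pure solvent, 10³ box (3,000 beads),
  20,000 steps; kinetic temperature averaged over the second half.
* **Spontaneous separation and the switch-off control** — one 16³ run
  (12,288 beads, ~12 IDPs at number fraction 0.001), ε = 0.76, 5 × 10⁴
  steps with ε → 0 scheduled at 2.5 × 10⁴.  These two checks encode the
  full-scale expectation (a condensed network before the switch, its
  dissolution after) and **fail at desk scale**: see the kinetics
  discussion below.
* **Dispersed control (ε = 0)** — a 24³ box (41,472 beads, ~39 IDPs),
  2 × 10⁴ steps.  The larger box is essential here: the largest-cluster
  fraction of a *dispersed* system has a random-contact floor that
  scales like the inverse IDP count (measured ≈ 0.20 with 12 IDPs but
  ≈ 0.06 with 39), so a small box cannot distinguish "dispersed" from
  "10% clustered".  The run is short because the system is in its
  dispersed steady state from the start; only statistics are collected.
* **Crowding-assisted separation** — three 16³ runs at ε = 0.6 (below
  the spontaneous-separation threshold) with P48 crowder fractions 0,
  0.001, 0.002, 4 × 10⁴ steps each; the production-mean dense-phase
  fraction must be non-decreasing in crowder concentration within
  sampling error (a 0.05 slack with ~12 IDPs).

Quantitative observables (junction separation, junction mass) carry
finite-size effects of order the box period at these sizes and are not
compared against full-scale values.

**Formation kinetics at desk scale.**  Spontaneous condensation of the
dilute sticker–spacer chains is *not* reachable at these reduced sizes,
and the suite documents this honestly rather than papering over it.
The evidence: a dense sticky-dimer fluid (number fraction ~0.02) at
ε = 0.76 condenses to a dense fraction of ~0.95 within 10⁴ steps, so
the attraction thermodynamics are correct; but 6B10 chains at number
fraction 0.001 stay at the dispersed random-contact floor for 2.5 × 10⁵
steps at 16³ (ε = 0.76 and even ε = 0.9) and for 4 × 10⁵ steps at 20³.
Nucleation and coarsening of this near-critical dilute model need the
production protocol — hundreds of chains and ~10⁶ steps (2 × 10⁴ τ) —
which is orders of magnitude beyond desk scale.  The two suite checks
that encode spontaneous formation and its mid-run switch-off dissolution
therefore fail at the sizes above; the dispersed control and the
crowding-monotonicity check, whose physics is resolvable at desk scale,
pass.

## What the synthetic systems do and do not show

All inputs are generated by the package itself from the printed model
parameters; there are no external datasets.  Passing tests therefore
demonstrate that the implementation reproduces the *model's* documented
behaviour — thermostat temperature, composition arithmetic, network
formation and its controls — not that the model describes any particular
protein.  Real IDPs have sequence-specific interactions, charge, and
hydrodynamics that a five-type sticker–spacer model with a single
affinity parameter deliberately omits.

## Numerical choices and edge cases

* Zero-separation non-bonded pairs and zero-length bonds contribute zero
  force and increment a diagnostic counter (soft potentials make these
  measure-zero events, but random initial placement can collide beads).
* The bending force uses dU/dcos φ = −k3 exactly when φ0 = 0 (no
  singularity at straight chains); for φ0 ≠ 0 the sin(φ−φ0)/sin φ form
  is used with a clamped denominator.
* The virial is accumulated over non-bonded pairs and bonds (angle terms
  omitted); it is intended for the homogeneous-solvent pressure check,
  where the measured equation of state was cross-validated against an
  independent Metropolis Monte Carlo sampler of the same pair potential
  (P = 23.64 at a = 25, ρ = 3 — note the popular quadratic fit
  ρkBT + 0.101 a ρ² overestimates by ~8% at this density).
* Molecule counts round half-up; the bead budget rounds to nearest.
* `kinetic_temperature` divides by 3N − 3, removing the three conserved
  momentum components.

## Known limitations

* No electrostatics, no hydrodynamic validation, no pressure coupling;
  single-node execution only.
* Non-cubic boxes are supported by the engine but untested beyond
  construction; non-periodic boundaries are not supported.
* The junction definition depends on the single-linkage cutoff; only
  cutoff-robust comparative statements should be made.
* Trajectory output is plain extended XYZ (17 significant digits for
  bit-exact restarts); there is no binary/compressed format.
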