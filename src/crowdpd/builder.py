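"""System construction: molecule bookkeeping and initial-state generation.

The simulated box is periodic and filled to a fixed average bead density
(3 beads per d0^3 by default): a chosen number of polymers is placed at
random positions, and the remaining bead budget is made up of single-bead
solvent.  Compositions are reported as *number fractions*: molecules of a
species divided by the total number of molecules in the box, solvent
included.  This convention reproduces the printed count/fraction pairs used
throughout the study (e.g. 180 6B10 chains in a 48^3 box at density 3 is a
number fraction of 0.0006).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .model import (
    BondSpec,
    AngleSpec,
    MoleculeTemplate,
    parse_species,
)

__all__ = [
    "SpeciesSpec",
    "ScheduleEvent",
    "SystemSpec",
    "State",
    "SOLVENT_ID",
    "total_bead_target",
    "counts_to_fractions",
    "fractions_to_counts",
    "build_initial_state",
    "load_system_spec",
    "save_system_spec",
]

#: Reserved molecule id carried by solvent beads.
SOLVENT_ID: int = -1


@dataclass(frozen=True)
class SpeciesSpec:
    """One polymeric species and how much of it to place.

    Exactly one of ``count`` (molecules) or ``fraction`` (number fraction
    including solvent) must be given.
    """

    template: MoleculeTemplate
    count: Optional[int] = None
    fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.count is None) == (self.fraction is None):
            raise ValueError("give exactly one of count or fraction")
        if self.count is not None and self.count < 0:
            raise ValueError("molecule count must be non-negative")
        if self.fraction is not None and not 0.0 <= self.fraction < 1.0:
            raise ValueError("number fraction must lie in [0, 1)")


@dataclass(frozen=True)
class ScheduleEvent:
    """A mid-run parameter mutation applied before the given step's forces.

    ``parameter`` is ``"epsilon"`` (sticker affinity; sets the E/F group
    amplitudes) or ``"crowder_repulsion"`` (sets the a_Px group).
    """

    step: int
    parameter: str
    value: float

    def __post_init__(self) -> None:
        if self.parameter not in ("epsilon", "crowder_repulsion"):
            raise ValueError(f"unknown schedule parameter {self.parameter!r}")
        if self.step < 0:
            raise ValueError("schedule step must be non-negative")


@dataclass(frozen=True)
class SystemSpec:
    """Complete, replayable description of one simulation scenario."""

    box: tuple[float, float, float] = (48.0, 48.0, 48.0)
    density: float = 3.0
    species: tuple[SpeciesSpec, ...] = ()
    epsilon: float = 0.0
    crowder_repulsion: float = 80.0
    seed: int = 0
    n_steps: int = 1_000_000
    dt: float = 0.02
    sample_every: int = 10_000
    schedule: tuple[ScheduleEvent, ...] = ()
    bond: BondSpec = field(default_factory=BondSpec)
    angle: AngleSpec = field(default_factory=AngleSpec)

    def __post_init__(self) -> None:
        if any(L <= 0 for L in self.box):
            raise ValueError("box lengths must be positive")
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.n_steps < 0 or self.sample_every <= 0:
            raise ValueError("invalid run length or sample cadence")
        steps = [ev.step for ev in self.schedule]
        if any(s2 <= s1 for s1, s2 in zip(steps, steps[1:])):
            raise ValueError("schedule steps must be strictly increasing")
        if steps and steps[-1] > self.n_steps:
            raise ValueError("schedule step beyond the end of the run")

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def resolved_counts(self) -> list[tuple[MoleculeTemplate, int]]:
        """Molecule counts for every species, resolving number fractions."""
        if any(s.fraction is not None for s in self.species):
            fractions = []
            for s in self.species:
                if s.fraction is not None:
                    fractions.append((s.template, s.fraction))
                else:
                    # Mixed count/fraction input: convert counts to their
                    # implied fraction first so the self-consistent solve
                    # sees a uniform problem.  Rare in practice.
                    raise ValueError(
                        "mix of counts and fractions is not supported; "
                        "give all species the same way"
                    )
            return fractions_to_counts(self.box, self.density, fractions)
        return [(s.template, int(s.count)) for s in self.species]


@dataclass
class State:
    """Positions, velocities and topology of every bead at one time step."""

    positions: np.ndarray  # (N, 3) float64, in d0, wrapped to [0, L)
    velocities: np.ndarray  # (N, 3) float64, in d0/tau
    bead_types: np.ndarray  # (N,) int64 codes in BEAD_TYPES order
    molecule_ids: np.ndarray  # (N,) int64; solvent carries SOLVENT_ID
    bonds: np.ndarray  # (nb, 2) int64
    angles: np.ndarray  # (na, 3) int64
    box: np.ndarray  # (3,) float64
    step: int = 0

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "State":
        return State(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            bead_types=self.bead_types,
            molecule_ids=self.molecule_ids,
            bonds=self.bonds,
            angles=self.angles,
            box=self.box.copy(),
            step=self.step,
        )


def total_bead_target(box: Sequence[float], density: float) -> int:
    """Total number of beads needed to fill the box at the given density."""
    if any(L <= 0 for L in box):
        raise ValueError("box lengths must be positive")
    if density < 0:
        raise ValueError("density must be non-negative")
    return int(round(density * float(np.prod(np.asarray(box, dtype=float)))))


def counts_to_fractions(
    box: Sequence[float],
    density: float,
    species_counts: Iterable[tuple[MoleculeTemplate, int]],
) -> list[float]:
    """Number fraction of each species after solvent fill.

    The solvent count is whatever remains of the bead budget after the
    polymers are placed; fractions are per-molecule, solvent included.
    """
    species_counts = list(species_counts)
    target = total_bead_target(box, density)
    polymer_beads = sum(t.n_beads * c for t, c in species_counts)
    solvent = target - polymer_beads
    if solvent < 0:
        raise ValueError(
            f"polymer beads ({polymer_beads}) exceed the bead budget ({target}): "
            "the box is over-filled"
        )
    total_molecules = solvent + sum(c for _, c in species_counts)
    if total_molecules == 0:
        return [0.0 for _ in species_counts]
    return [c / total_molecules for _, c in species_counts]


def fractions_to_counts(
    box: Sequence[float],
    density: float,
    species_fractions: Iterable[tuple[MoleculeTemplate, float]],
    max_iter: int = 200,
    tol: float = 1e-9,
) -> list[tuple[MoleculeTemplate, int]]:
    """Invert :func:`counts_to_fractions` by fixed-point iteration.

    The molecule total depends on the solvent count, which depends on the
    polymer counts, so the system is solved self-consistently starting from
    an all-solvent box, then rounded half-up to integers.
    """
    species_fractions = list(species_fractions)
    if any(f < 0 for _, f in species_fractions):
        raise ValueError("fractions must be non-negative")
    if sum(f for _, f in species_fractions) >= 1.0:
        raise ValueError("fractions must sum to less than 1")
    target = total_bead_target(box, density)
    total_molecules = float(target)  # all-solvent start
    counts = [0.0 for _ in species_fractions]
    for _ in range(max_iter):
        new_counts = [f * total_molecules for _, f in species_fractions]
        polymer_beads = sum(
            t.n_beads * c for (t, _), c in zip(species_fractions, new_counts)
        )
        solvent = target - polymer_beads
        if solvent < 0:
            raise ValueError("fractions over-fill the box at this density")
        new_total = solvent + sum(new_counts)
        if abs(new_total - total_molecules) < tol and all(
            abs(a - b) < tol for a, b in zip(new_counts, counts)
        ):
            counts = new_counts
            break
        counts, total_molecules = new_counts, new_total
    else:
        raise RuntimeError("count/fraction solve did not converge")
    return [
        (t, int(np.floor(c + 0.5)))
        for (t, _), c in zip(species_fractions, counts)
    ]


def build_initial_state(spec: SystemSpec, seed: Optional[int] = None) -> State:
    """Place polymers as random walks, fill with solvent, draw velocities.

    Chains start as unstretched random walks (step length ``l0``) from a
    uniformly random origin; the soft DPD potentials tolerate the resulting
    overlaps.  Velocities are Maxwell-Boltzmann at kBT = 1, shifted to zero
    net momentum.  The same seed always produces the identical state.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    box = np.asarray(spec.box, dtype=float)
    target = total_bead_target(box, spec.density)
    counts = spec.resolved_counts()
    polymer_beads = sum(t.n_beads * c for t, c in counts)
    n_solvent = target - polymer_beads
    if n_solvent < 0:
        raise ValueError("polymers over-fill the box at this density")

    n = target
    positions = np.empty((n, 3))
    types = np.empty(n, dtype=np.int64)
    mol_ids = np.empty(n, dtype=np.int64)
    bonds: list[np.ndarray] = []
    angles: list[np.ndarray] = []

    offset = 0
    mol = 0
    l0 = spec.bond.l0
    for template, count in counts:
        nb = template.n_beads
        codes = template.type_codes
        t_bonds = np.asarray(template.bonds, dtype=np.int64).reshape(-1, 2)
        t_angles = np.asarray(template.angles, dtype=np.int64).reshape(-1, 3)
        for _ in range(count):
            origin = rng.random(3) * box
            steps = rng.normal(size=(nb - 1, 3))
            norms = np.linalg.norm(steps, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            walk = np.vstack([np.zeros(3), np.cumsum(l0 * steps / norms, axis=0)])
            positions[offset : offset + nb] = (origin + walk) % box
            types[offset : offset + nb] = codes
            mol_ids[offset : offset + nb] = mol
            if t_bonds.size:
                bonds.append(t_bonds + offset)
            if t_angles.size:
                angles.append(t_angles + offset)
            offset += nb
            mol += 1

    positions[offset:] = rng.random((n_solvent, 3)) * box
    types[offset:] = 0  # W
    mol_ids[offset:] = SOLVENT_ID

    velocities = rng.normal(size=(n, 3))
    if n > 0:
        velocities -= velocities.mean(axis=0)

    return State(
        positions=positions,
        velocities=velocities,
        bead_types=types,
        molecule_ids=mol_ids,
        bonds=np.vstack(bonds) if bonds else np.empty((0, 2), dtype=np.int64),
        angles=np.vstack(angles) if angles else np.empty((0, 3), dtype=np.int64),
        box=box,
        step=0,
    )


# ---------------------------------------------------------------------------
# Scenario files
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: SystemSpec) -> dict:
    species = []
    for s in spec.species:
        entry: dict = {"name": s.template.species_name}
        if s.count is not None:
            entry["count"] = int(s.count)
        else:
            entry["fraction"] = float(s.fraction)
        species.append(entry)
    return {
        "box": [float(L) for L in spec.box],
        "density": float(spec.density),
        "epsilon": float(spec.epsilon),
        "crowder_repulsion": float(spec.crowder_repulsion),
        "seed": int(spec.seed),
        "steps": int(spec.n_steps),
        "dt": float(spec.dt),
        "sample_every": int(spec.sample_every),
        "species": species,
        "schedule": [
            {"step": int(ev.step), "set": ev.parameter, "value": float(ev.value)}
            for ev in spec.schedule
        ],
    }


def _spec_from_dict(data: dict) -> SystemSpec:
    species = []
    for entry in data.get("species", []):
        template = parse_species(str(entry["name"]))
        species.append(
            SpeciesSpec(
                template=template,
                count=entry.get("count"),
                fraction=entry.get("fraction"),
            )
        )
    schedule = tuple(
        ScheduleEvent(step=int(ev["step"]), parameter=str(ev["set"]), value=float(ev["value"]))
        for ev in data.get("schedule", [])
    )
    box = data.get("box", [48.0, 48.0, 48.0])
    if np.isscalar(box):
        box = [box, box, box]
    return SystemSpec(
        box=tuple(float(L) for L in box),
        density=float(data.get("density", 3.0)),
        species=tuple(species),
        epsilon=float(data.get("epsilon", 0.0)),
        crowder_repulsion=float(data.get("crowder_repulsion", 80.0)),
        seed=int(data.get("seed", 0)),
        n_steps=int(data.get("steps", 1_000_000)),
        dt=float(data.get("dt", 0.02)),
        sample_every=int(data.get("sample_every", 10_000)),
        schedule=schedule,
    )


def save_system_spec(spec: SystemSpec, path: str | Path) -> None:
    """Write a scenario file (YAML).  Re-saving is byte-stable."""
    text = yaml.safe_dump(_spec_to_dict(spec), sort_keys=True, default_flow_style=False)
    Path(path).write_text(text)


def load_system_spec(path: str | Path) -> SystemSpec:
    """Read a scenario file written by :func:`save_system_spec`."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"scenario file {path} is not a mapping")
    return _spec_from_dict(data)


def with_overrides(spec: SystemSpec, **kwargs) -> SystemSpec:
    """Return a copy of ``spec`` with scalar fields replaced."""
    return replace(spec, **kwargs)
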