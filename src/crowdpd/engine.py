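"""Time integration of the DPD equations of motion.

Non-bonded beads interact through three soft, pairwise, momentum-conserving
forces inside the range d0: a linear conservative repulsion a_ij (1 - r),
a dissipative drag -gamma (1 - r)^2 (rhat.v_ij) rhat, and a random kick
sqrt(2 gamma kBT / dt) (1 - r) zeta_ij rhat.  The latter two form the DPD
thermostat.  Bonded beads additionally feel Hookean springs and a chain
bending potential, and (following common DPD practice) keep their non-bonded
interactions.  Integration uses the Groot-Warren modified velocity-Verlet
scheme with lambda = 0.5, evaluating the dissipative force once per step
with the predicted velocities.

A run is bit-reproducible for a fixed seed: the thermostat noise is drawn
from a counter-based hash of (seed, step, pair), so the force field is a
pure function of the state, not of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _kernels
from .builder import ScheduleEvent, State, SystemSpec, build_initial_state
from .model import AngleSpec, BondSpec, InteractionTable, default_interaction_table

__all__ = [
    "conservative_force",
    "dissipative_random_force",
    "bond_force",
    "bond_energy",
    "angle_force",
    "angle_energy",
    "compute_all_forces",
    "integrate_step",
    "kinetic_temperature",
    "run",
    "TrajectorySample",
    "pair_noise",
]

def pair_noise(seed: int, step: int, i: int, j: int) -> float:
    """The symmetric unit random variate zeta_ij used by the thermostat."""
    return float(_kernels.pair_noise(np.uint64(seed), np.uint64(step), i, j))


# ---------------------------------------------------------------------------
# Elementary force laws (reference implementations used in tests and docs;
# the kernels in _kernels.py implement the same expressions)
# ---------------------------------------------------------------------------

def conservative_force(a: float, r: float, unit_vector: np.ndarray) -> np.ndarray:
    """Soft linear repulsion a (1 - r/d0) rhat, zero beyond the cutoff."""
    if r < 0:
        raise ValueError("separation must be non-negative")
    e = np.asarray(unit_vector, dtype=float)
    if r >= 1.0:
        return np.zeros(3)
    return a * (1.0 - r) * e


def dissipative_random_force(
    gamma: float,
    kBT: float,
    dt: float,
    r: float,
    unit_vector: np.ndarray,
    relative_velocity: np.ndarray,
    zeta: float,
) -> np.ndarray:
    """Thermostat force on bead i (the partner receives the negative).

    The dissipative part damps the radial component of the relative
    velocity; the random part injects sqrt(2 gamma kBT / dt) (1 - r) zeta
    along the pair axis.  ``zeta`` must be shared symmetrically by the pair.
    """
    if dt <= 0:
        raise ValueError("time step must be positive (the 1/sqrt(dt) factor diverges)")
    e = np.asarray(unit_vector, dtype=float)
    v = np.asarray(relative_velocity, dtype=float)
    if r >= 1.0:
        return np.zeros(3)
    w = 1.0 - r
    dissipative = -gamma * w * w * float(e @ v) * e
    random = np.sqrt(2.0 * gamma * kBT / dt) * w * zeta * e
    return dissipative + random


def bond_energy(k2: float, l0: float, r: float) -> float:
    return 0.5 * k2 * (r - l0) ** 2


def bond_force(
    k2: float, l0: float, r: float, unit_vector: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hookean spring forces on the two bonded beads (i first).

    ``unit_vector`` points from bead j to bead i.  A zero separation has no
    defined direction; both forces are zero in that degenerate case.
    """
    e = np.asarray(unit_vector, dtype=float)
    if r <= 0:
        return np.zeros(3), np.zeros(3)
    f_i = -k2 * (r - l0) * e
    return f_i, -f_i


def angle_energy(k3: float, phi0: float, r1, r2, r3) -> float:
    b1 = np.asarray(r2, float) - np.asarray(r1, float)
    b2 = np.asarray(r3, float) - np.asarray(r2, float)
    d1 = np.linalg.norm(b1)
    d2 = np.linalg.norm(b2)
    if d1 == 0 or d2 == 0:
        raise ValueError("degenerate bond vector in angle term")
    c = np.clip(b1 @ b2 / (d1 * d2), -1.0, 1.0)
    return k3 * (1.0 - np.cos(np.arccos(c) - phi0))


def angle_force(
    k3: float, phi0: float, r1, r2, r3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact negative gradient of the bending energy for one bead triple.

    phi is the angle between consecutive bond vectors (0 = straight chain).
    The three returned forces sum to zero, as does their total torque.
    """
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    r3 = np.asarray(r3, float)
    b1 = r2 - r1
    b2 = r3 - r2
    d1s = float(b1 @ b1)
    d2s = float(b2 @ b2)
    if d1s < 1e-24 or d2s < 1e-24:
        raise ValueError("degenerate bond vector in angle term")
    d1 = np.sqrt(d1s)
    d2 = np.sqrt(d2s)
    c = float(np.clip(b1 @ b2 / (d1 * d2), -1.0, 1.0))
    if phi0 == 0.0:
        dudc = -k3
    else:
        s2 = max(1.0 - c * c, 1e-16)
        dudc = -k3 * np.sin(np.arccos(c) - phi0) / np.sqrt(s2)
    g1 = b2 / (d1 * d2) - c * b1 / d1s  # dc/db1
    g2 = b1 / (d1 * d2) - c * b2 / d2s  # dc/db2
    f1 = dudc * g1
    f3 = -dudc * g2
    return f1, -(f1 + f3), f3


# ---------------------------------------------------------------------------
# Full-system force evaluation and integration
# ---------------------------------------------------------------------------

def _use_cells(box: np.ndarray) -> bool:
    """Cell sweep needs >= 3 cells of width >= d0 per dimension."""
    return bool((np.floor(box) >= 3).all())


def _check_box(box: np.ndarray) -> None:
    if float(np.min(box)) < 2.0:
        raise ValueError("box edges must be at least 2 d0 for minimum-image forces")


def compute_all_forces(
    state: State,
    table: InteractionTable,
    dt: float,
    seed: int = 0,
    bond: BondSpec = BondSpec(),
    angle: AngleSpec = AngleSpec(),
    method: str = "cells",
    return_virial: bool = False,
):
    """Evaluate all forces on every bead of ``state``.

    ``method="cells"`` uses the linked-cell sweep (the production path);
    ``method="brute"`` evaluates an explicit all-pairs list and serves as
    the independent reference.  Both draw identical per-pair thermostat
    noise, so the two results agree bead for bead to floating-point
    roundoff.  Boxes too small for 3 cells per dimension silently use the
    all-pairs path.
    """
    if dt <= 0:
        raise ValueError("time step must be positive")
    box = np.asarray(state.box, dtype=float)
    _check_box(box)
    n = state.n_beads
    frc = np.zeros((n, 3))
    counters = np.zeros(3, np.int64)
    sigma = np.sqrt(2.0 * table.gamma * table.kBT / dt)
    if method == "cells" and _use_cells(box):
        virial = _kernels.cell_forces(
            state.positions, state.velocities, state.bead_types,
            table.a, table.gamma, sigma, box,
            np.uint64(seed), np.uint64(state.step), frc, counters,
        )
    elif method in ("cells", "brute"):
        cap = n * (n - 1) // 2 + 1
        pairs_i = np.empty(cap, np.int64)
        pairs_j = np.empty(cap, np.int64)
        count = _kernels.build_pair_list_brute(state.positions, box, 1.0, pairs_i, pairs_j)
        virial = _kernels.pair_list_forces(
            state.positions, state.velocities, state.bead_types,
            table.a, table.gamma, sigma, box,
            np.uint64(seed), np.uint64(state.step),
            pairs_i, pairs_j, count, frc, counters,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    virial += _kernels.bonded_forces(
        state.positions, frc, state.bonds, state.angles, box,
        bond.k2, bond.l0, angle.k3, angle.phi0, counters,
    )
    if return_virial:
        return frc, float(virial)
    return frc


def kinetic_temperature(state_or_velocities) -> float:
    """Kinetic estimator sum(m v^2) / (3N - 3), removing net-momentum DOF."""
    v = (
        state_or_velocities.velocities
        if isinstance(state_or_velocities, State)
        else np.asarray(state_or_velocities, dtype=float)
    )
    n = v.shape[0]
    if n < 2:
        raise ValueError("temperature needs at least two beads")
    return float((v * v).sum() / (3.0 * n - 3.0))


@dataclass
class TrajectorySample:
    """One sampling point of a run."""

    step: int
    temperature: float
    phase: str  # "equilibration" (first half) or "production"
    state: Optional[State] = None
    virial: float = float("nan")


class _Workspace:
    """Reusable buffers for the in-place integration kernels."""

    def __init__(self, state: State):
        n = state.n_beads
        box = np.asarray(state.box, float)
        _check_box(box)
        self.box = box
        self.use_cells = _use_cells(box)
        cap = 1 if self.use_cells else n * (n - 1) // 2 + 1
        self.pairs_i = np.empty(cap, np.int64)
        self.pairs_j = np.empty(cap, np.int64)
        self.frc = np.zeros((n, 3))
        self.fnew = np.empty((n, 3))
        self.vtilde = np.empty((n, 3))
        self.counters = np.zeros(3, np.int64)

    def prime(self, state: State, table: InteractionTable, dt: float,
              bond: BondSpec, angle: AngleSpec, seed: int) -> None:
        """Evaluate forces for the entering state into the workspace."""
        self.frc[:, :] = compute_all_forces(
            state, table, dt, seed=seed, bond=bond, angle=angle, method="cells"
        )

    def advance(self, state: State, table: InteractionTable, dt: float,
                bond: BondSpec, angle: AngleSpec, seed: int, nsteps: int
                ) -> tuple[np.ndarray, np.ndarray]:
        """Run ``nsteps`` integration steps in place; returns (temps, virials)."""
        temps = np.empty(nsteps)
        virials = np.empty(nsteps)
        rc = _kernels.md_chunk(
            state.positions, state.velocities, self.frc, self.fnew, self.vtilde,
            state.bead_types, state.bonds, state.angles,
            table.a, table.gamma, table.kBT, self.box, dt,
            np.uint64(seed), np.uint64(state.step), nsteps,
            bond.k2, bond.l0, angle.k3, angle.phi0,
            self.use_cells, self.pairs_i, self.pairs_j,
            temps, virials, self.counters,
        )
        if rc == -1:
            raise RuntimeError("pair list overflow during integration")
        if rc == -3:
            raise FloatingPointError(
                f"non-finite coordinates near step {state.step}: "
                "the system has blown up (check dt and initial overlaps)"
            )
        state.step += nsteps
        return temps, virials


def integrate_step(
    state: State,
    table: InteractionTable,
    dt: float,
    seed: int = 0,
    bond: BondSpec = BondSpec(),
    angle: AngleSpec = AngleSpec(),
    n_steps: int = 1,
) -> State:
    """Advance ``state`` in place by ``n_steps`` velocity-Verlet steps."""
    ws = _Workspace(state)
    ws.prime(state, table, dt, bond, angle, seed)
    ws.advance(state, table, dt, bond, angle, seed, n_steps)
    return state


def _table_for(spec: SystemSpec, epsilon: float, crowder_repulsion: float) -> InteractionTable:
    return default_interaction_table(epsilon, crowder_repulsion)


def run(
    spec: SystemSpec,
    state: Optional[State] = None,
    schedule: Optional[Sequence[ScheduleEvent]] = None,
    sample_every: Optional[int] = None,
    store_states: bool = True,
    progress: bool = False,
) -> list[TrajectorySample]:
    """Execute a full scenario and return its trajectory samples.

    Schedule mutations are applied at their step index, before that step's
    force evaluation (e.g. setting epsilon to 0 at step 500000 switches the
    sticker attraction off for the second half of the run).  Samples are
    taken every ``sample_every`` steps and tagged as equilibration (first
    half of the run) or production (second half); equilibrium averages use
    the production samples only.
    """
    if state is None:
        state = build_initial_state(spec)
    if schedule is None:
        schedule = spec.schedule
    schedule = sorted(schedule, key=lambda ev: ev.step)
    for ev in schedule:
        if ev.step > spec.n_steps:
            raise ValueError(f"schedule step {ev.step} beyond run length {spec.n_steps}")
    if sample_every is None:
        sample_every = spec.sample_every
    if sample_every <= 0:
        raise ValueError("sample cadence must be positive")

    epsilon = spec.epsilon
    a_px = spec.crowder_repulsion
    table = _table_for(spec, epsilon, a_px)
    bond, angle = spec.bond, spec.angle
    dt = spec.dt
    seed = spec.seed

    ws = _Workspace(state)

    start = state.step
    end = start + spec.n_steps
    half = start + spec.n_steps // 2

    # breakpoints where integration must pause: schedule events and samples
    breaks = sorted(
        {start + ev.step for ev in schedule}
        | {s for s in range(start + sample_every, end + 1, sample_every)}
        | {end}
    )
    breaks = [b for b in breaks if b > start]

    pending = list(schedule)
    samples: list[TrajectorySample] = []

    def apply_events(now: int) -> bool:
        nonlocal epsilon, a_px, table
        changed = False
        while pending and start + pending[0].step <= now:
            ev = pending.pop(0)
            if ev.parameter == "epsilon":
                epsilon = ev.value
            else:
                a_px = ev.value
            changed = True
            if progress:
                print(f"[step {now}] set {ev.parameter} = {ev.value}")
        if changed:
            table = _table_for(spec, epsilon, a_px)
        return changed

    apply_events(start)
    ws.prime(state, table, dt, bond, angle, seed)

    for b in breaks:
        nsteps = b - state.step
        if nsteps > 0:
            temps, virials = ws.advance(state, table, dt, bond, angle, seed, nsteps)
        else:
            temps = virials = np.array([kinetic_temperature(state)])
        now = state.step
        if (now - start) % sample_every == 0 and now > start:
            samples.append(
                TrajectorySample(
                    step=now,
                    temperature=float(temps[-1]),
                    phase="production" if now > half else "equilibration",
                    state=state.copy() if store_states else None,
                    virial=float(virials[-1]),
                )
            )
            if progress:
                print(f"[step {now}] kBT = {temps[-1]:.4f}")
        if apply_events(now):
            # amplitudes changed: forces for the entering state must be
            # re-evaluated under the new table before continuing
            ws.prime(state, table, dt, bond, angle, seed)
    return samples
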