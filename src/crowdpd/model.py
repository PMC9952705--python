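"""Bead types, conservative-force matrix, and molecule templates.

The model is a minimal sticker-spacer representation of intrinsically
disordered proteins (IDPs) in explicit solvent.  Five bead types appear:

``W``
    single-bead solvent,
``E``
    sticky endcap binding site of an IDP,
``F``
    sticky internal binding site of an IDP (interacts identically to ``E``;
    the distinction is purely a rendering label),
``B``
    inert backbone (spacer) bead of an IDP,
``P``
    monomer of an inert, strongly self- and IDP-repulsive crowder polymer.

Molecules are linear chains of these beads.  An IDP with *n* binding sites
separated by *m* backbone beads is written ``nBm`` (e.g. ``6B10``); a
crowder homopolymer of *n* beads is written ``Pn`` (e.g. ``P48``).

All quantities are in reduced DPD units: lengths in the interaction range
``d0``, energies in ``kBT``, masses in the bead mass ``m`` (all three are 1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BEAD_TYPES",
    "BEAD_INDEX",
    "BeadSpec",
    "BondSpec",
    "AngleSpec",
    "InteractionTable",
    "MoleculeTemplate",
    "epsilon_to_aEE",
    "aEE_to_epsilon",
    "default_interaction_table",
    "make_idp_template",
    "make_crowder_template",
    "parse_species",
]

#: Canonical bead-type order used for all 5x5 matrices.
BEAD_TYPES: tuple[str, ...] = ("W", "E", "B", "F", "P")
BEAD_INDEX: dict[str, int] = {t: i for i, t in enumerate(BEAD_TYPES)}

#: Sticky (binding-site) bead types.  E and F carry identical interactions.
STICKY_TYPES: frozenset[str] = frozenset({"E", "F"})

#: Default solvent-solvent (and solvent-sticker) conservative amplitude.
DEFAULT_A_SOLVENT: float = 25.0
#: Default crowder repulsion against all non-solvent types (incl. itself).
DEFAULT_A_CROWDER: float = 80.0


@dataclass(frozen=True)
class BeadSpec:
    """A bead species.  Every bead carries unit mass."""

    name: str
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in BEAD_INDEX:
            raise ValueError(f"unknown bead type {self.name!r}")
        if self.mass != 1.0:
            raise ValueError("all beads carry unit mass in this model")


@dataclass(frozen=True)
class BondSpec:
    """Hookean bond: U = 1/2 k2 (r - l0)^2, shared by every bond."""

    k2: float = 128.0  # kBT / d0^2
    l0: float = 0.5  # d0

    def __post_init__(self) -> None:
        if self.k2 <= 0 or self.l0 <= 0:
            raise ValueError("bond parameters must be positive")


@dataclass(frozen=True)
class AngleSpec:
    """Chain bending: U = k3 (1 - cos(phi - phi0)) over bead triples."""

    k3: float = 5.0  # kBT
    phi0: float = 0.0  # radians; 0 favours straight chains

    def __post_init__(self) -> None:
        if self.k3 < 0:
            raise ValueError("bending constant must be non-negative")


def epsilon_to_aEE(epsilon: float, aEW: float = DEFAULT_A_SOLVENT) -> float:
    """Convert the dimensionless sticker affinity to a conservative amplitude.

    The affinity is defined relative to the sticker-solvent amplitude,
    eps = (a_EW - a_EE) / a_EW, so a_EE = a_EW (1 - eps).  The returned
    amplitude applies to every sticky pair (E-E, E-F, F-F).
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"affinity must lie in [0, 1], got {epsilon}")
    if aEW <= 0:
        raise ValueError("sticker-solvent amplitude must be positive")
    return aEW * (1.0 - epsilon)


def aEE_to_epsilon(aEE: float, aEW: float = DEFAULT_A_SOLVENT) -> float:
    """Inverse of :func:`epsilon_to_aEE`."""
    if aEW <= 0:
        raise ValueError("sticker-solvent amplitude must be positive")
    return (aEW - aEE) / aEW


@dataclass(frozen=True)
class InteractionTable:
    """Symmetric conservative amplitudes plus the thermostat constants.

    Parameters
    ----------
    a
        5x5 symmetric matrix of conservative amplitudes ``a_ij`` indexed in
        :data:`BEAD_TYPES` order, in units of kBT/d0.
    gamma
        Dissipative strength, identical for all pairs.
    kBT
        Reduced temperature.
    d0
        Interaction range (the unit of length).
    """

    a: np.ndarray
    gamma: float = 4.5
    kBT: float = 1.0
    d0: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.shape != (5, 5):
            raise ValueError("amplitude matrix must be 5x5")
        if not np.allclose(a, a.T):
            raise ValueError("amplitude matrix must be symmetric")
        if (a < 0).any():
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "a", a)

    def get(self, t1: str, t2: str) -> float:
        """Amplitude between two bead types, by name."""
        return float(self.a[BEAD_INDEX[t1], BEAD_INDEX[t2]])

    @property
    def epsilon(self) -> float:
        """Sticker affinity implied by the current E-E amplitude."""
        return aEE_to_epsilon(self.get("E", "E"), self.get("E", "W"))


def default_interaction_table(
    epsilon: float,
    crowder_repulsion: float = DEFAULT_A_CROWDER,
    gamma: float = 4.5,
    kBT: float = 1.0,
) -> InteractionTable:
    """Build the standard conservative matrix for a given sticker affinity.

    Solvent interacts with everything at 25 except the slightly softer W-B
    pair at 23; sticky pairs (E/F with E/F) share ``epsilon_to_aEE(eps)``;
    the crowder repels every non-solvent type (including itself) at
    ``crowder_repulsion`` (80 by default).
    """
    aEE = epsilon_to_aEE(epsilon)
    if crowder_repulsion < 0:
        raise ValueError("crowder repulsion must be non-negative")
    a = np.empty((5, 5))
    W, E, B, F, P = (BEAD_INDEX[t] for t in BEAD_TYPES)
    a[:] = DEFAULT_A_SOLVENT
    a[W, B] = a[B, W] = 23.0
    for s1 in (E, F):
        for s2 in (E, F):
            a[s1, s2] = aEE
    for x in (E, B, F, P):
        a[P, x] = a[x, P] = crowder_repulsion
    return InteractionTable(a=a, gamma=gamma, kBT=kBT)


@dataclass(frozen=True)
class MoleculeTemplate:
    """One molecular species: an ordered linear chain of beads.

    Bonds join consecutive beads; bending triples cover every run of three
    consecutive beads (both IDPs and crowders are semi-flexible).
    """

    species_name: str
    bead_sequence: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...] = field(default=())
    angles: tuple[tuple[int, int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.bead_sequence)
        if n < 1:
            raise ValueError("a molecule needs at least one bead")
        for t in self.bead_sequence:
            if t not in BEAD_INDEX:
                raise ValueError(f"unknown bead type {t!r}")
        expected_bonds = tuple((i, i + 1) for i in range(n - 1))
        expected_angles = tuple((i, i + 1, i + 2) for i in range(n - 2))
        if self.bonds != expected_bonds or self.angles != expected_angles:
            raise ValueError("templates must be strictly linear chains")

    @classmethod
    def linear(cls, name: str, sequence: Sequence[str]) -> "MoleculeTemplate":
        """Build a linear-chain template from a bead-type sequence."""
        n = len(sequence)
        return cls(
            species_name=name,
            bead_sequence=tuple(sequence),
            bonds=tuple((i, i + 1) for i in range(n - 1)),
            angles=tuple((i, i + 1, i + 2) for i in range(n - 2)),
        )

    @property
    def n_beads(self) -> int:
        return len(self.bead_sequence)

    @property
    def type_codes(self) -> np.ndarray:
        """Bead types as integer codes in :data:`BEAD_TYPES` order."""
        return np.array([BEAD_INDEX[t] for t in self.bead_sequence], dtype=np.int64)

    @property
    def n_sticky(self) -> int:
        return sum(t in STICKY_TYPES for t in self.bead_sequence)

    @property
    def is_idp(self) -> bool:
        return self.n_sticky > 0


def make_idp_template(n_sites: int, spacer: int) -> MoleculeTemplate:
    """Sticker-spacer IDP with ``n_sites`` binding sites ``spacer`` apart.

    The chain reads E (B^spacer X)^(n_sites-2) B^spacer E with X = F: sticky
    endcaps of type E, internal sites of type F, inert spacers of type B.
    Total length is ``n_sites + (n_sites - 1) * spacer``.
    """
    if n_sites < 2:
        raise ValueError("an IDP needs at least two binding sites (the endcaps)")
    if spacer < 0:
        raise ValueError("spacer length must be non-negative")
    seq: list[str] = ["E"]
    for site in range(1, n_sites):
        seq.extend(["B"] * spacer)
        seq.append("F" if site < n_sites - 1 else "E")
    return MoleculeTemplate.linear(f"{n_sites}B{spacer}", seq)


def make_crowder_template(n_beads: int) -> MoleculeTemplate:
    """Inert self-avoiding homopolymer of ``n_beads`` P monomers."""
    if n_beads < 1:
        raise ValueError("a crowder needs at least one bead")
    return MoleculeTemplate.linear(f"P{n_beads}", ["P"] * n_beads)


_IDP_RE = re.compile(r"^(\d+)B(\d+)$")
_CROWDER_RE = re.compile(r"^P(\d+)$")


def parse_species(name: str) -> MoleculeTemplate:
    """Parse a species notation string into a template.

    ``nBm`` is an IDP with n binding sites separated by m backbone beads
    (``6B10``, ``5B6``); ``Pn`` is an n-bead crowder (``P48``); ``W`` is the
    single-bead solvent.
    """
    name = name.strip()
    if name == "W":
        return MoleculeTemplate.linear("W", ["W"])
    m = _IDP_RE.match(name)
    if m:
        return make_idp_template(int(m.group(1)), int(m.group(2)))
    m = _CROWDER_RE.match(name)
    if m:
        return make_crowder_template(int(m.group(1)))
    raise ValueError(f"unrecognized species notation {name!r}")
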