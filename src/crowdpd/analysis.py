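"""Structural observables of the condensate.

The dense phase of sticker-spacer IDPs is characterised through the contact
topology of their binding sites:

* the *contact graph* joins two IDPs when any of their sticky beads (types
  E/F) approach within a cutoff (d0, the interaction range, by default);
* the *Largest Equilibrium Network* (LEN) is, at each sampling point, the
  largest connected component of that graph; its mean size over production
  samples characterises the dense phase, and the *dense-phase fraction* is
  the LEN size divided by the total number of IDPs;
* *junctions* are single-linkage clusters of sticky beads drawing members
  from at least two IDPs; the *junction mass* is the number of distinct
  IDPs meeting there, and the *junction separation* averages the distance
  between junction pairs bridged by at least one shared IDP.

All distances respect the periodic minimum image.  Observables that do not
exist for a sample (no second junction, no bridged pair) propagate as NaN
rather than zero, matching the convention of plotting absent values on the
abscissa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .builder import SOLVENT_ID, State
from .model import BEAD_INDEX

__all__ = [
    "DEFAULT_CUTOFF",
    "Junction",
    "NetworkStats",
    "sticky_mask",
    "idp_ids",
    "contact_graph",
    "len_sample",
    "find_junctions",
    "junction_separation",
    "sample_observables",
    "network_stats",
]

#: Default contact / single-linkage cutoff: the DPD interaction range d0,
#: the only length scale at which sticky beads attract each other.
DEFAULT_CUTOFF: float = 1.0

_STICKY_CODES = (BEAD_INDEX["E"], BEAD_INDEX["F"])


def sticky_mask(state: State) -> np.ndarray:
    """Boolean mask of binding-site beads (types E and F)."""
    return np.isin(state.bead_types, _STICKY_CODES)


def idp_ids(state: State) -> np.ndarray:
    """Sorted molecule ids of IDPs (molecules owning at least one sticker)."""
    ids = np.unique(state.molecule_ids[sticky_mask(state)])
    return ids[ids != SOLVENT_ID]


def _sticky_pairs(state: State, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into the sticky subset) of sticky-bead pairs within cutoff."""
    mask = sticky_mask(state)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return idx, np.empty((0, 2), dtype=np.int64)
    box = np.asarray(state.box, dtype=float)
    pos = np.mod(state.positions[idx], box)
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return idx, pairs.astype(np.int64).reshape(-1, 2)


def contact_graph(state: State, cutoff: float = DEFAULT_CUTOFF) -> nx.Graph:
    """IDP-IDP contact graph through sticky-bead proximity.

    Nodes are IDP molecule ids (isolated IDPs included); an edge joins two
    IDPs whenever any sticky bead of one lies within ``cutoff`` of a sticky
    bead of the other under the minimum image.  Solvent and crowders never
    appear.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    graph = nx.Graph()
    graph.add_nodes_from(int(m) for m in idp_ids(state))
    if graph.number_of_nodes() == 0:
        return graph
    idx, pairs = _sticky_pairs(state, cutoff)
    if pairs.size:
        mols = state.molecule_ids[idx]
        m1 = mols[pairs[:, 0]]
        m2 = mols[pairs[:, 1]]
        inter = m1 != m2
        graph.add_edges_from(
            (int(a), int(b)) for a, b in zip(m1[inter], m2[inter])
        )
    return graph


def len_sample(graph: nx.Graph) -> set[int]:
    """Largest connected component of the contact graph (the LEN).

    Ties are broken deterministically in favour of the component containing
    the lowest molecule id.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("contact graph has no IDPs")
    best: set[int] = set()
    for comp in nx.connected_components(graph):
        if len(comp) > len(best) or (len(comp) == len(best) and min(comp) < min(best)):
            best = set(comp)
    return best


@dataclass(frozen=True)
class Junction:
    """A single-linkage cluster of sticky beads from >= 2 distinct IDPs."""

    bead_indices: tuple[int, ...]
    molecule_ids: frozenset[int]
    center: tuple[float, float, float]

    @property
    def mass(self) -> int:
        """Number of distinct IDPs meeting at this junction."""
        return len(self.molecule_ids)


def _periodic_centroid(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Circular-mean centroid, correct for clusters spanning the boundary."""
    theta = 2.0 * np.pi * points / box
    mean = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return np.mod(mean / (2.0 * np.pi), 1.0) * box


def find_junctions(state: State, cutoff: float = DEFAULT_CUTOFF) -> list[Junction]:
    """Single-linkage clustering of all sticky beads at the cutoff.

    Clusters whose beads come from at least two distinct IDPs become
    junctions; single-molecule clusters (including isolated beads) do not.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    idx, pairs = _sticky_pairs(state, cutoff)
    if idx.size == 0:
        return []
    graph = nx.Graph()
    graph.add_nodes_from(range(idx.size))
    graph.add_edges_from(map(tuple, pairs))
    box = np.asarray(state.box, dtype=float)
    junctions = []
    for comp in nx.connected_components(graph):
        members = np.fromiter(comp, dtype=np.int64)
        beads = idx[members]
        mols = frozenset(int(m) for m in state.molecule_ids[beads])
        if len(mols) < 2:
            continue
        center = _periodic_centroid(np.mod(state.positions[beads], box), box)
        junctions.append(
            Junction(
                bead_indices=tuple(int(b) for b in np.sort(beads)),
                molecule_ids=mols,
                center=tuple(float(c) for c in center),
            )
        )
    junctions.sort(key=lambda j: j.bead_indices)
    return junctions


def junction_separation(
    junctions: Sequence[Junction], state: State
) -> tuple[float, float]:
    """Mean and SD of center distances over IDP-bridged junction pairs.

    Only pairs of junctions sharing at least one IDP (a chain with sticky
    beads in both) contribute: these are the network strands whose length
    sets the mesh size of the condensate.  Returns (nan, nan) when fewer
    than two junctions exist or no pair is bridged.
    """
    if len(junctions) < 2:
        return float("nan"), float("nan")
    box = np.asarray(state.box, dtype=float)
    dists = []
    for a in range(len(junctions)):
        for b in range(a + 1, len(junctions)):
            if junctions[a].molecule_ids & junctions[b].molecule_ids:
                d = np.asarray(junctions[a].center) - np.asarray(junctions[b].center)
                d -= box * np.rint(d / box)
                dists.append(float(np.linalg.norm(d)))
    if not dists:
        return float("nan"), float("nan")
    arr = np.asarray(dists)
    return float(arr.mean()), float(arr.std())


def sample_observables(state: State, cutoff: float = DEFAULT_CUTOFF) -> dict:
    """All per-sample structural observables for one snapshot."""
    graph = contact_graph(state, cutoff)
    n_idps = graph.number_of_nodes()
    if n_idps == 0:
        raise ValueError("state contains no IDPs")
    len_set = len_sample(graph)
    junctions = find_junctions(state, cutoff)
    sep_mean, _ = junction_separation(junctions, state)
    masses = [j.mass for j in junctions]
    return {
        "len_size": len(len_set),
        "dense_fraction": len(len_set) / n_idps,
        "n_junctions": len(junctions),
        "junction_mass": float(np.mean(masses)) if masses else float("nan"),
        "junction_separation": sep_mean,
        "n_idps": n_idps,
    }


@dataclass(frozen=True)
class NetworkStats:
    """Production-phase averages of the condensate structure."""

    len_mean: float
    len_sd: float
    dense_fraction_mean: float
    dense_fraction_sd: float
    junction_separation_mean: float
    junction_separation_sd: float
    junction_mass_mean: float
    junction_mass_sd: float
    n_samples: int
    n_idps: int

    def as_dict(self) -> dict:
        return {
            "len_mean": self.len_mean,
            "len_sd": self.len_sd,
            "dense_fraction_mean": self.dense_fraction_mean,
            "dense_fraction_sd": self.dense_fraction_sd,
            "junction_separation_mean": self.junction_separation_mean,
            "junction_separation_sd": self.junction_separation_sd,
            "junction_mass_mean": self.junction_mass_mean,
            "junction_mass_sd": self.junction_mass_sd,
            "n_samples": self.n_samples,
            "n_idps": self.n_idps,
        }


def _nan_stats(values: Iterable[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    return float(arr.mean()), float(arr.std())


def network_stats(samples, cutoff: float = DEFAULT_CUTOFF) -> NetworkStats:
    """Aggregate per-sample observables over the production phase.

    ``samples`` is an iterable of TrajectorySamples carrying states (or of
    bare States).  Samples tagged as equilibration are excluded; at least
    one production sample is required.
    """
    rows = []
    n_idps = 0
    for s in samples:
        state = getattr(s, "state", s)
        phase = getattr(s, "phase", "production")
        if phase != "production" or state is None:
            continue
        obs = sample_observables(state, cutoff)
        n_idps = obs["n_idps"]
        rows.append(obs)
    if not rows:
        raise ValueError("no production samples to average")
    len_mean, len_sd = _nan_stats(r["len_size"] for r in rows)
    df_mean, df_sd = _nan_stats(r["dense_fraction"] for r in rows)
    sep_mean, sep_sd = _nan_stats(r["junction_separation"] for r in rows)
    mass_mean, mass_sd = _nan_stats(r["junction_mass"] for r in rows)
    return NetworkStats(
        len_mean=len_mean,
        len_sd=len_sd,
        dense_fraction_mean=df_mean,
        dense_fraction_sd=df_sd,
        junction_separation_mean=sep_mean,
        junction_separation_sd=sep_sd,
        junction_mass_mean=mass_mean,
        junction_mass_sd=mass_sd,
        n_samples=len(rows),
        n_idps=n_idps,
    )
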