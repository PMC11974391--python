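"""SE(3)-invariant graph featurization of a Cα trace.

Each residue becomes one node. Per-node features (69 columns):

====================  =======  ==========================================
feature               columns  definition
====================  =======  ==========================================
packing density       1        # Cα within 10 Å (self excluded), divided
                               by the largest such count in the domain
N-terminus flag       1        1 for the first residue
C-terminus flag       1        1 for the last residue
τ pseudo-torsion      2        (sin τ, cos τ) of the dihedral through
                               Cα(i−1), Cα(i), Cα(i+1), Cα(i+2)
positional encoding   64       sinusoidal encoding of the 0-based
                               position within the domain
====================  =======  ==========================================

Edges connect Cα pairs within 10 Å (closed ball, stored in both
directions). Every feature is a function of inter-atomic distances,
dihedral angles, or sequence indices only, so the representation is
invariant under rigid rotation and translation of the input.

τ is encoded as (sin, cos) rather than a raw angle to remove the ±180°
discontinuity; residues without a complete quadruple get (0, 0).

The module also computes relative contact order, used to stratify the
retrieval benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import DomainStructure

logger = logging.getLogger(__name__)

__all__ = [
    "StructureGraph",
    "ContactOrderResult",
    "EDGE_CUTOFF",
    "CONTACT_CUTOFF",
    "N_NODE_FEATURES",
    "build_edges",
    "density_feature",
    "terminus_flags",
    "tau_angles",
    "positional_encoding",
    "featurize",
    "contact_order",
]

EDGE_CUTOFF = 10.0  # Å, Cα–Cα graph edges
CONTACT_CUTOFF = 8.0  # Å, Cβ–Cβ contact-order contacts
PE_DIM = 64
N_NODE_FEATURES = 1 + 2 + 2 + PE_DIM  # density, termini, (sin, cos) τ, PE


@dataclass
class StructureGraph:
    """Node features + radius-graph edges + coordinates for one domain."""

    node_features: np.ndarray  # (L, 69)
    coords: np.ndarray  # (L, 3) Å
    edges: np.ndarray  # (E, 2) int, directed, symmetric, no self-edges

    @property
    def n_nodes(self) -> int:
        return len(self.coords)


@dataclass
class ContactOrderResult:
    contact_order: float  # in [0, 1]
    N: int  # number of contacting pairs
    L: int  # sequence length
    pair_separations: np.ndarray  # (N,) sequence separations S_i


def build_edges(coords: np.ndarray, cutoff: float = EDGE_CUTOFF) -> np.ndarray:
    """Directed edge list over all Cα pairs within ``cutoff`` (inclusive).

    Each undirected pair appears in both orientations; no self-edges.
    Returned sorted lexicographically for determinism.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        return np.empty((0, 2), dtype=int)
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=int)
    directed = np.vstack([pairs, pairs[:, ::-1]])
    order = np.lexsort((directed[:, 1], directed[:, 0]))
    return directed[order]


def density_feature(coords: np.ndarray, cutoff: float = EDGE_CUTOFF) -> np.ndarray:
    """Neighbour count within ``cutoff`` (self excluded), normalized by the
    largest count in the domain. All zeros when no residue has a
    neighbour."""
    coords = np.asarray(coords, dtype=float)
    counts = np.zeros(len(coords), dtype=int)
    edges = build_edges(coords, cutoff)
    if len(edges):
        counts = np.bincount(edges[:, 0], minlength=len(coords))
    max_count = counts.max(initial=0)
    if max_count == 0:
        return np.zeros(len(coords))
    return counts / max_count


def terminus_flags(L: int) -> np.ndarray:
    """(L, 2) binary matrix flagging the N- and C-terminal residues.
    A single-residue domain is both termini."""
    if L < 1:
        raise ValueError("L must be >= 1")
    flags = np.zeros((L, 2))
    flags[0, 0] = 1.0
    flags[-1, 1] = 1.0
    return flags


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral (radians) of four points by the atan2 formula.
    Returns NaN when consecutive points coincide or are collinear."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1_norm = np.linalg.norm(b1)
    if b1_norm == 0 or np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        return float("nan")
    m1 = np.cross(n1, b1 / b1_norm)
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def tau_angles(coords: np.ndarray) -> np.ndarray:
    """(L, 2) matrix of (sin τ, cos τ).

    τ at node i is the dihedral through Cα(i−1), Cα(i), Cα(i+1), Cα(i+2);
    nodes without all four points — the first node, the last two, or any
    node of a chain shorter than 4 — get (0, 0), as do geometrically
    degenerate quadruples."""
    coords = np.asarray(coords, dtype=float)
    L = len(coords)
    out = np.zeros((L, 2))
    if L < 4:
        return out
    # vectorized signed dihedral over all complete quadruples
    b0 = coords[1:-2] - coords[:-3]
    b1 = coords[2:-1] - coords[1:-2]
    b2 = coords[3:] - coords[2:-1]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1_norm = np.linalg.norm(b1, axis=1)
    degenerate = (
        (b1_norm == 0)
        | (np.linalg.norm(n1, axis=1) == 0)
        | (np.linalg.norm(n2, axis=1) == 0)
    )
    safe_b1 = np.where(b1_norm[:, None] == 0, 1.0, b1_norm[:, None])
    m1 = np.cross(n1, b1 / safe_b1)
    tau = np.arctan2(
        np.einsum("ij,ij->i", m1, n2), np.einsum("ij,ij->i", n1, n2)
    )
    if np.any(degenerate):
        logger.warning(
            "degenerate Cα quadruple(s) at residues %s; τ set to 0",
            np.nonzero(degenerate)[0] + 1,
        )
    sin_cos = np.column_stack([np.sin(tau), np.cos(tau)])
    sin_cos[degenerate] = 0.0
    out[1 : L - 2] = sin_cos
    return out


def positional_encoding(L: int, d: int = PE_DIM) -> np.ndarray:
    """Transformer-style sinusoidal encoding of 0-based position within
    the domain: column 2k = sin(pos / 10000^(2k/d)), column 2k+1 the
    matching cosine."""
    if L < 1 or d < 2 or d % 2:
        raise ValueError("need L >= 1 and even d >= 2")
    pos = np.arange(L)[:, None]
    freq = 1.0 / 10000.0 ** (np.arange(0, d, 2) / d)
    angles = pos * freq[None, :]
    out = np.empty((L, d))
    out[:, 0::2] = np.sin(angles)
    out[:, 1::2] = np.cos(angles)
    return out


def featurize(structure: DomainStructure) -> StructureGraph:
    """Build the full node-feature matrix and 10 Å radius graph.

    Column order: [density | N-flag | C-flag | sin τ | cos τ | 64-D PE].
    """
    coords = structure.ca_coords
    L = structure.L
    edges = build_edges(coords)
    # density from the edge list (same 10 Å cutoff, self excluded)
    counts = (
        np.bincount(edges[:, 0], minlength=L) if len(edges) else np.zeros(L, dtype=int)
    )
    max_count = counts.max(initial=0)
    density = counts / max_count if max_count > 0 else np.zeros(L)
    features = np.concatenate(
        [
            density[:, None],
            terminus_flags(L),
            tau_angles(coords),
            positional_encoding(L),
        ],
        axis=1,
    )
    return StructureGraph(
        node_features=features,
        coords=coords.copy(),
        edges=edges,
    )


def contact_order(structure: DomainStructure) -> ContactOrderResult:
    """Relative contact order of the domain.

    All residue pairs i < j whose contact atoms (Cβ, or Cα where Cβ is
    absent) lie within 8 Å count as contacts; there is no minimum
    sequence separation. With S_i the separation j − i in positions
    within the domain, N contacts and length L, the contact order is
    Σ S_i / (L · N). Returns 0 with a warning when no pair is in
    contact.
    """
    if structure.L < 2:
        raise ValueError("contact order needs at least two residues")
    atoms = structure.contact_atoms()
    pairs = cKDTree(atoms).query_pairs(CONTACT_CUTOFF, output_type="ndarray")
    L = structure.L
    if len(pairs) == 0:
        logger.warning("no contacts within %.1f Å in %s", CONTACT_CUTOFF, structure.name)
        return ContactOrderResult(0.0, 0, L, np.empty(0, dtype=int))
    separations = np.abs(pairs[:, 1] - pairs[:, 0])
    value = separations.sum() / (L * len(pairs))
    return ContactOrderResult(float(value), len(pairs), L, np.sort(separations))
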