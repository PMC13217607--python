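"""Residue-graph construction: one-hot features and contact-map adjacency.

A protein chain becomes a graph whose nodes are residues.  Node features
are one-hot amino-acid identities (L x 20); edges connect residue pairs
whose representative coordinates lie strictly within a Euclidean distance
cutoff (9 A by default, which keeps consecutive backbone residues at
~3.8 A connected while limiting long-range noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import STANDARD_AA, ProteinChain

logger = logging.getLogger(__name__)

#: contact-map distance cutoff in Angstrom
DEFAULT_CUTOFF = 9.0

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@dataclass
class ProteinGraph:
    features: np.ndarray            # (L, 20) binary one-hot
    adjacency: np.ndarray           # (L, L) binary, symmetric, zero diagonal
    embeddings: np.ndarray          # (L, d) real
    target: np.ndarray | None       # (n_classes,) binary, None at predict time
    chain_ref: str = ""

    def __post_init__(self):
        L = self.features.shape[0]
        if self.adjacency.shape != (L, L):
            raise ValueError("adjacency shape mismatch")
        if self.embeddings.shape[0] != L:
            raise ValueError("embedding row count mismatch")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]

    @property
    def node_input(self) -> np.ndarray:
        """H0 = [X | E], the concatenated node input matrix."""
        return np.concatenate([self.features, self.embeddings], axis=1)


def one_hot_encode(sequence: str) -> np.ndarray:
    """One-hot encode a sequence over the 20 standard amino acids.

    Column order is alphabetical by one-letter code; 'X' (nonstandard or
    unknown) rows are all-zero.
    """
    X = np.zeros((len(sequence), 20), dtype=np.float64)
    for i, aa in enumerate(sequence):
        if aa == "X":
            logger.warning("nonstandard residue at position %d encoded as zeros",
                           i + 1)
            continue
        try:
            X[i, _AA_INDEX[aa]] = 1.0
        except KeyError:
            raise ValueError(f"unknown residue symbol {aa!r} at position {i + 1}")
    return X


def build_contact_map(coords: np.ndarray,
                      cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Binary adjacency: 1 iff inter-residue distance is strictly < cutoff.

    The diagonal is zero (no self-loops stored; graph layers that need
    self-loops add them internally).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (L, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinate")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    L = coords.shape[0]
    if L == 1:
        return np.zeros((1, 1))
    A = (squareform(pdist(coords)) < cutoff).astype(np.float64)
    np.fill_diagonal(A, 0.0)
    return A


def assemble_graph(chain: ProteinChain, embedder,
                   cutoff: float = DEFAULT_CUTOFF,
                   target: np.ndarray | None = None) -> ProteinGraph:
    """Build the full model input graph for one chain."""
    X = one_hot_encode(chain.sequence)
    A = build_contact_map(chain.coords(), cutoff=cutoff)
    E = np.asarray(embedder.embed(chain.sequence), dtype=np.float64)
    if E.shape[0] != len(chain):
        raise ValueError(
            f"embedder returned {E.shape[0]} rows for {len(chain)} residues")
    return ProteinGraph(features=X, adjacency=A, embeddings=E,
                        target=None if target is None
                        else np.asarray(target, dtype=np.int8),
                        chain_ref=chain.name)


# ---------------------------------------------------------------------------
# serialization: one .npz per graph, adjacency stored as COO edge list
# ---------------------------------------------------------------------------

def save_graph(graph: ProteinGraph, path: str | Path) -> None:
    ii, jj = np.nonzero(graph.adjacency)
    np.savez(path,
             features=graph.features.astype(np.int8),
             edges=np.stack([ii, jj]).astype(np.int32),
             n_nodes=np.int64(graph.n_nodes),
             embeddings=graph.embeddings,
             target=(np.array([]) if graph.target is None else graph.target),
             chain_ref=np.array(graph.chain_ref))


def load_graph(path: str | Path) -> ProteinGraph:
    with np.load(path, allow_pickle=False) as data:
        L = int(data["n_nodes"])
        A = np.zeros((L, L))
        ii, jj = data["edges"]
        A[ii, jj] = 1.0
        target = data["target"]
        return ProteinGraph(features=data["features"].astype(np.float64),
                            adjacency=A,
                            embeddings=data["embeddings"],
                            target=None if target.size == 0
                            else target.astype(np.int8),
                            chain_ref=str(data["chain_ref"]))
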