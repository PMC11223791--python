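"""Interface residue detection and the PPI interface graph.

Interface residues are those with at least one heavy atom within 5.0 A
(inclusive) of any atom of a different chain.  The interface graph has one
node per interface residue, carrying a per-residue embedding vector, and one
undirected edge per cross-chain residue pair in contact, carrying the
10-slot interaction-type count vector and the minimum contact distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .contacts import Contact, INTERACTION_ORDER
from .structures import (
    ComplexStructure,
    ResidueKey,
    StructureError,
    THREE_TO_ONE,
)


class InterfaceUndefinedError(StructureError):
    """Interface requested on a structure with fewer than two chains."""


class FeatureDimensionError(ValueError):
    """Embedding vectors of inconsistent dimension."""


class MissingEmbeddingError(KeyError):
    """Residue not present in a loaded embedding file."""


DEFAULT_INTERFACE_CUTOFF = 5.0


def interface_residues(
    structure: ComplexStructure, cutoff: float = DEFAULT_INTERFACE_CUTOFF
) -> set[ResidueKey]:
    """Residues with any heavy atom within ``cutoff`` of a different chain (<=)."""
    if len(structure.chains) < 2:
        raise InterfaceUndefinedError("interface requires at least two chains")
    residues = structure.residues()
    atoms = []
    owner = []
    for i, key in enumerate(residues):
        for atom in structure.residue_atoms(key):
            if not atom.is_hydrogen:
                atoms.append(atom)
                owner.append(i)
    coords = np.array([a.coords for a in atoms])
    owner = np.array(owner)
    chains = np.array([a.chain_id for a in atoms])
    tree = cKDTree(coords)
    result: set[ResidueKey] = set()
    for i, j in tree.query_pairs(cutoff):
        if chains[i] != chains[j]:
            result.add(residues[owner[i]])
            result.add(residues[owner[j]])
    return result


class EmbeddingProvider:
    """Contract: deterministic fixed-length vector per (structure, residue)."""

    dimension: int

    def vector(self, structure: ComplexStructure, key: ResidueKey) -> np.ndarray:
        raise NotImplementedError


class StubEmbeddingProvider(EmbeddingProvider):
    """Pseudorandom unit-norm vectors, a pure function of residue type and seed.

    Stands in for per-residue protein-language-model embeddings when none are
    supplied: identical residue types get identical vectors.
    """

    def __init__(self, dimension: int = 1024, seed: int = 0):
        if dimension < 1:
            raise ValueError("dimension must be >= 1")
        self.dimension = dimension
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def vector(self, structure: ComplexStructure, key: ResidueKey) -> np.ndarray:
        one = THREE_TO_ONE.get(structure.residue_name(key), "X")
        if one not in self._cache:
            rng = np.random.default_rng([self.seed, ord(one)])
            v = rng.standard_normal(self.dimension)
            self._cache[one] = v / np.linalg.norm(v)
        return self._cache[one]


def stub_embedding_provider(dimension: int = 1024, seed: int = 0) -> StubEmbeddingProvider:
    return StubEmbeddingProvider(dimension, seed)


class FileEmbeddingProvider(EmbeddingProvider):
    """Serves vectors stored per residue; lookups of absent residues raise."""

    def __init__(self, table: dict[ResidueKey, np.ndarray]):
        dims = {v.shape[0] for v in table.values()}
        if len(dims) > 1:
            raise FeatureDimensionError(f"inconsistent embedding dimensions {sorted(dims)}")
        if not table:
            raise FeatureDimensionError("empty embedding table")
        self.dimension = next(iter(dims))
        self._table = table

    def vector(self, structure: ComplexStructure, key: ResidueKey) -> np.ndarray:
        try:
            return self._table[key]
        except KeyError:
            raise MissingEmbeddingError(f"no embedding stored for residue {key}") from None


def load_embeddings(text: str) -> FileEmbeddingProvider:
    """Load a delimited embedding file: ``chain seq[icode] v1 v2 ...`` per line."""
    table: dict[ResidueKey, np.ndarray] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        chain, seq = parts[0], parts[1]
        icode = ""
        if seq[-1].isalpha():
            seq, icode = seq[:-1], seq[-1]
        table[ResidueKey(chain, int(seq), icode)] = np.array([float(x) for x in parts[2:]])
    return FileEmbeddingProvider(table)


def save_embeddings(table: dict[ResidueKey, np.ndarray]) -> str:
    lines = []
    for key in sorted(table):
        vec = " ".join(repr(float(x)) for x in table[key])
        lines.append(f"{key.chain_id} {key.residue_seq}{key.insertion_code} {vec}")
    return "\n".join(lines) + "\n"


@dataclass
class InterfaceGraph:
    """Undirected residue graph over the interface.

    ``edges[k] = (i, j)`` joins nodes of different chains; ``edge_type_counts``
    row k holds per-interaction-type contact counts, ``edge_min_distance[k]``
    the closest atom pair of that residue pair.
    """

    nodes: list[ResidueKey]
    node_features: np.ndarray  # (n_nodes, dim)
    edges: list[tuple[int, int]]
    edge_type_counts: np.ndarray  # (n_edges, 10)
    edge_min_distance: np.ndarray  # (n_edges,)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def adjacency(self, weighted: bool = False) -> np.ndarray:
        """Simple symmetric adjacency; weighted sums the edge type counts."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        for k, (i, j) in enumerate(self.edges):
            w = float(self.edge_type_counts[k].sum()) if weighted else 1.0
            a[i, j] = a[j, i] = w
        return a


def build_interface_graph(
    structure: ComplexStructure,
    contacts: list[Contact],
    provider: EmbeddingProvider,
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
) -> InterfaceGraph:
    """Assemble the interface graph from detected/imported contacts.

    Nodes are the interface residues in canonical order; intra-chain contacts
    never contribute edges; per-type counts aggregate over atom pairs of the
    same residue pair.
    """
    nodes = sorted(interface_residues(structure, cutoff))
    index = {key: i for i, key in enumerate(nodes)}
    type_index = {t: i for i, t in enumerate(INTERACTION_ORDER)}
    edge_data: dict[tuple[int, int], tuple[np.ndarray, float]] = {}
    for c in contacts:
        if not c.cross_chain:
            continue
        ra, rb = c.residues
        if ra not in index or rb not in index:
            continue
        i, j = sorted((index[ra], index[rb]))
        counts, dmin = edge_data.get((i, j), (np.zeros(len(INTERACTION_ORDER)), np.inf))
        for t in c.types:
            counts[type_index[t]] += 1
        edge_data[(i, j)] = (counts, min(dmin, c.distance))
    features = []
    for key in nodes:
        v = np.asarray(provider.vector(structure, key), dtype=float)
        if v.shape != (provider.dimension,):
            raise FeatureDimensionError(
                f"embedding for {key} has shape {v.shape}, expected ({provider.dimension},)"
            )
        features.append(v)
    edges = sorted(edge_data)
    return InterfaceGraph(
        nodes=nodes,
        node_features=np.array(features) if features else np.empty((0, provider.dimension)),
        edges=edges,
        edge_type_counts=(
            np.array([edge_data[e][0] for e in edges])
            if edges else np.empty((0, len(INTERACTION_ORDER)))
        ),
        edge_min_distance=np.array([edge_data[e][1] for e in edges]),
    )
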