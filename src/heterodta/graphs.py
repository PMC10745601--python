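"""Graph construction for targets, pockets and drugs.

Targets and pockets become residue contact graphs: vertices are C-alpha
atoms, and an edge joins any two residues whose C-alpha distance is within
a cutoff (8 A by default).  Drugs become molecular graphs whose vertices are
atoms and whose edges are the covalent bonds of the ligand file, hydrogens
optionally stripped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .encoders import Vocabulary, one_hot_encode
from .structio import LigandMolecule, ProteinStructure

__all__ = [
    "Graph",
    "BatchedGraph",
    "GraphShapeError",
    "build_residue_graph",
    "build_molecular_graph",
    "batch_graphs",
    "unbatch_graphs",
    "save_graph_archive",
    "load_graph_archive",
]

DEFAULT_CONTACT_CUTOFF_A = 8.0


class GraphShapeError(Exception):
    """Feature matrix and vertex set disagree."""


@dataclass
class Graph:
    """An undirected vertex-featured graph.

    ``edges`` holds unordered index pairs (stored as (min, max)); self-edges
    are never stored.  ``vertex_features`` has one row per vertex.
    """

    n_vertices: int
    edges: set
    vertex_features: np.ndarray
    vertex_labels: list | None = None

    def __post_init__(self):
        self.vertex_features = np.asarray(self.vertex_features, dtype=float)
        if self.vertex_features.shape[0] != self.n_vertices:
            raise GraphShapeError(
                f"feature rows ({self.vertex_features.shape[0]}) != "
                f"vertices ({self.n_vertices})"
            )
        norm = set()
        for i, j in self.edges:
            if i == j:
                raise GraphShapeError(f"self-edge on vertex {i}")
            if not (0 <= i < self.n_vertices and 0 <= j < self.n_vertices):
                raise GraphShapeError(f"edge ({i},{j}) out of range")
            norm.add((min(i, j), max(i, j)))
        self.edges = norm

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def feature_dim(self) -> int:
        return self.vertex_features.shape[1]

    def edge_index(self) -> np.ndarray:
        """Directed 2 x 2E edge array (both orientations), sorted for
        determinism.  Empty edge sets yield a 2 x 0 array."""
        if not self.edges:
            return np.zeros((2, 0), dtype=np.int64)
        pairs = sorted(self.edges)
        src = [i for i, j in pairs] + [j for i, j in pairs]
        dst = [j for i, j in pairs] + [i for i, j in pairs]
        return np.array([src, dst], dtype=np.int64)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class BatchedGraph:
    """Disjoint union of several graphs with a vertex-to-graph membership map."""

    graphs: list
    n_vertices: int
    edges: set
    vertex_features: np.ndarray
    membership: np.ndarray
    offsets: np.ndarray

    @property
    def n_graphs(self) -> int:
        return len(self.offsets) - 1

    def edge_index(self) -> np.ndarray:
        if not self.edges:
            return np.zeros((2, 0), dtype=np.int64)
        pairs = sorted(self.edges)
        src = [i for i, j in pairs] + [j for i, j in pairs]
        dst = [j for i, j in pairs] + [i for i, j in pairs]
        return np.array([src, dst], dtype=np.int64)


def build_residue_graph(
    structure: ProteinStructure,
    features: np.ndarray,
    cutoff_A: float = DEFAULT_CONTACT_CUTOFF_A,
) -> Graph:
    """Contact graph over the residues of a target or pocket.

    An edge joins residues i != j whenever their C-alpha Euclidean distance
    is <= ``cutoff_A`` (closed boundary, double precision).  Vertex order is
    residue order; extra (padded) feature rows are sliced off.
    """
    n = len(structure)
    features = np.asarray(features, dtype=float)
    if features.shape[0] < n:
        raise GraphShapeError(
            f"{features.shape[0]} feature rows for {n} residues"
        )
    coords = structure.ca_coords
    edges = set()
    if n > 1:
        dist = squareform(pdist(coords))
        src, dst = np.nonzero(np.triu(dist <= cutoff_A, k=1))
        edges = {(int(i), int(j)) for i, j in zip(src, dst)}
    return Graph(
        n_vertices=n,
        edges=edges,
        vertex_features=features[:n],
        vertex_labels=[
            f"{r.chain_id}:{r.resseq}{r.icode.strip()}:{r.three_letter_code}"
            for r in structure.residues
        ],
    )


def build_molecular_graph(
    mol: LigandMolecule,
    vocab: Vocabulary,
    include_hydrogens: bool = False,
) -> Graph:
    """Molecular graph of a drug: atoms as vertices, covalent bonds as edges.

    Hydrogens (and any bond touching one) are removed unless
    ``include_hydrogens``.  Vertex features are one-hot element encodings
    over the atom vocabulary.
    """
    keep = [
        k for k, (el, _) in enumerate(mol.atoms)
        if include_hydrogens or el.upper() != "H"
    ]
    remap = {old: new for new, old in enumerate(keep)}
    elements = [mol.atoms[k][0] for k in keep]
    edges = {
        (min(remap[i], remap[j]), max(remap[i], remap[j]))
        for i, j, _ in mol.bonds
        if i in remap and j in remap
    }
    features = one_hot_encode(
        [el if el in vocab else "UNK" for el in elements], vocab
    )
    return Graph(
        n_vertices=len(keep),
        edges=edges,
        vertex_features=features,
        vertex_labels=[f"{mol.id}:{k}:{mol.atoms[k][0]}" for k in keep],
    )


def batch_graphs(graphs) -> BatchedGraph:
    """Block-diagonal disjoint union; unbatching recovers the originals."""
    graphs = list(graphs)
    if not graphs:
        raise ValueError("cannot batch zero graphs")
    dims = {g.feature_dim for g in graphs}
    if len(dims) > 1:
        raise GraphShapeError(f"mixed feature dimensions: {sorted(dims)}")
    offsets = np.concatenate([[0], np.cumsum([g.n_vertices for g in graphs])])
    edges = set()
    membership = np.zeros(offsets[-1], dtype=np.int64)
    for k, g in enumerate(graphs):
        off = int(offsets[k])
        membership[off : off + g.n_vertices] = k
        edges.update((i + off, j + off) for i, j in g.edges)
    return BatchedGraph(
        graphs=graphs,
        n_vertices=int(offsets[-1]),
        edges=edges,
        vertex_features=np.vstack([g.vertex_features for g in graphs]),
        membership=membership,
        offsets=offsets.astype(np.int64),
    )


def unbatch_graphs(batched: BatchedGraph) -> list:
    out = []
    for k in range(batched.n_graphs):
        lo, hi = int(batched.offsets[k]), int(batched.offsets[k + 1])
        edges = {
            (i - lo, j - lo)
            for i, j in batched.edges
            if lo <= i < hi and lo <= j < hi
        }
        out.append(
            Graph(
                n_vertices=hi - lo,
                edges=edges,
                vertex_features=batched.vertex_features[lo:hi],
                vertex_labels=(
                    batched.graphs[k].vertex_labels if k < len(batched.graphs) else None
                ),
            )
        )
    return out


def save_graph_archive(path, graphs: dict) -> None:
    """Cache featurized graphs as an edge-list + feature-matrix archive."""
    payload = {}
    for name, g in graphs.items():
        payload[f"{name}__edges"] = g.edge_index()
        payload[f"{name}__features"] = g.vertex_features
    np.savez_compressed(path, **payload)


def load_graph_archive(path) -> dict:
    data = np.load(path)
    names = sorted({k.rsplit("__", 1)[0] for k in data.files})
    out = {}
    for name in names:
        ei = data[f"{name}__edges"]
        feats = data[f"{name}__features"]
        edges = {(int(i), int(j)) for i, j in zip(ei[0], ei[1]) if i < j}
        out[name] = Graph(
            n_vertices=feats.shape[0], edges=edges, vertex_features=feats
        )
    return out
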