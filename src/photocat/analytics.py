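"""Dataset diagnostics: Tanimoto similarity distributions and a tree-map
embedding of reaction fingerprints.

Molecule fingerprints are radius-2 circular (Morgan) substructure hashes on
2048 bits; dataset redundancy is summarized by the Tanimoto similarity
distribution over uniformly sampled product pairs (a diverse database
concentrates mass below ~0.2). Reactions are embedded by a structural
difference fingerprint — summed product counts minus summed reactant counts,
folded to a fixed length — and laid out as a tree: exact k-nearest-neighbor
graph under cosine distance, minimum spanning tree by Kruskal's algorithm
(stable tie-break in edge insertion order), and a deterministic radial tree
drawing. At this scale exact kNN replaces approximate LSH-forest indexing;
``knn_graph`` accepts any precomputed distance hook for larger corpora.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .records import ChemistryParseError, ReactionRecord

__all__ = [
    "Fingerprint",
    "TreeLayout",
    "fingerprint",
    "tanimoto",
    "similarity_distribution",
    "SimilarityDistribution",
    "reaction_fingerprint",
    "knn_graph",
    "mst",
    "tree_layout",
    "export_layout",
]


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length substructure bit set."""

    bits: np.ndarray  # bool array

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryParseError(f"unparsable SMILES: {smiles!r}")
    return mol


def fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Morgan (circular substructure) fingerprint; deterministic per molecule
    and invariant to the SMILES rendering of the same graph."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=bool)
    for b in gen.GetFingerprint(_mol(smiles)).GetOnBits():
        arr[b] = True
    return Fingerprint(arr)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a & b| / |a | b|; two empty sets are defined as identical (1.0)."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint lengths differ")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a.bits, b.bits).sum()) / union


@dataclass(frozen=True)
class SimilarityDistribution:
    """Histogram of pairwise product Tanimoto similarities."""

    bin_edges: np.ndarray  # fixed 0.0..1.0, width 0.05
    counts: np.ndarray
    n_pairs: int

    def fraction_below(self, threshold: float) -> float:
        centers_right = self.bin_edges[1:]
        mass = self.counts[centers_right <= threshold + 1e-12].sum()
        return float(mass / max(1, self.counts.sum()))


def similarity_distribution(
    records: Sequence[ReactionRecord],
    n_pairs: int,
    rng: np.random.Generator | int,
    radius: int = 2,
    n_bits: int = 2048,
) -> SimilarityDistribution:
    """Tanimoto over uniformly sampled pairs of (first) products."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    smiles = [r.products[0].smiles for r in records]
    fps: dict[int, Fingerprint] = {}

    def fp(i: int) -> Fingerprint:
        if i not in fps:
            fps[i] = fingerprint(smiles[i], radius, n_bits)
        return fps[i]

    edges = np.arange(0.0, 1.0001, 0.05)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for _ in range(n_pairs):
        i, j = rng.choice(len(records), size=2, replace=False)
        s = tanimoto(fp(int(i)), fp(int(j)))
        b = min(int(s / 0.05), len(counts) - 1)
        counts[b] += 1
    return SimilarityDistribution(edges, counts, n_pairs)


def reaction_fingerprint(
    record: ReactionRecord, radius: int = 2, n_bits: int = 256
) -> np.ndarray:
    """Signed structural difference fingerprint of a reaction.

    Summed product Morgan count-vectors minus summed reactant count-vectors,
    folded to ``n_bits``. The identity reaction maps to the zero vector.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    vec = np.zeros(n_bits, dtype=np.int32)
    for mol in record.products:
        cv = gen.GetCountFingerprint(_mol(mol.smiles))
        for idx, cnt in cv.GetNonzeroElements().items():
            vec[idx] += cnt
    for mol in record.reactants:
        cv = gen.GetCountFingerprint(_mol(mol.smiles))
        for idx, cnt in cv.GetNonzeroElements().items():
            vec[idx] -= cnt
    return vec


# ---------------------------------------------------------------------------
# kNN graph -> MST -> tree layout
# ---------------------------------------------------------------------------


def _cosine_distances(vectors: np.ndarray) -> np.ndarray:
    x = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    norms[norms == 0.0] = 1.0
    unit = x / norms[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    return 1.0 - sim


def knn_graph(vectors: np.ndarray, k: int) -> nx.Graph:
    """Symmetric exact k-nearest-neighbor graph with cosine-distance weights."""
    x = np.asarray(vectors, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two vectors")
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n, got k={k}, n={n}")
    dist = _cosine_distances(x)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        neighbors = [j for j in order if j != i][:k]
        for j in neighbors:
            g.add_edge(i, int(j), weight=float(dist[i, j]))
    return g


def mst(graph: nx.Graph) -> nx.Graph:
    """Minimum spanning tree (forest on disconnected input) via Kruskal.

    Edges are pre-sorted by (weight, insertion index); the stable sort makes
    tie-breaking deterministic in edge insertion order.
    """
    tree = nx.minimum_spanning_tree(graph, weight="weight", algorithm="kruskal")
    return tree


@dataclass(frozen=True)
class TreeLayout:
    """2-D coordinates per node plus the (acyclic, spanning) edge list."""

    coordinates: dict[int, tuple[float, float]]
    edges: tuple[tuple[int, int], ...]


def tree_layout(tree: nx.Graph) -> TreeLayout:
    """Deterministic radial drawing of a tree (or forest).

    Nodes sit on circles whose radius is their depth from the component root
    (the lowest-index node); each leaf claims an angular slot in DFS order
    and internal nodes take the mean angle of their subtree. No two nodes
    share coordinates.
    """
    n = tree.number_of_nodes()
    if n == 0:
        raise ValueError("empty tree")
    if tree.number_of_edges() >= n:
        raise ValueError("input graph has a cycle; expected a tree/forest")

    coords: dict[int, tuple[float, float]] = {}
    components = [sorted(c) for c in nx.connected_components(tree)]
    components.sort(key=lambda c: c[0])
    # leaves of all components share one global angular budget
    slot = [0]
    total_leaves = sum(
        max(1, sum(1 for v in comp if tree.degree(v) <= 1)) for comp in components
    )

    def angle_of(comp_root: int, offset_x: float) -> None:
        angles: dict[int, float] = {}

        def dfs(v: int, parent: int | None, depth: int) -> float:
            children = sorted(u for u in tree.neighbors(v) if u != parent)
            if not children:
                a = 2.0 * np.pi * slot[0] / max(1, total_leaves)
                slot[0] += 1
            else:
                a = float(np.mean([dfs(u, v, depth + 1) for u in children]))
            angles[v] = a
            r = float(depth)
            coords[v] = (offset_x + r * np.cos(a), r * np.sin(a))
            return a

        dfs(comp_root, None, 0)

    offset = 0.0
    for comp in components:
        angle_of(comp[0], offset)
        depth = max(1, len(comp))
        offset += 2.0 * depth  # keep components apart

    # perturb exact collisions deterministically (possible for mean-angle ties)
    seen: dict[tuple[float, float], int] = {}
    for v in sorted(coords):
        key = (round(coords[v][0], 9), round(coords[v][1], 9))
        if key in seen:
            bump = 1e-6 * (v + 1)
            coords[v] = (coords[v][0] + bump, coords[v][1] + bump)
        else:
            seen[key] = v
    edges = tuple(sorted(tuple(sorted(e)) for e in tree.edges()))
    return TreeLayout(coords, edges)


def export_layout(layout: TreeLayout, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.nodes.tsv`` (id, x, y) and ``<prefix>.edges.tsv``."""
    prefix = Path(prefix)
    nodes_path = prefix.with_suffix(".nodes.tsv")
    edges_path = prefix.with_suffix(".edges.tsv")
    with nodes_path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "x", "y"])
        for v in sorted(layout.coordinates):
            x, y = layout.coordinates[v]
            w.writerow([v, f"{x:.6f}", f"{y:.6f}"])
    with edges_path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["source", "target"])
        for a, b in layout.edges:
            w.writerow([a, b])
    return nodes_path, edges_path
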