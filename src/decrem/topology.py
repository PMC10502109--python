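"""Topological coupling analysis of metabolic networks.

A metabolic network is viewed as a directed bipartite graph with one node per
metabolite and one node per reaction; substrate->reaction and
reaction->product arcs carry the direction of flux (both orientations for
reversible reactions).  Reactions that share many simple directed cycles in
this graph are topologically *coupled*: they form closed routes (TCA-like
cycles, interlocked reversible pairs) whose fluxes move together.  The
coupling strength a_ij between reactions i and j is the number of simple
directed cycles passing through both reaction nodes, counted exhaustively up
to a configurable cycle-length cap.

Coupled reactions are then grouped into substructures by minimizing a
generalized weighted cut (WCut): the sum over clusters of the cross-cluster
cycle weight normalized by the cluster degree.  Reactions that lie on no
cycle at all are flagged non-coupled (NC) and left out of the clustering.

Notes on cycle counting
-----------------------
* Cycle length is measured in reaction nodes; a cap of L reaction nodes
  corresponds to 2L nodes of the bipartite graph (the cycle alternates
  metabolite and reaction nodes).  Unbounded simple-cycle counting is
  #P-hard, so genome-scale runs require the cap; counts are monotone
  nondecreasing in L.
* Cycles that traverse the same reaction in both directions (forward then
  backward through a reversible reaction) are excluded: they are artifacts
  of reversibility, not coordinated flux routes.
* For fully reversible cycles, the two opposite orientations count as two
  distinct directed cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .model_io import MetabolicModel

DEFAULT_MAX_CYCLE_LEN = 12
DEFAULT_SEED = 17

NC_LABEL = -1


@dataclass
class CouplingGraph:
    """Bipartite metabolite-reaction digraph plus its direction-resolved form.

    ``graph`` has exactly m + n nodes (``("M", i)`` and ``("R", j)``) with
    substrate->reaction and reaction->product arcs, duplicated in the reverse
    orientation for reversible reactions.  ``directed`` is the expansion used
    for cycle enumeration, where each reversible reaction is represented by
    two direction nodes ``("R", j, +1)`` and ``("R", j, -1)``.
    """

    graph: nx.DiGraph
    directed: nx.DiGraph
    reaction_ids: list[str]
    metabolite_ids: list[str]

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)


@dataclass
class SimilarityMatrix:
    """Simple-cycle co-membership counts between reactions."""

    A: np.ndarray
    reaction_ids: list[str]
    max_cycle_len: int

    def degrees(self) -> np.ndarray:
        """Weighted degree D_i = sum_j a_ij of every reaction node."""
        return self.A.sum(axis=1)


@dataclass
class ReactionClusters:
    """A partition of the coupled reactions plus the non-coupled remainder."""

    clusters: list[list[int]]
    non_coupled: list[int]
    objective: float
    reaction_ids: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> np.ndarray:
        """Per-reaction cluster label; NC reactions get -1."""
        n = len(self.reaction_ids) if self.reaction_ids else (
            max((max(c) for c in self.clusters if c), default=-1) + 1
        )
        lab = np.full(n, NC_LABEL, dtype=int)
        for k, members in enumerate(self.clusters):
            lab[list(members)] = k
        return lab


def build_coupling_graph(model: MetabolicModel) -> CouplingGraph:
    """Build the bipartite reaction-metabolite digraph of a model.

    Arcs run substrate -> reaction -> product; a reversible reaction
    contributes the mirrored arcs as well, so its arc count doubles.
    """
    if model.n_reactions == 0:
        raise ValueError("empty model")
    G = nx.DiGraph()
    H = nx.DiGraph()
    for i in range(model.n_metabolites):
        G.add_node(("M", i), kind="metabolite")
        H.add_node(("M", i), kind="metabolite")
    reversible = model.reversible
    for j in range(model.n_reactions):
        G.add_node(("R", j), kind="reaction")
        H.add_node(("R", j, +1), kind="reaction")
        if reversible[j]:
            H.add_node(("R", j, -1), kind="reaction")
    rows, cols = np.nonzero(model.S)
    for i, j in zip(rows, cols):
        coeff = model.S[i, j]
        if coeff < 0:  # substrate of the forward direction
            G.add_edge(("M", i), ("R", j))
            H.add_edge(("M", i), ("R", j, +1))
            if reversible[j]:
                G.add_edge(("R", j), ("M", i))
                H.add_edge(("R", j, -1), ("M", i))
        else:  # product of the forward direction
            G.add_edge(("R", j), ("M", i))
            H.add_edge(("R", j, +1), ("M", i))
            if reversible[j]:
                G.add_edge(("M", i), ("R", j))
                H.add_edge(("M", i), ("R", j, -1))
    return CouplingGraph(
        graph=G,
        directed=H,
        reaction_ids=list(model.reaction_ids),
        metabolite_ids=list(model.metabolite_ids),
    )


def _iter_reaction_cycles(directed: nx.DiGraph, max_cycle_len: int):
    """Yield the frozen reaction-index set of every admissible simple cycle.

    Enumerates simple directed cycles of the direction-resolved graph with at
    most ``max_cycle_len`` reaction nodes, discarding cycles that use the
    same reaction in both directions.
    """
    for cycle in nx.simple_cycles(directed, length_bound=2 * max_cycle_len):
        rxn_dirs = [node for node in cycle if node[0] == "R"]
        reactions = {node[1] for node in rxn_dirs}
        if len(reactions) < len(rxn_dirs):
            continue  # same reaction traversed forward and backward
        yield frozenset(reactions)


def cycle_similarity(
    graph: CouplingGraph, max_cycle_len: int = DEFAULT_MAX_CYCLE_LEN
) -> SimilarityMatrix:
    """Count, for every reaction pair, the simple cycles through both nodes.

    ``A[i, j]`` is the exhaustive number of simple directed cycles of length
    at most ``max_cycle_len`` reaction nodes that contain both reaction nodes
    i and j; the diagonal counts all cycles through a single reaction.
    """
    if max_cycle_len < 2:
        raise ValueError("max_cycle_len must be >= 2 reaction nodes")
    n = graph.n_reactions
    A = np.zeros((n, n), dtype=np.int64)
    for reactions in _iter_reaction_cycles(graph.directed, max_cycle_len):
        members = sorted(reactions)
        for i in members:
            A[i, i] += 1
        for i, j in combinations(members, 2):
            A[i, j] += 1
            A[j, i] += 1
    if n > 1 and not np.any(A[~np.eye(n, dtype=bool)]):
        warnings.warn(
            "no cycle couples two distinct reactions at this length cap",
            stacklevel=2,
        )
    return SimilarityMatrix(A=A, reaction_ids=list(graph.reaction_ids), max_cycle_len=max_cycle_len)


# ---------------------------------------------------------------------------
# Weighted-cut clustering
# ---------------------------------------------------------------------------


def wcut(clusters: ReactionClusters, similarity: SimilarityMatrix) -> float:
    """Generalized weighted cut of a clustering.

    WCut(C) = sum_k Cut(C_k, complement of C_k) / D_k, where Cut sums a_ij
    over cross-boundary pairs and D_k is the total cycle degree of the
    cluster.  Zero iff no cycle crosses a cluster boundary.
    """
    A = similarity.A
    D = A.sum(axis=1)
    total = 0.0
    n = A.shape[0]
    for members in clusters.clusters:
        members = np.asarray(members, dtype=int)
        D_k = float(D[members].sum())
        if D_k == 0:
            raise ValueError("cluster has no cycle weight (D_k = 0)")
        mask = np.zeros(n, dtype=bool)
        mask[members] = True
        cut = float(A[np.ix_(members, np.flatnonzero(~mask))].sum())
        total += cut / D_k
    return total


def _wcut_labels(labels: np.ndarray, A: np.ndarray) -> float:
    """WCut of a label vector over the coupled submatrix (no validity checks)."""
    D = A.sum(axis=1)
    total = 0.0
    for k in np.unique(labels):
        mask = labels == k
        D_k = D[mask].sum()
        if D_k == 0:
            return np.inf
        total += A[np.ix_(mask, ~mask)].sum() / D_k
    return float(total)


def _greedy_refine(labels: np.ndarray, A: np.ndarray, min_size: int = 2,
                   max_sweeps: int = 20) -> np.ndarray:
    """Single-node moves that decrease WCut, lowest-index-first tie break."""
    labels = labels.copy()
    n = labels.size
    cluster_ids = np.unique(labels)
    best = _wcut_labels(labels, A)
    for _ in range(max_sweeps):
        improved = False
        for i in range(n):
            current = labels[i]
            if np.count_nonzero(labels == current) <= min_size:
                continue
            for k in cluster_ids:
                if k == current:
                    continue
                labels[i] = k
                val = _wcut_labels(labels, A)
                if val < best - 1e-12:
                    best = val
                    current = k
                    improved = True
                else:
                    labels[i] = current
        if not improved:
            break
    return labels


def _spectral_labels(A: np.ndarray, K: int, seed: int) -> np.ndarray:
    """Normalized spectral embedding of A followed by seeded k-means."""
    D = A.sum(axis=1).astype(float)
    d_isqrt = 1.0 / np.sqrt(D)
    L_sym = np.eye(A.shape[0]) - (A * d_isqrt[:, None]) * d_isqrt[None, :]
    # K smallest eigenvectors of the symmetric-normalized Laplacian
    _, vecs = eigh(L_sym, subset_by_index=[0, K - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    embedding = vecs / norms
    km = KMeans(n_clusters=K, random_state=seed, n_init=10)
    return km.fit_predict(embedding)


def _relabel_min_size(labels: np.ndarray, A: np.ndarray, min_size: int = 2) -> np.ndarray:
    """Merge clusters smaller than min_size into their most-similar neighbor."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        small = ids[counts < min_size]
        if small.size == 0 or ids.size == 1:
            return labels
        k = small[0]
        members = np.flatnonzero(labels == k)
        best_target, best_weight = None, -1.0
        for other in ids:
            if other == k:
                continue
            weight = A[np.ix_(members, np.flatnonzero(labels == other))].sum()
            if weight > best_weight:
                best_weight, best_target = weight, other
        labels[members] = best_target


def best_wcut_cluster(
    similarity: SimilarityMatrix,
    K_range: range | list[int] = range(2, 11),
    seed: int = DEFAULT_SEED,
) -> ReactionClusters:
    """Cluster coupled reactions by minimizing the weighted cut.

    Reactions with zero total cycle weight are assigned to the non-coupled
    (NC) set.  For each candidate K, a spectral relaxation of the WCut
    objective (normalized-cut-style eigen-embedding) seeds k-means, followed
    by greedy single-move refinement; the connected components of the
    coupling matrix are also scored as a candidate partition.  The partition
    with the smallest WCut over all candidates is returned.
    """
    A_full = similarity.A
    n = A_full.shape[0]
    if not np.allclose(A_full, A_full.T):
        raise ValueError("similarity matrix must be symmetric")
    D = A_full.sum(axis=1)
    coupled = np.flatnonzero(D > 0)
    non_coupled = sorted(np.flatnonzero(D == 0).tolist())
    if coupled.size == 0:
        warnings.warn("no coupled reactions: empty clustering", stacklevel=2)
        return ReactionClusters(
            clusters=[], non_coupled=non_coupled, objective=0.0,
            reaction_ids=list(similarity.reaction_ids),
        )
    A = A_full[np.ix_(coupled, coupled)]
    m = coupled.size

    candidates: list[np.ndarray] = []
    # connected components of the coupling graph are a natural partition and
    # achieve WCut = 0 whenever the blocks are truly disjoint
    n_comp, comp_labels = _connected_components(A)
    K_values = sorted({int(K) for K in K_range if 2 <= int(K) <= m // 2 or int(K) == 1})
    if n_comp > 1 and any(K == n_comp for K in K_range):
        candidates.append(comp_labels)
    for K in K_values:
        if K == 1:
            candidates.append(np.zeros(m, dtype=int))
            continue
        raw = _spectral_labels(A, K, seed)
        raw = _relabel_min_size(raw, A)
        refined = _greedy_refine(raw, A)
        candidates.append(refined)
    if not candidates:
        candidates.append(np.zeros(m, dtype=int))

    best_labels, best_val = None, np.inf
    for labels in candidates:
        val = _wcut_labels(labels, A)
        if val < best_val - 1e-12:
            best_val, best_labels = val, labels
    clusters = [
        sorted(coupled[np.flatnonzero(best_labels == k)].tolist())
        for k in np.unique(best_labels)
    ]
    clusters.sort(key=lambda c: c[0])
    return ReactionClusters(
        clusters=clusters,
        non_coupled=non_coupled,
        objective=float(best_val),
        reaction_ids=list(similarity.reaction_ids),
    )


def _connected_components(A: np.ndarray) -> tuple[int, np.ndarray]:
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import csr_matrix

    n_comp, labels = connected_components(csr_matrix(A > 0), directed=False)
    return n_comp, labels
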