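"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: cycle counting is a
hand-rolled DFS over an adjacency structure built straight from the
stoichiometric matrix, and the minimal-support basis search enumerates
column subsets by size with an LP feasibility check per subset.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import linprog


def brute_cycle_counts(S: np.ndarray, lb: np.ndarray, max_len: int) -> np.ndarray:
    """Count simple directed cycles through each reaction pair by plain DFS.

    Nodes are metabolites ("m", i) and direction-resolved reactions
    ("r", j, d); cycles using both directions of one reaction are discarded;
    each directed cycle is counted once by only allowing its smallest node
    as the start.  ``max_len`` caps the number of reaction nodes per cycle.
    """
    m, n = S.shape
    reversible = lb < 0
    nodes: list[tuple] = [("m", i) for i in range(m)]
    for j in range(n):
        nodes.append(("r", j, 1))
        if reversible[j]:
            nodes.append(("r", j, -1))
    index = {node: k for k, node in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]

    def arc(a, b):
        adj[index[a]].append(index[b])

    for i in range(m):
        for j in range(n):
            coeff = S[i, j]
            if coeff < 0:
                arc(("m", i), ("r", j, 1))
                if reversible[j]:
                    arc(("r", j, -1), ("m", i))
            elif coeff > 0:
                arc(("r", j, 1), ("m", i))
                if reversible[j]:
                    arc(("m", i), ("r", j, -1))

    A = np.zeros((n, n), dtype=np.int64)
    n_nodes = len(nodes)
    on_path = [False] * n_nodes
    path: list[int] = []

    def record():
        rxn_dirs = [nodes[k] for k in path if nodes[k][0] == "r"]
        rxns = {node[1] for node in rxn_dirs}
        if len(rxns) < len(rxn_dirs):
            return
        members = sorted(rxns)
        for a in members:
            A[a, a] += 1
        for a, b in combinations(members, 2):
            A[a, b] += 1
            A[b, a] += 1

    def dfs(start: int, current: int, n_rxn: int):
        for nxt in adj[current]:
            if nxt == start:
                record()
            elif nxt > start and not on_path[nxt]:
                is_rxn = nodes[nxt][0] == "r"
                if is_rxn and n_rxn >= max_len:
                    continue
                on_path[nxt] = True
                path.append(nxt)
                dfs(start, nxt, n_rxn + (1 if is_rxn else 0))
                path.pop()
                on_path[nxt] = False

    for start in range(n_nodes):
        on_path[start] = True
        path.append(start)
        dfs(start, start, 1 if nodes[start][0] == "r" else 0)
        path.pop()
        on_path[start] = False
    return A


def _nonzero_in_box(S_T: np.ndarray, lb_T: np.ndarray, ub_T: np.ndarray,
                    rng: np.random.Generator, n_nonzero: int | None = None,
                    tries: int = 4) -> np.ndarray | None:
    """A steady-state vector in the box with nonzero leading part, or None."""
    k = S_T.shape[1]
    lead = k if n_nonzero is None else n_nonzero
    for _ in range(tries):
        w = np.zeros(k)
        w[:lead] = rng.uniform(-1.0, 1.0, size=lead)
        for sign in (1.0, -1.0):
            res = linprog(
                sign * w,
                A_eq=S_T,
                b_eq=np.zeros(S_T.shape[0]),
                bounds=list(zip(lb_T, ub_T)),
                method="highs",
            )
            if res.success and np.abs(res.x[:lead]).max() > 1e-7:
                return res.x
    return None


def minimal_support_basis_sizes(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    r: int,
    n_elements: int | None = None,
    seed: int = 0,
) -> list[int]:
    """Element-support sizes of a sparsest bound-feasible null-space basis.

    Enumerates element-column subsets by increasing size (columns beyond
    ``n_elements`` are artificial exchanges, always free); a subset is
    usable when a steady-state vector with nonzero element part supported on
    it fits the flux bounds.  The greedy accept-if-rank-increases rule over
    size-ordered subsets yields the minimal support-size multiset (matroid
    greedy argument).
    """
    rng = np.random.default_rng(seed)
    l = S.shape[1]
    n_elements = l if n_elements is None else n_elements
    art = list(range(n_elements, l))
    basis: list[np.ndarray] = []
    sizes: list[int] = []
    for size in range(1, n_elements + 1):
        if len(basis) == r:
            break
        for subset in combinations(range(n_elements), size):
            if len(basis) == r:
                break
            T = list(subset) + art
            if np.linalg.matrix_rank(S[:, T]) >= len(T):
                continue  # no null vector fully supported on T
            v_T = _nonzero_in_box(S[:, T], lb[T], ub[T], rng, n_nonzero=len(subset))
            if v_T is None:
                continue
            v = np.zeros(l)
            v[T] = v_T
            candidate = basis + [v]
            if np.linalg.matrix_rank(np.column_stack(candidate)) == len(candidate):
                basis.append(v)
                elem = v[:n_elements]
                sizes.append(int(np.sum(np.abs(elem) > 1e-7 * np.abs(elem).max())))
    return sorted(sizes)


def f1_score_sets(selected: set, truth: set) -> float:
    tp = len(selected & truth)
    fp = len(selected - truth)
    fn = len(truth - selected)
    if 2 * tp + fp + fn == 0:
        return 1.0
    return 2 * tp / (2 * tp + fp + fn)
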