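"""Sparse linear basis (SLB) decomposition of coupled reaction clusters.

Each coupled cluster C_k is cut out of the model as a submatrix S_Ck.  To
keep every metabolite of the submodel mass-balanceable, an artificial
exchange column is appended for each metabolite that is also produced or
consumed by reactions outside the cluster (these helper columns exist only
during basis extraction and are removed afterwards).  The null space of the
augmented matrix has dimension r_k = l_k - rank(S_Ck); it is re-expressed in
a minimal-support (sparsest) basis by solving at most 2 r_k linear programs:
each LP minimizes the L1 norm of a steady-state vector v (via the standard
|v| <= x split) subject to the original flux bounds and to a linear
independence condition w.P.v > zeta or < -zeta, where P projects onto the
part of the null space not yet spanned by previously extracted columns and w
is a vector of uniform random weights.  The disjunction is realized as two
LP runs; the sparser feasible solution is kept.

The sparse columns, with artificial-exchange rows dropped, become *linear
basis reactions* (LBRs): single merged columns S*_Ck . N*_Ck of the
decoupled model, whose bounds are the tightest interval consistent with
every element reaction's own bounds scaled by its basis coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space, svdvals
from scipy.optimize import linprog

from .exceptions import AssemblyError, BasisExtractionError
from .model_io import DEFAULT_BOUND, MetabolicModel

ZETA_DEFAULT = 1e-3
RANK_RTOL = 1e-9         # singular values below RANK_RTOL * sigma_max are zero
SUPPORT_RTOL = 1e-7      # |v| > SUPPORT_RTOL * max|v| counts as support
STEADY_STATE_RTOL = 1e-9


@dataclass
class ClusterSubmodel:
    """A coupled cluster's stoichiometry, augmented with artificial exchanges."""

    cluster: list[int]                  # reaction indices in the parent model
    metabolites: list[int]              # metabolite indices in the parent model
    S_aug: np.ndarray                   # rows: metabolites; cols: cluster + artificial
    lb: np.ndarray                      # bounds for all augmented columns
    ub: np.ndarray
    n_artificial: int
    artificial_metabolites: list[int]   # parent metabolite index per artificial column

    @property
    def l_k(self) -> int:
        return self.S_aug.shape[1]

    @property
    def rank(self) -> int:
        if self.S_aug.size == 0:
            return 0
        sv = svdvals(self.S_aug)
        if sv.size == 0:
            return 0
        return int(np.sum(sv > RANK_RTOL * sv[0]))

    @property
    def r_k(self) -> int:
        """Null-space dimension of the augmented submatrix."""
        return self.l_k - self.rank


@dataclass
class SparseBasis:
    """Minimal-support null-space basis of one cluster submodel."""

    cluster: list[int]
    N: np.ndarray          # l_k x r_k, includes artificial-exchange rows
    N_star: np.ndarray     # artificial rows removed: |cluster| x r_k
    support: list[list[int]] = field(default_factory=list)

    @property
    def r_k(self) -> int:
        return self.N.shape[1] if self.N.ndim == 2 else 0


@dataclass
class DecoupledModel:
    """The decoupled network [S^NC, S*_C1.N*_C1, ..., S*_CK.N*_CK].

    Non-coupled reactions keep their own columns; each coupled cluster is
    replaced by its LBR columns.  ``mapping`` records, per LBR column, the
    cluster index, basis column and the element reactions with their basis
    coefficients, so LBR-space solutions can be pushed back to the original
    reaction space.
    """

    S_IR: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    column_ids: list[str]
    nc_index: list[int]                      # parent reaction index per NC column
    lbr_mapping: list[dict]                  # per LBR column (after NC block)
    parent: MetabolicModel
    metadata: dict = field(default_factory=dict)

    @property
    def n_nc(self) -> int:
        return len(self.nc_index)

    @property
    def n_lbr(self) -> int:
        return len(self.lbr_mapping)

    @property
    def n_columns(self) -> int:
        return self.S_IR.shape[1]

    def column_of_reaction(self, rid: str) -> tuple[str, int]:
        """Locate a parent reaction: ("nc", column) or ("lbr", parent index)."""
        j = self.parent.reaction_index(rid)
        if j in self.nc_index:
            return "nc", self.nc_index.index(j)
        return "lbr", j


def build_cluster_submodel(model: MetabolicModel, cluster: list[int]) -> ClusterSubmodel:
    """Extract a cluster's stoichiometry and append artificial exchanges.

    An artificial exchange column (a single -1 entry, free bounds) is added
    for every metabolite of the submodel that also participates in reactions
    outside the cluster, so the submodel can carry steady state on its own.
    """
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    cluster = sorted(int(j) for j in cluster)
    sub = model.S[:, cluster]
    met_rows = np.flatnonzero(np.any(sub != 0, axis=1))
    S_sub = sub[met_rows, :]
    outside = np.ones(model.n_reactions, dtype=bool)
    outside[cluster] = False
    boundary: list[int] = []
    for local, i in enumerate(met_rows):
        if np.any(model.S[i, outside] != 0):
            boundary.append(local)
    n_art = len(boundary)
    S_aug = np.hstack([S_sub, np.zeros((S_sub.shape[0], n_art))])
    for a, local in enumerate(boundary):
        S_aug[local, len(cluster) + a] = -1.0
    lb = np.concatenate([model.lb[cluster], np.full(n_art, -DEFAULT_BOUND)])
    ub = np.concatenate([model.ub[cluster], np.full(n_art, DEFAULT_BOUND)])
    return ClusterSubmodel(
        cluster=cluster,
        metabolites=met_rows.tolist(),
        S_aug=S_aug,
        lb=lb,
        ub=ub,
        n_artificial=n_art,
        artificial_metabolites=[int(met_rows[b]) for b in boundary],
    )


def _rescale_column(v: np.ndarray, n_elements: int | None = None) -> np.ndarray:
    """Scale so the largest-magnitude element coefficient is 1 (sign kept)."""
    part = v if n_elements is None else v[:n_elements]
    peak = np.abs(part).max(initial=0.0)
    if peak == 0:
        return v
    return v / peak


def _column_support(v: np.ndarray, n_elements: int | None = None) -> np.ndarray:
    scaled = _rescale_column(v, n_elements)
    part = scaled if n_elements is None else scaled[:n_elements]
    return np.flatnonzero(np.abs(part) > SUPPORT_RTOL)


def _solve_sparsest(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    wP: np.ndarray,
    zeta: float,
    n_elements: int,
) -> np.ndarray | None:
    """min sum(x) over element reactions, s.t. S v = 0, -x <= v <= x,
    lb <= v <= ub, wP.v >= zeta.

    Artificial-exchange coordinates carry no sparsity cost: a sparse basis
    vector uses the fewest *element* reactions; the helper exchanges merely
    balance boundary metabolites.  Variables are stacked as (v, x).
    """
    l = S.shape[1]
    cost = np.concatenate([np.zeros(l), np.ones(n_elements), np.zeros(l - n_elements)])
    A_eq = np.hstack([S, np.zeros((S.shape[0], l))])
    b_eq = np.zeros(S.shape[0])
    eye = np.eye(l)
    # v - x <= 0 ; -v - x <= 0 ; -wP.v <= -zeta
    A_ub = np.vstack(
        [
            np.hstack([eye, -eye]),
            np.hstack([-eye, -eye]),
            np.concatenate([-wP, np.zeros(l)])[None, :],
        ]
    )
    b_ub = np.concatenate([np.zeros(2 * l), [-zeta]])
    bounds = [(float(lo), float(hi)) for lo, hi in zip(lb, ub)] + [(0.0, None)] * l
    res = linprog(
        cost,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs-ds",
    )
    if not res.success:
        return None
    return res.x[:l]


def sparsify_nullspace(
    sub: ClusterSubmodel,
    zeta: float = ZETA_DEFAULT,
    seed: int = 17,
) -> SparseBasis:
    """Extract a minimal-support basis of the augmented null space.

    Runs the iterative two-branch LP scheme: at step m, the projector P maps
    onto the part of null(S_aug) orthogonal to the m-1 columns already
    found; the constraint |w.P.v| > zeta (realized as two LPs with opposite
    signs) forces the new column to be linearly independent of them.  The
    sparser feasible branch wins; ties go to the positive branch.
    """
    r_k = sub.r_k
    if r_k < 1:
        raise ValueError("cluster submodel has a trivial null space (r_k = 0)")
    rng = np.random.default_rng(seed)
    l = sub.l_k
    basis_full = null_space(sub.S_aug, rcond=RANK_RTOL)
    if basis_full.shape[1] != r_k:
        # fall back to the rank actually found numerically
        r_k = basis_full.shape[1]
    n_elem = len(sub.cluster)
    columns: list[np.ndarray] = []
    scale = max(1.0, float(np.abs(sub.S_aug).max()))
    for _ in range(r_k):
        # orthonormal basis of null(S) not yet spanned by found columns
        if columns:
            Q, _ = np.linalg.qr(np.column_stack(columns))
            residual = basis_full - Q @ (Q.T @ basis_full)
            U, sv, _ = np.linalg.svd(residual, full_matrices=False)
            keep = sv > RANK_RTOL * max(sv[0], 1.0)
            directions = U[:, keep]
        else:
            directions = basis_full
        P = directions @ directions.T
        w = rng.uniform(0.0, 1.0, size=l)
        wP = w @ P
        v_pos = _solve_sparsest(sub.S_aug, sub.lb, sub.ub, wP, zeta, n_elem)
        v_neg = _solve_sparsest(sub.S_aug, sub.lb, sub.ub, -wP, zeta, n_elem)
        if v_pos is None and v_neg is None:
            raise BasisExtractionError(
                f"both disjunction branches infeasible for cluster {sub.cluster}"
            )
        if v_pos is None:
            v = v_neg
        elif v_neg is None:
            v = v_pos
        else:
            v = (
                v_pos
                if _column_support(v_pos, n_elem).size
                <= _column_support(v_neg, n_elem).size
                else v_neg
            )
        resid = np.abs(sub.S_aug @ v).max() if v.size else 0.0
        if resid > STEADY_STATE_RTOL * scale * max(1.0, np.abs(v).max()):
            raise BasisExtractionError(
                f"extracted column violates steady state (residual {resid:.2e})"
            )
        columns.append(_rescale_column(v, n_elem))
    N = np.column_stack(columns)
    N_star = N[:n_elem, :]
    support = [_column_support(N[:, i], n_elem).tolist() for i in range(N.shape[1])]
    return SparseBasis(cluster=list(sub.cluster), N=N, N_star=N_star, support=support)


def _lbr_bounds(
    coeffs: np.ndarray, lb: np.ndarray, ub: np.ndarray
) -> tuple[float, float]:
    """Tightest LBR interval consistent with every element reaction's bounds.

    For each element with basis coefficient a != 0 and bounds [lo, hi], the
    admissible LBR flux lies in [lo/a, hi/a] (swapped when a < 0); the LBR
    bound is the intersection over the support.
    """
    lows, highs = [], []
    for a, lo, hi in zip(coeffs, lb, ub):
        if a > 0:
            lows.append(lo / a)
            highs.append(hi / a)
        else:
            lows.append(hi / a)
            highs.append(lo / a)
    return max(lows), min(highs)


def assemble_decoupled_model(
    model: MetabolicModel,
    bases: list[SparseBasis],
) -> DecoupledModel:
    """Assemble S^IR = [S^NC, S*_C1.N*_C1, ..., S*_CK.N*_CK].

    Clusters whose basis is empty (r_k = 0) pass their reactions through as
    NC columns.  LBR objective weights are inherited from the element
    reactions through the basis coefficients, so c.v is preserved by the
    change of variables.
    """
    in_cluster = np.zeros(model.n_reactions, dtype=bool)
    effective: list[SparseBasis] = []
    for basis in bases:
        if basis.r_k == 0:
            continue
        members = np.asarray(basis.cluster, dtype=int)
        if np.any(in_cluster[members]):
            raise AssemblyError("clusters overlap: a reaction appears in two bases")
        in_cluster[members] = True
        effective.append(basis)
    nc_index = sorted(np.flatnonzero(~in_cluster).tolist())

    blocks = [model.S[:, nc_index]]
    lb_parts = [model.lb[nc_index]]
    ub_parts = [model.ub[nc_index]]
    c_parts = [model.c[nc_index]]
    column_ids = [model.reaction_ids[j] for j in nc_index]
    lbr_mapping: list[dict] = []

    for k, basis in enumerate(effective):
        members = np.asarray(basis.cluster, dtype=int)
        S_star = model.S[:, members]
        blocks.append(S_star @ basis.N_star)
        for i in range(basis.r_k):
            col = basis.N_star[:, i]
            support = np.flatnonzero(np.abs(col) > SUPPORT_RTOL * max(np.abs(col).max(), 1.0))
            if support.size == 0:
                raise AssemblyError(
                    f"LBR column {i} of cluster {k} has empty element support"
                )
            coeffs = col[support]
            elem = members[support]
            lo, hi = _lbr_bounds(coeffs, model.lb[elem], model.ub[elem])
            lbr_id = f"LBR_c{k}_{i}"
            if lo > hi + 1e-12:
                raise AssemblyError(
                    f"empty bound interval [{lo:.4g}, {hi:.4g}] for {lbr_id}"
                )
            lb_parts.append(np.array([lo]))
            ub_parts.append(np.array([hi]))
            c_parts.append(np.array([float(model.c[elem] @ coeffs)]))
            column_ids.append(lbr_id)
            lbr_mapping.append(
                {
                    "lbr_id": lbr_id,
                    "cluster": k,
                    "basis_column": i,
                    "elements": [
                        (model.reaction_ids[int(e)], float(a))
                        for e, a in zip(elem, coeffs)
                    ],
                    "element_index": elem.tolist(),
                    "coefficients": coeffs.tolist(),
                }
            )

    S_IR = np.hstack(blocks)
    return DecoupledModel(
        S_IR=S_IR,
        lb=np.concatenate(lb_parts),
        ub=np.concatenate(ub_parts),
        c=np.concatenate(c_parts),
        column_ids=column_ids,
        nc_index=nc_index,
        lbr_mapping=lbr_mapping,
        parent=model,
        metadata={
            "bases": effective,
            "negative_coefficient_bounds": "sign-swap",
        },
    )


def save_decoupled(
    model: DecoupledModel, model_path, mapping_path
) -> None:
    """Serialize a decoupled model as COBRA JSON plus a sidecar mapping TSV.

    The JSON holds S^IR with LBR columns as ordinary reactions; the TSV has
    one row per (lbr_id, cluster, element_reaction_id, coefficient).
    """
    import pandas as pd

    from .model_io import MetabolicModel as _MM, write_model

    proxy = _MM(
        metabolite_ids=list(model.parent.metabolite_ids),
        reaction_ids=list(model.column_ids),
        S=model.S_IR,
        lb=model.lb,
        ub=model.ub,
        c=model.c,
        metadata={"model_id": "decrem_decoupled"},
    )
    write_model(proxy, model_path, dialect="json")
    rows = []
    for entry in model.lbr_mapping:
        for rid, coeff in entry["elements"]:
            rows.append((entry["lbr_id"], entry["cluster"], rid, coeff))
    pd.DataFrame(
        rows, columns=["lbr_id", "cluster", "element_reaction_id", "coefficient"]
    ).to_csv(mapping_path, sep="\t", index=False)


def load_decoupled(model_path, mapping_path, parent: MetabolicModel) -> DecoupledModel:
    """Rebuild a :class:`DecoupledModel` from its JSON + mapping TSV pair."""
    import pandas as pd

    from .model_io import read_model

    proxy = read_model(model_path, dialect="json")
    mapping = pd.read_csv(mapping_path, sep="\t")
    lbr_ids = list(dict.fromkeys(mapping["lbr_id"]))
    parent_ids = set(parent.reaction_ids)
    nc_index = [
        parent.reaction_index(rid)
        for rid in proxy.reaction_ids
        if rid in parent_ids
    ]
    lbr_mapping = []
    for lbr_id in lbr_ids:
        rows = mapping[mapping["lbr_id"] == lbr_id]
        elements = [(r, float(a)) for r, a in zip(rows["element_reaction_id"], rows["coefficient"])]
        lbr_mapping.append(
            {
                "lbr_id": lbr_id,
                "cluster": int(rows["cluster"].iloc[0]),
                "basis_column": 0,
                "elements": elements,
                "element_index": [parent.reaction_index(r) for r, _ in elements],
                "coefficients": [a for _, a in elements],
            }
        )
    order = {rid: k for k, rid in enumerate(proxy.reaction_ids)}
    lbr_mapping.sort(key=lambda e: order[e["lbr_id"]])
    return DecoupledModel(
        S_IR=proxy.S,
        lb=proxy.lb,
        ub=proxy.ub,
        c=proxy.c,
        column_ids=list(proxy.reaction_ids),
        nc_index=nc_index,
        lbr_mapping=lbr_mapping,
        parent=parent,
        metadata={"source": str(model_path)},
    )


def recover_element_fluxes(solution: np.ndarray, model: DecoupledModel) -> np.ndarray:
    """Map an LBR-space flux vector back to original-reaction fluxes.

    NC columns are copied; each cluster contributes N* . v_cluster.
    """
    solution = np.asarray(solution, dtype=float)
    if solution.shape != (model.n_columns,):
        raise ValueError(
            f"solution has shape {solution.shape}, expected ({model.n_columns},)"
        )
    v = np.zeros(model.parent.n_reactions)
    v[model.nc_index] = solution[: model.n_nc]
    for offset, entry in enumerate(model.lbr_mapping):
        flux = solution[model.n_nc + offset]
        for e, a in zip(entry["element_index"], entry["coefficients"]):
            v[e] += a * flux
    return v
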