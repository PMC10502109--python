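"""Flux balance analysis on decoupled models, with plain-FBA baselines.

All solves reduce to linear programs over either the original stoichiometric
matrix S (FBA / pFBA / FVA baselines) or the decoupled matrix S^IR whose
columns are non-coupled reactions plus linear basis reactions (Decrem-FBA,
pDecrem, Decrem-FVA, kinetic-constrained Decrem).  The LP backend is HiGHS
dual simplex through :func:`scipy.optimize.linprog`.

The parsimonious variants are two-stage: the objective is first maximized,
then, with the objective pinned at its optimum, the total absolute flux
sum(|v|) is minimized through the standard t >= |v| split (no integer
variables).  Kinetic constraints are flux boxes v_KF +/- delta imposed in
element (original-reaction) space; for a reaction merged into an LBR the box
becomes a linear row over the cluster's LBR columns via the basis
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.stats import pearsonr, spearmanr

from .exceptions import InfeasibleError, MetricError
from .model_io import MetabolicModel
from .slb import DecoupledModel, recover_element_fluxes

FEASIBILITY_TOL = 1e-9
NONZERO_FLUX_TOL = 1e-6    # |v| above this counts as an activated reaction
KINETIC_DELTA_FRACTION = 0.05


@dataclass
class FluxSolution:
    """Result of one LP solve on a (decoupled) metabolic model."""

    objective_value: float
    lbr_flux: np.ndarray          # flux per column of the solved matrix
    element_flux: np.ndarray      # recovered original-reaction fluxes
    status: str                   # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class KineticConstraint:
    """A predicted kinetic flux box v_KF +/- delta for one reaction."""

    reaction_id: str
    v_kf: float
    delta: float | None = None
    extrapolated: bool = False

    def resolved_delta(self) -> float:
        if self.delta is not None:
            if self.delta < 0:
                raise ValueError("delta must be nonnegative")
            return self.delta
        return KINETIC_DELTA_FRACTION * abs(self.v_kf)


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------


def _linprog_max(
    c: np.ndarray,
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
):
    """max c.v  s.t.  S.v = 0, lb <= v <= ub, A_ub.v <= b_ub."""
    res = linprog(
        -np.asarray(c, dtype=float),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs-ds",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    return res


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _status_of(res) -> str:
    return _STATUS.get(res.status, "infeasible")


def _min_l1_at_optimum(
    c: np.ndarray,
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    optimum: float,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
) -> np.ndarray:
    """min sum|v| with c.v pinned at its optimum (t >= |v| split)."""
    n = S.shape[1]
    cost = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([S, np.zeros((S.shape[0], n))])
    eye = np.eye(n)
    rows = [np.hstack([eye, -eye]), np.hstack([-eye, -eye])]
    rhs = [np.zeros(n), np.zeros(n)]
    slack = FEASIBILITY_TOL * max(1.0, abs(optimum))
    rows.append(np.concatenate([-np.asarray(c, float), np.zeros(n)])[None, :])
    rhs.append(np.array([-(optimum - slack)]))
    if A_ub is not None:
        rows.append(np.hstack([A_ub, np.zeros((A_ub.shape[0], n))]))
        rhs.append(np.asarray(b_ub, float))
    bounds = list(zip(lb, ub)) + [(0.0, None)] * n
    res = linprog(
        cost,
        A_ub=np.vstack(rows),
        b_ub=np.concatenate(rhs),
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs-ds",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    if not res.success:
        raise InfeasibleError("parsimonious stage infeasible at the fixed optimum")
    return res.x[:n]


# ---------------------------------------------------------------------------
# Baselines on the original model
# ---------------------------------------------------------------------------


def _objective_vector_plain(model: MetabolicModel, objective: str | None) -> np.ndarray:
    if objective is None:
        return model.c.copy()
    c = np.zeros(model.n_reactions)
    c[model.reaction_index(objective)] = 1.0
    return c


def solve_fba(model: MetabolicModel, objective: str | None = None) -> FluxSolution:
    """Plain FBA on the original model (internal baseline)."""
    c = _objective_vector_plain(model, objective)
    res = _linprog_max(c, model.S, model.lb, model.ub)
    if not res.success:
        return FluxSolution(np.nan, np.empty(0), np.empty(0), _status_of(res))
    return FluxSolution(float(c @ res.x), res.x.copy(), res.x.copy(), "optimal")


def solve_pfba(model: MetabolicModel, objective: str | None = None) -> FluxSolution:
    """Parsimonious FBA on the original model (internal baseline)."""
    base = solve_fba(model, objective)
    if not base.optimal:
        return base
    c = _objective_vector_plain(model, objective)
    v = _min_l1_at_optimum(c, model.S, model.lb, model.ub, base.objective_value)
    return FluxSolution(float(c @ v), v.copy(), v.copy(), "optimal")


def fva(
    model: MetabolicModel, fraction_of_optimum: float = 1.0, objective: str | None = None
) -> np.ndarray:
    """Plain FVA baseline; returns an (n, 2) array of [min, max] per reaction."""
    return _fva_core(
        model.S, model.lb, model.ub,
        _objective_vector_plain(model, objective), fraction_of_optimum,
    )


def _fva_core(S, lb, ub, c, fraction_of_optimum) -> np.ndarray:
    if not (0.0 < fraction_of_optimum <= 1.0):
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    res = _linprog_max(c, S, lb, ub)
    if not res.success:
        raise InfeasibleError("FVA base problem is not optimal")
    optimum = float(c @ res.x)
    threshold = fraction_of_optimum * optimum
    A_ub = -np.asarray(c, float)[None, :]
    b_ub = np.array([-(threshold - FEASIBILITY_TOL * max(1.0, abs(threshold)))])
    n = S.shape[1]
    intervals = np.empty((n, 2))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        lo = _linprog_max(-e, S, lb, ub, A_ub=A_ub, b_ub=b_ub)
        hi = _linprog_max(e, S, lb, ub, A_ub=A_ub, b_ub=b_ub)
        if not (lo.success and hi.success):
            raise InfeasibleError(f"FVA subproblem infeasible for column {j}")
        intervals[j] = (lo.x[j], hi.x[j])
    intervals[:, 0] = np.minimum(intervals[:, 0], intervals[:, 1])
    return intervals


# ---------------------------------------------------------------------------
# Decrem solves
# ---------------------------------------------------------------------------


def _objective_vector(model: DecoupledModel, objective: str | None) -> np.ndarray:
    """Objective over S^IR columns; accepts a column id or a parent reaction id."""
    if objective is None:
        return model.c.copy()
    c = np.zeros(model.n_columns)
    if objective in model.column_ids:
        c[model.column_ids.index(objective)] = 1.0
        return c
    kind, idx = model.column_of_reaction(objective)
    if kind == "nc":
        c[idx] = 1.0
        return c
    # coupled element reaction: its flux is a linear form over LBR columns
    for offset, entry in enumerate(model.lbr_mapping):
        for e, a in zip(entry["element_index"], entry["coefficients"]):
            if e == idx:
                c[model.n_nc + offset] += a
    if not np.any(c):
        raise KeyError(f"objective reaction {objective!r} maps to no column")
    return c


def solve_decrem_fba(model: DecoupledModel, objective: str | None = None) -> FluxSolution:
    """FBA on the decoupled network S^IR, with element fluxes recovered."""
    c = _objective_vector(model, objective)
    res = _linprog_max(c, model.S_IR, model.lb, model.ub)
    if not res.success:
        return FluxSolution(np.nan, np.empty(0), np.empty(0), _status_of(res))
    v = res.x
    return FluxSolution(
        float(c @ v), v.copy(), recover_element_fluxes(v, model), "optimal"
    )


def solve_pdecrem(model: DecoupledModel, objective: str | None = None) -> FluxSolution:
    """Parsimonious Decrem: minimal total |flux| among Decrem-FBA optima."""
    base = solve_decrem_fba(model, objective)
    if not base.optimal:
        return base
    c = _objective_vector(model, objective)
    v = _min_l1_at_optimum(c, model.S_IR, model.lb, model.ub, base.objective_value)
    return FluxSolution(
        float(c @ v), v, recover_element_fluxes(v, model), "optimal"
    )


def decrem_fva(
    model: DecoupledModel,
    fraction_of_optimum: float = 1.0,
    objective: str | None = None,
) -> np.ndarray:
    """FVA over the columns of S^IR at a fraction of the Decrem optimum."""
    c = _objective_vector(model, objective)
    return _fva_core(model.S_IR, model.lb, model.ub, c, fraction_of_optimum)


def _element_row(model: DecoupledModel, reaction_id: str) -> np.ndarray:
    """Row expressing an element reaction's flux over the S^IR columns."""
    kind, idx = model.column_of_reaction(reaction_id)
    row = np.zeros(model.n_columns)
    if kind == "nc":
        row[idx] = 1.0
        return row
    for offset, entry in enumerate(model.lbr_mapping):
        for e, a in zip(entry["element_index"], entry["coefficients"]):
            if e == idx:
                row[model.n_nc + offset] += a
    if not np.any(row):
        raise KeyError(f"constrained reaction {reaction_id!r} maps to no column")
    return row


def solve_kinetic_decrem(
    model: DecoupledModel,
    constraints: list[KineticConstraint],
    objective: str | None = None,
) -> FluxSolution:
    """Decrem-FBA with kinetic flux boxes v_KF +/- delta on named reactions.

    Boxes are imposed in element space: a constrained reaction inside a
    cluster contributes a linear row over its cluster's LBR columns.
    """
    rows, rhs = [], []
    for kc in constraints:
        delta = kc.resolved_delta()
        row = _element_row(model, kc.reaction_id)
        rows.append(row)
        rhs.append(kc.v_kf + delta)
        rows.append(-row)
        rhs.append(-(kc.v_kf - delta))
    A_ub = np.vstack(rows) if rows else None
    b_ub = np.asarray(rhs) if rows else None
    c = _objective_vector(model, objective)
    res = _linprog_max(c, model.S_IR, model.lb, model.ub, A_ub=A_ub, b_ub=b_ub)
    if not res.success:
        ids = ", ".join(kc.reaction_id for kc in constraints)
        raise InfeasibleError(
            f"kinetic-constrained problem {_status_of(res)}; "
            f"active kinetic boxes: [{ids}]"
        )
    v = res.x
    return FluxSolution(
        float(c @ v), v.copy(), recover_element_fluxes(v, model), "optimal"
    )


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------


def interval_jaccard(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Jaccard index |a∩b| / |a∪b| of two real intervals."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    inter = max(0.0, hi - lo)
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    if union <= 0:
        return 1.0 if inter == 0 and a == b else 0.0
    return inter / union


def evaluate_predictions(
    predicted: pd.Series,
    measured: pd.Series,
    predicted_intervals: pd.DataFrame | None = None,
    measured_intervals: pd.DataFrame | None = None,
) -> dict:
    """Compare predicted and measured fluxes on their shared reactions.

    Returns Pearson r, Spearman rho, MSE, the number of co-occurring nonzero
    fluxes, and — when FVA-style [min, max] interval tables are supplied —
    the mean interval Jaccard index.
    """
    shared = predicted.index.intersection(measured.index)
    shared = [r for r in shared if np.isfinite(predicted[r]) and np.isfinite(measured[r])]
    if len(shared) < 3:
        raise MetricError(f"only {len(shared)} shared finite reactions (need >= 3)")
    p = predicted[shared].to_numpy(dtype=float)
    m = measured[shared].to_numpy(dtype=float)
    r = float(pearsonr(p, m).statistic) if np.std(p) > 0 and np.std(m) > 0 else np.nan
    rho = float(spearmanr(p, m).statistic) if np.std(p) > 0 and np.std(m) > 0 else np.nan
    mse = float(np.mean((p - m) ** 2))
    co_nonzero = int(
        np.sum((np.abs(p) > NONZERO_FLUX_TOL) & (np.abs(m) > NONZERO_FLUX_TOL))
    )
    out = {
        "n_shared": len(shared),
        "pearson_r": r,
        "spearman_rho": rho,
        "mse": mse,
        "co_nonzero": co_nonzero,
    }
    if predicted_intervals is not None and measured_intervals is not None:
        both = predicted_intervals.index.intersection(measured_intervals.index)
        if len(both) > 0:
            jac = [
                interval_jaccard(
                    tuple(predicted_intervals.loc[r].iloc[:2]),
                    tuple(measured_intervals.loc[r].iloc[:2]),
                )
                for r in both
            ]
            out["interval_jaccard"] = float(np.mean(jac))
    return out
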