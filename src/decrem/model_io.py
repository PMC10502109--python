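"""Reading, writing and canonicalizing genome-scale metabolic models and omics tables.

Models are accepted in the three common COBRA dialects (SBML L3/FBC, COBRA
JSON, COBRA MAT) through :mod:`cobra`, and canonicalized into a plain
:class:`MetabolicModel` that stores the stoichiometric matrix column-per-
reaction together with flux bounds, reversibility flags and the linear
objective.  Omics measurements (metabolite concentrations, gene expression,
measured fluxes, growth rates) are read from delimited text tables sharing a
strain key column and held as an aligned :class:`OmicsDataset`.

Conventions
-----------
* A reaction is *reversible* iff its lower bound is negative (BIGG
  convention); reversible reactions are never split at I/O time.
* Missing bounds default to +/-1000 mmol/gDW/h, the customary "unbounded"
  flux cap of genome-scale models.
* Reaction and metabolite ordering follows the source file and is preserved
  by write/read round trips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ParseError

DEFAULT_BOUND = 1000.0

_DIALECTS = ("sbml", "json", "mat")

_EXT_TO_DIALECT = {
    ".xml": "sbml",
    ".sbml": "sbml",
    ".json": "json",
    ".mat": "mat",
}


@dataclass
class MetabolicModel:
    """A stoichiometric model: S, bounds, reversibility and objective.

    Attributes
    ----------
    metabolite_ids : list of str
        Row labels of ``S`` (m entries).
    reaction_ids : list of str
        Column labels of ``S`` (n entries).
    S : (m, n) ndarray
        Stoichiometric coefficients (dimensionless).
    lb, ub : (n,) ndarray
        Lower/upper flux bounds in mmol/gDW/h.
    c : (n,) ndarray
        Linear objective weights (typically the biomass reaction).
    subsystem : list of str, optional
        Per-reaction pathway labels.
    gene_rules : list of str, optional
        Per-reaction gene association strings (stored verbatim).
    metadata : dict
        Provenance (source path, dialect, model id).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    subsystem: list[str] | None = None
    gene_rules: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        m, n = self.S.shape
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != n:
            raise ValueError(
                f"S is {m}x{n} but {len(self.metabolite_ids)} metabolites / "
                f"{len(self.reaction_ids)} reactions declared"
            )
        for name in ("lb", "ub", "c"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}, got {arr.shape}")
            setattr(self, name, arr)
        if np.any(self.lb > self.ub):
            bad = self.reaction_ids[int(np.argmax(self.lb > self.ub))]
            raise ValueError(f"lb > ub for reaction {bad!r}")

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def reversible(self) -> np.ndarray:
        """Boolean mask: reversible iff lb < 0 (BIGG convention)."""
        return self.lb < 0

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def objective_reaction(self) -> str:
        """Id of the (first) reaction carrying nonzero objective weight."""
        nz = np.flatnonzero(self.c)
        if nz.size == 0:
            raise ValueError("model has an all-zero objective")
        return self.reaction_ids[int(nz[0])]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            c=self.c.copy(),
            subsystem=list(self.subsystem) if self.subsystem else None,
            gene_rules=list(self.gene_rules) if self.gene_rules else None,
            metadata=dict(self.metadata),
        )


@dataclass
class OmicsDataset:
    """Strain-aligned multi-omics blocks.

    All blocks are indexed by the same ordered strain list.  Missing entries
    stay as NaN — they are flagged, never silently zeroed.
    """

    strains: list[str]
    metabolite_conc: pd.DataFrame | None = None
    gene_expr: pd.DataFrame | None = None
    measured_flux: pd.DataFrame | None = None
    growth_rate: pd.Series | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("metabolite_conc", "gene_expr", "measured_flux"):
            block = getattr(self, name)
            if block is not None and list(block.index) != list(self.strains):
                raise AlignmentError(
                    f"{name} index does not match the shared strain list"
                )
        if self.growth_rate is not None and list(self.growth_rate.index) != list(
            self.strains
        ):
            raise AlignmentError("growth_rate index does not match the strain list")
        if self.metabolite_conc is not None:
            conc = self.metabolite_conc.to_numpy(dtype=float)
            if np.nanmin(conc, initial=0.0) < 0:
                raise ValueError("negative metabolite concentrations")

    @property
    def n_strains(self) -> int:
        return len(self.strains)


# ---------------------------------------------------------------------------
# Model I/O via cobra
# ---------------------------------------------------------------------------


def _infer_dialect(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix not in _EXT_TO_DIALECT:
        raise ParseError(f"cannot infer model dialect from extension {suffix!r}")
    return _EXT_TO_DIALECT[suffix]


def from_cobra(cb_model) -> MetabolicModel:
    """Canonicalize a ``cobra.Model`` into a :class:`MetabolicModel`."""
    met_ids = [m.id for m in cb_model.metabolites]
    rxn_ids = [r.id for r in cb_model.reactions]
    met_pos = {mid: i for i, mid in enumerate(met_ids)}
    m, n = len(met_ids), len(rxn_ids)
    S = np.zeros((m, n))
    lb = np.empty(n)
    ub = np.empty(n)
    c = np.zeros(n)
    subsystem: list[str] = []
    gene_rules: list[str] = []
    for j, rxn in enumerate(cb_model.reactions):
        for met, coeff in rxn.metabolites.items():
            S[met_pos[met.id], j] = coeff
        lb[j] = rxn.lower_bound if rxn.lower_bound is not None else -DEFAULT_BOUND
        ub[j] = rxn.upper_bound if rxn.upper_bound is not None else DEFAULT_BOUND
        c[j] = rxn.objective_coefficient
        subsystem.append(rxn.subsystem or "")
        gene_rules.append(rxn.gene_reaction_rule or "")
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lb=lb,
        ub=ub,
        c=c,
        subsystem=subsystem,
        gene_rules=gene_rules,
        metadata={"model_id": cb_model.id or ""},
    )


def to_cobra(model: MetabolicModel):
    """Convert a :class:`MetabolicModel` back to a ``cobra.Model``."""
    import cobra

    cb = cobra.Model(model.metadata.get("model_id") or "decrem_model")
    mets = []
    for mid in model.metabolite_ids:
        # cobra requires a compartment for SBML export; parse the usual _c/_e
        # suffix, defaulting to cytosol.
        comp = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
        if len(comp) > 2 or not comp.isalpha():
            comp = "c"
        met = cobra.Metabolite(mid, compartment=comp)
        mets.append(met)
    cb.add_metabolites(mets)
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lb[j])
        rxn.upper_bound = float(model.ub[j])
        if model.subsystem:
            rxn.subsystem = model.subsystem[j]
        rxns.append(rxn)
    cb.add_reactions(rxns)
    for j, rxn in enumerate(cb.reactions):
        col = model.S[:, j]
        rxn.add_metabolites(
            {mets[i]: float(col[i]) for i in np.flatnonzero(col)}
        )
        if model.gene_rules and model.gene_rules[j]:
            rxn.gene_reaction_rule = model.gene_rules[j]
    objective = {
        cb.reactions.get_by_id(model.reaction_ids[j]): float(model.c[j])
        for j in np.flatnonzero(model.c)
    }
    if objective:
        from cobra.util.solver import set_objective

        set_objective(cb, objective)
    return cb


def read_model(path: str | Path, dialect: str | None = None) -> MetabolicModel:
    """Read a genome-scale model file into the canonical representation.

    Parameters
    ----------
    path : str or Path
        Model file.
    dialect : {"sbml", "json", "mat"}, optional
        File dialect; inferred from the extension when omitted.
    """
    import cobra.io

    path = Path(path)
    dialect = (dialect or _infer_dialect(path)).lower()
    if dialect not in _DIALECTS:
        raise ParseError(f"unknown model dialect {dialect!r}; expected one of {_DIALECTS}")
    if not path.exists():
        raise ParseError(f"model file not found: {path}")
    try:
        if dialect == "json":
            cb = cobra.io.load_json_model(str(path))
        elif dialect == "sbml":
            cb = cobra.io.read_sbml_model(str(path))
        else:
            cb = cobra.io.load_matlab_model(str(path))
    except Exception as exc:  # cobra raises heterogeneous parse errors
        raise ParseError(f"failed to parse {path} as {dialect}: {exc}") from exc
    model = from_cobra(cb)
    model.metadata.update({"source_path": str(path), "dialect": dialect})
    return model


def write_model(model: MetabolicModel, path: str | Path, dialect: str | None = None) -> None:
    """Write a model in the requested dialect (inferred from extension if omitted)."""
    import cobra.io

    path = Path(path)
    dialect = (dialect or _infer_dialect(path)).lower()
    if dialect not in _DIALECTS:
        raise ParseError(f"unknown model dialect {dialect!r}; expected one of {_DIALECTS}")
    cb = to_cobra(model)
    if dialect == "json":
        cobra.io.save_json_model(cb, str(path))
    elif dialect == "sbml":
        cobra.io.write_sbml_model(cb, str(path))
    else:
        cobra.io.save_matlab_model(cb, str(path))


# ---------------------------------------------------------------------------
# Omics I/O
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise ParseError(f"failed to parse table {path}: {exc}") from exc
    df.index = df.index.astype(str)
    return df


def read_omics(
    metabolite_conc: str | Path | None = None,
    gene_expr: str | Path | None = None,
    measured_flux: str | Path | None = None,
    growth_rate: str | Path | None = None,
) -> OmicsDataset:
    """Read delimited-text omics tables and align them on the strain key.

    Every table must carry the strain label in its first column.  All
    supplied tables must cover exactly the same strain set; mismatched
    strains raise an :class:`AlignmentError` rather than being dropped.
    """
    blocks: dict[str, pd.DataFrame] = {}
    for name, path in (
        ("metabolite_conc", metabolite_conc),
        ("gene_expr", gene_expr),
        ("measured_flux", measured_flux),
        ("growth_rate", growth_rate),
    ):
        if path is not None:
            blocks[name] = _read_table(path)
    if not blocks:
        raise ParseError("no omics tables supplied")
    names = list(blocks)
    strain_sets = {name: set(df.index) for name, df in blocks.items()}
    reference = strain_sets[names[0]]
    for name in names[1:]:
        if strain_sets[name] != reference:
            missing = sorted(reference ^ strain_sets[name])
            raise AlignmentError(
                f"strain sets of {names[0]!r} and {name!r} differ: {missing}"
            )
    strains = list(blocks[names[0]].index)
    aligned = {name: df.loc[strains] for name, df in blocks.items()}
    growth = None
    if "growth_rate" in aligned:
        gdf = aligned.pop("growth_rate")
        growth = gdf.iloc[:, 0].astype(float)
    return OmicsDataset(strains=strains, growth_rate=growth, **aligned)


def write_omics(dataset: OmicsDataset, out_dir: str | Path, sep: str = ",") -> dict[str, Path]:
    """Write each omics block as a delimited table; returns block→path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".tsv" if sep == "\t" else ".csv"
    written: dict[str, Path] = {}
    for name in ("metabolite_conc", "gene_expr", "measured_flux"):
        block = getattr(dataset, name)
        if block is not None:
            path = out_dir / f"{name}{ext}"
            block.to_csv(path, sep=sep, index_label="strain")
            written[name] = path
    if dataset.growth_rate is not None:
        path = out_dir / f"growth_rate{ext}"
        dataset.growth_rate.rename("growth_rate").to_csv(
            path, sep=sep, index_label="strain"
        )
        written["growth_rate"] = path
    return written
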