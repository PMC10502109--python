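"""Global transcription regulation and metabolite-driven linearized kinetics.

The regulation model is log-linear: gene expression follows
``log(E_g) ~ alpha_g * sum_j theta_j log(M_bj) + sum_i beta_gi log(M_gi) + b``
where M_bj are biomass-constituent (BG) metabolites whose concentrations
track the growth rate and M_gi are local precursor/regulator (PG)
metabolites.  Candidate regulators are split into the BG and PG groups by
hierarchical clustering of their gene-correlation profiles; the regulatory
link between the BG group and gene expression is then quantified by partial
least squares regression (PLSR), and genes are called *globally regulated*
when both their total regression correlation and their first-component
correlation clear stringent thresholds (defaults 0.84 and 0.38).  An
empirical significance is attached by re-fitting PLSR on random same-size
metabolite subsets.

The kinetic half linearizes the reversible Michaelis-Menten rate law under
the Haldane relationship k_eq = exp(-dG'0 / RT) and the observation that
substrate concentrations sit at or above their K_m in central metabolism:
``log v ~ alpha sum_j theta_j log(M_bj) + log(1 - ([P]/[S])/k_eq)
+ ([P]/[S])/k_eq + sum_u k_A^u/[A_u] + const``,
so the unknown kinetic parameters collapse into ordinary linear-regression
coefficients over concentration-derived design columns.  The fitted model
predicts per-strain key-reaction fluxes v_KF that are handed to the
kinetic-constrained Decrem solver as flux boxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cross_decomposition import PLSRegression

from .exceptions import ConfigurationError
from .model_io import OmicsDataset
from .solver import KineticConstraint

RT_KJ_PER_MOL = 2.4788          # R*T at 298.15 K, kJ/mol
R_TOTAL_MIN_DEFAULT = 0.84      # total PLSR regression correlation threshold
R_PC1_MIN_DEFAULT = 0.38        # first-component correlation threshold
N_DRAWS_DEFAULT = 10_000
TEST_FRACTION_DEFAULT = 0.2
EXTRAPOLATION_FACTOR = 10.0


# ---------------------------------------------------------------------------
# Log transforms
# ---------------------------------------------------------------------------


def log_concentrations(conc: pd.DataFrame) -> pd.DataFrame:
    """Natural log of concentrations, flooring zeros per metabolite.

    Zeros are replaced by half the smallest positive observed value of the
    same metabolite before taking the log; all-zero columns raise.
    """
    out = conc.astype(float).copy()
    if (out.to_numpy() < 0).any():
        raise ValueError("negative concentrations cannot be log-transformed")
    for col in out.columns:
        vals = out[col]
        positive = vals[vals > 0]
        if positive.empty:
            raise ValueError(f"metabolite {col!r} has no positive concentration")
        out[col] = vals.replace(0.0, positive.min() / 2.0)
    return np.log(out)


# ---------------------------------------------------------------------------
# Regulator classification
# ---------------------------------------------------------------------------


def classify_regulators(
    omics: OmicsDataset,
    candidates: list[str],
    bg_cluster: int | None = None,
) -> tuple[set[str], set[str]]:
    """Split candidate regulators into BG and PG groups.

    Each candidate metabolite is profiled by the vector of correlations
    between its log concentration and every gene's log expression; the
    profiles are cut into two groups by average-linkage hierarchical
    clustering with correlation distance.  The group whose concentrations
    correlate more strongly with growth rate is labeled BG
    (biomass-constituent); without growth data the caller must pick the BG
    group via ``bg_cluster`` (1 or 2).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate regulators")
    if omics.metabolite_conc is None or omics.gene_expr is None:
        raise ValueError("omics must carry metabolite_conc and gene_expr blocks")
    missing = [m for m in candidates if m not in omics.metabolite_conc.columns]
    if missing:
        raise KeyError(f"candidate metabolites absent from omics: {missing}")
    logc = log_concentrations(omics.metabolite_conc[candidates])
    loge = np.log(omics.gene_expr.clip(lower=np.nextafter(0, 1)))
    profiles = np.corrcoef(logc.to_numpy().T, loge.to_numpy().T)[
        : len(candidates), len(candidates):
    ]
    Z = linkage(profiles, method="average", metric="correlation")
    labels = fcluster(Z, t=2, criterion="maxclust")
    groups = {
        1: {candidates[i] for i in np.flatnonzero(labels == 1)},
        2: {candidates[i] for i in np.flatnonzero(labels == 2)},
    }
    if omics.growth_rate is not None:
        logr = np.log(omics.growth_rate.clip(lower=np.nextafter(0, 1)))
        mean_abs_corr = {}
        for lab, mets in groups.items():
            corrs = [
                abs(np.corrcoef(logc[m], logr)[0, 1]) for m in sorted(mets)
            ]
            mean_abs_corr[lab] = float(np.mean(corrs)) if corrs else 0.0
        bg_label = max(mean_abs_corr, key=mean_abs_corr.get)
    elif bg_cluster in (1, 2):
        bg_label = bg_cluster
    else:
        raise ConfigurationError(
            "no growth_rate block: specify bg_cluster (1 or 2) explicitly"
        )
    pg_label = 1 if bg_label == 2 else 2
    return groups[bg_label], groups[pg_label]


# ---------------------------------------------------------------------------
# PLSR fit and gene selection
# ---------------------------------------------------------------------------


@dataclass
class PlsrFit:
    """A fitted PLSR decomposition X = T P' + E, Y = U Q' + F."""

    pls: PLSRegression
    x_columns: list[str]
    gene_ids: list[str]
    n_components: int
    x_scores: np.ndarray          # T
    y_scores: np.ndarray          # U
    x_loadings: np.ndarray        # P
    y_loadings: np.ndarray        # Q
    r_total: pd.Series            # per-gene corr(observed, fitted)
    r_pc1: pd.Series              # per-gene |corr(observed, first X score)|
    fitted: pd.DataFrame


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _loo_r2(X: np.ndarray, Y: np.ndarray, l: int) -> float:
    n = X.shape[0]
    press = 0.0
    total = np.sum((Y - Y.mean(axis=0)) ** 2)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pls = PLSRegression(n_components=l, scale=False)
        pls.fit(X[mask], Y[mask])
        press += float(np.sum((Y[i] - pls.predict(X[i][None, :])[0]) ** 2))
    return 1.0 - press / total if total > 0 else -np.inf


def fit_plsr(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_components: int | None = None,
    max_components: int = 10,
) -> PlsrFit:
    """Covariance-maximizing PLSR of gene expression on log concentrations.

    Component count is chosen by leave-one-out predictive R-squared when not
    fixed by the caller.  Reports per-gene total correlation (observed vs
    fitted) and first-component correlation.
    """
    if X.shape[0] < 3:
        raise ValueError("need at least 3 strains")
    if list(X.index) != list(Y.index):
        raise ValueError("X and Y must share the strain index")
    zero_var = [c for c in X.columns if X[c].std() == 0]
    if zero_var:
        raise ValueError(f"zero-variance predictor columns: {zero_var}")
    Xv = X.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)
    rank = int(np.linalg.matrix_rank(Xv - Xv.mean(axis=0)))
    cap = max(1, min(max_components, rank, Xv.shape[0] - 2))
    if n_components is None:
        scores = [(_loo_r2(Xv, Yv, l), -l) for l in range(1, cap + 1)]
        n_components = -max(scores)[1]
    elif n_components > cap:
        warnings.warn(
            f"n_components reduced from {n_components} to rank cap {cap}",
            stacklevel=2,
        )
        n_components = cap
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xv, Yv)
    fitted = pls.predict(Xv)
    t1 = pls.x_scores_[:, 0]
    r_total = pd.Series(
        [_safe_corr(Yv[:, g], fitted[:, g]) for g in range(Yv.shape[1])],
        index=list(Y.columns),
    )
    r_pc1 = pd.Series(
        [abs(_safe_corr(Yv[:, g], t1)) for g in range(Yv.shape[1])],
        index=list(Y.columns),
    )
    return PlsrFit(
        pls=pls,
        x_columns=list(X.columns),
        gene_ids=list(Y.columns),
        n_components=n_components,
        x_scores=pls.x_scores_,
        y_scores=pls.y_scores_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_,
        r_total=r_total,
        r_pc1=r_pc1,
        fitted=pd.DataFrame(fitted, index=Y.index, columns=Y.columns),
    )


def select_regulated_genes(
    fit: PlsrFit,
    r_total_min: float = R_TOTAL_MIN_DEFAULT,
    r_pc1_min: float = R_PC1_MIN_DEFAULT,
) -> set[str]:
    """Genes passing BOTH the total and first-component correlation cuts."""
    mask = (fit.r_total > r_total_min) & (fit.r_pc1 > r_pc1_min)
    return set(fit.r_total.index[mask])


def _mean_fit_correlation(
    logc: pd.DataFrame, loge: pd.DataFrame, subset: list[str], n_components: int
) -> float:
    l = min(n_components, len(subset), logc.shape[0] - 2)
    l = max(1, l)
    pls = PLSRegression(n_components=l, scale=False)
    Xs = logc[subset].to_numpy(dtype=float)
    Yv = loge.to_numpy(dtype=float)
    pls.fit(Xs, Yv)
    fitted = pls.predict(Xs)
    return float(
        np.mean([_safe_corr(Yv[:, g], fitted[:, g]) for g in range(Yv.shape[1])])
    )


def sampling_significance(
    omics: OmicsDataset,
    selected_metabolites: list[str],
    candidates: list[str],
    n_draws: int = N_DRAWS_DEFAULT,
    seed: int = 17,
    n_components: int = 2,
    genes: list[str] | None = None,
) -> float:
    """Empirical p-value of the selected regulator set by random sampling.

    Draws random same-size subsets of the candidate pool, refits PLSR and
    scores each by the mean per-gene predicted-vs-measured correlation;
    p is the fraction of draws scoring at least as high as the selected set.
    ``genes`` restricts the scoring to a gene subset (typically the genes
    identified as globally regulated); default is all genes.
    """
    if not set(selected_metabolites) <= set(candidates):
        raise ValueError("selected metabolites must come from the candidate pool")
    if n_draws < 100:
        warnings.warn("n_draws < 100 gives a coarse p-value", stacklevel=2)
    rng = np.random.default_rng(seed)
    logc = log_concentrations(omics.metabolite_conc[candidates])
    expr = omics.gene_expr if genes is None else omics.gene_expr[list(genes)]
    loge = np.log(expr.clip(lower=np.nextafter(0, 1)))
    observed = _mean_fit_correlation(
        logc, loge, list(selected_metabolites), n_components
    )
    k = len(selected_metabolites)
    pool = np.asarray(candidates)
    hits = 0
    for _ in range(n_draws):
        subset = rng.choice(pool, size=k, replace=False).tolist()
        if _mean_fit_correlation(logc, loge, subset, n_components) >= observed:
            hits += 1
    return hits / n_draws


# ---------------------------------------------------------------------------
# Linearized kinetics
# ---------------------------------------------------------------------------


@dataclass
class KineticDesign:
    """Design matrix over the linearized rate-law terms for one reaction."""

    reaction_id: str
    X: pd.DataFrame               # rows: retained strains
    excluded: dict[str, str]      # strain -> reason
    roles: dict
    k_eq: float | None
    bg_metabolites: list[str]


def _resolve_keq(thermo: dict | None) -> float | None:
    if thermo is None:
        return None
    if "k_eq" in thermo:
        return float(thermo["k_eq"])
    if "dG0" in thermo:
        return float(np.exp(-thermo["dG0"] / RT_KJ_PER_MOL))
    return None


def _conc_product(conc: pd.DataFrame, mets: list[str]) -> pd.Series:
    prod = pd.Series(1.0, index=conc.index)
    for m in mets:
        prod = prod * conc[m]
    return prod


def build_kinetic_design(
    omics: OmicsDataset,
    reaction_id: str,
    roles: dict,
    thermo: dict | None = None,
    bg_metabolites: list[str] | None = None,
    include_inhibitors: bool = False,
) -> KineticDesign:
    """Build the linearized rate-law design matrix for one reaction.

    ``roles`` maps "substrates", "products", "activators" (and optionally
    "inhibitors") to metabolite-id lists; ``thermo`` supplies ``k_eq`` or the
    standard Gibbs energy ``dG0`` (kJ/mol).  Columns: log-concentrations of
    the BG metabolites, the thermodynamic saturation term
    log(1 - ([P]/[S])/k_eq), the mass-action ratio ([P]/[S])/k_eq,
    reciprocal activator concentrations, and an intercept.  Strains where
    the saturation argument is nonpositive (at or past equilibrium) are
    excluded and reported.  Inhibitor reciprocal terms are accepted but off
    by default, matching the retained linearization terms.
    """
    if omics.metabolite_conc is None:
        raise ValueError("omics must carry metabolite concentrations")
    conc = omics.metabolite_conc.astype(float)
    substrates = list(roles.get("substrates", []))
    products = list(roles.get("products", []))
    activators = list(roles.get("activators", []))
    inhibitors = list(roles.get("inhibitors", [])) if include_inhibitors else []
    needed = substrates + products + activators + inhibitors
    missing = [m for m in needed if m not in conc.columns]
    if missing:
        raise KeyError(f"metabolites absent from omics: {missing}")
    if not substrates:
        raise ValueError("at least one substrate role is required")
    bg = list(bg_metabolites or [])
    missing_bg = [m for m in bg if m not in conc.columns]
    if missing_bg:
        raise KeyError(f"BG metabolites absent from omics: {missing_bg}")

    k_eq = _resolve_keq(thermo)
    if products and k_eq is None:
        raise ConfigurationError(
            f"reaction {reaction_id!r} has products but no k_eq/dG0 supplied"
        )

    s_conc = _conc_product(conc, substrates)
    if products:
        p_conc = _conc_product(conc, products)
        ratio = (p_conc / s_conc) / k_eq
    else:
        ratio = pd.Series(0.0, index=conc.index)

    excluded: dict[str, str] = {}
    keep = []
    for strain in conc.index:
        if s_conc[strain] <= 0:
            excluded[strain] = "nonpositive substrate concentration"
        elif ratio[strain] >= 1.0:
            excluded[strain] = "saturation argument nonpositive (at/past equilibrium)"
        else:
            keep.append(strain)

    cols: dict[str, pd.Series] = {}
    logc = log_concentrations(conc[bg]) if bg else None
    for m in bg:
        cols[f"log_{m}"] = logc[m]
    cols["saturation"] = np.log(1.0 - ratio.clip(upper=1.0 - 1e-300))
    cols["mass_action"] = ratio
    for a in activators:
        cols[f"inv_{a}"] = 1.0 / conc[a]
    for i in inhibitors:
        cols[f"inv_inh_{i}"] = 1.0 / conc[i]
    cols["const"] = pd.Series(1.0, index=conc.index)
    X = pd.DataFrame(cols).loc[keep]
    return KineticDesign(
        reaction_id=reaction_id,
        X=X,
        excluded=excluded,
        roles=dict(roles),
        k_eq=k_eq,
        bg_metabolites=bg,
    )


@dataclass
class KineticFit:
    """Linear regression of log-flux on the linearized rate-law terms."""

    reaction_id: str
    coef: pd.Series
    coef_se: pd.Series
    train_r: float
    test_r: float
    train_strains: list[str]
    test_strains: list[str]
    excluded: dict[str, str]
    design_columns: list[str]
    column_ranges: pd.DataFrame        # train min/max per design column
    roles: dict = field(default_factory=dict)
    thermo_k_eq: float | None = None
    bg_metabolites: list[str] = field(default_factory=list)
    ridge_alpha: float | None = None


def _stratified_split(
    strains: list[str],
    test_fraction: float,
    seed: int,
    growth: pd.Series | None,
) -> tuple[list[str], list[str]]:
    """80/20-style split; stratified along the growth-rate ordering if known."""
    rng = np.random.default_rng(seed)
    n = len(strains)
    n_test = max(1, int(round(test_fraction * n)))
    if growth is not None:
        order = list(pd.Series(growth[strains]).sort_values().index)
        step = max(1, n // n_test)
        start = int(rng.integers(0, step))
        test = order[start::step][:n_test]
    else:
        test = list(rng.choice(strains, size=n_test, replace=False))
    train = [s for s in strains if s not in set(test)]
    return train, test


def fit_linear_kinetics(
    design: KineticDesign,
    measured_flux: pd.Series,
    test_fraction: float = TEST_FRACTION_DEFAULT,
    seed: int = 17,
    growth: pd.Series | None = None,
) -> KineticFit:
    """Ordinary least squares of log-flux on the design columns.

    Strains with nonpositive flux (log undefined) are excluded and reported.
    When the training set is thinner than twice the column count, a small
    ridge penalty is used instead, with a warning.  Train and held-out
    correlations between observed and fitted log-flux are reported.
    """
    excluded = dict(design.excluded)
    shared = [s for s in design.X.index if s in measured_flux.index]
    usable = []
    for s in shared:
        flux = measured_flux[s]
        if not np.isfinite(flux) or flux <= 0:
            excluded[s] = "nonpositive or missing flux (log undefined)"
        else:
            usable.append(s)
    if len(usable) < 2:
        raise ValueError(f"only {len(usable)} usable strains; need at least 2")
    train, test = _stratified_split(usable, test_fraction, seed, growth)
    X = design.X.loc[train].to_numpy(dtype=float)
    y = np.log(measured_flux[train].to_numpy(dtype=float))
    p = X.shape[1]
    ridge_alpha = None
    if X.shape[0] < 2 * p:
        ridge_alpha = 1e-6
        warnings.warn(
            f"{X.shape[0]} training strains for {p} columns: ridge fallback",
            stacklevel=2,
        )
        XtX = X.T @ X + ridge_alpha * np.eye(p)
    else:
        XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = max(1, X.shape[0] - p)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    yhat_train = X @ beta
    train_r = _safe_corr(y, yhat_train)
    if len(test) >= 2:
        Xt = design.X.loc[test].to_numpy(dtype=float)
        yt = np.log(measured_flux[test].to_numpy(dtype=float))
        test_r = _safe_corr(yt, Xt @ beta)
    else:
        test_r = np.nan
    ranges = pd.DataFrame(
        {
            "min": design.X.loc[train].min(),
            "max": design.X.loc[train].max(),
        }
    )
    return KineticFit(
        reaction_id=design.reaction_id,
        coef=pd.Series(beta, index=list(design.X.columns)),
        coef_se=pd.Series(se, index=list(design.X.columns)),
        train_r=train_r,
        test_r=test_r,
        train_strains=train,
        test_strains=test,
        excluded=excluded,
        design_columns=list(design.X.columns),
        column_ranges=ranges,
        roles=design.roles,
        thermo_k_eq=design.k_eq,
        bg_metabolites=design.bg_metabolites,
        ridge_alpha=ridge_alpha,
    )


def predict_kinetic_flux(
    fit: KineticFit,
    omics: OmicsDataset,
    strains: list[str] | None = None,
    delta: float | None = None,
) -> dict[str, KineticConstraint]:
    """Predict per-strain kinetic fluxes v_KF for the fitted reaction.

    Predictions are exponentiated back to flux units.  A strain whose design
    values fall beyond 10x the training range of any column is flagged as an
    extrapolation on the returned constraint.
    """
    design = build_kinetic_design(
        omics,
        fit.reaction_id,
        fit.roles,
        thermo={"k_eq": fit.thermo_k_eq} if fit.thermo_k_eq is not None else None,
        bg_metabolites=fit.bg_metabolites,
    )
    strains = list(strains) if strains is not None else list(design.X.index)
    constraints: dict[str, KineticConstraint] = {}
    for s in strains:
        if s not in design.X.index:
            continue
        row = design.X.loc[s]
        v_kf = float(np.exp(row.to_numpy(dtype=float) @ fit.coef.to_numpy()))
        extrapolated = False
        for col in fit.design_columns:
            lo, hi = fit.column_ranges.loc[col, "min"], fit.column_ranges.loc[col, "max"]
            span = max(abs(lo), abs(hi), 1e-12)
            if row[col] < lo - (EXTRAPOLATION_FACTOR - 1) * span or row[col] > hi + (
                EXTRAPOLATION_FACTOR - 1
            ) * span:
                extrapolated = True
                break
        if extrapolated:
            warnings.warn(
                f"strain {s!r} extrapolates beyond the training range", stacklevel=2
            )
        constraints[s] = KineticConstraint(
            reaction_id=fit.reaction_id,
            v_kf=v_kf,
            delta=delta,
            extrapolated=extrapolated,
        )
    return constraints
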