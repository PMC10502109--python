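"""Synthetic fixtures: toy metabolic networks and generative multi-omics.

``make_network`` plants closed reaction cycles (the coupled substructures)
next to linear uptake->chain->secretion routes (the non-coupled remainder),
optionally bridged so that cycle metabolites also feed the chains.  The
planted truth — cluster membership and the all-ones sparse-basis support of
every cycle — is returned alongside the model, so each pipeline stage can be
checked against construction-time ground truth.

``make_omics`` simulates strain panels from the package's own regulatory and
kinetic models, used generatively: biomass-constituent (BG) metabolite
concentrations are log-normal; growth follows the multiplicative biomass law
R = lambda * prod_j (1 + M_bj/K_mj)^theta_j; globally regulated genes follow
the log-linear law log E = alpha_g sum_j theta_j log M_bj + b (plus Gaussian
log-noise) while the remaining genes are driven by local precursor (PG)
metabolites; and measured fluxes come from the full reversible
Michaelis-Menten rate law with Haldane-consistent k_eq, evaluated at the
sampled concentrations with multiplicative noise.  Defaults mirror a
24-strain knockout panel with 45 candidate regulators (23 BG + 22 PG) and
85 genes of which 32 are globally regulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import MetabolicModel, OmicsDataset

IRREVERSIBLE_BOUNDS = (0.0, 10.0)
REVERSIBLE_BOUNDS = (-10.0, 10.0)


# ---------------------------------------------------------------------------
# Toy networks
# ---------------------------------------------------------------------------


@dataclass
class SynthNetworkSpec:
    """Blueprint of a planted-structure toy network."""

    n_cycles: int = 2
    cycle_lengths: list[int] | None = None      # default: all 3
    n_chain_reactions: int = 4
    n_bridge_reactions: int = 0
    randomize_bounds: bool = False              # draw chain ub from [5, 15]
    seed: int = 17

    def resolved_cycle_lengths(self) -> list[int]:
        lengths = self.cycle_lengths or [3] * self.n_cycles
        if len(lengths) != self.n_cycles:
            raise ValueError("cycle_lengths must have n_cycles entries")
        if any(L < 3 for L in lengths):
            raise ValueError("cycle lengths must be >= 3")
        return lengths


def make_network(spec: SynthNetworkSpec) -> tuple[MetabolicModel, dict]:
    """Build a toy model with planted coupled cycles and linear chains.

    Returns the model and a truth dict with keys ``clusters`` (reaction
    index sets per planted cycle), ``slb_supports`` (expected sparse-basis
    support per cycle: all its reactions with unit coefficients),
    ``chain_reactions`` and ``objective_id``.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = spec.resolved_cycle_lengths()
    met_ids: list[str] = []
    rxn_ids: list[str] = []
    entries: list[tuple[int, int, float]] = []  # (met, rxn, coeff)
    lb: list[float] = []
    ub: list[float] = []

    def add_met(mid: str) -> int:
        met_ids.append(mid)
        return len(met_ids) - 1

    def add_rxn(rid: str, stoich: dict[int, float], bounds: tuple[float, float]) -> int:
        rxn_ids.append(rid)
        j = len(rxn_ids) - 1
        for i, coeff in stoich.items():
            entries.append((i, j, coeff))
        lb.append(bounds[0])
        ub.append(bounds[1])
        return j

    clusters: list[list[int]] = []
    cycle_mets: list[list[int]] = []
    for c, L in enumerate(lengths):
        mets = [add_met(f"M_cyc{c}_{i}") for i in range(L)]
        cycle_mets.append(mets)
        members = []
        for i in range(L):
            j = add_rxn(
                f"CYC{c}_{i}",
                {mets[i]: -1.0, mets[(i + 1) % L]: 1.0},
                IRREVERSIBLE_BOUNDS,
            )
            members.append(j)
        clusters.append(members)

    # linear chains: uptake -> internal reactions -> secretion
    chain_rxns: list[int] = []
    chain_mets: list[int] = []
    objective_id = None
    remaining = spec.n_chain_reactions
    chain_idx = 0
    while remaining > 0:
        length = int(min(remaining, max(2, rng.integers(2, 5))))
        mets = [add_met(f"M_ch{chain_idx}_{i}") for i in range(length + 1)]
        chain_mets.extend(mets)
        hi = float(rng.uniform(5, 15)) if spec.randomize_bounds else IRREVERSIBLE_BOUNDS[1]
        add_rxn(f"EX_in_{chain_idx}", {mets[0]: 1.0}, (0.0, hi))
        for i in range(length):
            j = add_rxn(
                f"CH{chain_idx}_{i}",
                {mets[i]: -1.0, mets[i + 1]: 1.0},
                (0.0, float(rng.uniform(5, 15)) if spec.randomize_bounds else IRREVERSIBLE_BOUNDS[1]),
            )
            chain_rxns.append(j)
        out = add_rxn(f"EX_out_{chain_idx}", {mets[-1]: -1.0}, IRREVERSIBLE_BOUNDS)
        if objective_id is None:
            objective_id = out
        remaining -= length
        chain_idx += 1

    # bridges: cycle metabolite -> chain metabolite, never closing a new cycle
    for b in range(spec.n_bridge_reactions):
        if not chain_mets:
            break
        c = b % len(cycle_mets)
        src = int(rng.choice(cycle_mets[c]))
        dst = int(rng.choice(chain_mets))
        add_rxn(f"BR_{b}", {src: -1.0, dst: 1.0}, IRREVERSIBLE_BOUNDS)

    m, n = len(met_ids), len(rxn_ids)
    S = np.zeros((m, n))
    for i, j, coeff in entries:
        S[i, j] = coeff
    c_vec = np.zeros(n)
    if objective_id is not None:
        c_vec[objective_id] = 1.0
    model = MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lb=np.asarray(lb),
        ub=np.asarray(ub),
        c=c_vec,
        metadata={"model_id": f"synth_net_seed{spec.seed}"},
    )
    truth = {
        "clusters": clusters,
        "slb_supports": [sorted(members) for members in clusters],
        "chain_reactions": chain_rxns,
        "objective_id": rxn_ids[objective_id] if objective_id is not None else None,
    }
    return model, truth


# ---------------------------------------------------------------------------
# Generative multi-omics
# ---------------------------------------------------------------------------


@dataclass
class SynthOmicsSpec:
    """Blueprint of a generative strain panel.

    Coefficient ranges follow the log-linear regulation law; kinetic
    parameters parameterize the full reversible rate law used as the flux
    simulator.  ``noise_sd`` is the Gaussian standard deviation applied on
    the log scale to expression and flux.
    """

    n_strains: int = 24
    n_bg: int = 23
    n_pg: int = 22
    n_genes: int = 85
    n_regulated: int = 32
    theta_range: tuple[float, float] = (0.02, 0.08)
    alpha_range: tuple[float, float] = (0.5, 1.5)
    beta_range: tuple[float, float] = (0.3, 1.0)
    conc_log_sd: float = 0.3        # idiosyncratic spread of log concentrations
    growth_coupling: float = 0.5    # shared growth-state factor on BG pools
    noise_sd: float = 0.05
    n_kinetic_reactions: int = 3
    substrate_km_ratio: tuple[float, float] = (2.0, 8.0)   # [S]/K_m regime
    seed: int = 17


def make_omics(
    spec: SynthOmicsSpec, model: MetabolicModel | None = None
) -> tuple[OmicsDataset, dict]:
    """Simulate a strain panel from the generative regulation/kinetic laws.

    Returns the dataset plus a truth dict holding the BG/PG memberships,
    the planted regulated-gene set, the regression coefficients
    (theta, alpha, beta, lambda) and per-reaction kinetic parameters
    (k_eq, K_m values, activator affinity, roles).
    """
    rng = np.random.default_rng(spec.seed)
    strains = [f"strain_{i:02d}" for i in range(spec.n_strains)]
    bg_ids = [f"BG_{j:02d}" for j in range(spec.n_bg)]
    pg_ids = [f"PG_{j:02d}" for j in range(spec.n_pg)]
    gene_ids = [f"gene_{g:03d}" for g in range(spec.n_genes)]
    regulated = sorted(
        rng.choice(spec.n_genes, size=spec.n_regulated, replace=False).tolist()
    )
    regulated_genes = {gene_ids[g] for g in regulated}

    # concentrations: strictly positive log-normal draws.  Biomass pools share
    # a per-strain growth-state factor z (knockouts mainly shift the global
    # state), plus idiosyncratic noise; precursor pools are independent.
    mu_bg = rng.uniform(0.0, 1.0, size=spec.n_bg)
    z = rng.standard_normal(spec.n_strains)
    log_bg = (
        mu_bg
        + spec.growth_coupling * z[:, None]
        + spec.conc_log_sd * rng.standard_normal((spec.n_strains, spec.n_bg))
    )
    mu_pg = rng.uniform(0.0, 1.0, size=spec.n_pg)
    log_pg = mu_pg + 0.5 * rng.standard_normal((spec.n_strains, spec.n_pg))
    conc = pd.DataFrame(
        np.exp(np.hstack([log_bg, log_pg])), index=strains, columns=bg_ids + pg_ids
    )

    # growth via the multiplicative biomass law
    theta = rng.uniform(*spec.theta_range, size=spec.n_bg)
    K_m_bio = np.exp(mu_bg)  # cell-state kinetic constants near typical conc
    raw = np.prod((1.0 + conc[bg_ids].to_numpy() / K_m_bio) ** theta, axis=1)
    lam = 0.7 / float(np.median(raw))  # scale to a physiological growth range
    growth = lam * raw
    growth_series = pd.Series(growth, index=strains, name="growth_rate")

    # the shared global index driving regulated genes
    bg_index = log_bg @ theta

    alpha = rng.uniform(*spec.alpha_range, size=spec.n_genes)
    beta = rng.uniform(*spec.beta_range, size=(spec.n_genes, 2))
    intercepts = rng.uniform(-0.5, 0.5, size=spec.n_genes)
    log_expr = np.empty((spec.n_strains, spec.n_genes))
    pg_pairs = rng.integers(0, spec.n_pg, size=(spec.n_genes, 2))
    for g in range(spec.n_genes):
        noise = spec.noise_sd * rng.standard_normal(spec.n_strains)
        if g in regulated:
            log_expr[:, g] = alpha[g] * bg_index + intercepts[g] + noise
        else:
            local = log_pg[:, pg_pairs[g]] @ beta[g]
            log_expr[:, g] = local + intercepts[g] + noise
    expr = pd.DataFrame(np.exp(log_expr), index=strains, columns=gene_ids)

    # measured fluxes from the full reversible rate law
    kinetic_truth: dict[str, dict] = {}
    flux_cols: dict[str, np.ndarray] = {}
    if model is not None and model.n_reactions >= spec.n_kinetic_reactions:
        rxn_ids = list(model.reaction_ids[: spec.n_kinetic_reactions])
    else:
        rxn_ids = [f"KIN_{k}" for k in range(spec.n_kinetic_reactions)]
    for k, rid in enumerate(rxn_ids):
        substrate = bg_ids[k % spec.n_bg]          # substrate within the BG block
        product = pg_ids[k % spec.n_pg]
        activator = pg_ids[(k + 1) % spec.n_pg]
        gene = gene_ids[regulated[k % len(regulated)]]
        s = conc[substrate].to_numpy()
        p = conc[product].to_numpy()
        a = conc[activator].to_numpy()
        lo, hi = spec.substrate_km_ratio
        k_m_s = float(np.exp(mu_bg[k % spec.n_bg]) / rng.uniform(lo, hi))
        k_m_p = float(np.median(p) / rng.uniform(lo, hi))
        k_eq = float(rng.uniform(5.0, 20.0) * np.median(p) / np.median(s))
        k_a = float(np.median(a) / rng.uniform(5.0, 20.0))
        k_plus = float(rng.uniform(5.0, 15.0))
        enzyme = np.exp(alpha[regulated[k % len(regulated)]] * bg_index)
        gamma = (p / s) / k_eq
        rate = (
            enzyme
            * k_plus
            * (s / k_m_s)
            * (1.0 - gamma)
            / (1.0 + s / k_m_s + p / k_m_p)
            * ((a / k_a) / (1.0 + a / k_a))
        )
        rate = rate * np.exp(spec.noise_sd * rng.standard_normal(spec.n_strains))
        flux_cols[rid] = rate
        kinetic_truth[rid] = {
            "roles": {
                "substrates": [substrate],
                "products": [product],
                "activators": [activator],
            },
            "gene": gene,
            "k_eq": k_eq,
            "k_m_s": k_m_s,
            "k_m_p": k_m_p,
            "k_a": k_a,
            "k_plus": k_plus,
        }
    flux = pd.DataFrame(flux_cols, index=strains)

    dataset = OmicsDataset(
        strains=strains,
        metabolite_conc=conc,
        gene_expr=expr,
        measured_flux=flux if flux_cols else None,
        growth_rate=growth_series,
        metadata={"seed": spec.seed},
    )
    truth = {
        "bg": set(bg_ids),
        "pg": set(pg_ids),
        "regulated_genes": regulated_genes,
        "theta": pd.Series(theta, index=bg_ids),
        "alpha": pd.Series(alpha, index=gene_ids),
        "lambda": lam,
        "K_m_bio": pd.Series(K_m_bio, index=bg_ids),
        "bg_index": pd.Series(bg_index, index=strains),
        "kinetics": kinetic_truth,
    }
    return dataset, truth
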