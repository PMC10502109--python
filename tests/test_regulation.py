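import itertools

import numpy as np
import pandas as pd
import pytest

from decrem import (
    ConfigurationError,
    OmicsDataset,
    SynthOmicsSpec,
    build_kinetic_design,
    classify_regulators,
    fit_linear_kinetics,
    fit_plsr,
    make_omics,
    predict_kinetic_flux,
    sampling_significance,
    select_regulated_genes,
)
from decrem.regulation import (
    N_DRAWS_DEFAULT,
    R_PC1_MIN_DEFAULT,
    R_TOTAL_MIN_DEFAULT,
    RT_KJ_PER_MOL,
    log_concentrations,
)

from oracle_utils import f1_score_sets


def small_panel(seed=5, **kw):
    return make_omics(SynthOmicsSpec(seed=seed, **kw))


class TestLogTransform:
    def test_zeros_floored_at_half_minimum(self):
        conc = pd.DataFrame({"m": [0.0, 2.0, 4.0]}, index=list("abc"))
        logged = log_concentrations(conc)
        assert logged.loc["a", "m"] == pytest.approx(np.log(1.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_concentrations(pd.DataFrame({"m": [-1.0]}, index=["a"]))


class TestClassifyRegulators:
    def test_growth_driving_metabolites_form_bg(self, omics_panel):
        ds, truth = omics_panel
        cands = sorted(truth["bg"]) + sorted(truth["pg"])
        bg, pg = classify_regulators(ds, cands)
        assert bg.isdisjoint(pg)
        assert bg | pg == set(cands)
        # the growth-driving cluster must be recovered with high fidelity
        assert f1_score_sets(bg, truth["bg"]) >= 0.75

    def test_absent_candidate_rejected(self, omics_panel):
        ds, _ = omics_panel
        with pytest.raises(KeyError):
            classify_regulators(ds, ["BG_00", "NOT_A_METABOLITE"])

    def test_too_few_candidates(self, omics_panel):
        ds, _ = omics_panel
        with pytest.raises(ValueError):
            classify_regulators(ds, ["BG_00"])


class TestPlsr:
    def test_exact_linear_relation_fits_perfectly(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("wxyz"))
        W = rng.normal(size=(4, 3))
        Y = pd.DataFrame(X.to_numpy() @ W, columns=["g1", "g2", "g3"])
        fit = fit_plsr(X, Y, n_components=4)
        assert (fit.r_total > 1 - 1e-8).all()

    def test_independent_noise_yields_low_correlation(self):
        rs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(50, 5)))
            Y = pd.DataFrame(rng.normal(size=(50, 8)))
            fit = fit_plsr(X, Y, n_components=1)
            rs.append(fit.r_total.abs().median())
        assert np.median(rs) < 0.3

    def test_joint_strain_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(15, 3)))
        Y = pd.DataFrame(rng.normal(size=(15, 4)))
        fit = fit_plsr(X, Y, n_components=2)
        perm = rng.permutation(15)
        fit_p = fit_plsr(X.iloc[perm].reset_index(drop=True),
                         Y.iloc[perm].reset_index(drop=True), n_components=2)
        pd.testing.assert_series_equal(fit.r_total, fit_p.r_total, atol=1e-9)

    def test_scores_loadings_reproduce_fitted(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(12, 4)))
        Y = pd.DataFrame(rng.normal(size=(12, 2)))
        fit = fit_plsr(X, Y, n_components=2)
        assert fit.x_scores.shape == (12, 2)
        assert fit.x_loadings.shape == (4, 2)
        # X is reproduced within residuals of the bilinear decomposition
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        resid = Xc - fit.x_scores @ fit.x_loadings.T
        assert np.linalg.norm(resid) < np.linalg.norm(Xc)


class TestGeneSelection:
    def test_default_selection_thresholds(self):
        assert R_TOTAL_MIN_DEFAULT == 0.84
        assert R_PC1_MIN_DEFAULT == 0.38

    def test_impossible_thresholds_select_nothing(self, omics_panel):
        ds, truth = omics_panel
        X = log_concentrations(ds.metabolite_conc[sorted(truth["bg"])])
        Y = np.log(ds.gene_expr)
        fit = fit_plsr(X, Y, n_components=2)
        assert select_regulated_genes(fit, 1.1, 1.1) == set()

    def test_selection_monotone_in_thresholds(self, omics_panel):
        ds, truth = omics_panel
        X = log_concentrations(ds.metabolite_conc[sorted(truth["bg"])])
        Y = np.log(ds.gene_expr)
        fit = fit_plsr(X, Y, n_components=2)
        loose = select_regulated_genes(fit, 0.5, 0.2)
        tight = select_regulated_genes(fit, 0.9, 0.5)
        assert tight <= loose

    def test_planted_regulated_genes_recovered(self, omics_panel):
        ds, truth = omics_panel
        X = log_concentrations(ds.metabolite_conc[sorted(truth["bg"])])
        Y = np.log(ds.gene_expr)
        fit = fit_plsr(X, Y)
        selected = select_regulated_genes(fit)
        assert f1_score_sets(selected, truth["regulated_genes"]) >= 0.9


class TestSamplingSignificance:
    def test_default_draw_count(self):
        assert N_DRAWS_DEFAULT == 10_000

    def test_true_regulators_are_significant(self, omics_panel):
        ds, truth = omics_panel
        cands = sorted(truth["bg"]) + sorted(truth["pg"])
        p = sampling_significance(
            ds, sorted(truth["bg"]), cands, n_draws=300, seed=1,
            genes=sorted(truth["regulated_genes"]),
        )
        assert p <= 0.01

    def test_matches_exhaustive_enumeration_on_small_pool(self):
        """Empirical p agrees with full enumeration within binomial error."""
        ds, truth = small_panel(seed=7, n_bg=4, n_pg=4, n_genes=10, n_regulated=4)
        pool = sorted(truth["bg"]) + sorted(truth["pg"])  # 8 candidates
        selected = sorted(truth["bg"])[:3]
        genes = sorted(truth["regulated_genes"])
        from decrem.regulation import _mean_fit_correlation

        logc = log_concentrations(ds.metabolite_conc[pool])
        loge = np.log(ds.gene_expr[genes])
        observed = _mean_fit_correlation(logc, loge, selected, 2)
        stats = [
            _mean_fit_correlation(logc, loge, list(sub), 2)
            for sub in itertools.combinations(pool, 3)
        ]
        exact = np.mean([s >= observed for s in stats])
        n_draws = 400
        p = sampling_significance(
            ds, selected, pool, n_draws=n_draws, seed=3, genes=genes
        )
        se = np.sqrt(max(exact * (1 - exact), 1e-4) / n_draws)
        assert abs(p - exact) <= 4 * se + 1e-9

    def test_small_draw_count_warns(self, omics_panel):
        ds, truth = omics_panel
        cands = sorted(truth["bg"]) + sorted(truth["pg"])
        with pytest.warns(UserWarning):
            sampling_significance(ds, sorted(truth["bg"])[:3], cands, n_draws=50, seed=0)


class TestKineticDesign:
    def panel_with_kinetics(self):
        ds, truth = small_panel(seed=9)
        rid = list(truth["kinetics"])[0]
        return ds, truth, rid, truth["kinetics"][rid]

    def test_no_product_gives_pure_forward_limit(self):
        ds, truth, rid, kt = self.panel_with_kinetics()
        roles = {"substrates": kt["roles"]["substrates"], "products": [],
                 "activators": kt["roles"]["activators"]}
        design = build_kinetic_design(ds, rid, roles, bg_metabolites=[])
        assert (design.X["saturation"] == 0).all()
        assert (design.X["mass_action"] == 0).all()

    def test_equilibrium_strain_excluded(self):
        ds, truth, rid, kt = self.panel_with_kinetics()
        # force one strain to equilibrium by an absurdly small k_eq
        design = build_kinetic_design(
            ds, rid, kt["roles"], thermo={"k_eq": 1e-12}, bg_metabolites=[]
        )
        assert len(design.excluded) == ds.n_strains
        assert design.X.shape[0] == 0

    def test_missing_thermo_constant_rejected(self):
        ds, truth, rid, kt = self.panel_with_kinetics()
        with pytest.raises(ConfigurationError):
            build_kinetic_design(ds, rid, kt["roles"], thermo=None)

    def test_design_reproduces_generative_terms(self):
        """Design columns equal hand-computed rate-law terms to 1e-12."""
        ds, truth, rid, kt = self.panel_with_kinetics()
        design = build_kinetic_design(
            ds, rid, kt["roles"], thermo={"k_eq": kt["k_eq"]},
            bg_metabolites=sorted(truth["bg"]),
        )
        s = ds.metabolite_conc[kt["roles"]["substrates"][0]]
        p = ds.metabolite_conc[kt["roles"]["products"][0]]
        gamma = (p / s) / kt["k_eq"]
        np.testing.assert_allclose(
            design.X["saturation"], np.log(1 - gamma[design.X.index]), atol=1e-12
        )
        np.testing.assert_allclose(
            design.X["mass_action"], gamma[design.X.index], atol=1e-12
        )
        a = ds.metabolite_conc[kt["roles"]["activators"][0]]
        np.testing.assert_allclose(
            design.X[f"inv_{kt['roles']['activators'][0]}"],
            1.0 / a[design.X.index], atol=1e-12,
        )

    def test_dg0_converts_through_rt(self):
        ds, truth, rid, kt = self.panel_with_kinetics()
        dg0 = -RT_KJ_PER_MOL * np.log(kt["k_eq"])
        d1 = build_kinetic_design(ds, rid, kt["roles"], thermo={"dG0": dg0},
                                  bg_metabolites=[])
        d2 = build_kinetic_design(ds, rid, kt["roles"], thermo={"k_eq": kt["k_eq"]},
                                  bg_metabolites=[])
        pd.testing.assert_frame_equal(d1.X, d2.X)


class TestLinearKinetics:
    def noise_free_fit(self, n_strains=40):
        ds, truth = make_omics(
            SynthOmicsSpec(n_strains=n_strains, noise_sd=0.0, n_bg=6, n_pg=6,
                           n_genes=12, n_regulated=6, seed=11)
        )
        rid = list(truth["kinetics"])[0]
        kt = truth["kinetics"][rid]
        design = build_kinetic_design(
            ds, rid, kt["roles"], thermo={"k_eq": kt["k_eq"]},
            bg_metabolites=sorted(truth["bg"]),
        )
        fit = fit_linear_kinetics(design, ds.measured_flux[rid], seed=1,
                                  growth=ds.growth_rate)
        return ds, truth, rid, kt, design, fit

    def test_degenerate_input_rejected(self):
        ds, truth = small_panel(seed=9)
        rid = list(truth["kinetics"])[0]
        kt = truth["kinetics"][rid]
        design = build_kinetic_design(ds, rid, kt["roles"],
                                      thermo={"k_eq": kt["k_eq"]}, bg_metabolites=[])
        single = ds.measured_flux[rid].iloc[:1]
        with pytest.raises(ValueError):
            fit_linear_kinetics(design, single)

    def test_nonpositive_flux_strains_excluded(self):
        ds, truth = small_panel(seed=9)
        rid = list(truth["kinetics"])[0]
        kt = truth["kinetics"][rid]
        design = build_kinetic_design(ds, rid, kt["roles"],
                                      thermo={"k_eq": kt["k_eq"]}, bg_metabolites=[])
        flux = ds.measured_flux[rid].copy()
        bad = flux.index[0]
        flux[bad] = -1.0
        fit = fit_linear_kinetics(design, flux, seed=1)
        assert bad in fit.excluded
        assert bad not in fit.train_strains + fit.test_strains

    def test_joint_concentration_scaling_shifts_only_intercept(self):
        """Multiplying all concentrations by a constant leaves predictions put."""
        ds, truth, rid, kt, design, fit = self.noise_free_fit()
        scaled = OmicsDataset(
            strains=ds.strains,
            metabolite_conc=ds.metabolite_conc * 10.0,
            gene_expr=ds.gene_expr,
            measured_flux=ds.measured_flux,
            growth_rate=ds.growth_rate,
        )
        d2 = build_kinetic_design(
            scaled, rid, kt["roles"], thermo={"k_eq": kt["k_eq"]},
            bg_metabolites=sorted(truth["bg"]),
        )
        # ratio-based columns unchanged; log columns shifted by log(10)
        np.testing.assert_allclose(d2.X["mass_action"], design.X["mass_action"])
        np.testing.assert_allclose(d2.X["saturation"], design.X["saturation"])
        bg0 = f"log_{sorted(truth['bg'])[0]}"
        np.testing.assert_allclose(
            d2.X[bg0] - design.X[bg0], np.log(10.0), atol=1e-12
        )

    def test_exact_linear_flux_recovered_to_machine_precision(self):
        """Flux generated from the linearized law itself fits with r = 1."""
        ds, truth, rid, kt, design, _ = self.noise_free_fit()
        rng = np.random.default_rng(2)
        beta = rng.normal(size=design.X.shape[1])
        flux = pd.Series(
            np.exp(design.X.to_numpy() @ beta), index=design.X.index
        )
        fit = fit_linear_kinetics(design, flux, seed=1, growth=ds.growth_rate)
        assert fit.train_r > 1 - 1e-6
        assert fit.test_r > 1 - 1e-6
        preds = predict_kinetic_flux(fit, ds)
        strain = fit.train_strains[0]
        assert preds[strain].v_kf == pytest.approx(flux[strain], rel=1e-6)

    def test_predict_reproduces_training_flux_noise_free(self):
        ds, truth, rid, kt, design, fit = self.noise_free_fit()
        # the full rate law is only approximately linear in the design terms;
        # with zero noise the fit should still be essentially exact
        assert fit.train_r > 0.995
        preds = predict_kinetic_flux(fit, ds)
        strain = fit.train_strains[0]
        assert preds[strain].v_kf == pytest.approx(
            ds.measured_flux.loc[strain, rid], rel=0.05
        )
        assert not preds[strain].extrapolated

    def test_extreme_concentrations_flag_extrapolation(self):
        ds, truth, rid, kt, design, fit = self.noise_free_fit()
        wild = OmicsDataset(
            strains=ds.strains,
            metabolite_conc=ds.metabolite_conc * 1e4,
            gene_expr=ds.gene_expr,
            measured_flux=ds.measured_flux,
            growth_rate=ds.growth_rate,
        )
        with pytest.warns(UserWarning):
            preds = predict_kinetic_flux(fit, wild)
        assert any(kc.extrapolated for kc in preds.values())
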