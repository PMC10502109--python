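import numpy as np
import pytest

from decrem import (
    AssemblyError,
    MetabolicModel,
    assemble_decoupled_model,
    build_cluster_submodel,
    recover_element_fluxes,
    sparsify_nullspace,
    solve_decrem_fba,
)
from decrem.slb import ZETA_DEFAULT, _lbr_bounds

from conftest import fed_cycle_model, toy_cycle_model
from oracle_utils import minimal_support_basis_sizes


class TestClusterSubmodel:
    def test_closed_cycle_needs_no_exchanges(self):
        model = toy_cycle_model()
        sub = build_cluster_submodel(model, [0, 1, 2])
        assert sub.n_artificial == 0
        assert sub.rank == 2  # 3x3 cycle matrix has rank 2
        assert sub.r_k == 1

    def test_boundary_metabolite_gets_exchange(self):
        # A <-> B pair where A also feeds an external drain
        S = np.array([[-1.0, 1.0, -1.0], [1.0, -1.0, 0.0]])
        model = MetabolicModel(
            metabolite_ids=["A", "B"],
            reaction_ids=["Rab", "Rba", "Rdrain"],
            S=S,
            lb=np.zeros(3),
            ub=np.full(3, 10.0),
            c=np.zeros(3),
        )
        sub = build_cluster_submodel(model, [0, 1])
        assert sub.n_artificial == 1
        assert sub.artificial_metabolites == [0]

    def test_full_rank_cluster_flagged_passthrough(self):
        # two independent irreversible conversions, no cycle: r_k = 0
        S = np.array([[-1.0, 0.0], [1.0, -1.0], [0.0, 1.0]])
        model = MetabolicModel(
            metabolite_ids=["A", "B", "C"],
            reaction_ids=["R1", "R2"],
            S=S,
            lb=np.zeros(2),
            ub=np.full(2, 10.0),
            c=np.zeros(2),
        )
        sub = build_cluster_submodel(model, [0, 1])
        assert sub.n_artificial == 0
        assert sub.r_k == 0


class TestSparsifyNullspace:
    def test_zeta_default(self):
        assert ZETA_DEFAULT == 1e-3

    def test_three_cycle_basis_is_all_ones(self):
        sub = build_cluster_submodel(toy_cycle_model(), [0, 1, 2])
        basis = sparsify_nullspace(sub, seed=17)
        assert basis.r_k == 1
        col = basis.N[:, 0]
        np.testing.assert_allclose(col / col[0], np.ones(3), atol=1e-9)

    def test_two_independent_pairs_split_supports(self):
        S = np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]])
        model = MetabolicModel(
            metabolite_ids=["A", "B"],
            reaction_ids=["R1", "R2", "R3", "R4"],
            S=S,
            lb=np.full(4, -10.0),
            ub=np.full(4, 10.0),
            c=np.zeros(4),
        )
        sub = build_cluster_submodel(model, [0, 1, 2, 3])
        basis = sparsify_nullspace(sub, seed=17)
        supports = sorted(tuple(s) for s in basis.support)
        assert supports == [(0, 1), (2, 3)]

    def test_steady_state_residual_tiny(self, two_cycle_network):
        model, truth = two_cycle_network
        for members in truth["clusters"]:
            sub = build_cluster_submodel(model, members)
            basis = sparsify_nullspace(sub, seed=17)
            assert np.abs(sub.S_aug @ basis.N).max() < 1e-9
            assert np.linalg.matrix_rank(basis.N) == basis.r_k

    @pytest.mark.parametrize("seed", range(4))
    def test_supports_match_brute_force_minimal_basis(self, seed):
        """Column support sizes equal the exhaustive sparsest-basis search."""
        rng = np.random.default_rng(seed)
        # random wide matrix with a multi-dimensional null space
        m = int(rng.integers(2, 4))
        l = int(rng.integers(m + 2, m + 5))
        S = np.zeros((m, l))
        for j in range(l):
            i = int(rng.integers(0, m))
            S[i, j] = rng.choice([-1.0, 1.0])
        lb = np.full(l, -10.0)
        ub = np.full(l, 10.0)
        model = MetabolicModel(
            metabolite_ids=[f"M{i}" for i in range(m)],
            reaction_ids=[f"R{j}" for j in range(l)],
            S=S,
            lb=lb,
            ub=ub,
            c=np.zeros(l),
        )
        sub = build_cluster_submodel(model, list(range(l)))
        if sub.r_k == 0 or sub.r_k > 6:
            pytest.skip("degenerate draw")
        basis = sparsify_nullspace(sub, seed=seed)
        sizes = sorted(len(s) for s in basis.support)
        oracle = minimal_support_basis_sizes(
            sub.S_aug, sub.lb, sub.ub, sub.r_k, len(sub.cluster), seed
        )
        assert sizes == oracle


class TestAssembly:
    def test_lbr_bound_intersection(self):
        lo, hi = _lbr_bounds(
            np.array([1.0, 1.0, 1.0]), np.zeros(3), np.array([10.0, 5.0, 8.0])
        )
        assert (lo, hi) == (0.0, 5.0)

    def test_negative_coefficient_swaps_bounds(self):
        lo, hi = _lbr_bounds(np.array([-1.0]), np.array([0.0]), np.array([10.0]))
        assert (lo, hi) == (-10.0, 0.0)

    def test_empty_interval_raises(self):
        # element bounds admit no common LBR flux through the (1,1,1) basis
        from decrem.slb import SparseBasis

        model = toy_cycle_model()
        model.lb[0] = 2.0   # R1 must run >= 2
        model.ub[1] = 1.0   # R2 cannot exceed 1
        basis = SparseBasis(
            cluster=[0, 1, 2],
            N=np.ones((3, 1)),
            N_star=np.ones((3, 1)),
            support=[[0, 1, 2]],
        )
        with pytest.raises(AssemblyError):
            assemble_decoupled_model(model, [basis])

    def test_column_count_invariant(self, two_cycle_network):
        model, truth = two_cycle_network
        bases = [
            sparsify_nullspace(build_cluster_submodel(model, members), seed=17)
            for members in truth["clusters"]
        ]
        dm = assemble_decoupled_model(model, bases)
        assert dm.n_columns == dm.n_nc + sum(b.r_k for b in bases)
        covered = {e for b in bases for e in b.cluster}
        assert covered.isdisjoint(dm.nc_index)
        assert covered | set(dm.nc_index) == set(range(model.n_reactions))


class TestRecovery:
    def build_decoupled(self):
        model = fed_cycle_model()
        sub = build_cluster_submodel(model, [1, 2, 3])
        basis = sparsify_nullspace(sub, seed=17)
        return model, assemble_decoupled_model(model, [basis])

    def test_zero_maps_to_zero(self):
        _, dm = self.build_decoupled()
        np.testing.assert_array_equal(
            recover_element_fluxes(np.zeros(dm.n_columns), dm), np.zeros(5)
        )

    def test_scalar_multiple_on_cycle_basis(self):
        model = toy_cycle_model()
        sub = build_cluster_submodel(model, [0, 1, 2])
        basis = sparsify_nullspace(sub, seed=17)
        dm = assemble_decoupled_model(model, [basis])
        assert dm.n_lbr == 1 and dm.n_nc == 0
        v = recover_element_fluxes(np.array([2.0]), dm)
        np.testing.assert_allclose(v, np.full(3, 2.0), atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        _, dm = self.build_decoupled()
        with pytest.raises(ValueError):
            recover_element_fluxes(np.zeros(dm.n_columns + 1), dm)

    def test_recovered_solution_in_original_nullspace(self):
        """Optimal decoupled fluxes map into null(S) of the original model."""
        model, dm = self.build_decoupled()
        sol = solve_decrem_fba(dm)
        assert sol.optimal
        resid = model.S @ sol.element_flux
        assert np.abs(resid).max() < 1e-6
        # cross-check with an SVD projection onto null(S)
        from scipy.linalg import null_space

        N0 = null_space(model.S)
        projected = N0 @ (N0.T @ sol.element_flux)
        np.testing.assert_allclose(projected, sol.element_flux, atol=1e-6)
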