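"""Polychoric estimation: thresholds, cell probabilities, rho recovery,
PSD repair."""

import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import multivariate_normal

from symptomnet.data import Item, ItemResponseMatrix
from symptomnet.errors import DegenerateItemError, EstimationError
from symptomnet.polychoric import (bivariate_rectangle_prob, bvn_cdf,
                                   contingency_table, estimate_thresholds,
                                   nearest_psd_repair, polychoric_matrix,
                                   polychoric_rho)
from symptomnet.simulate import (ItemModel, PTS_THRESHOLDS, PTG_THRESHOLDS,
                                 preset_items, sample_ordinal)


class TestThresholds:
    def test_median_split_gives_zero(self):
        assert estimate_thresholds([50, 50]) == pytest.approx([0.0])

    def test_inverse_normal_of_cumulative_proportion(self):
        # Phi(1.0) ~ 0.8413
        cuts = estimate_thresholds([841, 159])
        assert cuts[0] == pytest.approx(1.0, abs=0.01)

    def test_uniform_four_categories_antisymmetric(self):
        cuts = estimate_thresholds([25, 25, 25, 25])
        assert cuts == pytest.approx([ndtri(0.25), 0.0, ndtri(0.75)])
        assert cuts[0] == pytest.approx(-cuts[2])

    def test_single_category_degenerate(self):
        with pytest.raises(DegenerateItemError):
            estimate_thresholds([0, 120, 0])

    def test_empty_extreme_categories_give_infinite_cuts(self):
        cuts = estimate_thresholds([0, 60, 40, 0])
        assert cuts[0] == -np.inf
        assert cuts[-1] == np.inf

    def test_interior_empty_category_breaks_tie_with_warning(self):
        with pytest.warns(UserWarning, match="interior empty"):
            cuts = estimate_thresholds([30, 0, 70])
        assert cuts[1] > cuts[0]


class TestRectangleProb:
    def test_independence_orthant(self):
        assert bivariate_rectangle_prob(0.0, -np.inf, 0, -np.inf, 0) \
            == pytest.approx(0.25)

    def test_independence_factorizes(self):
        from scipy.special import ndtr
        p = bivariate_rectangle_prob(0.0, -1.0, 0.5, -0.3, 2.0)
        p1 = ndtr(0.5) - ndtr(-1.0)
        p2 = ndtr(2.0) - ndtr(-0.3)
        assert p == pytest.approx(p1 * p2, abs=1e-12)

    def test_arcsine_orthant_formula(self):
        expected = 0.25 + np.arcsin(0.5) / (2 * np.pi)
        assert bivariate_rectangle_prob(0.5, -np.inf, 0, -np.inf, 0) \
            == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("rho", [-0.97, -0.5, 0.3, 0.8, 0.97])
    def test_cdf_matches_scipy_genz(self, rho):
        rng = np.random.default_rng(4)
        x, y = rng.uniform(-2.5, 2.5, (2, 10))
        ref = multivariate_normal(
            mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf(
            np.stack([x, y], axis=1))
        assert np.max(np.abs(bvn_cdf(x, y, rho) - ref)) < 1e-7

    def test_rho_at_one_rejected(self):
        with pytest.raises(EstimationError):
            bivariate_rectangle_prob(1.0, -1, 1, -1, 1)


def _simulate_pair(rho, n, seed, th1=PTS_THRESHOLDS, th2=PTG_THRESHOLDS):
    items = [ItemModel("A", "PTS", len(th1) + 1, th1),
             ItemModel("B", "PTG", len(th2) + 1, th2)]
    cov = np.array([[1.0, rho], [rho, 1.0]])
    data = sample_ordinal(cov, items, n, seed=seed)
    table, _ = contingency_table(data.values[:, 0], data.values[:, 1],
                                 len(th1) + 1, len(th2) + 1)
    c1 = np.bincount(data.values[:, 0], minlength=len(th1) + 1)
    c2 = np.bincount(data.values[:, 1], minlength=len(th2) + 1)
    return table, estimate_thresholds(c1), estimate_thresholds(c2)


class TestPolychoricRho:
    def test_independent_items_estimate_near_zero(self):
        table, t1, t2 = _simulate_pair(0.0, 10_000, seed=3)
        assert abs(polychoric_rho(table, t1, t2)) < 0.05

    def test_latent_half_recovered(self):
        table, t1, t2 = _simulate_pair(0.5, 10_000, seed=7)
        assert polychoric_rho(table, t1, t2) == pytest.approx(0.5, abs=0.05)

    def test_perfectly_concordant_table_clamps_at_boundary(self):
        table = np.array([[50.0, 0.0], [0.0, 50.0]])
        th = np.array([0.0])
        assert polychoric_rho(table, th, th) == pytest.approx(0.999)

    def test_row_column_symmetry(self):
        table, t1, t2 = _simulate_pair(0.4, 2000, seed=9)
        r1 = polychoric_rho(table, t1, t2)
        r2 = polychoric_rho(table.T, t2, t1)
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_optimum_beats_grid(self):
        """Returned rho has log-likelihood >= 21 grid points (optimizer
        sanity)."""
        from symptomnet.polychoric import _neg_loglik
        table, t1, t2 = _simulate_pair(0.3, 1500, seed=2)
        rho = polychoric_rho(table, t1, t2)
        best = _neg_loglik(rho, table, t1, t2)
        for g in np.linspace(-0.99, 0.99, 21):
            assert best <= _neg_loglik(g, table, t1, t2) + 1e-8

    @pytest.mark.parametrize("rho", [-0.6, -0.3, 0.0, 0.3, 0.6])
    def test_recovery_bias_and_rmse(self, rho):
        ests = []
        for rep in range(8):
            table, t1, t2 = _simulate_pair(rho, 10_000, seed=100 * rep + 11)
            ests.append(polychoric_rho(table, t1, t2))
        ests = np.array(ests)
        assert abs(ests.mean() - rho) < 0.02
        assert np.sqrt(((ests - rho) ** 2).mean()) < 0.05


class TestPolychoricMatrix:
    def test_identity_covariance_gives_near_zero_offdiagonals(self):
        data = sample_ordinal(np.eye(16), preset_items(), 5000, seed=13)
        est = polychoric_matrix(data)
        off = est.matrix[~np.eye(16, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_duplicated_column_hits_boundary_and_flags_repair(self):
        items = preset_items()[:3]
        base = sample_ordinal(np.eye(3), items, 400, seed=5)
        values = base.values.copy()
        values[:, 2] = values[:, 1]
        dup = ItemResponseMatrix(
            values, [items[0].as_item(), items[1].as_item(),
                     Item("PTS3", "PTS", items[1].n_categories)])
        est = polychoric_matrix(dup)
        assert est.repaired
        assert any({"PTS2", "PTS3"} == set(pair)
                   for pair in est.boundary_pairs)

    def test_type_invariants_on_preset(self, preset):
        _, _, data = preset
        est = polychoric_matrix(data)
        assert np.allclose(est.matrix, est.matrix.T)
        assert np.allclose(np.diag(est.matrix), 1.0)
        assert np.all(np.abs(est.matrix) <= 1.0)
        assert np.linalg.eigvalsh(est.matrix)[0] >= -1e-8

    def test_degenerate_item_error_names_item(self):
        items = [Item("A", "PTS", 3), Item("B", "PTS", 3)]
        values = np.column_stack([np.ones(50, dtype=np.int64),
                                  np.arange(50, dtype=np.int64) % 3])
        with pytest.raises(DegenerateItemError, match="'A'"):
            polychoric_matrix(ItemResponseMatrix(values, items))

    def test_pairwise_deletion_records_pair_n(self):
        from symptomnet.data import MISSING
        items = preset_items()[:3]
        data = sample_ordinal(np.eye(3), items, 300, seed=1)
        values = data.values.copy()
        values[:30, 0] = MISSING
        est = polychoric_matrix(ItemResponseMatrix(
            values, [it.as_item() for it in items]))
        assert est.pair_n[0, 1] == 270
        assert est.pair_n[1, 2] == 300
        assert est.n_effective == 270


class TestPsdRepair:
    def test_psd_input_unchanged(self, random_corr):
        S = random_corr(6, 3)
        assert np.max(np.abs(nearest_psd_repair(S) - S)) < 1e-12

    def test_indefinite_input_repaired(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 0.9
        A[0, 2] = A[2, 0] = 0.9
        A[1, 2] = A[2, 1] = -0.9
        assert np.linalg.eigvalsh(A)[0] < 0
        R = nearest_psd_repair(A)
        assert np.linalg.eigvalsh(R)[0] >= -1e-12
        assert np.allclose(np.diag(R), 1.0)
        assert np.all(np.abs(R) <= 1.0 + 1e-12)

    def test_identity_fixed_point(self):
        assert np.array_equal(nearest_psd_repair(np.eye(4)), np.eye(4))
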