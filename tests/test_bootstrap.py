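"""Bootstrap procedures: determinism, CIs, CS rule, difference tests."""

import warnings

import numpy as np
import pytest

from symptomnet.bootstrap import (BootstrapRun, case_dropping_bootstrap,
                                  cs_coefficient, difference_tests, edge_ci,
                                  ei_stability_table,
                                  nonparametric_bootstrap)
from symptomnet.centrality import expected_influence
from symptomnet.data import Item, ItemResponseMatrix
from symptomnet.errors import ResamplingError
from symptomnet.glasso import estimate_network
from symptomnet.simulate import default_study_preset

N_LAMBDA = 30  # reduced penalty grid keeps replicate loops fast in tests


@pytest.fixture(scope="module")
def small_run():
    _, _, data = default_study_preset(1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return nonparametric_bootstrap(data, B=40, seed=11,
                                       n_lambda=N_LAMBDA)


def _fake_run(edge_weights, ei, kind="nonparametric", drop=None):
    edge_weights = np.asarray(edge_weights, dtype=float)
    ei = np.asarray(ei, dtype=float)
    p = ei.shape[1]
    labels = [f"n{i}" for i in range(p)]
    iu = np.triu_indices(p, k=1)
    pairs = [(labels[i], labels[j]) for i, j in zip(*iu)]
    return BootstrapRun(kind, edge_weights.shape[0], 0, edge_weights, ei,
                        0, labels, pairs, drop_proportion=drop,
                        feasible=True)


class TestNonparametric:
    def test_single_replicate_reproducible(self):
        _, _, data = default_study_preset(1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = nonparametric_bootstrap(data, B=1, seed=5,
                                        n_lambda=N_LAMBDA)
            b = nonparametric_bootstrap(data, B=1, seed=5,
                                        n_lambda=N_LAMBDA)
        assert np.array_equal(a.edge_weights, b.edge_weights)
        assert np.array_equal(a.ei, b.ei)

    def test_constant_column_aborts_with_stage_error(self):
        items = [Item("A", "PTS", 3), Item("B", "PTG", 3)]
        values = np.column_stack([
            np.ones(60, dtype=np.int64),
            np.arange(60, dtype=np.int64) % 3])
        data = ItemResponseMatrix(values, items)
        with pytest.raises(ResamplingError):
            nonparametric_bootstrap(data, B=5, seed=0, n_lambda=10)

    def test_worker_count_does_not_change_results(self):
        _, _, data = default_study_preset(1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            serial = nonparametric_bootstrap(data, B=6, seed=3,
                                             n_lambda=N_LAMBDA, n_jobs=1)
            parallel = nonparametric_bootstrap(data, B=6, seed=3,
                                               n_lambda=N_LAMBDA, n_jobs=2)
        assert np.array_equal(serial.edge_weights, parallel.edge_weights)


class TestEdgeCi:
    def test_identical_replicates_zero_width(self):
        x = np.tile(np.array([[0.1, 0.0, -0.2]]), (20, 1))
        run = _fake_run(x, np.zeros((20, 3)))
        ci = edge_ci(run)
        assert np.array_equal(ci["lo"], ci["hi"])

    def test_percentiles_match_direct_computation(self):
        vals = np.linspace(0.1, 1.0, 10)[:, None]
        run = _fake_run(np.repeat(vals, 3, axis=1), np.zeros((10, 3)))
        ci = edge_ci(run)
        assert ci["lo"].iloc[0] == pytest.approx(
            np.quantile(vals.ravel(), 0.025))
        assert ci["hi"].iloc[0] == pytest.approx(
            np.quantile(vals.ravel(), 0.975))

    def test_invariant_to_replicate_order(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 3))
        run1 = _fake_run(x, np.zeros((50, 3)))
        run2 = _fake_run(x[::-1], np.zeros((50, 3)))
        assert np.array_equal(edge_ci(run1)[["lo", "hi"]],
                              edge_ci(run2)[["lo", "hi"]])

    def test_case_drop_run_rejected(self):
        run = _fake_run(np.zeros((5, 3)), np.zeros((5, 3)),
                        kind="case_drop", drop=0.1)
        with pytest.raises(ResamplingError):
            edge_ci(run)

    def test_point_estimates_inside_intervals(self, small_run, preset):
        _, _, data = preset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = estimate_network(data, n_lambda=N_LAMBDA)
        ci = edge_ci(small_run, point=net.edge_vector())
        inside = ((ci["lo"] <= ci["point"] + 1e-12)
                  & (ci["point"] <= ci["hi"] + 1e-12))
        assert inside.mean() >= 0.95


class TestCaseDrop:
    def test_zero_drop_rejected(self):
        _, _, data = default_study_preset(1)
        with pytest.raises(ResamplingError):
            case_dropping_bootstrap(data, drop_grid=(0.0, 0.5),
                                    B_per_level=2, seed=0)

    def test_subset_sizes_follow_grid(self):
        _, _, data = default_study_preset(1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            runs = case_dropping_bootstrap(data, drop_grid=(0.3, 0.7),
                                           B_per_level=2, seed=4,
                                           n_lambda=N_LAMBDA)
        assert runs[0].subset_size == round(0.7 * 406)
        assert runs[1].subset_size == round(0.3 * 406) == 122
        assert all(r.feasible for r in runs)

    def test_too_small_subset_marked_infeasible(self):
        _, _, data = default_study_preset(1, n=40)
        runs = case_dropping_bootstrap(data, drop_grid=(0.9,),
                                       B_per_level=2, seed=0,
                                       n_lambda=10)
        assert not runs[0].feasible
        assert runs[0].B_ok == 0


class TestCsCoefficient:
    def _runs_from_correlation_targets(self, grid, cor_by_level, B=40):
        """Hand-built case-drop runs whose replicate EI vectors correlate
        with the original at exactly the requested level pattern."""
        original = np.arange(6, dtype=float)
        runs = []
        for q, good_frac in zip(grid, cor_by_level):
            eis = []
            n_good = int(round(good_frac * B))
            for r in range(B):
                if r < n_good:
                    eis.append(original.copy())          # correlation 1
                else:
                    eis.append(original[::-1].copy())    # correlation -1
            eis = np.array(eis)
            run = _fake_run(np.zeros((B, 15)), eis, kind="case_drop",
                            drop=q)
            runs.append(run)
        return runs, original

    def test_perfect_stability_gives_max_grid_value(self):
        grid = (0.1, 0.25, 0.5, 0.75)
        runs, orig = self._runs_from_correlation_targets(
            grid, [1.0, 1.0, 1.0, 1.0])
        assert cs_coefficient(runs, orig) == 0.75

    def test_no_stability_gives_zero(self):
        grid = (0.1, 0.25)
        runs, orig = self._runs_from_correlation_targets(grid, [0.0, 0.0])
        assert cs_coefficient(runs, orig) == 0.0

    def test_boundary_level_rule(self):
        """Level 0.25 passes (>=95% replicates correlate), 0.30 fails ->
        CS = 0.25 by definition."""
        grid = (0.1, 0.25, 0.3, 0.5)
        runs, orig = self._runs_from_correlation_targets(
            grid, [1.0, 0.95, 0.90, 1.0])
        assert cs_coefficient(runs, orig) == 0.25

    def test_lowering_threshold_cannot_decrease_cs(self):
        rng = np.random.default_rng(8)
        grid = (0.1, 0.3, 0.5)
        original = np.arange(6, dtype=float)
        runs = []
        for q in grid:
            eis = original + rng.normal(0, q * 6, size=(30, 6))
            runs.append(_fake_run(np.zeros((30, 15)), eis,
                                  kind="case_drop", drop=q))
        cs_strict = cs_coefficient(runs, original, cor_threshold=0.9)
        cs_loose = cs_coefficient(runs, original, cor_threshold=0.5)
        assert cs_loose >= cs_strict

    def test_zero_variance_original_rejected(self):
        runs, _ = self._runs_from_correlation_targets((0.1,), [1.0])
        with pytest.raises(ResamplingError):
            cs_coefficient(runs, np.ones(6))


class TestDifferenceTests:
    def test_hand_built_three_edge_run(self):
        """Three edges with replicate values built so exactly one pair
        differs: percentile rule evaluated by hand."""
        B = 200
        rng = np.random.default_rng(1)
        e1 = rng.normal(0.10, 0.005, B)   # tight around 0.10
        e2 = rng.normal(0.50, 0.005, B)   # tight around 0.50 -> differs
        e3 = rng.normal(0.12, 0.200, B)   # wide -> overlaps both
        x = np.column_stack([e1, e2, e3])
        run = _fake_run(x, np.zeros((B, 3)))
        edge_sig, _ = difference_tests(run, alpha=0.05)
        # hand evaluation of the percentile rule: only the two tight,
        # well-separated edges differ; the wide edge overlaps both
        for (i, j), expect in {(0, 1): True, (0, 2): False,
                               (1, 2): False}.items():
            d = x[:, i] - x[:, j]
            lo, hi = np.quantile(d, [0.025, 0.975])
            assert expect == ((lo > 0) | (hi < 0))
            assert edge_sig[i, j] == expect

    def test_self_comparison_never_significant(self, small_run):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            edge_sig, ei_sig = difference_tests(small_run)
        assert not edge_sig.diagonal().any()
        assert not ei_sig.diagonal().any()

    def test_symmetry(self, small_run):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            edge_sig, ei_sig = difference_tests(small_run)
        assert np.array_equal(edge_sig, edge_sig.T)
        assert np.array_equal(ei_sig, ei_sig.T)

    def test_disjoint_ranges_significant(self):
        x = np.column_stack([np.linspace(0.0, 0.1, 50),
                             np.linspace(0.5, 0.6, 50)])
        run = _fake_run(x, np.zeros((50, 2)))
        edge_sig, _ = difference_tests(run)
        assert edge_sig[0, 1]

    def test_too_few_replicates_for_alpha_rejected(self):
        run = _fake_run(np.zeros((10, 3)), np.zeros((10, 3)))
        with pytest.raises(ResamplingError):
            difference_tests(run, alpha=0.05)


class TestStabilityTable:
    def test_nan_for_zero_variance_replicates(self):
        original = np.arange(4, dtype=float)
        eis = np.vstack([original, np.ones(4)])
        run = _fake_run(np.zeros((2, 6)), eis, kind="case_drop", drop=0.1)
        table = ei_stability_table([run], original)
        assert table["correlation"].iloc[0] == pytest.approx(1.0)
        assert np.isnan(table["correlation"].iloc[1])


def test_ci_width_shrinks_with_sample_size():
    """Mean bootstrap edge-CI width at n=200 exceeds that at n=2000."""
    widths = {}
    for n in (200, 2000):
        _, _, data = default_study_preset(1, n=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = nonparametric_bootstrap(data, B=40, seed=21,
                                          n_lambda=N_LAMBDA)
            ci = edge_ci(run)
        widths[n] = float((ci["hi"] - ci["lo"]).mean())
    assert widths[200] > widths[2000]
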