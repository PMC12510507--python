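"""Fuzzy-AHP engine: aggregation, consistency, extent analysis, composition."""

import numpy as np
import pytest

from fmeaplus import (
    CrispComparisonMatrix,
    FuzzyAhpWeights,
    FuzzyComparisonMatrix,
    WeightVector,
    aggregate_panel,
    crisp_consistency,
    extent_weights,
    fuzzy_consistency,
    geometric_mean_weights,
    global_weights,
    screen_experts,
)
from fmeaplus.consistency import principal_eigenvalue
from fmeaplus.fahp import ZeroPossibilityWarning
from fmeaplus.synthesis import PanelSpec, synth_panel


def tfn_matrix(items, upper):
    return FuzzyComparisonMatrix.from_upper_triangle(items, upper)


def consistent_fuzzy(weights, spread=0.2):
    """Perfectly consistent matrix: modal ratios w_i/w_j, symmetric spread."""
    items = tuple(f"c{k}" for k in range(len(weights)))
    upper = {}
    for i in range(len(weights)):
        for j in range(i + 1, len(weights)):
            m = weights[i] / weights[j]
            upper[(items[i], items[j])] = (m / (1 + spread), m, m * (1 + spread))
    return tfn_matrix(items, upper)


class TestMatrixValidation:
    def test_incomplete_upper_triangle_rejected(self):
        with pytest.raises(ValueError, match="missing pairs"):
            FuzzyComparisonMatrix.from_upper_triangle(
                ("a", "b", "c"), {("a", "b"): (1, 2, 3)}
            )

    def test_non_reciprocal_rejected(self):
        arr = np.ones((2, 2, 3))
        arr[0, 1] = (1, 2, 3)
        arr[1, 0] = (1, 2, 3)  # should be (1/3, 1/2, 1)
        with pytest.raises(ValueError, match="reciprocal"):
            FuzzyComparisonMatrix(("a", "b"), arr)

    def test_nonunit_diagonal_rejected(self):
        arr = np.ones((2, 2, 3))
        arr[0, 0] = (2, 2, 2)
        with pytest.raises(ValueError, match="diagonal"):
            FuzzyComparisonMatrix(("a", "b"), arr)

    def test_weight_vector_contract(self):
        with pytest.raises(ValueError):
            WeightVector(("a", "b"), np.array([0.7, 0.7]))
        wv = WeightVector.from_raw(("a", "b"), [3, 1])
        assert wv["a"] == pytest.approx(0.75)


class TestAggregation:
    def test_single_matrix_upper_triangle_unchanged(self):
        m = consistent_fuzzy([0.5, 0.3, 0.2])
        agg = aggregate_panel([m])
        assert np.allclose(agg.values, m.values, atol=1e-12)

    def test_two_expert_cell_geometric_mean(self):
        items = ("a", "b")
        m1 = tfn_matrix(items, {("a", "b"): (1, 2, 3)})
        m2 = tfn_matrix(items, {("a", "b"): (3, 4, 5)})
        agg = aggregate_panel([m1, m2])
        assert tuple(agg.entry("a", "b")) == pytest.approx(
            (np.sqrt(3), np.sqrt(8), np.sqrt(15))
        )

    def test_reciprocal_judgments_cancel(self):
        items = ("a", "b")
        m1 = tfn_matrix(items, {("a", "b"): (2, 2, 2)})
        m2 = tfn_matrix(items, {("a", "b"): (0.5, 0.5, 0.5)})
        agg = aggregate_panel([m1, m2])
        assert tuple(agg.entry("a", "b")) == pytest.approx((1, 1, 1))

    def test_exactly_reciprocal_and_order_invariant(self):
        panel = synth_panel(
            PanelSpec(WeightVector.from_raw(("a", "b", "c"), [5, 3, 2]), 7, seed=3)
        )
        agg1 = aggregate_panel(panel)
        agg2 = aggregate_panel(panel[::-1])
        assert np.allclose(agg1.values, agg2.values)
        v = agg1.values
        for i in range(3):
            for j in range(3):
                assert v[j, i, 0] == pytest.approx(1.0 / v[i, j, 2], rel=1e-12)
                assert v[j, i, 1] == pytest.approx(1.0 / v[i, j, 1], rel=1e-12)

    def test_mismatched_items_rejected(self):
        m1 = consistent_fuzzy([0.6, 0.4])
        m2 = tfn_matrix(("x", "y"), {("x", "y"): (1, 2, 3)})
        with pytest.raises(ValueError, match="item set"):
            aggregate_panel([m1, m2])

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty panel"):
            aggregate_panel([])


class TestCrispConsistency:
    def test_consistent_matrix_zero_cr(self):
        m = CrispComparisonMatrix(
            ("a", "b", "c"), np.array([[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1]])
        )
        rep = crisp_consistency(m, "saaty")
        assert rep.lambda_max == pytest.approx(3.0, abs=1e-9)
        assert rep.cr == pytest.approx(0.0, abs=1e-9)

    def test_cycle_matrix_closed_form(self):
        # 3x3 cycle a12=a23=2, a13=0.5: lambda = 1 + alpha + 1/alpha with
        # alpha = (a12 a23 a31)^(1/3) = 2, giving lambda=3.5, CI=0.25
        m = CrispComparisonMatrix(
            ("a", "b", "c"), np.array([[1, 2, 0.5], [0.5, 1, 2], [2, 0.5, 1]])
        )
        rep = crisp_consistency(m, "saaty")
        assert rep.lambda_max == pytest.approx(3.5, abs=1e-9)
        assert rep.cr == pytest.approx(0.25 / 0.58, abs=1e-6)

    def test_published_middle_matrix_ratio(self):
        m = CrispComparisonMatrix(
            ("severity", "detectability", "occurrence"),
            np.array([[1, 0.980, 1.172], [1.021, 1, 0.837], [0.853, 1.195, 1]]),
        )
        rep = crisp_consistency(m, "gogus_boucher_m")
        assert rep.cr == pytest.approx(0.015, abs=1e-3)

    def test_closed_form_matches_eigen_route(self, rng):
        # random reciprocal 3x3: principal eigenvalue equals 1 + a + 1/a
        for _ in range(20):
            a12, a13, a23 = np.exp(rng.normal(0, 0.5, 3))
            mat = np.array([[1, a12, a13], [1 / a12, 1, a23], [1 / a13, 1 / a23, 1]])
            alpha = (a12 * a23 * (1 / a13)) ** (1 / 3)
            assert principal_eigenvalue(mat) == pytest.approx(
                1 + alpha + 1 / alpha, abs=1e-9
            )

    def test_n2_defined_zero(self):
        m = CrispComparisonMatrix(("a", "b"), np.array([[1, 3], [1 / 3, 1]]))
        assert crisp_consistency(m).cr == 0.0

    def test_unknown_ri_table(self):
        m = CrispComparisonMatrix(("a", "b"), np.array([[1, 2], [0.5, 1]]))
        with pytest.raises(KeyError):
            crisp_consistency(m, "nope")


class TestFuzzyConsistency:
    def test_consistent_matrix_zero_ratios(self):
        fm = consistent_fuzzy([0.5, 0.3, 0.2])
        rep = fuzzy_consistency(fm)
        assert rep.crm == pytest.approx(0.0, abs=1e-9)
        assert rep.crg == pytest.approx(0.0, abs=1e-9)

    def test_published_factor_matrix(self, factor_fm):
        rep = fuzzy_consistency(factor_fm)
        assert rep.crm == pytest.approx(0.015, abs=1e-3)
        assert rep.crg == pytest.approx(0.025, abs=2e-3)

    def test_published_subfactor_matrices(self, subfactor_fms):
        # published ratios: occurrence CRm=0.008/CRg=0.020,
        # severity 0.007/0.016, detectability 0.010/0.025
        expected = {
            "occurrence": (0.008, 0.020),
            "severity": (0.007, 0.016),
            "detectability": (0.010, 0.025),
        }
        for name, (crm, crg) in expected.items():
            rep = fuzzy_consistency(subfactor_fms[name])
            assert rep.crm == pytest.approx(crm, abs=1e-3), name
            assert rep.crg == pytest.approx(crg, abs=2e-3), name


class TestScreening:
    def test_consistent_kept_inconsistent_excluded(self):
        good = consistent_fuzzy([0.5, 0.3, 0.2])
        # cyclic modal judgments a12=a23=a31=2: CRm = 0.25/0.489 >> 0.1
        items = good.items
        bad = tfn_matrix(
            items,
            {
                (items[0], items[1]): (1.8, 2.0, 2.2),
                (items[1], items[2]): (1.8, 2.0, 2.2),
                (items[0], items[2]): (1 / 2.2, 1 / 2.0, 1 / 1.8),
            },
        )
        kept, excluded, reports = screen_experts([good, bad])
        assert kept == [good]
        assert excluded == [bad]
        assert reports[1].max_fuzzy_cr > 0.1


class TestExtentWeights:
    def test_uniform_on_all_ones(self):
        items = ("a", "b", "c")
        fm = tfn_matrix(items, {p: (1, 1, 1) for p in
                                [("a", "b"), ("a", "c"), ("b", "c")]})
        assert extent_weights(fm).weights == pytest.approx([1 / 3] * 3)

    def test_uniform_on_symmetric_fuzzy(self):
        items = ("a", "b", "c", "d")
        upper = {
            (items[i], items[j]): (0.8, 1.0, 1.25)
            for i in range(4)
            for j in range(i + 1, 4)
        }
        fm = tfn_matrix(items, upper)
        assert extent_weights(fm).weights == pytest.approx([0.25] * 4)

    def test_published_tables_reproduced(self, factor_fm, subfactor_fms):
        assert extent_weights(factor_fm).rounded() == {
            "severity": 0.348,
            "detectability": 0.315,
            "occurrence": 0.337,
        }
        assert extent_weights(subfactor_fms["occurrence"]).rounded() == {
            "human reliability": 0.311,
            "reliability": 0.247,
            "incidents learning": 0.211,
            "redundancy": 0.231,
        }
        assert extent_weights(subfactor_fms["severity"]).rounded() == {
            "human injury": 0.337,
            "financial loss": 0.257,
            "operational interruption": 0.206,
            "reputation damage": 0.200,
        }
        assert extent_weights(subfactor_fms["detectability"]).rounded() == {
            "technical inspection": 0.324,
            "employee participation": 0.217,
            "daily/routine inspection": 0.218,
            "permanent maintenance": 0.241,
        }

    def test_label_permutation_equivariance(self, factor_fm):
        base = extent_weights(factor_fm).as_dict()
        perm = extent_weights(factor_fm.permuted(
            ("occurrence", "severity", "detectability")
        )).as_dict()
        for k in base:
            assert perm[k] == pytest.approx(base[k], abs=1e-12)

    def test_crisp_degenerate_refused(self):
        items = ("a", "b")
        fm = tfn_matrix(items, {("a", "b"): (2, 2, 2)})
        with pytest.raises(ValueError, match="degenerates"):
            extent_weights(fm)

    def test_dominated_item_zero_weight_warns(self):
        fm = consistent_fuzzy([0.70, 0.25, 0.05], spread=0.05)
        with pytest.warns(ZeroPossibilityWarning):
            wv = extent_weights(fm)
        assert wv["c2"] == 0.0
        assert wv.weights.sum() == pytest.approx(1.0)

    def test_geometric_mean_alternative(self, factor_fm):
        assert geometric_mean_weights(factor_fm).rounded() == {
            "severity": 0.346,
            "detectability": 0.318,
            "occurrence": 0.336,
        }


class TestGlobalWeights:
    def test_identity_parent(self):
        parent = WeightVector(("f",), np.array([1.0]))
        child = WeightVector(("x", "y"), np.array([0.5, 0.5]))
        gw = global_weights(parent, {"f": child})
        assert gw.as_dict() == {"x": 0.5, "y": 0.5}

    def test_published_leaf_product(self, taxonomy):
        gw = taxonomy.global_weights()
        assert gw["human reliability"] == pytest.approx(0.337 * 0.311, abs=1e-9)
        assert gw["human reliability"] == pytest.approx(0.1048, abs=5e-4)

    def test_twelve_leaves_sum_to_one(self, taxonomy):
        gw = taxonomy.global_weights()
        assert len(gw.items) == 12
        assert gw.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_leaf_passthrough(self):
        parent = WeightVector(("f", "g"), np.array([0.6, 0.4]))
        gw = global_weights(parent, {"f": WeightVector(("x", "y"), np.array([0.5, 0.5]))})
        assert gw["g"] == pytest.approx(0.4)


class TestFuzzyAhpEstimator:
    def test_fit_recovers_true_ranking(self):
        true = WeightVector.from_raw(("a", "b", "c"), [5, 3, 2])
        panel = synth_panel(PanelSpec(true, n_experts=25, seed=11))
        est = FuzzyAhpWeights().fit(panel)
        assert est.weights_.ranking() == ("a", "b", "c")
        assert est.consistency_.max_fuzzy_cr < 0.1
        assert len(est.kept_) + len(est.excluded_) == len(panel)
        assert all(r.max_fuzzy_cr <= 0.1 for m, r in
                   zip(panel, est.expert_reports_) if m in est.kept_)

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = FuzzyAhpWeights(method="geometric_mean", cr_threshold=0.2)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        with pytest.raises(ValueError, match="unknown method"):
            FuzzyAhpWeights(method="bogus").fit([])
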