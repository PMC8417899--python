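import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvstim import evaluate as ev


def scalar_linear(n, sc):
    cost_min = sc / sum(range(1, n))
    return [0.0] + [(i - 1) * cost_min for i in range(2, n + 1)]


def scalar_inverse_square(n, sc):
    raw = [1 - 1 / i**2 for i in range(1, n + 1)]
    return [sc * r / sum(raw) for r in raw]


def scalar_gompertz(n, sc, beta, gamma):
    import math

    g = [math.exp(-beta * math.exp(-gamma * i)) for i in range(1, n + 1)]
    raw = [v - g[0] for v in g]
    return [sc * r / sum(raw) for r in raw]


class TestSubcostWeights:
    def test_linear_n3(self):
        w = ev.subcost_weights(3, ev.CostScheme("linear"), 1.0)
        assert np.allclose(w, [0, 1 / 3, 2 / 3], atol=1e-12)

    def test_inverse_square_n3(self):
        w = ev.subcost_weights(3, ev.CostScheme("inverse_square"), 1.0)
        assert np.allclose(w, [0, 27 / 59, 32 / 59], atol=1e-12)

    def test_gompertz_n3_matches_scalar_oracle(self):
        w = ev.subcost_weights(3, ev.CostScheme("gompertz", 1.0, 1.0), 1.0)
        assert np.allclose(w, scalar_gompertz(3, 1.0, 1.0, 1.0), atol=1e-12)
        assert w[1] == pytest.approx(0.4114, abs=5e-4)
        assert w[2] == pytest.approx(0.5886, abs=5e-4)

    @pytest.mark.parametrize("kind", ["linear", "inverse_square", "gompertz"])
    def test_single_wrong_option_gets_whole_budget(self, kind):
        w = ev.subcost_weights(2, ev.CostScheme(kind), 1.0)
        assert np.allclose(w, [0.0, 1.0], atol=1e-12)

    @pytest.mark.parametrize("kind", ["linear", "inverse_square", "gompertz"])
    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8])
    def test_matches_scalar_oracles_and_sums_to_budget(self, kind, n):
        sc = 0.5
        w = ev.subcost_weights(n, ev.CostScheme(kind, beta=2.0, gamma=0.7), sc)
        assert w[0] == 0.0
        assert np.all(np.diff(w) >= 0)
        assert w.sum() == pytest.approx(sc if n > 1 else 0.0, abs=1e-12)
        if n > 1:
            oracle = {
                "linear": scalar_linear(n, sc),
                "inverse_square": scalar_inverse_square(n, sc),
                "gompertz": scalar_gompertz(n, sc, 2.0, 0.7),
            }[kind]
            assert np.allclose(w, oracle, atol=1e-12)

    def test_invalid_budget(self):
        with pytest.raises(ValueError, match="budget"):
            ev.subcost_weights(3, ev.CostScheme("linear"), 0.0)


hierarchies = (
    st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=4)
    .filter(lambda sizes: sum(sizes) >= 2)
    .map(
        lambda sizes: ev.ClassHierarchy(
            [(f"G{g}", [f"G{g}c{i}" for i in range(n)]) for g, n in enumerate(sizes)]
        )
    )
)
schemes = st.sampled_from(["linear", "inverse_square", "gompertz"]).flatmap(
    lambda kind: st.builds(
        ev.CostScheme,
        st.just(kind),
        st.floats(0.2, 5.0),
        st.floats(0.2, 5.0),
        st.floats(0.5, 2.0),
    )
)


class TestBuildCostMatrix:
    def test_two_by_two_linear_example(self, hierarchy_2x2):
        cost = ev.build_cost_matrix(hierarchy_2x2, ev.CostScheme("linear", C=1.0))
        assert np.allclose(cost.costs[0], [0, 0.5, 0.25, 0.25], atol=1e-12)

    def test_single_class_rows_are_weight_permutations(self):
        h = ev.ClassHierarchy({"A": ["a1", "a2", "a3"]})
        cost = ev.build_cost_matrix(h, ev.CostScheme("linear"))
        for row in cost.costs:
            assert sorted(row) == pytest.approx([0, 1 / 3, 2 / 3], abs=1e-12)

    def test_diagonal_zero(self, hierarchy_2x2):
        for kind in ("linear", "inverse_square", "gompertz"):
            cost = ev.build_cost_matrix(hierarchy_2x2, ev.CostScheme(kind))
            assert np.all(np.diag(cost.costs) == 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(h=hierarchies, scheme=schemes)
    def test_budget_conservation_property(self, h, scheme):
        cost = ev.build_cost_matrix(h, scheme)
        assert np.allclose(cost.costs.sum(axis=1), scheme.C, atol=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scheme=schemes)
    def test_within_class_monotone_in_distance(self, scheme):
        h = ev.ClassHierarchy({"A": [f"a{i}" for i in range(5)]})
        cost = ev.build_cost_matrix(h, scheme)
        # from the first subclass, distance equals column index
        row = cost.costs[0]
        assert np.all(np.diff(row) > 0)

    def test_cross_class_cost_uniform(self):
        h = ev.ClassHierarchy({"A": ["a1", "a2"], "B": ["b1", "b2", "b3"]})
        cost = ev.build_cost_matrix(h, ev.CostScheme("gompertz"))
        sc = 1.0 / 2
        assert np.allclose(cost.costs[0, 2:], sc / 3)
        assert np.allclose(cost.costs[2, :2], sc / 2)


class TestConfusionAndBasicMetrics:
    def test_perfect_agreement_diagonal(self):
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        cm = ev.confusion_matrix(labels, labels, ["a", "b", "c"])
        assert np.trace(cm.counts) == 30 and cm.counts.sum() == 30
        acc, per_class, macro = ev.basic_metrics(cm)
        assert acc == 1.0 and macro == 1.0

    def test_label_order_respected(self):
        cm = ev.confusion_matrix(["b", "a"], ["b", "a"], ["a", "b"])
        assert cm.labels == ("a", "b")
        assert cm.counts[0, 0] == 1 and cm.counts[1, 1] == 1

    def test_half_right(self):
        cm = ev.ConfusionMatrix(np.array([[3, 3], [3, 3]]), ("a", "b"))
        acc, _, _ = ev.basic_metrics(cm)
        assert acc == 0.5

    def test_absent_class_warns_f1_zero(self):
        cm = ev.ConfusionMatrix(np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]]),
                                ("a", "b", "c"))
        with pytest.warns(UserWarning, match="'c'"):
            _, per_class, _ = ev.basic_metrics(cm)
        assert per_class["c"] == 0.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ev.confusion_matrix(["a"], ["z"], ["a", "b"])


class TestKappa:
    @pytest.mark.parametrize(
        "counts,value,label",
        [
            ([[10, 0], [0, 10]], 1.0, "almost perfect"),
            ([[6, 2], [2, 6]], 0.5, "moderate"),
            ([[5, 5], [5, 5]], 0.0, "slight"),
        ],
    )
    def test_printed_interval_labels(self, counts, value, label):
        k, lab = ev.cohen_kappa(ev.ConfusionMatrix(np.array(counts), ("a", "b")))
        assert k == pytest.approx(value, abs=1e-12)
        assert lab == label

    def test_negative_reported_below_scale(self):
        k, lab = ev.cohen_kappa(ev.ConfusionMatrix(np.array([[0, 10], [10, 0]]),
                                                   ("a", "b")))
        assert k == -1.0 and lab == "below scale"

    def test_sklearn_oracle(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        for _ in range(10):
            t = rng.integers(0, 3, 50).astype(str)
            p = rng.integers(0, 3, 50).astype(str)
            cm = ev.confusion_matrix(list(t), list(p), ["0", "1", "2"])
            assert ev.cohen_kappa(cm)[0] == pytest.approx(
                cohen_kappa_score(t, p), abs=1e-12
            )


class TestMcc:
    def test_perfect_inverted_random_anchors(self):
        assert ev.mcc(ev.ConfusionMatrix(np.array([[5, 0], [0, 5]]), ("a", "b"))) == 1.0
        assert ev.mcc(ev.ConfusionMatrix(np.array([[0, 5], [5, 0]]), ("a", "b"))) == -1.0
        assert ev.mcc(ev.ConfusionMatrix(np.array([[3, 3], [3, 3]]), ("a", "b"))) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    def test_binary_closed_form_equivalence(self, cells):
        tp, fn, fp, tn = cells
        cm = ev.ConfusionMatrix(np.array([[tp, fn], [fp, tn]]), ("a", "b"))
        if cm.n_instances == 0:
            return
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = ev.mcc(cm)
        expected = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_sklearn_multiclass_oracle(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(1)
        for _ in range(10):
            t = rng.integers(0, 4, 80).astype(str)
            p = rng.integers(0, 4, 80).astype(str)
            cm = ev.confusion_matrix(list(t), list(p), ["0", "1", "2", "3"])
            assert ev.mcc(cm) == pytest.approx(matthews_corrcoef(t, p), abs=1e-12)


class TestCosts:
    def test_diagonal_confusion_costs_nothing(self, hierarchy_2x2):
        cost = ev.build_cost_matrix(hierarchy_2x2, ev.CostScheme("gompertz"))
        cm = ev.ConfusionMatrix(np.diag([5, 5, 5, 5]), hierarchy_2x2.leaf_labels)
        assert ev.total_cost(cm, cost) == 0.0
        assert ev.normalized_cost(cm, cost) == 0.0

    def test_binary_off_diagonal_example(self):
        h = ev.ClassHierarchy({"A": ["a1", "a2"]})
        cost = ev.build_cost_matrix(h, ev.CostScheme("linear"))
        cm = ev.ConfusionMatrix(np.array([[4, 1], [1, 4]]), ("a1", "a2"))
        assert ev.total_cost(cm, cost) == pytest.approx(2.0)
        assert ev.normalized_cost(cm, cost) == pytest.approx(0.2)

    def test_linearity_in_counts(self, hierarchy_2x2):
        cost = ev.build_cost_matrix(hierarchy_2x2, ev.CostScheme("inverse_square"))
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 10, (4, 4))
        cm1 = ev.ConfusionMatrix(counts, hierarchy_2x2.leaf_labels)
        cm2 = ev.ConfusionMatrix(2 * counts, hierarchy_2x2.leaf_labels)
        assert ev.total_cost(cm2, cost) == pytest.approx(2 * ev.total_cost(cm1, cost))

    def test_worst_case_normalizes_to_one(self, hierarchy_2x2):
        cost = ev.build_cost_matrix(hierarchy_2x2, ev.CostScheme("linear"))
        counts = np.zeros((4, 4), dtype=int)
        for i in range(4):
            counts[i, np.argmax(cost.costs[i])] = 7
        cm = ev.ConfusionMatrix(counts, hierarchy_2x2.leaf_labels)
        assert ev.normalized_cost(cm, cost) == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        h=hierarchies,
        scheme=schemes,
        data=st.data(),
    )
    def test_normalized_cost_in_unit_interval(self, h, scheme, data):
        k = h.n_leaves
        counts = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(0, 20), min_size=k, max_size=k),
                    min_size=k, max_size=k,
                )
            )
        )
        if counts.sum() == 0:
            return
        cost = ev.build_cost_matrix(h, scheme)
        cm = ev.ConfusionMatrix(counts, h.leaf_labels)
        assert 0.0 <= ev.normalized_cost(cm, cost) <= 1.0 + 1e-12

    def test_shape_mismatch(self, hierarchy_2x2):
        cost = ev.build_cost_matrix(hierarchy_2x2, ev.CostScheme("linear"))
        cm = ev.ConfusionMatrix(np.eye(2, dtype=int), ("a1", "a2"))
        with pytest.raises(ValueError):
            ev.total_cost(cm, cost)


class TestEvaluationReport:
    def test_report_bundles_everything(self, hierarchy_2x2):
        truth = ["unison"] * 5 + ["fifth"] * 5 + ["tritone"] * 5 + ["minor_second"] * 5
        report = ev.evaluate_report(truth, truth, hierarchy_2x2)
        assert report.accuracy == 1.0
        assert report.mcc == 1.0
        assert report.kappa_label == "almost perfect"
        assert report.normalized_cost == 0.0
        text = report.summary()
        assert "MCC" in text and "normalized cost" in text
        d = report.to_dict()
        assert set(d) >= {"accuracy", "kappa", "mcc", "normalized_cost"}
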