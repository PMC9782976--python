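import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from ekbn.bn_inference import (
    Factor,
    auc_ci,
    cv_auc,
    delong_test,
    fit_cpts,
    predict_outcome,
    roc_auc,
    roc_points,
    to_xmlbif,
)
from ekbn.structure_learning import DAG
from ekbn.synthetic import random_ground_truth, sample_dataset


def _cat(a, cats=(0, 1)):
    return pd.Categorical(a, categories=list(cats))


def enumerate_posterior(net, evidence, outcome, event_level=1):
    """Brute-force full-joint enumeration oracle, independent of the
    variable-elimination path."""
    nodes = list(net.dag.nodes)
    cards = {n: len(net.levels[n]) for n in nodes}
    num = 0.0
    den = 0.0
    for config in itertools.product(*[range(cards[n]) for n in nodes]):
        assign = dict(zip(nodes, config))
        ok = all(assign[k] == net.levels[k].index(v) for k, v in evidence.items())
        if not ok:
            continue
        p = 1.0
        for n in nodes:
            f = net.cpts[n]
            idx = tuple(assign[v] for v in f.variables)
            p *= float(f.values[idx])
        den += p
        if assign[outcome] == net.levels[outcome].index(event_level):
            num += p
    return num / den


class TestFitCpts:
    def test_mle_frequency(self):
        df = pd.DataFrame({"a": _cat([1, 1, 0, 1])})
        net = fit_cpts(DAG(("a",)), df, ess=0.0)
        assert net.cpts["a"].values[1] == pytest.approx(0.75)

    def test_dirichlet_posterior_mean(self):
        """Binary node, counts (3, 1), ess=1: P(1) = (3 + 0.5) / (4 + 1) = 0.7."""
        df = pd.DataFrame({"a": _cat([1, 1, 0, 1])})
        net = fit_cpts(DAG(("a",)), df, ess=1.0)
        assert net.cpts["a"].values[1] == pytest.approx(0.7)

    def test_parentless_nodes_are_marginals(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": _cat(rng.integers(0, 2, 200)),
                           "b": _cat(rng.integers(0, 2, 200))})
        net = fit_cpts(DAG(("a", "b")), df, ess=0.0)
        assert net.cpts["a"].values[1] == pytest.approx(float((df["a"] == 1).mean()))

    def test_rows_sum_to_one_with_parents(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({c: _cat(rng.integers(0, 2, 300)) for c in "abc"})
        net = fit_cpts(DAG(("a", "b", "c"), {("a", "c"), ("b", "c")}), df)
        assert np.allclose(net.cpts["c"].values.sum(axis=-1), 1.0)

    def test_no_zero_probabilities_with_smoothing(self):
        df = pd.DataFrame({"a": _cat([0, 0, 0, 0])})
        net = fit_cpts(DAG(("a",)), df, ess=1.0)
        assert net.cpts["a"].values.min() > 0


class TestPredictOutcome:
    def _collider_net(self):
        # f1 -> o <- f2 with hand-specified CPTs
        dag = DAG(("f1", "f2", "o"), {("f1", "o"), ("f2", "o")})
        p_o = np.array([[[0.9, 0.1], [0.4, 0.6]], [[0.3, 0.7], [0.05, 0.95]]])
        cpts = {
            "f1": Factor(("f1",), np.array([0.6, 0.4])),
            "f2": Factor(("f2",), np.array([0.3, 0.7])),
            "o": Factor(("f1", "f2", "o"), p_o),
        }
        from ekbn.bn_inference import BayesNet
        return BayesNet(dag=dag, cpts=cpts,
                        levels={"f1": [0, 1], "f2": [0, 1], "o": [0, 1]},
                        outcome_name="o")

    def test_direct_cpt_read(self):
        net = self._collider_net()
        assert predict_outcome(net, {"f1": 1, "f2": 0}) == pytest.approx(0.7, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        net = self._collider_net()
        for ev in ({}, {"f1": 0}, {"f2": 1}, {"f1": 1, "f2": 1}):
            assert predict_outcome(net, ev) == pytest.approx(
                enumerate_posterior(net, ev, "o"), abs=1e-12)

    def test_no_evidence_gives_marginal(self):
        net = self._collider_net()
        marg = enumerate_posterior(net, {}, "o")
        assert predict_outcome(net, {}) == pytest.approx(marg, abs=1e-12)

    def test_complement(self):
        net = self._collider_net()
        p1 = predict_outcome(net, {"f1": 1}, event_level=1)
        p0 = predict_outcome(net, {"f1": 1}, event_level=0)
        assert p1 + p0 == pytest.approx(1.0, abs=1e-12)

    def test_outcome_in_evidence_rejected(self):
        net = self._collider_net()
        with pytest.raises(ValueError):
            predict_outcome(net, {"o": 1})

    def test_unseen_level_marginalized(self):
        net = self._collider_net()
        assert predict_outcome(net, {"f1": 99}) == pytest.approx(
            predict_outcome(net, {}), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_networks_match_enumeration(self, seed):
        """Fitted nets on random <= 6-node DAGs: VE equals enumeration to 1e-12."""
        truth = random_ground_truth(6, p_edge=0.4, seed=seed)
        tab = sample_dataset(truth, 400, seed=seed + 50)
        df = tab.with_outcome_column()
        rng = np.random.default_rng(seed)
        net = fit_cpts(truth.dag, df, ess=1.0, outcome_name=tab.outcome_name)
        feats = [n for n in truth.dag.nodes if n != tab.outcome_name]
        for _ in range(3):
            ev = {f: int(rng.integers(0, 2)) for f in
                  rng.choice(feats, size=rng.integers(0, len(feats) + 1), replace=False)}
            assert predict_outcome(net, ev, outcome=tab.outcome_name) == pytest.approx(
                enumerate_posterior(net, ev, tab.outcome_name), abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_hand_counted(self):
        assert roc_auc([0.2, 0.8, 0.4, 0.9], [0, 0, 1, 1]) == 0.75

    def test_negation_symmetry(self):
        rng = np.random.default_rng(2)
        s = rng.random(100)
        y = rng.integers(0, 2, 100)
        assert roc_auc(s, y) == pytest.approx(1 - roc_auc(-s, y))

    def test_matches_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            s = rng.choice([0.1, 0.3, 0.5, 0.7], size=60)  # ties included
            y = rng.integers(0, 2, 60)
            if y.min() == y.max():
                continue
            assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestSerialization:
    def test_xmlbif_well_formed_and_complete(self):
        import xml.etree.ElementTree as ET

        rng = np.random.default_rng(21)
        df = pd.DataFrame({c: _cat(rng.integers(0, 2, 100)) for c in "abc"})
        net = fit_cpts(DAG(("a", "b", "c"), {("a", "c"), ("b", "c")}), df)
        root = ET.fromstring(to_xmlbif(net, "demo"))
        network = root.find("NETWORK")
        assert network.find("NAME").text == "demo"
        assert len(network.findall("VARIABLE")) == 3
        defs = {d.find("FOR").text: d for d in network.findall("DEFINITION")}
        assert [g.text for g in defs["c"].findall("GIVEN")] == ["a", "b"]
        table = list(map(float, defs["c"].find("TABLE").text.split()))
        assert len(table) == 8
        assert sum(table) == pytest.approx(4.0)  # four parent rows, each sums to 1

    def test_roc_points_match_sklearn(self):
        from sklearn.metrics import roc_curve

        rng = np.random.default_rng(22)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        s = rng.choice([0.1, 0.4, 0.6, 0.9], size=80)
        pts = roc_points(s, y)
        fpr, tpr, _ = roc_curve(y, s)
        assert np.allclose(pts["fpr"].to_numpy(), fpr)
        assert np.allclose(pts["tpr"].to_numpy(), tpr)

    def test_roc_points_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([0.1, 0.2], [1, 1])


class TestCvAuc:
    def _table(self, n, seed):
        from conftest import noise_table
        return noise_table(n, 4, 0, 0.3, seed)

    def test_constant_scorer_gives_half(self):
        table = self._table(100, 0)
        ev = cv_auc(table, lambda tr: (lambda X: np.full(len(X), 0.25)),
                    folds=5, repeats=2, seed=0, ci_B=200)
        assert ev.auc == 0.5

    def test_oracle_scorer_matches_analytic_auc(self):
        """A scorer returning the true event probability attains the analytic
        AUC of that score distribution."""
        rng = np.random.default_rng(1)
        n = 2000
        x = rng.integers(0, 2, n)
        p = np.where(x == 1, 0.45, 0.15)
        y = (rng.random(n) < p).astype(np.int8)
        from ekbn.dataset_io import FeatureRole, FeatureTable
        table = FeatureTable(units=[f"u{i}" for i in range(n)], outcome_name="y",
                             outcome=y,
                             features=pd.DataFrame({"x": _cat(x)}),
                             roles={"x": FeatureRole()})
        # analytic AUC of the two-point score distribution
        p1 = float((x[y == 1] == 1).mean())
        p0 = float((x[y == 0] == 1).mean())
        analytic = p1 * (1 - p0) + 0.5 * (p1 * p0 + (1 - p1) * (1 - p0))
        ev = cv_auc(table,
                    lambda tr: (lambda X: np.where(X["x"] == 1, 0.45, 0.15)),
                    folds=5, repeats=2, seed=0, ci_B=200)
        assert ev.auc == pytest.approx(analytic, abs=0.03)

    def test_seed_changes_folds_not_config(self):
        table = self._table(80, 2)
        builder = lambda tr: (lambda X: np.random.default_rng(0).random(len(X)))
        a = cv_auc(table, builder, folds=4, repeats=1, seed=1, ci_B=100)
        b = cv_auc(table, builder, folds=4, repeats=1, seed=2, ci_B=100)
        assert not np.array_equal(a.fold_assignment, b.fold_assignment)
        assert a.config["folds"] == b.config["folds"] == 4

    def test_folds_reduced_when_minority_small(self):
        table = self._table(40, 3)  # 12 events
        ev = cv_auc(table, lambda tr: (lambda X: np.full(len(X), 0.3)),
                    folds=30, repeats=1, seed=0, ci_B=100)
        assert ev.config["folds"] <= 12


class TestAucCi:
    def test_perfect_separation_upper_bound(self):
        scores = np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[np.zeros(50), np.ones(50)]
        lo, hi = auc_ci(scores, labels, seed=0)
        assert hi == 1.0

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(4)

        def width(n):
            y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
            s = np.r_[rng.normal(0, 1, n // 2), rng.normal(1, 1, n // 2)]
            lo, hi = auc_ci(s, y, B=500, seed=0)
            return hi - lo

        assert width(1000) < width(100)

    def test_delong_variance_method(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.zeros(100), np.ones(100)]
        s = np.r_[rng.normal(0, 1, 100), rng.normal(1, 1, 100)]
        lo, hi = auc_ci(s, y, method="delong-variance")
        assert 0 <= lo < hi <= 1
        a = roc_auc(s, y)
        assert lo < a < hi


class TestDelong:
    def test_identical_scores(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.random(100)
        z, p = delong_test((s, y), (s.copy(), y))
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        y = np.r_[np.zeros(60), np.ones(40)]
        a = rng.random(100) + 0.3 * y
        b = rng.random(100) + 0.1 * y
        z1, p1 = delong_test((a, y), (b, y))
        z2, p2 = delong_test((b, y), (a, y))
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_detects_real_difference(self):
        rng = np.random.default_rng(8)
        y = np.r_[np.zeros(300), np.ones(300)]
        good = rng.normal(0, 1, 600) + 1.5 * y
        bad = rng.normal(0, 1, 600)
        z, p = delong_test((good, y), (bad, y))
        assert z > 0 and p < 1e-6

    def test_unit_mismatch_rejected(self):
        y1 = np.array([0, 1, 0, 1])
        y2 = np.array([1, 0, 1, 0])
        with pytest.raises(ValueError, match="share units"):
            delong_test((np.random.rand(4), y1), (np.random.rand(4), y2))
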