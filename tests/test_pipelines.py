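import numpy as np
import pytest

from conftest import noise_table
from ekbn.feature_ranking import CVSpec, IntegratedRanking
from ekbn.pipelines import (
    CVConfig,
    HITLConfig,
    SLConfig,
    candidate_nonekfs,
    evaluate_on,
    hitl_bn_run,
    initial_fraction,
    initial_model,
    pd_bn_fit,
)
from ekbn.synthetic import ScenarioSpec, make_ground_truth, sample_dataset

FAST_CFG = dict(
    rank_cv=CVSpec(folds=5, repeats=1, n_permutations=3),
    cv=CVConfig(folds=5, repeats=2, ci_B=100),
    sl=SLConfig(R=20, cv_R=1),
)


@pytest.fixture(scope="module")
def medium_truth():
    spec = ScenarioSpec(n_units=300, prevalence=0.3, n_mb=4, n_redundant=2,
                        n_noise=6, n_ekf=6, seed=3)
    return make_ground_truth(spec)


class TestInitialFraction:
    def test_direct_substitution(self):
        assert initial_fraction(100, 10) == 10.0

    def test_study_sized_window(self):
        assert initial_fraction(69, 10) == pytest.approx(14.4927536, abs=1e-6)

    def test_boundary(self):
        assert initial_fraction(7, 7) == 100.0

    def test_d_exceeds_n(self):
        with pytest.raises(ValueError):
            initial_fraction(5, 6)
        with pytest.raises(ValueError):
            initial_fraction(5, 0)


class TestPdBn:
    def test_null_outcome_prior_predictor(self):
        """Outcome independent of everything: empty blanket, AUC near 0.5."""
        table = noise_table(120, 10, 0, 0.3, seed=0)
        net, ev = pd_bn_fit(table, sl_config=SLConfig(R=10, cv_R=1),
                            cv_config=CVConfig(folds=5, repeats=1, ci_B=100), seed=0)
        assert net is None
        assert abs(ev.auc - 0.5) < 0.15

    def test_recovers_most_of_true_blanket(self, medium_truth):
        hits = 0
        seeds = 5
        for seed in range(seeds):
            tab = sample_dataset(medium_truth, 2000, seed=seed)
            net, _ = pd_bn_fit(tab, sl_config=SLConfig(R=10, cv_R=1),
                               cv_config=CVConfig(folds=5, repeats=1, ci_B=100),
                               seed=seed)
            found = set(net.dag.nodes) & set(medium_truth.true_mb)
            hits += len(found) >= 3
        assert hits >= 0.8 * seeds

    def test_determinism(self, medium_truth):
        tab = sample_dataset(medium_truth, 300, seed=9)
        kw = dict(sl_config=SLConfig(R=15, cv_R=1),
                  cv_config=CVConfig(folds=5, repeats=1, ci_B=100), seed=4)
        net1, ev1 = pd_bn_fit(tab, **kw)
        net2, ev2 = pd_bn_fit(tab, **kw)
        assert net1.dag == net2.dag
        assert ev1.auc == ev2.auc
        assert np.array_equal(ev1.scores, ev2.scores)


@pytest.fixture(scope="module")
def hitl_run(medium_truth):
    tab = sample_dataset(medium_truth, 300, seed=5)
    cfg = HITLConfig(seed=5, **FAST_CFG)
    return medium_truth, tab, hitl_bn_run(tab, cfg)


class TestHitl:
    def test_requires_ekfs(self):
        table = noise_table(80, 6, 0, 0.3, seed=1)
        with pytest.raises(ValueError, match="expert-knowledge"):
            hitl_bn_run(table, HITLConfig(seed=0, **FAST_CFG))

    def test_trace_replay_bit_identical(self, medium_truth):
        tab = sample_dataset(medium_truth, 300, seed=6)
        cfg = HITLConfig(seed=7, **FAST_CFG)
        a = hitl_bn_run(tab, cfg).to_json()
        b = hitl_bn_run(tab, cfg).to_json()
        assert a == b

    def test_accepted_aucs_strictly_increase(self, hitl_run):
        _, _, trace = hitl_run
        aucs = [e["auc"] for e in trace.entries if e["accepted"]]
        eps = trace.config.epsilon
        assert all(b > a + eps for a, b in zip(aucs, aucs[1:]))

    def test_final_eval_matches_last_accepted(self, hitl_run):
        _, _, trace = hitl_run
        accepted = [e for e in trace.entries if e["accepted"]]
        assert trace.final.eval.auc == accepted[-1]["auc"]
        assert sorted(trace.final.selected) == sorted(
            accepted[-1]["selected_after_elimination"])

    def test_target_auc_zero_stops_after_initial(self, medium_truth):
        tab = sample_dataset(medium_truth, 300, seed=8)
        cfg = HITLConfig(seed=8, target_auc=0.0, **FAST_CFG)
        trace = hitl_bn_run(tab, cfg)
        assert len(trace.entries) == 1  # the initial model only

    def test_infinite_epsilon_freezes_model(self, medium_truth):
        tab = sample_dataset(medium_truth, 300, seed=9)
        cfg = HITLConfig(seed=9, epsilon=float("inf"), **FAST_CFG)
        trace = hitl_bn_run(tab, cfg)
        assert all(not e["accepted"] for e in trace.entries[1:])
        assert sorted(trace.final.selected) == sorted(
            trace.entries[0]["selected_after_elimination"])

    def test_excluded_ekf_skipped(self, medium_truth):
        tab = sample_dataset(medium_truth, 300, seed=10)
        ekf = tab.ekf_names()[0]
        cfg = HITLConfig(seed=10, exclude=(ekf,), **FAST_CFG)
        trace = hitl_bn_run(tab, cfg)
        assert ekf not in trace.final.ekf_sequence
        assert all(e["ekf"] != ekf for e in trace.entries)

    def test_human_decider_can_skip(self, medium_truth):
        tab = sample_dataset(medium_truth, 300, seed=11)
        cfg = HITLConfig(seed=11, **FAST_CFG)
        trace = hitl_bn_run(tab, cfg, decide=lambda info: False)
        assert all(e.get("human_skip") for e in trace.entries[1:])

    def test_degenerate_ekfs_auc_near_half(self):
        """All EKFs independent of the outcome: held-out AUC in 0.5 +/- 0.1."""
        aucs = []
        for seed in range(4):
            train = noise_table(81, 12, 6, 0.28, seed=seed)
            test = noise_table(400, 12, 6, 0.28, seed=1000 + seed)
            trace = hitl_bn_run(train, HITLConfig(seed=seed, **FAST_CFG))
            _, auc = evaluate_on(trace.final.net, test)
            aucs.append(auc)
        assert all(abs(a - 0.5) <= 0.1 for a in aucs)


class TestCandidateNonekfs:
    def _state(self, table, cfg, seed):
        from ekbn._discrete import derive_seed
        from ekbn.feature_ranking import importance_list, integrate_rankings
        lists = [importance_list(table, learner="rf", cv=cfg.rank_cv,
                                 seed=derive_seed(seed, "rank_rf"))]
        ranking = integrate_rankings(lists)
        return initial_model(table, ranking, D=4, config=cfg)

    def test_consecutive_ekfs_empty_s_star(self, medium_truth):
        """Two EKFs adjacent in L*: the in-between non-EKF set is empty."""
        from ekbn.pipelines import HITLState

        tab = sample_dataset(medium_truth, 300, seed=12)
        cfg = HITLConfig(seed=12, **FAST_CFG)
        head = ["P1", "C1"]  # consecutive EKFs at the top of the list
        order = head + [f for f in tab.feature_names if f not in head]
        ranking = IntegratedRanking(
            wrs={f: float(i + 1) for i, f in enumerate(order)}, order=order)
        state = HITLState(ranking=ranking, ekf_sequence=["P1", "C1", "S1", "S2"],
                          i=1, selected=["P1"], net=None, eval=None, D=1,
                          n_pct=100.0 / len(order), config=cfg)
        s, s_star = candidate_nonekfs(tab, state, 2)
        assert s == [] and s_star == []

    def test_child_of_new_ekf_selected(self):
        """A non-EKF that is a child of the incoming EKF lands in S*, while
        a pure-noise feature in the same gap does not."""
        from ekbn.pipelines import HITLState

        spec = ScenarioSpec(n_units=300, prevalence=0.3, n_mb=4, n_redundant=4,
                            n_noise=4, n_ekf=4, seed=13)
        truth = make_ground_truth(spec)
        tab = sample_dataset(truth, 5000, seed=13)
        cfg = HITLConfig(seed=13, **FAST_CFG)
        # hand-built ranking: the shadow of C1 and one noise feature sit
        # strictly between EKF P1 (rank 1) and EKF C1 (rank 4)
        head = ["P1", "R2_C1", "N01", "C1"]
        order = head + [f for f in tab.feature_names if f not in head]
        ranking = IntegratedRanking(
            wrs={f: float(i + 1) for i, f in enumerate(order)}, order=order)
        state = HITLState(ranking=ranking, ekf_sequence=["P1", "C1", "S1", "S2"],
                          i=1, selected=["P1"], net=None, eval=None, D=1,
                          n_pct=100.0 / len(order), config=cfg)
        s, s_star = candidate_nonekfs(tab, state, 2)
        assert s == ["R2_C1", "N01"]
        assert "R2_C1" in s_star and "N01" not in s_star

    def test_index_out_of_range(self, medium_truth):
        tab = sample_dataset(medium_truth, 300, seed=14)
        cfg = HITLConfig(seed=14, **FAST_CFG)
        state = self._state(tab, cfg, 14)
        with pytest.raises(ValueError, match="out of range"):
            candidate_nonekfs(tab, state, len(state.ekf_sequence) + 1)


class TestAntiLeakage:
    def test_leaky_variant_inflates_auc_on_noise(self):
        """Selecting features on the full cohort before CV inflates the
        estimate on pure-noise data; the honest nested pipeline does not."""
        diffs = []
        for seed in range(6):
            table = noise_table(81, 40, 0, 0.28, seed=100 + seed)
            # laxer alpha so spurious selection actually happens on noise —
            # the point is the clean/leaky contrast, not the alpha
            cfg = dict(alpha=0.3, sl_config=SLConfig(R=5, cv_R=1),
                       cv_config=CVConfig(folds=5, repeats=2, ci_B=100))
            _, clean = pd_bn_fit(table, seed=seed, **cfg)
            _, leaky = pd_bn_fit(table, seed=seed, leaky=True, **cfg)
            diffs.append(leaky.auc - clean.auc)
        assert np.mean(diffs) > 0.04


def test_initial_model_window_extends_to_first_ekf(medium_truth):
    """If the top-D window holds no EKF, it is widened to the first EKF."""
    tab = sample_dataset(medium_truth, 400, seed=15)
    nonekfs = tab.nonekf_names()
    ekfs = tab.ekf_names()
    order = nonekfs + ekfs  # force every EKF below the window
    ranking = IntegratedRanking(wrs={f: i + 1.0 for i, f in enumerate(order)},
                                order=order)
    cfg = HITLConfig(seed=16, **FAST_CFG)
    state = initial_model(tab, ranking, D=3, config=cfg)
    assert state.i >= 1
    assert state.ekf_sequence[0] == ekfs[0]
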