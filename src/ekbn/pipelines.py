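"""End-to-end model builders: the pure data-driven baseline (PD-BN) and the
human-in-the-loop, expert-knowledge-guided pipeline (HITL-BN).

PD-BN is the classical two-step recipe: select the outcome's Markov blanket
from all features, then learn a bootstrap-averaged network over the selected
features and fit its CPTs.

HITL-BN interleaves two "computational agents" with expert knowledge:

1. Ensemble learners (RF, GBM) each rank all features; the rankings are
   fused into one integrated list L* by AUC-weighted ranking scores.
2. An initial window — the top D features of L*, i.e. the top n = 100·D/N
   percent — seeds the model: expert-knowledge features (EKFs) in the window
   are filtered through the outcome's Markov blanket, and non-EKFs through
   the blankets of the kept EKFs. Structure learning plus backward
   elimination produces the initial model HITL-BN(i), where i EKFs have been
   considered so far.
3. The list is then walked EKF by EKF: for the (i+1)-th EKF, the non-EKFs
   ranked between the i-th and (i+1)-th EKFs form a candidate set S, filtered
   to S* by membership in the blankets of the selected EKFs or the new one.
   A candidate model on the union is built and accepted only if its
   cross-validated AUC improves on the incumbent by more than ε.
4. Iteration stops when the list is exhausted, a target AUC is reached, or
   (optionally) after a run of consecutive rejections.

Every decision is recorded in a replayable trace — the audit trail is the
explainability deliverable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from ._discrete import derive_seed
from .bn_inference import BayesNet, ModelEval, cv_auc, fit_cpts, predict_outcome, roc_auc
from .dataset_io import FeatureTable
from .feature_ranking import CVSpec, IntegratedRanking, importance_list, integrate_rankings
from .markov_blanket import markov_blanket
from .structure_learning import DAG, averaged_network, bootstrap_arc_strength, tabu_search

log = logging.getLogger(__name__)

__all__ = [
    "SLConfig", "CVConfig", "HITLConfig", "HITLState", "HITLTrace",
    "pd_bn_fit", "initial_fraction", "initial_model", "candidate_nonekfs",
    "hitl_step", "hitl_bn_run", "evaluate_on",
]


@dataclass(frozen=True)
class SLConfig:
    """Structure-learning knobs. ``R`` governs the final reported network;
    ``cv_R`` the (cheaper) networks refit inside cross-validated accept/reject
    evaluations — 1 means a single tabu search, no averaging."""

    R: int = 200
    threshold: float = 0.5
    tabu_len: int = 10
    max_iter: int = 200
    cv_R: int = 1
    ess: float = 1.0


@dataclass(frozen=True)
class CVConfig:
    folds: int = 5
    repeats: int = 2
    ci_B: int = 500


@dataclass(frozen=True)
class HITLConfig:
    alpha: float = 0.05
    D: int | None = None  # initial window size; default min(10, n_units // 10)
    epsilon: float = 0.001  # minimum CV-AUC improvement to accept a step
    learners: tuple[str, ...] = ("rf", "gbm")
    weighting: str = "literal"
    rank_cv: CVSpec = CVSpec()
    cv: CVConfig = CVConfig()
    sl: SLConfig = SLConfig()
    target_auc: float | None = None
    patience: int | None = None  # consecutive rejections before stopping
    exclude: tuple[str, ...] = ()  # EKFs the human chose to skip
    mb_window_restricted: bool = True
    elimination: str = "greedy"  # none | disconnected | greedy
    seed: int = 0


@dataclass
class HITLState:
    ranking: IntegratedRanking
    ekf_sequence: list[str]  # EKFs in L* order (after exclusions)
    i: int  # EKFs considered so far
    selected: list[str]
    net: BayesNet | None
    eval: ModelEval | None
    D: int
    n_pct: float
    config: HITLConfig


@dataclass
class HITLTrace:
    entries: list[dict]
    final: HITLState
    config: HITLConfig

    def accepted_aucs(self) -> list[float]:
        return [e["auc"] for e in self.entries if e.get("accepted")]

    def to_json(self) -> str:
        payload = {
            "config": _config_dict(self.config),
            "entries": self.entries,
            "final": {
                "selected": list(self.final.selected),
                "i": self.final.i,
                "D": self.final.D,
                "n_pct": self.final.n_pct,
                "auc": None if self.final.eval is None else self.final.eval.auc,
                "edges": [] if self.final.net is None else self.final.net.dag.sorted_edges(),
            },
        }
        return json.dumps(payload, sort_keys=True, indent=1, default=_jsonify)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    raise TypeError(type(o))


def _config_dict(cfg) -> dict:
    d = asdict(cfg)
    return d


# ---------------------------------------------------------------------------
# shared building blocks
# ---------------------------------------------------------------------------

def _prior_scorer(train: FeatureTable):
    p = float(train.outcome.mean())
    return lambda feat_df: np.full(len(feat_df), p)


def _learn_structure(table: FeatureTable, features: list[str], sl: SLConfig,
                     seed: int, R: int) -> DAG:
    nodes = list(features) + [table.outcome_name]
    df = table.with_outcome_column()[nodes]
    if R <= 1:
        return tabu_search(df, nodes, tabu_len=sl.tabu_len, max_iter=sl.max_iter, seed=seed)
    strengths = bootstrap_arc_strength(df, nodes, R=R, seed=seed,
                                       tabu_len=sl.tabu_len, max_iter=sl.max_iter)
    return averaged_network(strengths, sl.threshold)


def _net_scorer(net: BayesNet, outcome: str):
    cache: dict[tuple, float] = {}
    nodes = [n for n in net.dag.nodes if n != outcome]
    reachable = net.dag.connected_component(outcome)
    used = [n for n in nodes if n in reachable]

    def scorer(feat_df: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(feat_df))
        for i, (_, row) in enumerate(feat_df.iterrows()):
            key = tuple(row[f] for f in used)
            if key not in cache:
                cache[key] = predict_outcome(net, {f: row[f] for f in used}, outcome=outcome)
            out[i] = cache[key]
        return out

    return scorer


def _fit_builder(features: list[str], sl: SLConfig, seed: int):
    """A cv_auc model_builder: relearn structure + CPTs on the training rows
    over a *fixed* feature set."""
    feats = list(features)

    def build(train: FeatureTable):
        if not feats:
            return _prior_scorer(train)
        dag = _learn_structure(train, feats, sl, seed, R=sl.cv_R)
        net = fit_cpts(dag, train.with_outcome_column()[list(dag.nodes)], ess=sl.ess,
                       outcome_name=train.outcome_name)
        return _net_scorer(net, train.outcome_name)

    return build


def _cv_eval(table: FeatureTable, features: list[str], cv: CVConfig, sl: SLConfig,
             seed: int) -> ModelEval:
    return cv_auc(table, _fit_builder(features, sl, seed),
                  folds=cv.folds, repeats=cv.repeats, seed=seed, ci_B=cv.ci_B)


class _Evaluator:
    """Memoized, fold-paired CV evaluation of feature sets within one run.

    A single seed fixes the fold draws for every evaluation, so comparisons
    between feature sets are paired and identical sets score identically —
    the accept rule can never be fooled by fresh fold noise.
    """

    def __init__(self, table: FeatureTable, cv: CVConfig, sl: SLConfig, seed: int):
        self.table, self.cv, self.sl, self.seed = table, cv, sl, seed
        self._memo: dict[frozenset, ModelEval] = {}

    def __call__(self, features: list[str]) -> ModelEval:
        key = frozenset(features)
        if key not in self._memo:
            self._memo[key] = _cv_eval(self.table, sorted(key), self.cv, self.sl, self.seed)
        return self._memo[key]


def _final_net(table: FeatureTable, features: list[str], sl: SLConfig, seed: int) -> BayesNet:
    dag = _learn_structure(table, features, sl, seed, R=sl.R)
    return fit_cpts(dag, table.with_outcome_column()[list(dag.nodes)], ess=sl.ess,
                    outcome_name=table.outcome_name)


def evaluate_on(net: BayesNet | None, table: FeatureTable) -> tuple[np.ndarray, float]:
    """Score a fitted network on an independent cohort; returns (scores, AUC)."""
    if net is None:
        scores = np.full(table.n_units, float(table.outcome.mean()))
    else:
        scorer = _net_scorer(net, table.outcome_name)
        usable = [f for f in net.dag.nodes if f != table.outcome_name
                  and f in table.features.columns]
        scores = scorer(table.features[usable]) if usable else np.full(
            table.n_units, 0.5)
    try:
        auc = roc_auc(scores, table.outcome)
    except ValueError:
        auc = float("nan")
    return scores, auc


def _eliminate(table: FeatureTable, features: list[str], cfg: HITLConfig,
               evaluator: _Evaluator) -> tuple[list[str], ModelEval]:
    """Backward elimination to maximize CV AUC.

    First drop features disconnected from the outcome in a network learned on
    the full training cohort; then (mode "greedy") one pass of removals,
    worst-ranked first, keeping any removal that improves or preserves the
    AUC within ε.
    """
    selected = list(features)
    sl = cfg.sl
    if cfg.elimination in ("disconnected", "greedy") and selected:
        dag = _learn_structure(table, selected, sl, evaluator.seed, R=max(sl.cv_R, 1))
        keep = dag.connected_component(table.outcome_name)
        dropped = [f for f in selected if f not in keep]
        if dropped:
            log.info("eliminating disconnected features: %s", dropped)
            selected = [f for f in selected if f in keep]
    ev = evaluator(selected)
    if cfg.elimination != "greedy":
        return selected, ev
    for f in list(reversed(selected)):
        if len(selected) <= 1:
            break
        trial = [x for x in selected if x != f]
        trial_ev = evaluator(trial)
        if trial_ev.auc >= ev.auc - cfg.epsilon:
            selected, ev = trial, trial_ev
    return selected, ev


# ---------------------------------------------------------------------------
# PD-BN baseline
# ---------------------------------------------------------------------------

def pd_bn_fit(table: FeatureTable, alpha: float = 0.05,
              sl_config: SLConfig = SLConfig(), cv_config: CVConfig = CVConfig(),
              seed: int = 0, leaky: bool = False) -> tuple[BayesNet | None, ModelEval]:
    """Pure data-driven pipeline: outcome blanket -> averaged network -> CPTs.

    The cross-validated evaluation re-runs the *whole* pipeline (blanket
    selection included) inside each training fold, so the reported AUC is
    leakage-free. ``leaky=True`` deliberately selects features once on the
    full cohort and only refits CPTs per fold — a negative control used by
    leakage-audit tests, never for reporting.
    """
    outcome = table.outcome_name

    def build(train: FeatureTable):
        mb = markov_blanket(train, outcome, alpha=alpha)
        if not mb.members:
            return _prior_scorer(train)
        dag = _learn_structure(train, mb.members, sl_config, seed, R=sl_config.cv_R)
        net = fit_cpts(dag, train.with_outcome_column()[list(dag.nodes)],
                       ess=sl_config.ess, outcome_name=outcome)
        return _net_scorer(net, outcome)

    mb_full = markov_blanket(table, outcome, alpha=alpha)
    if leaky:
        feats = mb_full.members

        def build(train: FeatureTable):  # noqa: F811 - documented negative control
            if not feats:
                return _prior_scorer(train)
            dag = _learn_structure(train, feats, sl_config, seed, R=sl_config.cv_R)
            net = fit_cpts(dag, train.with_outcome_column()[list(dag.nodes)],
                           ess=sl_config.ess, outcome_name=outcome)
            return _net_scorer(net, outcome)

    ev = cv_auc(table, build, folds=cv_config.folds, repeats=cv_config.repeats,
                seed=seed, ci_B=cv_config.ci_B)
    if not mb_full.members:
        log.warning("empty outcome blanket; PD-BN degenerates to the prior predictor")
        return None, ev
    net = _final_net(table, mb_full.members, sl_config, seed)
    return net, ev


# ---------------------------------------------------------------------------
# HITL-BN
# ---------------------------------------------------------------------------

def initial_fraction(n_features: int, D: int) -> float:
    """The initial window as a percentage: n = 100·D/N."""
    if not 1 <= D <= n_features:
        raise ValueError(f"D must satisfy 1 <= D <= {n_features}, got {D}")
    return 100.0 * D / n_features


def _ekf_sequence(table: FeatureTable, ranking: IntegratedRanking,
                  exclude: tuple[str, ...]) -> list[str]:
    ekfs = set(table.ekf_names()) - set(exclude)
    return [f for f in ranking.order if f in ekfs]


def initial_model(table: FeatureTable, ranking: IntegratedRanking, D: int,
                  alpha: float = 0.05, sl_config: SLConfig = SLConfig(),
                  cv_config: CVConfig = CVConfig(), seed: int = 0,
                  config: HITLConfig | None = None,
                  evaluator: _Evaluator | None = None) -> HITLState:
    """HITL-BN(i): the model seeded from the top-D window of L*.

    EKFs in the window are filtered through the outcome's blanket (computed
    over the window candidates); non-EKFs through the blankets of the kept
    EKFs, computed among the window's non-EKFs. If the window holds no EKF it
    is extended to the first EKF in L*.
    """
    cfg = config or HITLConfig(alpha=alpha, D=D, sl=sl_config, cv=cv_config, seed=seed)
    order = ranking.order
    if set(order) != set(table.feature_names):
        raise ValueError("ranking does not cover the table's features")
    ekf_seq = _ekf_sequence(table, ranking, cfg.exclude)
    if not ekf_seq:
        raise ValueError("HITL-BN requires at least one expert-knowledge feature")
    window = list(order[:D])
    if not any(f in set(ekf_seq) for f in window):
        first = next(f for f in order if f in set(ekf_seq))
        end = order.index(first) + 1
        log.warning("no EKF in the top-%d window; extending to rank %d", D, end)
        window = list(order[:end])

    ekfs_in_window = [f for f in window if f in set(ekf_seq)]
    nonekfs_in_window = [f for f in window if f not in set(ekf_seq)
                         and not table.roles[f].is_ekf]
    mb_out = markov_blanket(table.subset_features(window), table.outcome_name,
                            candidates=window, alpha=cfg.alpha)
    kept_ekfs = [f for f in ekfs_in_window if f in set(mb_out.members)]
    kept_non = []
    for ekf in kept_ekfs:
        pool = [f for f in nonekfs_in_window if f != ekf]
        if not pool:
            continue
        sub = table.with_outcome_column()[pool + [ekf]]
        mb = markov_blanket(sub, ekf, candidates=pool, alpha=cfg.alpha)
        kept_non.extend(f for f in mb.members if f not in kept_non)
    selected = [f for f in order if f in set(kept_ekfs) | set(kept_non)]

    # one shared evaluation seed: every CV estimate in the run uses the same
    # fold draws, so accept/reject and elimination comparisons are paired
    if evaluator is None:
        evaluator = _Evaluator(table, cfg.cv, cfg.sl, derive_seed(cfg.seed, "cv_eval"))
    selected, ev = _eliminate(table, selected, cfg, evaluator)
    net = _final_net(table, selected, cfg.sl, derive_seed(cfg.seed, "structure")) \
        if selected else None
    i = len([f for f in window if f in set(ekf_seq)])
    return HITLState(
        ranking=ranking, ekf_sequence=ekf_seq, i=max(i, 1), selected=selected,
        net=net, eval=ev, D=D, n_pct=initial_fraction(len(order), D), config=cfg,
    )


def candidate_nonekfs(table: FeatureTable, state: HITLState,
                      next_ekf_index: int) -> tuple[list[str], list[str]]:
    """The candidate non-EKFs S between EKF i and i+1 in L*, and the filtered
    S*: members of S lying in the blanket of any selected EKF or of the new
    EKF, each blanket computed over S plus that EKF alone."""
    i1 = next_ekf_index
    if not 1 <= i1 <= len(state.ekf_sequence):
        raise ValueError(f"EKF index {i1} out of range 1..{len(state.ekf_sequence)}")
    order = state.ranking.order
    new_ekf = state.ekf_sequence[i1 - 1]
    r_hi = order.index(new_ekf)
    prev_ekf = state.ekf_sequence[i1 - 2] if i1 >= 2 else None
    r_lo = order.index(prev_ekf) if prev_ekf is not None else -1
    s = [f for f in order[r_lo + 1: r_hi] if not table.roles[f].is_ekf]
    if not s:
        return [], []
    anchors = [f for f in state.selected if table.roles[f].is_ekf] + [new_ekf]
    star: list[str] = []
    for ekf in anchors:
        pool = [f for f in s if f != ekf]
        if not pool:
            continue
        sub = table.with_outcome_column()[pool + [ekf]]
        mb = markov_blanket(sub, ekf, candidates=pool, alpha=state.config.alpha)
        star.extend(f for f in mb.members if f not in star)
    return s, [f for f in order if f in set(star)]


def hitl_step(table: FeatureTable, state: HITLState, next_ekf_index: int,
              evaluator: _Evaluator | None = None) -> tuple[HITLState, bool, dict]:
    """Consider the next EKF (plus its filtered non-EKFs); accept the refit
    model only if its CV AUC beats the incumbent by more than ε."""
    cfg = state.config
    new_ekf = state.ekf_sequence[next_ekf_index - 1]
    s, s_star = candidate_nonekfs(table, state, next_ekf_index)
    cand = [f for f in state.ranking.order
            if f in set(state.selected) | {new_ekf} | set(s_star)]
    if evaluator is None:
        evaluator = _Evaluator(table, cfg.cv, cfg.sl, derive_seed(cfg.seed, "cv_eval"))
    selected, ev = _eliminate(table, cand, cfg, evaluator)
    inc_auc = state.eval.auc if state.eval is not None else 0.5
    accepted = bool(ev.auc > inc_auc + cfg.epsilon) if np.isfinite(cfg.epsilon) else False
    entry = {
        "step": next_ekf_index, "ekf": new_ekf, "S": s, "S_star": s_star,
        "candidate_set": cand, "selected_after_elimination": selected,
        "auc": ev.auc, "incumbent_auc": inc_auc, "accepted": accepted,
    }
    if accepted:
        net = _final_net(table, selected, cfg.sl,
                         derive_seed(cfg.seed, "structure")) if selected else None
        new_state = HITLState(
            ranking=state.ranking, ekf_sequence=state.ekf_sequence,
            i=next_ekf_index, selected=selected, net=net, eval=ev,
            D=state.D, n_pct=state.n_pct, config=cfg,
        )
        return new_state, True, entry
    state = HITLState(**{**state.__dict__, "i": next_ekf_index})
    return state, False, entry


def hitl_bn_run(table: FeatureTable, config: HITLConfig = HITLConfig(),
                decide=None) -> HITLTrace:
    """Run the full HITL-BN pipeline and return its replayable trace.

    ``decide``, if given, is the human in the loop: a callable receiving each
    step's candidate summary and returning True (try it), False (skip this
    EKF), or None (defer to the AUC rule). Batch runs leave it unset.
    """
    cfg = config
    if not table.ekf_names():
        raise ValueError("HITL-BN requires at least one expert-knowledge feature")
    D = cfg.D if cfg.D is not None else max(1, min(10, table.n_units // 10))
    D = min(D, table.n_features)

    lists = [
        importance_list(table, learner=lr, cv=cfg.rank_cv,
                        seed=derive_seed(cfg.seed, f"rank_{lr}"))
        for lr in cfg.learners
    ]
    ranking = integrate_rankings(lists, weighting=cfg.weighting)

    evaluator = _Evaluator(table, cfg.cv, cfg.sl, derive_seed(cfg.seed, "cv_eval"))
    state = initial_model(table, ranking, D, config=cfg, evaluator=evaluator)
    entries: list[dict] = [{
        "step": 0, "ekf": None, "S": [], "S_star": [],
        "candidate_set": list(state.selected),
        "selected_after_elimination": list(state.selected),
        "auc": state.eval.auc, "incumbent_auc": None, "accepted": True,
    }]
    rejections = 0
    for i1 in range(state.i + 1, len(state.ekf_sequence) + 1):
        if cfg.target_auc is not None and state.eval.auc >= cfg.target_auc:
            break
        if decide is not None:
            verdict = decide({"step": i1, "ekf": state.ekf_sequence[i1 - 1]})
            if verdict is False:
                entries.append({"step": i1, "ekf": state.ekf_sequence[i1 - 1],
                                "S": [], "S_star": [], "candidate_set": [],
                                "selected_after_elimination": list(state.selected),
                                "auc": state.eval.auc, "incumbent_auc": state.eval.auc,
                                "accepted": False, "human_skip": True})
                continue
        state, accepted, entry = hitl_step(table, state, i1, evaluator=evaluator)
        entries.append(entry)
        rejections = 0 if accepted else rejections + 1
        if cfg.patience is not None and rejections >= cfg.patience:
            break
    return HITLTrace(entries=entries, final=state, config=cfg)
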