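"""Discrete Bayesian-network parameter fitting, exact inference, and model
evaluation (cross-validated AUC, confidence intervals, DeLong comparison).

CPTs are Bayesian estimates with a symmetric Dirichlet prior (BDeu-style:
equivalent sample size spread uniformly over the cells of each CPT), so no
posterior probability is ever exactly zero — important at cohort sizes near
one hundred. Outcome posteriors are computed by exact variable elimination.

Evaluation follows the conventions of imbalanced clinical prediction:
repeated stratified k-fold cross-validation with pooled out-of-fold scores,
AUC as the headline metric, stratified-bootstrap or DeLong-variance
confidence intervals, and DeLong's test for comparing two correlated AUCs
measured on the same units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._discrete import derive_seed
from .structure_learning import DAG, ArcStrengthTable

log = logging.getLogger(__name__)

__all__ = [
    "Factor",
    "BayesNet",
    "ModelEval",
    "fit_cpts",
    "predict_outcome",
    "roc_auc",
    "cv_auc",
    "auc_ci",
    "delong_test",
]


# ---------------------------------------------------------------------------
# factors and variable elimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Factor:
    """A nonnegative table over a tuple of discrete variables."""

    variables: tuple[str, ...]
    values: np.ndarray  # shape = cardinalities of variables, in order

    def __post_init__(self):
        if self.values.ndim != len(self.variables):
            raise ValueError("factor shape does not match variable list")

    def reduce(self, var: str, level_ix: int) -> "Factor":
        i = self.variables.index(var)
        vals = np.take(self.values, level_ix, axis=i)
        return Factor(tuple(v for v in self.variables if v != var), vals)

    def marginalize(self, var: str) -> "Factor":
        i = self.variables.index(var)
        return Factor(tuple(v for v in self.variables if v != var),
                      self.values.sum(axis=i))

    def multiply(self, other: "Factor") -> "Factor":
        out_vars = tuple(dict.fromkeys(self.variables + other.variables))
        a = _broadcast(self, out_vars)
        b = _broadcast(other, out_vars)
        return Factor(out_vars, a * b)


def _broadcast(f: Factor, out_vars: tuple[str, ...]) -> np.ndarray:
    shape = [1] * len(out_vars)
    src = {v: i for i, v in enumerate(f.variables)}
    perm = [src[v] for v in out_vars if v in src]
    vals = np.transpose(f.values, perm) if perm else f.values
    it = iter(vals.shape)
    for j, v in enumerate(out_vars):
        if v in src:
            shape[j] = next(it)
    return vals.reshape(shape)


@dataclass
class BayesNet:
    """A fitted discrete network: DAG + CPTs + level labels."""

    dag: DAG
    cpts: dict[str, Factor]  # per node, variables = (*sorted parents, node)
    levels: dict[str, list]
    outcome_name: str | None = None
    strengths: ArcStrengthTable | None = None

    def __post_init__(self):
        for node, f in self.cpts.items():
            rows = f.values.sum(axis=-1)
            if not np.allclose(rows, 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {node!r} do not sum to 1")


def to_xmlbif(net: "BayesNet", network_name: str = "ekbn") -> str:
    """Serialize a fitted network in the XMLBIF interchange format."""
    from xml.sax.saxutils import escape

    lines = ['<?xml version="1.0" encoding="UTF-8"?>',
             '<BIF VERSION="0.3">', "<NETWORK>",
             f"<NAME>{escape(network_name)}</NAME>"]
    for node in net.dag.nodes:
        lines.append('<VARIABLE TYPE="nature">')
        lines.append(f"<NAME>{escape(str(node))}</NAME>")
        for lv in net.levels[node]:
            lines.append(f"<OUTCOME>{escape(str(lv))}</OUTCOME>")
        lines.append("</VARIABLE>")
    for node in net.dag.nodes:
        f = net.cpts[node]
        parents = f.variables[:-1]
        lines.append("<DEFINITION>")
        lines.append(f"<FOR>{escape(str(node))}</FOR>")
        for p in parents:
            lines.append(f"<GIVEN>{escape(str(p))}</GIVEN>")
        # XMLBIF table order: parent configurations vary fastest-last, the
        # node's own outcomes fastest — exactly the C-order flattening here
        flat = " ".join(repr(float(x)) for x in f.values.reshape(-1))
        lines.append(f"<TABLE>{flat}</TABLE>")
        lines.append("</DEFINITION>")
    lines += ["</NETWORK>", "</BIF>"]
    return "\n".join(lines)


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for plotting or export."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], (labels[order] == 1).astype(int)
    n1, n0 = y.sum(), len(y) - y.sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    keep = np.r_[np.flatnonzero(np.diff(s) != 0), len(s) - 1]
    return pd.DataFrame({
        "threshold": np.r_[np.inf, s[keep]],
        "fpr": np.r_[0.0, fps[keep] / n0],
        "tpr": np.r_[0.0, tps[keep] / n1],
    })


def fit_cpts(dag: DAG, data, ess: float = 1.0,
             levels: dict[str, list] | None = None,
             outcome_name: str | None = None) -> BayesNet:
    """Dirichlet-smoothed CPTs: cell prior = ess / (levels × parent configs)."""
    df = data.with_outcome_column() if hasattr(data, "with_outcome_column") else data
    lv: dict[str, list] = {}
    for node in dag.nodes:
        s = df[node]
        if isinstance(s.dtype, pd.CategoricalDtype):
            lv[node] = list(s.cat.categories)
        elif levels and node in levels:
            lv[node] = list(levels[node])
        else:
            lv[node] = sorted(s.unique(), key=str)
    code = {node: pd.Categorical(df[node], categories=lv[node]).codes for node in dag.nodes}

    cpts = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        r = len(lv[node])
        pcards = [len(lv[p]) for p in parents]
        q = int(np.prod(pcards)) if parents else 1
        idx = code[node].astype(np.int64).copy()
        mult = r
        for p, pc in zip(parents, pcards):
            idx += code[p].astype(np.int64) * mult
            mult *= pc
        counts = np.bincount(idx, minlength=r * q).astype(float)
        counts = counts.reshape(tuple(reversed(pcards)) + (r,) if parents else (r,))
        if parents:  # bincount laid out with node fastest; reorder axes to (*parents, node)
            counts = counts.reshape(tuple(pcards[::-1]) + (r,))
            counts = np.transpose(counts, tuple(range(len(parents) - 1, -1, -1)) + (len(parents),))
        prior = ess / (r * q) if ess > 0 else 0.0
        post = counts + prior
        rows = post.sum(axis=-1, keepdims=True)
        rows = np.where(rows == 0, 1.0, rows)
        probs = post / rows
        if ess <= 0:  # pure MLE; give empty rows a uniform distribution
            empty = post.sum(axis=-1, keepdims=True) == 0
            probs = np.where(empty, 1.0 / r, probs)
        cpts[node] = Factor(tuple(parents) + (node,), probs)
    return BayesNet(dag=dag, cpts=cpts, levels=lv, outcome_name=outcome_name)


def predict_outcome(bn: BayesNet, evidence: dict, outcome: str | None = None,
                    event_level=None) -> float:
    """Exact posterior P(outcome = event | evidence) by variable elimination.

    Evidence features outside the network are ignored with a warning; values
    not among a node's known levels are treated as missing (marginalized).
    """
    outcome = outcome or bn.outcome_name
    if outcome is None:
        raise ValueError("no outcome node specified")
    if outcome in evidence:
        raise ValueError("outcome cannot appear in the evidence")
    ev: dict[str, int] = {}
    for k, v in evidence.items():
        if k not in bn.cpts:
            log.warning("evidence feature %r not in network; ignored", k)
            continue
        lv = bn.levels[k]
        if v in lv:
            ev[k] = lv.index(v)
        else:
            log.warning("evidence level %r unseen for %r; marginalized", v, k)

    factors = []
    for node, f in bn.cpts.items():
        for var, ix in ev.items():
            if var in f.variables:
                f = f.reduce(var, ix)
        factors.append(f)

    hidden = [n for n in bn.dag.nodes if n != outcome and n not in ev]
    # min-degree elimination ordering
    while hidden:
        def degree(h):
            vs = set()
            for f in factors:
                if h in f.variables:
                    vs |= set(f.variables)
            return (len(vs), h)
        h = min(hidden, key=degree)
        hidden.remove(h)
        related = [f for f in factors if h in f.variables]
        factors = [f for f in factors if h not in f.variables]
        if related:
            prod = related[0]
            for f in related[1:]:
                prod = prod.multiply(f)
            factors.append(prod.marginalize(h))

    result = Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    vals = result.values if result.variables == (outcome,) else result.values.reshape(-1)
    total = vals.sum()
    if total <= 0:
        return float("nan")
    post = vals / total
    if event_level is None:
        event_ix = bn.levels[outcome].index(1) if 1 in bn.levels[outcome] else len(post) - 1
    else:
        event_ix = bn.levels[outcome].index(event_level)
    return float(post[event_ix])


# ---------------------------------------------------------------------------
# AUC machinery
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """AUC as the scaled Mann–Whitney U statistic; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


@dataclass
class ModelEval:
    """Pooled out-of-fold evaluation of one model on one cohort."""

    auc: float
    ci: tuple[float, float]
    scores: np.ndarray  # per-unit out-of-fold score (averaged over repeats)
    labels: np.ndarray
    fold_assignment: np.ndarray  # (repeats, n) fold index per unit
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.ci[0] <= self.auc <= self.ci[1]):
            raise ValueError("CI must bracket the AUC")
        if len(self.scores) != len(self.labels):
            raise ValueError("scores and labels disagree in length")


def _stratified_folds(labels: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    assign = np.empty(len(labels), dtype=np.int32)
    for cls in np.unique(labels):
        ix = np.flatnonzero(labels == cls)
        rng.shuffle(ix)
        assign[ix] = np.arange(len(ix)) % folds
    return assign


def cv_auc(table, model_builder, folds: int = 5, repeats: int = 10,
           seed: int = 0, ci_method: str = "stratified-bootstrap",
           ci_B: int = 2000) -> ModelEval:
    """Repeated stratified k-fold CV of an arbitrary model-building pipeline.

    ``model_builder(train_table)`` must return a scorer mapping a feature
    DataFrame to per-row event probabilities; the builder re-runs *all* model
    construction (feature selection, structure learning, CPTs) on the
    training rows only, so no selection leaks into the held-out folds.
    AUC is computed on each repeat's pooled out-of-fold scores and averaged
    over repeats; the CI is attached to the per-unit mean scores.
    """
    labels = table.outcome
    n = len(labels)
    n_min = int(min((labels == 1).sum(), (labels == 0).sum()))
    if n_min < 2:
        raise ValueError("outcome too imbalanced for CV spec")
    if n_min < folds:
        log.warning("minority count %d < folds %d; reducing folds", n_min, folds)
        folds = n_min
    rng = np.random.default_rng(derive_seed(seed, "cv_auc"))
    all_scores = np.zeros(n)
    assignment = np.empty((repeats, n), dtype=np.int32)
    aucs = []
    for rep in range(repeats):
        assign = _stratified_folds(labels, folds, rng)
        assignment[rep] = assign
        scores = np.empty(n)
        for f in range(folds):
            test = assign == f
            train_tab = table.subset_rows(np.flatnonzero(~test))
            scorer = model_builder(train_tab)
            scores[test] = scorer(table.features.iloc[np.flatnonzero(test)])
        aucs.append(roc_auc(scores, labels))
        all_scores += scores
    all_scores /= repeats
    auc = float(np.mean(aucs))
    lo, hi = auc_ci(all_scores, labels, method=ci_method, B=ci_B,
                    seed=derive_seed(seed, "auc_ci"))
    lo, hi = min(lo, auc), max(hi, auc)
    return ModelEval(
        auc=auc, ci=(lo, hi), scores=all_scores, labels=np.asarray(labels),
        fold_assignment=assignment,
        config={"folds": folds, "repeats": repeats, "seed": seed, "ci_method": ci_method},
    )


def auc_ci(scores, labels, level: float = 0.95, method: str = "stratified-bootstrap",
           B: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Confidence interval for an AUC.

    stratified-bootstrap (default): resample positives and negatives
    separately B times, percentile interval. delong-variance: normal interval
    with DeLong's closed-form variance.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    alpha = 1 - level
    if method == "delong-variance":
        auc, var = _delong_auc_var(pos, neg)
        se = np.sqrt(max(var, 0.0))
        z = norm.ppf(1 - alpha / 2)
        return (float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se)))
    if method != "stratified-bootstrap":
        raise ValueError(f"unknown CI method {method!r}")
    rng = np.random.default_rng(seed)
    n1, n0 = len(pos), len(neg)
    p = pos[rng.integers(0, n1, size=(B, n1))]
    q = neg[rng.integers(0, n0, size=(B, n0))]
    both = np.concatenate([p, q], axis=1)
    ranks = rankdata(both, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2
    aucs = u / (n1 * n0)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    n1, n0 = len(pos), len(neg)
    order = np.concatenate([pos, neg])
    ranks = rankdata(order)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (ranks[:n1] - r_pos) / n0
    v01 = 1.0 - (ranks[n1:] - r_neg) / n1
    auc = float(v10.mean())
    return v10, v01, auc


def _delong_auc_var(pos, neg) -> tuple[float, float]:
    v10, v01, auc = _placements(np.asarray(pos, float), np.asarray(neg, float))
    s10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    return auc, s10 / len(v10) + s01 / len(v01)


def delong_test(eval_a, eval_b) -> tuple[float, float]:
    """DeLong's test for two correlated AUCs on the same units.

    Accepts two ModelEvals (or (scores, labels) pairs) scored on identical
    units and labels; returns (z, two-sided p).
    """
    sa, la = (eval_a.scores, eval_a.labels) if isinstance(eval_a, ModelEval) else eval_a
    sb, lb = (eval_b.scores, eval_b.labels) if isinstance(eval_b, ModelEval) else eval_b
    la, lb = np.asarray(la), np.asarray(lb)
    if len(la) != len(lb) or not np.array_equal(la, lb):
        raise ValueError("the two evaluations must share units and labels")
    sa, sb = np.asarray(sa, float), np.asarray(sb, float)
    pos_ix, neg_ix = la == 1, la != 1
    va10, va01, auc_a = _placements(sa[pos_ix], sa[neg_ix])
    vb10, vb01, auc_b = _placements(sb[pos_ix], sb[neg_ix])
    n1, n0 = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10])) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01])) if n0 > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    diff = auc_a - auc_b
    if var <= 0:
        return (0.0, 1.0) if abs(diff) < 1e-12 else (float(np.sign(diff) * np.inf), 0.0)
    z = diff / np.sqrt(var)
    return float(z), float(2 * norm.sf(abs(z)))
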