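"""Score-based Bayesian-network structure learning with bootstrap averaging.

The search is tabu hill-climbing over add/delete/reverse arc moves scored by
the decomposable BIC of a discrete network. Robustness against the small
cohorts this package targets (n ≈ 100) comes from nonparametric bootstrap
model averaging: the search is repeated on resampled rows, each arc's
empirical frequency across replicates is its *strength*, and the averaged
network keeps arcs above a strength threshold, oriented by majority
direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._discrete import encode_columns, joint_config

log = logging.getLogger(__name__)

__all__ = [
    "DAG",
    "ArcStrengthTable",
    "bic_score",
    "tabu_search",
    "bootstrap_arc_strength",
    "averaged_network",
]


@dataclass(frozen=True)
class DAG:
    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        ns = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u}->{v}")
            if u not in ns or v not in ns:
                raise ValueError(f"edge {u}->{v} references unknown node")
        if not self.is_acyclic():
            raise ValueError("graph is cyclic")

    def is_acyclic(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return nx.is_directed_acyclic_graph(g)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(v for u, v in self.edges if u == node))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in self.sorted_edges():
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)

    def connected_component(self, node: str) -> set[str]:
        g = self.to_networkx().to_undirected()
        return set(nx.node_connected_component(g, node))


@dataclass
class ArcStrengthTable:
    """Bootstrap arc frequencies.

    ``strength(u, v)``: fraction of replicates containing u–v in either
    direction (symmetric); ``direction(u, v)``: among those, the fraction
    oriented u→v (direction(u,v) + direction(v,u) = 1 whenever strength > 0).
    """

    nodes: tuple[str, ...]
    counts_any: dict[frozenset, int] = field(default_factory=dict)
    counts_dir: dict[tuple[str, str], int] = field(default_factory=dict)
    n_replicates: int = 0

    def strength(self, u: str, v: str) -> float:
        return self.counts_any.get(frozenset((u, v)), 0) / self.n_replicates

    def direction(self, u: str, v: str) -> float:
        any_ = self.counts_any.get(frozenset((u, v)), 0)
        if any_ == 0:
            return 0.0
        return self.counts_dir.get((u, v), 0) / any_

    def pairs(self):
        for pair in sorted(self.counts_any, key=sorted):
            u, v = sorted(pair)
            yield u, v

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for u, v in self.pairs():
            rows.append({"from": u, "to": v, "strength": self.strength(u, v),
                         "direction": self.direction(u, v)})
            rows.append({"from": v, "to": u, "strength": self.strength(v, u),
                         "direction": self.direction(v, u)})
        return pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class _ScoreCache:
    """Decomposable BIC with per-(node, parents) memoization."""

    def __init__(self, df: pd.DataFrame, columns: list[str]):
        codes, cards, _ = encode_columns(df, columns)
        self.codes = codes
        self.cards = {c: int(k) for c, k in zip(columns, cards)}
        self.col_ix = {c: i for i, c in enumerate(columns)}
        self.n = codes.shape[0]
        self.logn = np.log(max(self.n, 1))
        self._cache: dict[tuple[str, frozenset], float] = {}

    def local(self, node: str, parents: tuple[str, ...]) -> float:
        key = (node, frozenset(parents))
        if key in self._cache:
            return self._cache[key]
        r = self.cards[node]
        pcols = [self.col_ix[p] for p in sorted(parents)]
        pcards = np.array([self.cards[p] for p in sorted(parents)], dtype=np.int64)
        pc, q = joint_config(self.codes[:, pcols], pcards)
        idx = self.codes[:, self.col_ix[node]].astype(np.int64) + r * pc
        counts = np.bincount(idx, minlength=r * q).reshape(q, r).astype(float)
        rowsum = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(counts > 0, counts * np.log(counts / rowsum), 0.0).sum()
        penalty = 0.5 * self.logn * (r - 1) * q
        val = float(ll - penalty)
        self._cache[key] = val
        return val

    def total(self, dag: DAG) -> float:
        return sum(self.local(n, dag.parents(n)) for n in dag.nodes)


def bic_score(dag: DAG, data) -> float:
    """BIC of a discrete network: Σ_nodes [max log-likelihood] − (log n / 2)·k."""
    df = data.with_outcome_column() if hasattr(data, "with_outcome_column") else data
    return _ScoreCache(df, list(dag.nodes)).total(dag)


# ---------------------------------------------------------------------------
# tabu search
# ---------------------------------------------------------------------------

def _has_path(adj: dict[str, set], src: str, dst: str) -> bool:
    stack, seen = [src], set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        if u in seen:
            continue
        seen.add(u)
        stack.extend(adj[u])
    return False


def tabu_search(
    data,
    features: list[str],
    score: str = "bic",
    tabu_len: int = 10,
    max_iter: int = 1000,
    seed: int = 0,
    blacklist: set[tuple[str, str]] | None = None,
    whitelist: set[tuple[str, str]] | None = None,
) -> DAG:
    """Tabu hill-climbing over add/delete/reverse moves.

    Keeps a tabu list of the last ``tabu_len`` visited structures and allows
    the best non-improving admissible move to escape plateaus; returns the
    best structure seen. Deterministic: moves are tie-broken lexically, and
    ``seed`` only matters if a score backend ever becomes stochastic.
    """
    if score != "bic":
        raise ValueError(f"unknown score {score!r}")
    blacklist = set(blacklist or ())
    whitelist = set(whitelist or ())
    for e in whitelist:
        if e in blacklist:
            raise ValueError(f"edge {e} appears in both whitelist and blacklist")

    df = data.with_outcome_column() if hasattr(data, "with_outcome_column") else data
    features = list(features)
    cache = _ScoreCache(df, features)

    edges = set(whitelist)
    start = DAG(tuple(features), frozenset(edges))  # validates whitelist acyclicity
    parents = {n: set() for n in features}
    children = {n: set() for n in features}
    for u, v in edges:
        parents[v].add(u)
        children[u].add(v)

    def local(node):
        return cache.local(node, tuple(parents[node]))

    cur_score = sum(local(n) for n in features)
    best_edges, best_score = frozenset(edges), cur_score
    tabu: list[frozenset] = [frozenset(edges)]
    stale = 0

    for _ in range(max_iter):
        moves = []  # (delta, kind, u, v, new_edge_set)
        for u in features:
            for v in features:
                if u == v:
                    continue
                e = (u, v)
                if e in edges:
                    if e not in whitelist:
                        # delete
                        delta = cache.local(v, tuple(parents[v] - {u})) - local(v)
                        moves.append((delta, "del", u, v))
                        # reverse
                        if ((v, u) not in blacklist and e not in whitelist
                                and not _cycle_on_reverse(children, u, v)):
                            delta_r = (
                                cache.local(v, tuple(parents[v] - {u}))
                                - local(v)
                                + cache.local(u, tuple(parents[u] | {v}))
                                - local(u)
                            )
                            moves.append((delta_r, "rev", u, v))
                elif e not in blacklist and (v, u) not in edges:
                    if not _has_path(children, v, u):
                        delta = cache.local(v, tuple(parents[v] | {u})) - local(v)
                        moves.append((delta, "add", u, v))
        if not moves:
            break
        moves.sort(key=lambda m: (-m[0], m[1], m[2], m[3]))
        chosen = None
        for delta, kind, u, v in moves:
            new_edges = set(edges)
            if kind == "add":
                new_edges.add((u, v))
            elif kind == "del":
                new_edges.discard((u, v))
            else:
                new_edges.discard((u, v))
                new_edges.add((v, u))
            fz = frozenset(new_edges)
            if fz in tabu:
                continue
            chosen = (delta, kind, u, v, fz)
            break
        if chosen is None:
            break
        delta, kind, u, v, fz = chosen
        if kind == "add":
            edges.add((u, v))
            parents[v].add(u)
            children[u].add(v)
        elif kind == "del":
            edges.discard((u, v))
            parents[v].discard(u)
            children[u].discard(v)
        else:
            edges.discard((u, v))
            parents[v].discard(u)
            children[u].discard(v)
            edges.add((v, u))
            parents[u].add(v)
            children[v].add(u)
        cur_score += delta
        tabu.append(fz)
        if len(tabu) > max(tabu_len, 1):
            tabu.pop(0)
        if cur_score > best_score + 1e-12:
            best_edges, best_score = fz, cur_score
            stale = 0
        else:
            stale += 1
            if stale >= max(tabu_len, 1):
                break
    return DAG(tuple(features), best_edges)


def _cycle_on_reverse(children: dict[str, set], u: str, v: str) -> bool:
    # reversing u->v creates a cycle iff a u->...->v path exists avoiding the edge u->v
    saved = children[u].copy()
    children[u].discard(v)
    try:
        return _has_path(children, u, v)
    finally:
        children[u] = saved


# ---------------------------------------------------------------------------
# bootstrap averaging
# ---------------------------------------------------------------------------

def bootstrap_arc_strength(
    data,
    features: list[str],
    R: int = 200,
    seed: int = 0,
    tabu_len: int = 10,
    max_iter: int = 1000,
    blacklist: set | None = None,
    whitelist: set | None = None,
) -> ArcStrengthTable:
    """Arc strengths from R nonparametric bootstrap replicates of the rows."""
    if R <= 0:
        raise ValueError("R must be >= 1")
    df = data.with_outcome_column() if hasattr(data, "with_outcome_column") else data
    df = df[list(features)]
    rng = np.random.default_rng(seed)
    n = len(df)
    tab = ArcStrengthTable(nodes=tuple(features), n_replicates=R)
    for _ in range(R):
        idx = rng.integers(0, n, size=n)
        boot = df.iloc[idx].reset_index(drop=True)
        dag = tabu_search(boot, features, tabu_len=tabu_len, max_iter=max_iter,
                          blacklist=blacklist, whitelist=whitelist)
        for u, v in dag.edges:
            key = frozenset((u, v))
            tab.counts_any[key] = tab.counts_any.get(key, 0) + 1
            tab.counts_dir[(u, v)] = tab.counts_dir.get((u, v), 0) + 1
    return tab


def averaged_network(strengths: ArcStrengthTable, threshold: float = 0.5) -> DAG:
    """Keep arcs with strength ≥ threshold, oriented by majority direction.

    Direction ties go to the lexically smaller endpoint as source. Averaging
    can produce directed cycles; each is broken by removing its weakest arc
    (smallest strength, then smallest direction fraction), logged.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    chosen = []
    for u, v in strengths.pairs():
        s = strengths.strength(u, v)
        if s >= threshold:
            d_uv = strengths.direction(u, v)
            if d_uv > 0.5 or (d_uv == 0.5 and u < v):
                chosen.append((u, v, s, d_uv))
            else:
                chosen.append((v, u, s, strengths.direction(v, u)))
    g = nx.DiGraph()
    g.add_nodes_from(strengths.nodes)
    meta = {}
    for u, v, s, d in chosen:
        g.add_edge(u, v)
        meta[(u, v)] = (s, d)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: (meta[(e[0], e[1])], e))
        g.remove_edge(*weakest[:2])
        log.warning("cycle broken: removed arc %s->%s (strength %.3f)",
                    weakest[0], weakest[1], meta[(weakest[0], weakest[1])][0])
    dag = DAG(strengths.nodes, frozenset((u, v) for u, v in g.edges))
    assert dag.is_acyclic()
    return dag
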