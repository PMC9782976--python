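"""Conditional-independence testing and Markov-blanket discovery.

The Markov blanket (MB) of a variable in a faithful Bayesian network is its
parents, children, and co-parents (spouses); conditioning on the blanket
renders the variable independent of everything else. MB discovery is the
explainability-oriented feature-selection step here: the blanket of the
clinical outcome is exactly the set of strongly relevant, non-redundant
predictors.

The discovery algorithm is Inter-IAMB — incremental association with
interleaved shrinking: greedily add the candidate most associated with the
target given the current blanket, and after every addition re-test members
for redundancy. All tests are discrete G² (likelihood-ratio) tests; tests
with too few samples per contingency cell are flagged ineffective and never
justify an addition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._discrete import encode_columns, joint_config

__all__ = ["CITestResult", "MarkovBlanket", "ci_test", "markov_blanket", "brute_force_mb"]

MIN_AVG_CELL = 5.0  # average samples per contingency cell for a test to count


@dataclass(frozen=True)
class CITestResult:
    statistic: float  # G^2, >= 0
    dof: int
    p_value: float
    effective: bool  # enough samples per cell to trust the asymptotics

    def independent(self, alpha: float) -> bool:
        """Non-rejection: also returned when the test is ineffective."""
        return (not self.effective) or self.p_value >= alpha


@dataclass
class MarkovBlanket:
    target: str
    members: list[str]
    trail: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.target in self.members:
            raise ValueError("target cannot be a member of its own blanket")


def _as_frame(data) -> pd.DataFrame:
    # accepts a FeatureTable or a plain categorical DataFrame
    if hasattr(data, "with_outcome_column"):
        return data.with_outcome_column()
    return data


def ci_test(data, x: str, y: str, z: list[str] | tuple[str, ...] = ()) -> CITestResult:
    """G² test of X ⟂ Y | Z on discrete columns.

    dof = (|X|-1)(|Y|-1)·Π|Z_i| using declared cardinalities. ``effective``
    is False when n over the full contingency size falls below 5 per cell;
    callers treat such tests as non-rejections.
    """
    df = _as_frame(data)
    z = list(z)
    if x == y:
        raise ValueError("X and Y must differ")
    if x in z or y in z:
        raise ValueError("X and Y must not appear in the conditioning set")
    codes, cards, _ = encode_columns(df, [x, y] + z)
    n = codes.shape[0]
    rx, ry = int(cards[0]), int(cards[1])
    zc, nz = joint_config(codes[:, 2:], cards[2:])
    idx = codes[:, 0].astype(np.int64) + rx * (codes[:, 1].astype(np.int64) + ry * zc)
    counts = np.bincount(idx, minlength=rx * ry * nz).reshape(nz, ry, rx).astype(float)

    nz_tot = counts.sum(axis=(1, 2), keepdims=True)
    rows = counts.sum(axis=2, keepdims=True)  # per (z, y)
    cols = counts.sum(axis=1, keepdims=True)  # per (z, x)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows * cols / nz_tot
        ratio = np.where(counts > 0, counts / expected, 1.0)
        g2 = 2.0 * float(np.sum(counts * np.log(ratio)))
    g2 = max(g2, 0.0)

    dof = max((rx - 1) * (ry - 1) * int(nz), 1)
    p = float(chi2.sf(g2, dof))
    effective = n / (rx * ry * nz) >= MIN_AVG_CELL
    return CITestResult(statistic=g2, dof=dof, p_value=p, effective=effective)


def markov_blanket(
    data,
    target: str,
    candidates: list[str] | None = None,
    alpha: float = 0.05,
    interleaved: bool = True,
) -> MarkovBlanket:
    """Inter-IAMB blanket discovery for ``target`` among ``candidates``.

    Grow: add the candidate with the smallest G² p-value given the current
    blanket, provided the test is effective and p < alpha. After each
    addition (interleaved variant) shrink: drop any member whose test against
    the target given the rest of the blanket no longer rejects. With
    ``interleaved=False`` the shrink phase runs once at the end (plain IAMB).
    Deterministic: ties in p-value break on lexical feature name.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = _as_frame(data)
    if len(df) == 0:
        raise ValueError("empty data")
    if target not in df.columns:
        raise ValueError(f"target {target!r} not in data")
    if candidates is None:
        candidates = [c for c in df.columns if c != target]
    else:
        bad = [c for c in candidates if c not in df.columns or c == target]
        if bad:
            raise ValueError(f"invalid candidates: {bad}")

    mb: list[str] = []
    trail: list[dict] = []

    def shrink(just_added: str | None):
        removed = True
        while removed:
            removed = False
            for m in sorted(mb):
                if m == just_added:
                    continue
                rest = [v for v in mb if v != m]
                res = ci_test(df, target, m, rest)
                if res.effective and res.p_value >= alpha:
                    mb.remove(m)
                    trail.append(
                        {"candidate": m, "given": rest, "p": res.p_value, "action": "remove"}
                    )
                    removed = True
                    break

    while True:
        best_name, best_p = None, None
        for c in sorted(set(candidates) - set(mb)):
            res = ci_test(df, target, c, mb)
            if not res.effective:
                trail.append({"candidate": c, "given": list(mb), "p": res.p_value, "action": "skip"})
                continue
            if res.p_value < alpha and (best_p is None or res.p_value < best_p):
                best_name, best_p = c, res.p_value
        if best_name is None:
            break
        mb.append(best_name)
        trail.append({"candidate": best_name, "given": [v for v in mb if v != best_name],
                      "p": best_p, "action": "add"})
        if interleaved:
            shrink(just_added=best_name)
    if not interleaved:
        shrink(just_added=None)
    return MarkovBlanket(target=target, members=sorted(mb), trail=trail)


def brute_force_mb(data, target: str, alpha: float = 0.05,
                   candidates: list[str] | None = None) -> MarkovBlanket:
    """Exhaustive-search oracle: the smallest S with every X ∉ S independent
    of the target given S. Exponential in the candidate count; refuses more
    than 8 candidates. Test-harness use only.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = _as_frame(data)
    if candidates is None:
        candidates = [c for c in df.columns if c != target]
    if len(candidates) > 8:
        raise ValueError("oracle limited to 8 features")
    cand = sorted(candidates)
    for size in range(len(cand) + 1):
        for subset in combinations(cand, size):
            s = list(subset)
            ok = True
            for x in cand:
                if x in subset:
                    continue
                if not ci_test(df, target, x, s).independent(alpha):
                    ok = False
                    break
            if ok:
                return MarkovBlanket(target=target, members=s,
                                     trail=[{"candidate": m, "given": [v for v in s if v != m],
                                             "p": float("nan"), "action": "add"} for m in s])
    return MarkovBlanket(target=target, members=cand, trail=[])
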