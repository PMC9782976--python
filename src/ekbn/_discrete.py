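"""Shared helpers for discrete (categorical) data matrices.

Everything downstream of discretization — conditional-independence tests,
network scores, CPT fitting — works on integer-coded columns. These helpers
centralize the coding so cardinalities and level orders are consistent.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

__all__ = ["encode_columns", "joint_config", "derive_seed"]


def encode_columns(
    df: pd.DataFrame, columns: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, dict[str, list]]:
    """Integer-code categorical columns.

    Returns (codes, cards, levels): an (n, m) int32 array, per-column
    cardinalities, and the level labels backing each code. Cardinality is the
    number of declared categories (pandas Categorical) or observed distinct
    values, never less than 1. Raises on float columns — callers must
    discretize first.
    """
    if columns is None:
        columns = list(df.columns)
    n = len(df)
    codes = np.empty((n, len(columns)), dtype=np.int32)
    cards = np.empty(len(columns), dtype=np.int64)
    levels: dict[str, list] = {}
    for i, col in enumerate(columns):
        s = df[col]
        if isinstance(s.dtype, pd.CategoricalDtype):
            c = s.cat.codes.to_numpy()
            cats = list(s.cat.categories)
        else:
            if s.dtype.kind == "f" and not np.all(s.dropna() == s.dropna().astype(int)):
                raise ValueError(
                    f"column {col!r} is continuous; discretize it before discrete analysis"
                )
            cats, c = np.unique(s.to_numpy(), return_inverse=True)
            cats = list(cats)
        if (np.asarray(c) < 0).any():
            raise ValueError(f"column {col!r} has missing values; impute before analysis")
        codes[:, i] = c
        cards[i] = max(len(cats), 1)
        levels[col] = cats
    return codes, cards, levels


def joint_config(codes: np.ndarray, cards: np.ndarray) -> tuple[np.ndarray, int]:
    """Collapse the columns of an (n, m) code matrix into a single joint index."""
    if codes.shape[1] == 0:
        return np.zeros(codes.shape[0], dtype=np.int64), 1
    idx = np.zeros(codes.shape[0], dtype=np.int64)
    mult = 1
    for j in range(codes.shape[1]):
        idx += codes[:, j].astype(np.int64) * mult
        mult *= int(cards[j])
    return idx, mult


def derive_seed(master: int, stage: str) -> int:
    """Fan a top-level seed out to a per-stage sub-seed (stable across runs)."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
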