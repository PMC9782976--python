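"""Cohort tables, feature-role metadata, and discretization.

A cohort is a rectangular table: one row per analysis unit (a tumor or a
patient, treated as independent), one binary outcome column, and a mix of
continuous and categorical features. A metadata sidecar assigns each feature
a role: whether physicians flagged it as an expert-knowledge feature (EKF),
whether it is available before treatment or only during treatment, and which
outcomes it applies to.

All downstream machinery (conditional-independence tests, network scores,
conditional probability tables) is discrete, so continuous features are
discretized into ordered quantile bins here, once, up front.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

PHASES = ("pre", "during")


@dataclass(frozen=True)
class FeatureRole:
    """Role metadata for one feature."""

    is_ekf: bool = False
    phase: str = "pre"
    applicable_outcomes: frozenset[str] | None = None  # None = applies to all

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")

    def applies_to(self, outcome: str) -> bool:
        return self.applicable_outcomes is None or outcome in self.applicable_outcomes


@dataclass
class FeatureTable:
    """A validated cohort: units x (features + one binary outcome).

    ``outcome`` is coded so that 1 is the minority class (the clinical event,
    e.g. a liver-toxicity grade increase or a local failure) regardless of the
    labels in the input file; ``event_label``/``nonevent_label`` record the
    original labels so reports stay interpretable.
    """

    units: list[str]
    outcome_name: str
    outcome: np.ndarray
    features: pd.DataFrame
    roles: dict[str, FeatureRole]
    levels: dict[str, list] = field(default_factory=dict)
    event_label: object = 1
    nonevent_label: object = 0

    def __post_init__(self):
        self.outcome = np.asarray(self.outcome, dtype=np.int8)
        uniq = np.unique(self.outcome)
        if not np.array_equal(uniq, [0, 1]):
            raise ValueError(
                f"outcome not binary: column {self.outcome_name!r} has levels {list(uniq)}"
            )
        if len(self.units) != len(set(self.units)):
            dupes = pd.Series(self.units)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate unit ids: {dupes}")
        if len(self.units) != len(self.features):
            raise ValueError("units and feature rows disagree in length")
        missing = set(self.features.columns) - set(self.roles)
        if missing:
            raise ValueError(f"features without roles: {sorted(missing)}")
        extra = set(self.roles) - set(self.features.columns)
        if extra:
            raise ValueError(f"roles without feature columns: {sorted(extra)}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def ekf_names(self) -> list[str]:
        return [f for f in self.features.columns if self.roles[f].is_ekf]

    def nonekf_names(self) -> list[str]:
        return [f for f in self.features.columns if not self.roles[f].is_ekf]

    @property
    def prevalence(self) -> float:
        return float(self.outcome.mean())

    def subset_features(self, names: list[str]) -> "FeatureTable":
        names = [n for n in self.features.columns if n in set(names)]
        return FeatureTable(
            units=list(self.units),
            outcome_name=self.outcome_name,
            outcome=self.outcome.copy(),
            features=self.features[names].copy(),
            roles={n: self.roles[n] for n in names},
            levels={n: self.levels[n] for n in names if n in self.levels},
            event_label=self.event_label,
            nonevent_label=self.nonevent_label,
        )

    def subset_rows(self, index: np.ndarray) -> "FeatureTable":
        index = np.asarray(index)
        return FeatureTable(
            units=[self.units[i] for i in index],
            outcome_name=self.outcome_name,
            outcome=self.outcome[index],
            features=self.features.iloc[index].reset_index(drop=True),
            roles=dict(self.roles),
            levels=dict(self.levels),
            event_label=self.event_label,
            nonevent_label=self.nonevent_label,
        )

    def with_outcome_column(self) -> pd.DataFrame:
        """Features plus the outcome as one categorical DataFrame."""
        df = self.features.copy()
        df[self.outcome_name] = pd.Categorical(self.outcome, categories=[0, 1])
        return df

    def known_outcomes(self) -> set[str]:
        out = {self.outcome_name}
        for r in self.roles.values():
            if r.applicable_outcomes is not None:
                out |= set(r.applicable_outcomes)
        return out


@dataclass(frozen=True)
class DiscretizationSpec:
    """How to bin continuous features.

    quantile: cut at empirical quantiles (default, keeps cells balanced);
    fixed-bins: equal-width cuts over the observed range;
    supplied-cuts: per-feature explicit cut points via ``overrides``.
    """

    method: str = "quantile"
    bins: int = 3
    overrides: dict[str, "DiscretizationSpec | list[float]"] = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in ("quantile", "fixed-bins", "supplied-cuts"):
            raise ValueError(f"unknown discretization method {self.method!r}")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        for k, v in self.overrides.items():
            if isinstance(v, list):
                if any(b >= a for a, b in zip(v[1:], v)):
                    raise ValueError(f"cut points for {k!r} must be strictly increasing")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _read_metadata(path) -> dict:
    text = open(path, "r", encoding="utf-8").read()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _delimiter(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_cohort(table_path, metadata_path) -> FeatureTable:
    """Load a delimited cohort file plus its metadata sidecar.

    The sidecar declares the outcome column and per-feature roles; table
    columns absent from the sidecar are assigned non-EKF / pre-treatment roles
    with a warning. The minority outcome class is coded 1 internally.
    """
    meta = _read_metadata(metadata_path)
    if "outcome" not in meta:
        raise ValueError("metadata must declare the outcome column")
    outcome_name = meta["outcome"]
    df = pd.read_csv(table_path, sep=_delimiter(table_path))

    unit_col = meta.get("unit", "unit" if "unit" in df.columns else None)
    if unit_col is not None:
        units = [str(u) for u in df[unit_col]]
        df = df.drop(columns=[unit_col])
    else:
        units = [f"u{i}" for i in range(len(df))]
    if len(units) != len(set(units)):
        dupes = pd.Series(units)
        dupes = sorted(dupes[dupes.duplicated()].unique())
        raise ValueError(f"duplicate unit ids in column {unit_col!r}: {dupes}")

    if outcome_name not in df.columns:
        raise ValueError(f"missing outcome column {outcome_name!r}")

    keep = df[outcome_name].notna().to_numpy()
    if not keep.all():
        log.warning("dropping %d rows with missing outcome", (~keep).sum())
        df = df.loc[keep].reset_index(drop=True)
        units = [u for u, k in zip(units, keep) if k]

    raw_outcome = df[outcome_name]
    obs = raw_outcome.value_counts()
    if len(obs) != 2:
        raise ValueError(
            f"outcome not binary: column {outcome_name!r} has {len(obs)} observed levels"
        )
    # minority class -> 1 (ties broken toward the lexically larger label,
    # so numeric {0,1} keeps 1 as the event)
    lo, hi = sorted(obs.index, key=str)
    if obs[lo] < obs[hi]:
        event_label, nonevent_label = lo, hi
    else:
        event_label, nonevent_label = hi, lo
    outcome = (raw_outcome == event_label).to_numpy().astype(np.int8)

    features = df.drop(columns=[outcome_name])
    roles: dict[str, FeatureRole] = {}
    declared = {f["name"]: f for f in meta.get("features", [])}
    for name in features.columns:
        if name in declared:
            d = declared[name]
            outcomes = d.get("outcomes")
            roles[name] = FeatureRole(
                is_ekf=d.get("role", "non_ekf") == "ekf",
                phase=d.get("phase", "pre"),
                applicable_outcomes=frozenset(outcomes) if outcomes else None,
            )
        else:
            log.warning("feature %r absent from metadata; assuming non-EKF / pre", name)
            roles[name] = FeatureRole()

    levels = {}
    for name, lv in meta.get("levels", {}).items():
        if name in features.columns:
            features[name] = pd.Categorical(features[name].astype(type(lv[0])), categories=lv)
            levels[name] = list(lv)

    return FeatureTable(
        units=units,
        outcome_name=outcome_name,
        outcome=outcome,
        features=features,
        roles=roles,
        levels=levels,
        event_label=event_label,
        nonevent_label=nonevent_label,
    )


def write_cohort(table: FeatureTable, table_path, metadata_path) -> None:
    """Write a cohort and sidecar such that ``read_cohort`` round-trips it."""
    df = table.features.copy()
    out = np.where(table.outcome == 1, table.event_label, table.nonevent_label)
    df.insert(0, table.outcome_name, out)
    df.insert(0, "unit", table.units)
    df.to_csv(table_path, sep=_delimiter(table_path), index=False)

    meta = {
        "outcome": table.outcome_name,
        "unit": "unit",
        "features": [
            {
                "name": name,
                "role": "ekf" if role.is_ekf else "non_ekf",
                "phase": role.phase,
                **(
                    {"outcomes": sorted(role.applicable_outcomes)}
                    if role.applicable_outcomes is not None
                    else {}
                ),
            }
            for name, role in ((n, table.roles[n]) for n in table.features.columns)
        ],
        "levels": {k: list(v) for k, v in table.levels.items()},
    }
    with open(metadata_path, "w", encoding="utf-8") as fh:
        if str(metadata_path).endswith(".json"):
            json.dump(meta, fh, indent=1, default=_json_default)
        else:
            yaml.safe_dump(meta, fh, sort_keys=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


# ---------------------------------------------------------------------------
# views and discretization
# ---------------------------------------------------------------------------

def phase_view(table: FeatureTable, outcome: str, phase: str) -> FeatureTable:
    """Features applicable to (outcome, phase).

    The pre-treatment view keeps only pre-treatment features; the
    during-treatment view keeps both, so it is always a superset.
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    if outcome not in table.known_outcomes():
        raise ValueError(f"unknown outcome {outcome!r}; known: {sorted(table.known_outcomes())}")
    allowed = ("pre",) if phase == "pre" else PHASES
    keep = [
        f
        for f in table.features.columns
        if table.roles[f].phase in allowed and table.roles[f].applies_to(outcome)
    ]
    return table.subset_features(keep)


def _is_discrete(s: pd.Series) -> bool:
    if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object or s.dtype == bool:
        return True
    return s.dropna().nunique() <= 2


def _quantile_cuts(values: np.ndarray, bins: int) -> np.ndarray:
    qs = np.linspace(0, 1, bins + 1)[1:-1]
    return np.unique(np.quantile(values, qs))


def discretize(
    table: FeatureTable, spec: DiscretizationSpec | None = None, seed: int | None = None
) -> FeatureTable:
    """Map every continuous column to ordered categories.

    Deterministic given the data and spec (``seed`` is accepted for interface
    symmetry but unused — quantile cuts are a pure function of the data).
    Already-categorical and binary columns pass through. Columns whose cuts
    collapse fall back to fewer bins; columns collapsing to a single category
    are dropped with a warning. Missing feature cells are imputed by the
    column mode after binning.
    """
    spec = spec or DiscretizationSpec()
    out = {}
    levels: dict[str, list] = {}
    dropped = []
    for name in table.features.columns:
        s = table.features[name]
        if _is_discrete(s):
            if isinstance(s.dtype, pd.CategoricalDtype):
                cat = s
            else:
                obs = sorted(s.dropna().unique(), key=str)
                cat = pd.Categorical(s, categories=obs, ordered=True)
                cat = pd.Series(cat, index=s.index)
        else:
            vals = s.dropna().to_numpy(dtype=float)
            override = spec.overrides.get(name)
            if isinstance(override, list):
                cuts = np.asarray(override, dtype=float)
            else:
                sub = override or spec
                nbins = 2 if s.dropna().nunique() < 5 else sub.bins
                if sub.method == "fixed-bins":
                    cuts = np.linspace(vals.min(), vals.max(), nbins + 1)[1:-1]
                else:
                    cuts = _quantile_cuts(vals, nbins)
                cuts = np.unique(cuts)
            nbins_eff = len(cuts) + 1
            if nbins_eff < (2 if isinstance(override, list) else 2):
                dropped.append(name)
                log.warning("feature %r collapsed to one bin; dropped", name)
                continue
            binned = np.digitize(s.to_numpy(dtype=float), cuts, right=True)
            labels = [f"b{i + 1}" for i in range(nbins_eff)]
            codes = np.where(s.isna().to_numpy(), -1, binned)
            cat = pd.Series(
                pd.Categorical.from_codes(codes, categories=labels, ordered=True),
                index=s.index,
            )
        # mode imputation for missing cells
        if cat.isna().any():
            mode = cat.mode(dropna=True)
            if len(mode) == 0:
                dropped.append(name)
                continue
            cat = cat.fillna(mode.iloc[0])
            log.warning("feature %r: imputed missing cells by mode", name)
        if cat.nunique(dropna=True) < 2:
            dropped.append(name)
            log.warning("feature %r constant after discretization; dropped", name)
            continue
        # drop unobserved categories so CPT/CI cardinalities reflect the data
        cat = pd.Series(cat).cat.remove_unused_categories()
        out[name] = cat.reset_index(drop=True)
        levels[name] = list(out[name].cat.categories)

    features = pd.DataFrame(out, index=pd.RangeIndex(len(table.units)))
    roles = {n: table.roles[n] for n in features.columns}
    if dropped:
        warnings.warn(f"dropped {len(dropped)} degenerate feature(s): {dropped}")
    return FeatureTable(
        units=list(table.units),
        outcome_name=table.outcome_name,
        outcome=table.outcome.copy(),
        features=features,
        roles=roles,
        levels=levels,
        event_label=table.event_label,
        nonevent_label=table.nonevent_label,
    )
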