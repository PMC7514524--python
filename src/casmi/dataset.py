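"""Categorical data containers and preprocessing.

Everything downstream of this module sees data as purely categorical: every
cell is an opaque token compared by exact equality, with no ordinal
semantics.  Numeric columns enter the categorical world through
:func:`discretize`; sparse categorical columns can be merged with
:func:`regroup` to improve their sample coverage.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_TOKEN",
    "CategoricalTable",
    "FrequencyVector",
    "ContingencyTable",
    "BinningSpec",
    "read_table",
    "write_table",
    "compose_joint",
    "discretize",
    "coverage_report",
    "regroup",
]

MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class FrequencyVector:
    """Observed category -> count map for one (possibly joint) variable.

    Zero-count categories are never stored; ``n`` is the total number of
    observations and ``n1`` the number of singletons (categories seen
    exactly once), which drives the Turing coverage estimate.
    """

    counts: Mapping[object, int]

    def __post_init__(self):
        if not self.counts:
            raise ValueError("frequency vector is empty")
        for c in self.counts.values():
            if not isinstance(c, (int, np.integer)) or c < 1:
                raise ValueError(f"all counts must be positive integers, got {c!r}")

    @classmethod
    def from_labels(cls, labels: Sequence) -> "FrequencyVector":
        return cls(dict(Counter(labels)))

    @property
    def n(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n1(self) -> int:
        """Number of singletons."""
        return sum(1 for c in self.counts.values() if c == 1)

    @property
    def coverage(self) -> float:
        """Turing estimate of sample coverage, 1 - N1/n."""
        return 1.0 - self.n1 / self.n

    def counts_array(self) -> np.ndarray:
        return np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))


@dataclass(frozen=True)
class ContingencyTable:
    """Joint counts of a (possibly joint) feature against the outcome.

    ``K1`` and ``K2`` are the effective cardinalities: the numbers of
    distinct categories actually observed for the feature and the outcome.
    """

    joint_counts: Mapping[tuple, int]

    def __post_init__(self):
        if not self.joint_counts:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return int(sum(self.joint_counts.values()))

    @property
    def K1(self) -> int:
        return len({k[0] for k in self.joint_counts})

    @property
    def K2(self) -> int:
        return len({k[1] for k in self.joint_counts})

    def feature_margin(self) -> FrequencyVector:
        m: Counter = Counter()
        for (f, _), c in self.joint_counts.items():
            m[f] += c
        return FrequencyVector(dict(m))

    def outcome_margin(self) -> FrequencyVector:
        m: Counter = Counter()
        for (_, o), c in self.joint_counts.items():
            m[o] += c
        return FrequencyVector(dict(m))

    def joint_margin(self) -> FrequencyVector:
        return FrequencyVector(dict(self.joint_counts))


@dataclass
class CategoricalTable:
    """n observations of p categorical feature columns plus one outcome.

    Wraps a string-valued :class:`pandas.DataFrame`; tokens are opaque and
    compared by exact equality only.  Instances are treated as immutable:
    preprocessing operations return new tables.
    """

    data: pd.DataFrame
    outcome_name: str
    _codes: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.outcome_name not in self.data.columns:
            raise ValueError(f"outcome column {self.outcome_name!r} not in table")
        if len(self.data.columns) != len(set(self.data.columns)):
            raise ValueError("duplicate column names")
        # normalise every cell to a string token
        self.data = self.data.astype(str)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list:
        return [c for c in self.data.columns if c != self.outcome_name]

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"unknown column {name!r}")
        return self.data[name].to_numpy()

    def codes(self, name: str) -> tuple[np.ndarray, int]:
        """Integer codes (0..K-1) and effective cardinality K for a column.

        Cached; used by the estimator fast paths.  Codes index distinct
        tokens; the token order is irrelevant to every downstream quantity.
        """
        if name not in self._codes:
            codes, levels = pd.factorize(self.data[name].to_numpy())
            self._codes[name] = (codes.astype(np.int64), len(levels))
        return self._codes[name]

    def replace_column(self, name: str, values: Sequence) -> "CategoricalTable":
        df = self.data.copy()
        df[name] = [str(v) for v in values]
        return CategoricalTable(df, self.outcome_name)


def read_table(path, outcome: str, na_policy: str = "keep") -> CategoricalTable:
    """Read a CSV/TSV file with a header row into a :class:`CategoricalTable`.

    Missing cells (empty fields) are either kept as the category ``"NA"``
    (``na_policy="keep"``, the least-assumption remedy — it cannot create
    false associations) or their rows dropped (``na_policy="drop"``).
    """
    if na_policy not in ("keep", "drop"):
        raise ValueError(f"na_policy must be 'keep' or 'drop', got {na_policy!r}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[])
    if df.shape[1] == 0 or len(df) == 0:
        raise ValueError(f"empty table in {path}")
    if outcome not in df.columns:
        raise ValueError(f"outcome column {outcome!r} not found in {path}")
    missing = df == ""
    if na_policy == "drop":
        df = df[~missing.any(axis=1)]
        if len(df) == 0:
            raise ValueError("no rows remain after dropping rows with missing cells")
    else:
        df = df.mask(missing, MISSING_TOKEN)
    return CategoricalTable(df.reset_index(drop=True), outcome)


def write_table(table: CategoricalTable, path) -> None:
    """Write a table back to CSV/TSV (by suffix), preserving column order."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    table.data.to_csv(path, sep=sep, index=False)


def compose_joint(table: CategoricalTable, names: Sequence[str]) -> FrequencyVector:
    """Frequency vector of the joint feature over the given columns.

    Each observation's joint category is the tuple of its component tokens
    (never a string concatenation, which could collide).  A single name
    degenerates to the marginal frequency vector with plain tokens.
    """
    if not names:
        raise ValueError("empty name list")
    for nm in names:
        if nm not in table.data.columns:
            raise KeyError(f"unknown column {nm!r}")
        if nm == table.outcome_name:
            raise ValueError(f"{nm!r} is the outcome, not a feature")
    if len(names) == 1:
        return FrequencyVector.from_labels(table.column(names[0]))
    rows = zip(*(table.column(nm) for nm in names))
    return FrequencyVector.from_labels(list(rows))


@dataclass(frozen=True)
class BinningSpec:
    """How to discretize one numeric column.

    ``method`` is ``"quantile"`` (default: edges at empirical quantiles
    i/bin_count, which balances bin counts and protects sample coverage) or
    ``"equal-width"``.
    """

    column: str
    bin_count: int
    method: str = "quantile"

    def __post_init__(self):
        if self.method not in ("quantile", "equal-width"):
            raise ValueError(f"unknown binning method {self.method!r}")
        if self.bin_count < 2:
            raise ValueError("bin_count must be >= 2")


def discretize(table: CategoricalTable, spec: BinningSpec) -> CategoricalTable:
    """Replace a numeric column by bin-label tokens ``b0..b{k-1}``.

    Equal-width bins are left-closed/right-open with the last bin closed;
    quantile bins assign values tied with an edge to the lower bin.
    """
    raw = table.column(spec.column)
    try:
        vals = np.asarray([float(v) for v in raw])
    except ValueError as e:
        raise ValueError(f"column {spec.column!r} has non-numeric values: {e}") from None
    distinct = np.unique(vals)
    k = spec.bin_count
    if len(distinct) == 1:
        warnings.warn(f"column {spec.column!r} is constant; produced a single bin")
        return table.replace_column(spec.column, ["b0"] * len(vals))
    if k > len(distinct):
        warnings.warn(
            f"bin_count {k} exceeds the {len(distinct)} distinct values of "
            f"{spec.column!r}; reduced to {len(distinct)}"
        )
        k = len(distinct)
    if spec.method == "equal-width":
        edges = np.linspace(vals.min(), vals.max(), k + 1)[1:-1]
        idx = np.digitize(vals, edges, right=False)
    else:
        edges = np.quantile(vals, [i / k for i in range(1, k)])
        idx = np.searchsorted(edges, vals, side="left")
    return table.replace_column(spec.column, [f"b{i}" for i in idx])


def coverage_report(table: CategoricalTable) -> pd.DataFrame:
    """Estimated sample coverage (1 - N1/n) for every feature column.

    Columns with coverage below 0.5 are flagged: with most of the
    population mass unobserved, no reliable association can be estimated
    and regrouping (or dropping, for ID-like columns) is advisable.
    """
    rows = {}
    for nm in table.feature_names:
        fv = FrequencyVector.from_labels(table.column(nm))
        rows[nm] = {"coverage": fv.coverage, "flagged": fv.coverage < 0.5}
    return pd.DataFrame.from_dict(rows, orient="index")


def regroup(
    table: CategoricalTable, column: str, mapping: Mapping[str, str]
) -> CategoricalTable:
    """Relabel the categories of a column through ``mapping``.

    The mapping must cover every observed category.  Merging categories can
    only remove singletons, so the estimated coverage never decreases; this
    is asserted.
    """
    raw = table.column(column)
    observed = set(raw)
    missing = observed - set(mapping)
    if missing:
        raise ValueError(f"mapping misses observed categories: {sorted(missing)}")
    before = FrequencyVector.from_labels(raw).coverage
    out = table.replace_column(column, [mapping[v] for v in raw])
    after = FrequencyVector.from_labels(out.column(column)).coverage
    assert after >= before - 1e-12, "regrouping must not decrease coverage"
    return out
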