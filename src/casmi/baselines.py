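"""Classical entropic feature-selection criteria, for comparison.

Six widely used forward-greedy criteria built on plug-in mutual
information: MIM, JMI, CMIM, MRMR (difference form), DISR, and NJMIM.
They are exercised here purely as comparators: all of them estimate
entropies with the plug-in (maximum likelihood) estimator, which is the
convention in their original formulations, and all require the caller to
fix the number of features k.  The first feature is the plug-in MI argmax
for every criterion.  ``use_hz=True`` swaps in the bias-corrected entropy
estimator, off by default.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .dataset import CategoricalTable
from .estimators import _combine_codes, _entropy_plugin_counts, _entropy_z_counts

__all__ = ["BASELINE_NAMES", "baseline_select"]

BASELINE_NAMES = ("MIM", "JMI", "CMIM", "MRMR", "DISR", "NJMIM")


class _PluginMI:
    """Cached plug-in entropies/MIs over a table's coded columns."""

    def __init__(self, table: CategoricalTable, use_hz: bool = False):
        self.n = table.n
        self._H: Callable[[np.ndarray], float] = (
            _entropy_z_counts if use_hz else _entropy_plugin_counts
        )
        self.cols = {}
        for nm in table.feature_names:
            self.cols[nm] = table.codes(nm)
        self.y, self.ky = table.codes(table.outcome_name)
        self._cache: dict = {}

    def _entropy(self, codes: np.ndarray) -> float:
        _, counts = np.unique(codes, return_counts=True)
        return self._H(counts, self.n)

    def _joint(self, a, ka, b, kb):
        codes, counts = _combine_codes(a, ka, b, kb)
        return codes, len(counts)

    def H(self, *names, with_y: bool = False) -> float:
        key = (tuple(names), with_y)
        if key not in self._cache:
            codes, k = self.cols[names[0]]
            for nm in names[1:]:
                c2, k2 = self.cols[nm]
                codes, k = self._joint(codes, k, c2, k2)
            if with_y:
                codes, k = self._joint(codes, k, self.y, self.ky)
            self._cache[key] = self._entropy(codes)
        return self._cache[key]

    def Hy(self) -> float:
        if "y" not in self._cache:
            self._cache["y"] = self._entropy(self.y)
        return self._cache["y"]

    def mi_with_y(self, *names) -> float:
        return self.H(*names) + self.Hy() - self.H(*names, with_y=True)

    def mi_pair(self, a: str, b: str) -> float:
        codes, k = self._joint(*self.cols[a], *self.cols[b])
        return self.H(a) + self.H(b) - self._entropy(codes)


def baseline_select(
    table: CategoricalTable, method: str, k: int, use_hz: bool = False
) -> list[str]:
    """Select exactly ``k`` features with one of the six classical criteria.

    Greedy order is returned; argmax ties break toward the smallest
    original column index.
    """
    method = method.upper()
    if method not in BASELINE_NAMES:
        raise ValueError(f"unknown method {method!r}; choose from {BASELINE_NAMES}")
    feats = table.feature_names
    if not 0 < k <= len(feats):
        raise ValueError(f"k={k} must be in 1..{len(feats)}")
    est = _PluginMI(table, use_hz=use_hz)

    relevance = {nm: est.mi_with_y(nm) for nm in feats}
    if method == "MIM":
        ranked = sorted(feats, key=lambda nm: (-relevance[nm], feats.index(nm)))
        return ranked[:k]

    selected = [max(feats, key=lambda nm: (relevance[nm], -feats.index(nm)))]
    while len(selected) < k:
        remaining = [nm for nm in feats if nm not in selected]
        best, best_score = None, -np.inf
        for nm in remaining:
            if method == "JMI":
                score = sum(est.H(nm, j) + est.Hy() - est.H(nm, j, with_y=True) for j in selected)
            elif method == "CMIM":
                # I(X;Y|Xj) = I((X,Xj);Y) - I(Xj;Y); >= 0 for plug-in estimates
                terms = []
                for j in selected:
                    cmi = est.mi_with_y(nm, j) - est.mi_with_y(j)
                    assert cmi >= -1e-12, "plug-in conditional MI must be nonnegative"
                    terms.append(cmi)
                score = min(terms)
            elif method == "MRMR":
                score = relevance[nm] - sum(est.mi_pair(nm, j) for j in selected) / len(selected)
            elif method == "DISR":
                score = sum(
                    est.mi_with_y(nm, j) / est.H(nm, j, with_y=True) for j in selected
                )
            else:  # NJMIM
                score = min(
                    est.mi_with_y(nm, j) / est.H(nm, j, with_y=True) for j in selected
                )
            if score > best_score:
                best, best_score = nm, score
        selected.append(best)
    return selected
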