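"""Stage 2: greedy CASMI maximisation with automatic stopping.

The first feature is the single-candidate CASMI argmax; each later step
joins the current selection with every remaining candidate and keeps the
joint with the highest CASMI.  The algorithm stops as soon as the best
candidate fails to *strictly* increase the score: the score of the joint
feature already prices in redundancy (a redundant candidate adds no mutual
information but lowers coverage) and finite-sample noise (through the
bias-corrected estimator), so a non-increasing step signals that no
remaining feature adds usable information.  Ties in the argmax are broken
toward the smallest original column index, making the whole procedure
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import CategoricalTable
from .estimators import _combine_codes, _entropy_z_counts, _score_from_codes
from .screening import screen_all

__all__ = ["SelectionResult", "greedy_select", "select_features"]

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of a greedy CASMI selection.

    ``selected`` lists the chosen features in selection order and
    ``trajectory`` the CASMI score of the joint after each step; the first
    ``c`` entries are strictly increasing.  ``c`` is the automatic stopping
    index; entries beyond it (present only when a desired count d > c was
    requested) are listed in ``beyond_stop``.
    """

    selected: list
    trajectory: list
    survivors: list
    c: int
    u: float
    n: int
    alpha: Optional[float] = None
    beyond_stop: list = field(default_factory=list)
    stage1_pvalues: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "trajectory": [float(t) for t in self.trajectory],
            "survivors": list(self.survivors),
            "c": self.c,
            "u": self.u,
            "n": self.n,
            "alpha": self.alpha,
            "beyond_stop": list(self.beyond_stop),
            "stage1_pvalues": self.stage1_pvalues,
        }


def greedy_select(
    table: CategoricalTable,
    candidates: Sequence[str],
    u: float = 1.0,
    max_features: Optional[int] = None,
) -> SelectionResult:
    """Greedy joint-feature selection among ``candidates``.

    With ``max_features`` set, the greedy argmax keeps running past the
    automatic stop until that many features are selected (or truncates
    before it); the automatic stopping index is still reported as ``c``.

    An empty candidate list, or one where no single feature scores above
    zero, yields an empty selection with c = 0.
    """
    if u <= 0:
        raise ValueError("u must be positive")
    candidates = list(candidates)
    order = {nm: i for i, nm in enumerate(table.feature_names)}
    for nm in candidates:
        if nm not in order:
            raise KeyError(f"unknown feature {nm!r}")
    y_codes, ky = table.codes(table.outcome_name)
    _, y_counts = np.unique(y_codes, return_counts=True)
    hy = _entropy_z_counts(y_counts, table.n)
    if hy <= 0.0:
        raise ValueError("outcome is constant: it carries no information to predict")

    selected: list = []
    trajectory: list = []
    beyond: list = []
    cur_codes: Optional[np.ndarray] = None
    cur_k = 1
    cur_score = 0.0
    stopped = False
    c = 0
    remaining = sorted(candidates, key=order.__getitem__)
    limit = len(candidates) if max_features is None else min(max_features, len(candidates))

    while remaining and len(selected) < limit:
        best_name = None
        best_score = -np.inf
        best_codes = None
        for nm in remaining:  # original column order => deterministic tie-break
            codes, k = table.codes(nm)
            if cur_codes is not None:
                codes, counts = _combine_codes(cur_codes, cur_k, codes, k)
                k = len(counts)
            score, _, _ = _score_from_codes(codes, k, y_codes, ky, hy, u)
            if score > best_score:
                best_name, best_score, best_codes = nm, score, codes
        if not stopped and best_score <= cur_score:
            stopped = True
            c = len(selected)
            if best_score == cur_score:
                logger.info("stopping on an exact score tie at step %d", c + 1)
            if max_features is None:
                break
        selected.append(best_name)
        trajectory.append(best_score)
        if stopped:
            beyond.append(best_name)
        remaining.remove(best_name)
        cur_codes, cur_k = best_codes, int(best_codes.max()) + 1 if len(best_codes) else 1
        cur_score = best_score
    if not stopped:
        c = len(selected)
    return SelectionResult(
        selected=selected,
        trajectory=trajectory,
        survivors=list(candidates),
        c=c,
        u=u,
        n=table.n,
        beyond_stop=beyond,
    )


def select_features(
    table: CategoricalTable,
    alpha: float = 0.10,
    u: float = 1.0,
    d: Optional[int] = None,
) -> SelectionResult:
    """The full two-stage pipeline: independence screen, then greedy CASMI.

    ``d``, if given, overrides the automatic number of selected features:
    d < c truncates the greedy path, d > c keeps running the argmax past
    the automatic stop (those extra features are flagged in
    ``beyond_stop``).  The screen is run at level ``alpha``; the coverage
    exponent ``u`` affects only the selection scores, not the test.
    """
    results = screen_all(table, alpha)
    survivors = [r.feature for r in results if r.reject]
    if d is not None:
        if d > len(survivors):
            raise ValueError(
                f"requested {d} features but only {len(survivors)} survived stage 1"
            )
        if d == 0:
            res = SelectionResult(
                selected=[], trajectory=[], survivors=survivors, c=0, u=u, n=table.n
            )
            res.alpha = alpha
            res.stage1_pvalues = {r.feature: r.p_value for r in results}
            return res
    res = greedy_select(table, survivors, u=u, max_features=d)
    res.alpha = alpha
    res.stage1_pvalues = {r.feature: r.p_value for r in results}
    return res
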