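"""Stage 1: eliminate features independent of the outcome.

Under independence (MI = 0) the statistic 2n*MI_z + (K1-1)(K2-1) converges
in law to a chi-squared with (K1-1)(K2-1) degrees of freedom, where K1 and
K2 are the effective (observed) cardinalities of feature and outcome.  Each
feature is tested one-sidedly at level alpha (default 0.10; a smaller alpha
risks dropping useful features, a larger one keeps noise that slows the
selection stage).  No multiple-testing correction is applied across
features: the procedure is a per-feature level-alpha screen, and users with
large p can pass an adjusted alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .dataset import CategoricalTable
from .estimators import _entropy_z_counts

__all__ = ["IndependenceTestResult", "mi_z_independence_test", "stage1_filter", "screen_all"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndependenceTestResult:
    feature: str
    statistic: float
    df: int
    p_value: float
    reject: bool


def _test_codes(
    x_codes: np.ndarray, kx: int, y_codes: np.ndarray, ky: int, n: int, alpha: float
) -> tuple[float, int, float, bool]:
    _, cx = np.unique(x_codes, return_counts=True)
    _, cy = np.unique(y_codes, return_counts=True)
    _, cxy = np.unique(x_codes * np.int64(ky) + y_codes, return_counts=True)
    k1, k2 = len(cx), len(cy)
    df = (k1 - 1) * (k2 - 1)
    miz = (
        _entropy_z_counts(cx, n) + _entropy_z_counts(cy, n) - _entropy_z_counts(cxy, n)
    )
    stat = 2.0 * n * miz + df
    if df == 0:
        # a constant column cannot evidence dependence
        return stat, 0, 1.0, False
    p = float(chi2.sf(stat, df))
    return stat, df, p, p < alpha


def mi_z_independence_test(
    table: CategoricalTable, feature: str, alpha: float = 0.10
) -> IndependenceTestResult:
    """Chi-squared test of independence between one feature and the outcome.

    Tests H0: MI(X, Y) = 0 against MI > 0 with the bias-corrected mutual
    information statistic.  When either variable is constant the degrees of
    freedom are zero and the result is automatic non-rejection.
    """
    if feature not in table.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    x_codes, kx = table.codes(feature)
    y_codes, ky = table.codes(table.outcome_name)
    stat, df, p, rej = _test_codes(x_codes, kx, y_codes, ky, table.n, alpha)
    return IndependenceTestResult(feature, stat, df, p, rej)


def screen_all(table: CategoricalTable, alpha: float = 0.10) -> list[IndependenceTestResult]:
    """Independence test results for every feature, in column order."""
    return [mi_z_independence_test(table, nm, alpha) for nm in table.feature_names]


def stage1_filter(table: CategoricalTable, alpha: float = 0.10) -> list[str]:
    """Feature names surviving the independence screen, in column order.

    Redundant features all survive as long as each is marginally associated
    with the outcome; redundancy is handled later, by the joint-feature
    scoring of the selection stage.  An empty survivor list is legal.
    """
    survivors = []
    for res in screen_all(table, alpha):
        if res.reject:
            survivors.append(res.feature)
        else:
            logger.info(
                "stage 1 eliminated %s (p=%.4g, df=%d)", res.feature, res.p_value, res.df
            )
    return survivors
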