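"""Information-theoretic estimators.

Natural logarithms throughout; all entropies are in nats.

The package's scoring function is the coverage-adjusted standardized mutual
information

    kappa*(X, Y) = kappa_z(X, Y) * (1 - T1(X))**u,

where kappa_z = MI_z / H_z(Y) is standardized mutual information estimated
with a bias-corrected entropy estimator H_z, and 1 - T1 = 1 - N1/n is
Turing's estimate of the sample coverage of the feature.  H_z has an
exponentially decaying bias in n, against the 1/n (power-law) bias of the
plug-in estimator; the coverage factor suppresses features whose sample
reveals little of their population behaviour (ID-like columns score zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .dataset import CategoricalTable, ContingencyTable, FrequencyVector

__all__ = [
    "DiscreteDistribution",
    "CasmiScore",
    "entropy_pmf",
    "entropy_plugin",
    "entropy_z",
    "coverage_t1",
    "mi_z",
    "kappa_z",
    "casmi_score",
]


@dataclass(frozen=True)
class DiscreteDistribution:
    """A probability mass function with strictly positive atoms."""

    pmf: Mapping[object, float]

    def __post_init__(self):
        probs = np.fromiter(self.pmf.values(), dtype=float)
        if len(probs) == 0:
            raise ValueError("empty pmf")
        if (probs <= 0).any():
            raise ValueError("probabilities must be strictly positive")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"pmf sums to {probs.sum()!r}, not 1")

    def probs(self) -> np.ndarray:
        return np.fromiter(self.pmf.values(), dtype=float)


@dataclass(frozen=True)
class CasmiScore:
    """A CASMI score with its components retained for reporting."""

    kappa_z: float
    coverage: float
    u: float
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


# ---------------------------------------------------------------------------
# count-array fast paths (private)
# ---------------------------------------------------------------------------

def _as_counts(freq) -> np.ndarray:
    if isinstance(freq, FrequencyVector):
        return freq.counts_array()
    counts = np.asarray(freq)
    if counts.size == 0:
        raise ValueError("empty frequency vector")
    return counts.astype(np.int64)


def _entropy_plugin_counts(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _entropy_z_counts(counts: np.ndarray, n: int) -> float:
    """Bias-corrected entropy from a vector of positive category counts.

    The estimator is

        H_z = sum_{v=1}^{n-1} (1/v) w_v sum_k p_k prod_{j=0}^{v-1} (1 - p_k - j/n)

    with w_v = n^{1+v} (n-1-v)! / n!.  For a category with count f the
    weighted product telescopes to prod_{j<v} (n-f-j)/(n-1-j), which
    vanishes for v > n-f; this form never touches a factorial (n! overflows
    doubles near n=171) and is evaluated with one cumulative product per
    distinct count value.
    """
    if n <= 1:
        return 0.0
    uniq, mult = np.unique(counts[counts > 0], return_counts=True)
    denom = np.arange(n - 1, 0, -1, dtype=float)
    inv_v = 1.0 / np.arange(1, n, dtype=float)
    total = 0.0
    for f, m in zip(uniq, mult):
        length = int(n - f)
        if length <= 0:
            continue
        ratios = np.arange(length, 0, -1, dtype=float) / denom[:length]
        total += m * (f / n) * float(np.dot(np.cumprod(ratios), inv_v[:length]))
    return total


def _coverage_counts(counts: np.ndarray, n: int) -> float:
    return 1.0 - int((counts == 1).sum()) / n


def _combine_codes(a: np.ndarray, ka: int, b: np.ndarray, kb: int):
    """Compact integer codes and counts for the pairing of two coded columns."""
    _, codes, counts = np.unique(a * np.int64(kb) + b, return_inverse=True, return_counts=True)
    return codes.astype(np.int64), counts


def _score_from_codes(
    codes: np.ndarray,
    k: int,
    y_codes: np.ndarray,
    ky: int,
    hy: float,
    u: float,
) -> tuple[float, float, float]:
    """(score, kappa_z, coverage) of a coded joint feature against the outcome."""
    n = len(codes)
    _, counts = np.unique(codes, return_counts=True)
    hf = _entropy_z_counts(counts, n)
    cov = _coverage_counts(counts, n)
    _, joint_counts = np.unique(codes * np.int64(ky) + y_codes, return_counts=True)
    hfy = _entropy_z_counts(joint_counts, n)
    kz = (hf + hy - hfy) / hy
    kz = min(max(kz, 0.0), 1.0)
    return kz * cov**u, kz, cov


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def entropy_pmf(dist: Union[DiscreteDistribution, Mapping, Sequence]) -> float:
    """Shannon entropy -sum p ln p of a known distribution, in nats."""
    if isinstance(dist, DiscreteDistribution):
        p = dist.probs()
    elif isinstance(dist, Mapping):
        p = DiscreteDistribution(dist).probs()
    else:
        p = np.asarray(dist, dtype=float)
        if (p <= 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be positive and sum to 1")
    return float(-(p * np.log(p)).sum())


def entropy_plugin(freq: FrequencyVector) -> float:
    """Plug-in (maximum likelihood) entropy estimate from observed counts.

    Negatively biased, with bias of order (K-1)/(2n); fine for large
    samples, poor for small ones.
    """
    counts = _as_counts(freq)
    return _entropy_plugin_counts(counts, int(counts.sum()))


def entropy_z(freq: FrequencyVector) -> float:
    """Bias-corrected entropy estimate with exponentially decaying bias.

    Returns 0 for n = 1 (the sum over v is empty).  Always nonnegative.
    """
    counts = _as_counts(freq)
    return _entropy_z_counts(counts, int(counts.sum()))


def coverage_t1(freq: FrequencyVector) -> float:
    """Turing's formula T1 = N1/n, the estimated *uncovered* mass.

    The estimated sample coverage is ``1 - coverage_t1(freq)``.
    """
    counts = _as_counts(freq)
    return int((counts == 1).sum()) / int(counts.sum())


def mi_z(
    feature: FrequencyVector, outcome: FrequencyVector, joint: ContingencyTable
) -> float:
    """Bias-corrected mutual information H_z(X) + H_z(Y) - H_z(X,Y).

    The raw value is returned and may be slightly negative from estimator
    noise; the independence test needs the unclamped statistic, and
    clamping happens only inside :func:`kappa_z`.
    """
    n = feature.n
    if outcome.n != n or joint.n != n:
        raise ValueError(
            f"inconsistent sample sizes: feature {n}, outcome {outcome.n}, joint {joint.n}"
        )
    return (
        entropy_z(feature)
        + entropy_z(outcome)
        - _entropy_z_counts(joint.joint_margin().counts_array(), n)
    )


def kappa_z(
    feature: FrequencyVector, outcome: FrequencyVector, joint: ContingencyTable
) -> float:
    """Standardized mutual information MI_z / H_z(Y), clamped to [0, 1].

    The population quantity lives in [0, 1]; estimator excursions outside
    are noise.  A constant outcome is an error: it carries no information
    to predict, so standardizing by its entropy is meaningless.
    """
    hy = entropy_z(outcome)
    if hy <= 0.0:
        raise ValueError("outcome is constant: it carries no information to predict")
    val = mi_z(feature, outcome, joint) / hy
    return min(max(val, 0.0), 1.0)


def casmi_score(
    table: CategoricalTable, feature_names: Sequence[str], u: float = 1.0
) -> CasmiScore:
    """CASMI of the joint of ``feature_names`` against the table's outcome.

    ``u`` is the coverage exponent: the score is kappa_z * coverage**u,
    so u > 1 penalises poorly covered features harder and 0 < u < 1 more
    gently.  With coverage 1 the score equals kappa_z; an all-singleton
    (ID-like) joint feature scores exactly 0 whatever its kappa_z.
    """
    if u <= 0:
        raise ValueError("u must be positive")
    if not feature_names:
        raise ValueError("empty feature name list")
    y_codes, ky = table.codes(table.outcome_name)
    _, y_counts = np.unique(y_codes, return_counts=True)
    hy = _entropy_z_counts(y_counts, table.n)
    if hy <= 0.0:
        raise ValueError("outcome is constant: it carries no information to predict")
    codes, k = table.codes(feature_names[0])
    if feature_names[0] == table.outcome_name:
        raise ValueError("outcome cannot appear among the features")
    for nm in feature_names[1:]:
        if nm == table.outcome_name:
            raise ValueError("outcome cannot appear among the features")
        c2, k2 = table.codes(nm)
        combined, _ = _combine_codes(codes, k, c2, k2)
        codes, k = combined, int(combined.max()) + 1
    score, kz, cov = _score_from_codes(codes, k, y_codes, ky, hy, u)
    return CasmiScore(kappa_z=kz, coverage=cov, u=u, score=score)
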