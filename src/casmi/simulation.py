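"""Synthetic data generators used by the simulation studies.

Two generators are provided:

* a ten-feature categorical benchmark whose outcome depends nonlinearly on
  five relevant features, with one exactly redundant copy and four
  irrelevant features (:func:`generate_benchmark`), used for evaluating feature
  selection; and
* a 2000-category triangle distribution p_k = k/2001000
  (:func:`generate_triangle`), used for studying entropy-estimator bias.

The benchmark discretizes latent draws (three standard normals, two
Poisson(2), Binomial(4, 0.1), Binomial(6, 0.2), two Uniform(-1, 1) and one
Uniform(0, 1)) into small category sets and forms the outcome

    Y = X1 + X2 + X3^3 - 0.5*X4^2 + |X5| + X6 + eps,

where X6 is an exact copy of X4 (so X6 -- or equivalently X4 -- is
redundant) and eps is ternary noise taking -1, 0, 1 with probability 1/3
each.  X7..X10 are generated but never enter Y.  Everything is emitted as
category tokens: features with one decimal place, the outcome with three,
enough to keep mathematically distinct sums in distinct categories while
merging floating-point representations of equal sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import CategoricalTable, FrequencyVector

__all__ = ["SimConfig", "generate_benchmark", "generate_triangle", "triangle_pmf", "TRIANGLE_K"]

TRIANGLE_K = 2000

FEATURE_NAMES = tuple(f"X{i}" for i in range(1, 11))
OUTCOME_NAME = "Y"


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one benchmark draw."""

    n: int
    seed: Optional[int] = None
    include_outcome: bool = True

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _benchmark_numeric(n: int, rng: np.random.Generator) -> tuple[dict, np.ndarray]:
    """Latent draws -> numeric feature values and outcome.

    Indicator boundaries that overlap (measure-zero events for continuous
    latents) resolve in listed order, first match wins; latent ranges not
    covered by any indicator map to 0.
    """
    z1, z2, z3 = rng.standard_normal((3, n))
    po1 = rng.poisson(2.0, n)
    po2 = rng.poisson(2.0, n)
    b1 = rng.binomial(4, 0.1, n)
    b2 = rng.binomial(6, 0.2, n)
    u1 = rng.uniform(-1.0, 1.0, n)
    u2 = rng.uniform(-1.0, 1.0, n)
    u3 = rng.uniform(0.0, 1.0, n)

    x = {}
    x["X1"] = np.select(
        [z1 < -3, z1 <= -0.5, (z1 >= 0.5) & (z1 <= 3), z1 > 3],
        [-3.5, -1.4, 1.0, 2.2], 0.0,
    )
    x["X2"] = np.select(
        [po1 == 0, po1 == 1, (po1 == 3) | (po1 == 4), po1 >= 5],
        [-5.0, -3.0, 2.4, 5.4], 0.0,
    )
    x["X3"] = np.select(
        [u1 <= -0.6, u1 < -0.2, (u1 > 0.2) & (u1 < 0.6), u1 >= 0.6],
        [-2.0, -1.0, 1.0, 2.0], 0.0,
    )
    x["X4"] = np.where(b1 == 4, 5.0, b1 - 2.0)
    x["X5"] = np.select(
        [z2 < -0.5, z2 <= -0.2, z2 <= 0.2, z2 <= 0.6],
        [-2.5, -2.0, 1.7, 2.0], 4.0,
    )
    x["X6"] = x["X4"].copy()
    x["X7"] = np.where(po2 < 2, po2 - 2.0, 2.0)
    x["X8"] = np.select(
        [u2 <= -0.6, u2 < -0.2, (u2 > 0.2) & (u2 < 0.6), u2 >= 0.6],
        [-2.0, -1.0, 1.0, 2.0], 0.0,
    )
    x["X9"] = b2 - 1.2
    x["X10"] = np.select(
        [z3 < -1.5, z3 <= -0.7, (z3 >= 0.7) & (z3 <= 1.5), z3 > 1.5],
        [-2.0, -1.5, 1.5, 2.0], 0.0,
    )
    eps = np.select([u3 <= 1 / 3, u3 >= 2 / 3], [-1.0, 1.0], 0.0)
    y = x["X1"] + x["X2"] + x["X3"] ** 3 - 0.5 * x["X4"] ** 2 + np.abs(x["X5"]) + x["X6"] + eps
    return x, y


def _tokens(values: np.ndarray, decimals: int) -> np.ndarray:
    """Fixed-precision string tokens, formatting each distinct value once."""
    rounded = np.round(values, decimals) + 0.0  # +0.0 folds -0.0 into 0.0
    uniq, inv = np.unique(rounded, return_inverse=True)
    toks = np.array([f"{v:.{decimals}f}" for v in uniq])
    return toks[inv]


def generate_benchmark(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> CategoricalTable:
    """Draw the ten-feature benchmark as a :class:`CategoricalTable`.

    Deterministic under ``config.seed``; an explicit ``rng`` overrides the
    seed (used by experiment runners to hand out replicate substreams).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x, y = _benchmark_numeric(config.n, rng)
    cols = {nm: _tokens(x[nm], 1) for nm in FEATURE_NAMES}
    if not config.include_outcome:
        # covariates only, for users supplying their own outcome
        return pd.DataFrame(cols)
    cols[OUTCOME_NAME] = _tokens(y, 3)
    return CategoricalTable(pd.DataFrame(cols), OUTCOME_NAME)


def triangle_pmf() -> np.ndarray:
    """The triangle pmf p_k = k/2001000, k = 1..2000 (sums exactly to 1)."""
    k = np.arange(1, TRIANGLE_K + 1, dtype=float)
    return k / 2001000.0


def generate_triangle(
    n: int, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> FrequencyVector:
    """An iid sample of size n from the triangle distribution, as counts.

    The category alphabet is 1..2000; since the sample is iid, the count
    vector is one multinomial draw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, triangle_pmf())
    nz = np.nonzero(counts)[0]
    return FrequencyVector({int(i + 1): int(counts[i]) for i in nz})
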