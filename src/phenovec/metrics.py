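"""Pairwise (dis)similarity and significance statistics.

Hamming distance ``d`` counts differing positions between two binary
vectors; the Jaccard index ``J`` is the ratio of intersection over union of
their '1' positions.  With ``L`` the union count, ``J = (L - d) / L`` holds
whenever ``L > 0``.  Because weights repeat characters, all three are
weighted quantities on weighted vectors.

Two standardizations accompany a ranking:

* an *empirical* Z-score of each pair statistic against the distribution of
  that statistic over all patient-vs-reference pairs (sample standard
  deviation, ``n - 1`` denominator), with one-tailed normal p-values —
  lower tail for distance (smaller is better), upper tail for Jaccard;
* a *random-model* Z-score ``(d - L/2) / (sqrt(L)/2)`` for the distance,
  i.e. the standardization under a null in which each of the ``L``
  informative positions differs independently with probability 1/2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .encoder import EncodedVector

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairStats:
    """One pairwise comparison: union length, Hamming distance, Jaccard."""

    L: int
    d: int
    J: float


@dataclass(frozen=True)
class RankingContext:
    """Mean/sd of d and J over all patient-vs-reference pairs."""

    mu_d: float
    sigma_d: float
    mu_j: float
    sigma_j: float

    @classmethod
    def from_populations(
        cls, distances: Sequence[float], jaccards: Sequence[float]
    ) -> "RankingContext":
        return cls(
            mu_d=float(np.mean(distances)),
            sigma_d=float(np.std(distances, ddof=1)),
            mu_j=float(np.mean(jaccards)),
            sigma_j=float(np.std(jaccards, ddof=1)),
        )


def pair_stats(v1: EncodedVector, v2: EncodedVector) -> PairStats:
    """Weighted union length, Hamming distance and Jaccard index of a pair.

    Both vectors must be encoded against the same vocabulary and weights.
    ``J`` is defined as 1.0 for two all-zero vectors (nothing to disagree
    on).
    """
    if len(v1.bits) != len(v2.bits):
        raise ValueError(
            f"vector length mismatch: {len(v1.bits)} vs {len(v2.bits)} "
            "(encoded against different vocabularies or weights?)"
        )
    a = v1.as_array()
    b = v2.as_array()
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    d = union - inter
    return PairStats(L=union, d=d, J=inter / union if union else 1.0)


def z_rand(d: float, L: float) -> float:
    """Distance Z-score under the coin-flip null on the pair union.

    Each of the ``L`` positions where either vector is set differs with
    probability 1/2 under the null, so ``E[d] = L/2`` and
    ``sd(d) = sqrt(L)/2``; the statistic is ``(d - L/2) / (sqrt(L)/2)``,
    equivalently ``(2d - L)/sqrt(L)``.  Undefined (NaN) when ``L = 0``.
    """
    if L <= 0:
        log.warning("z_rand undefined for empty union (L=0)")
        return math.nan
    return (2.0 * d - L) / math.sqrt(L)


def empirical_z(x: float, population: Sequence[float]) -> float:
    """Standardize ``x`` against ``population`` (sample sd, n-1).

    A degenerate population (sd = 0) yields 0 when ``x`` equals the mean
    and signed infinity otherwise; both cases are logged.
    """
    if len(population) < 2:
        raise ValueError("empirical_z needs a population of size >= 2")
    mean = float(np.mean(population))
    sd = float(np.std(population, ddof=1))
    if sd == 0.0:
        log.warning("degenerate population (sd=0) in empirical_z")
        if x == mean:
            return 0.0
        return math.inf if x > mean else -math.inf
    return (x - mean) / sd


def p_from_z(z: float, tail: str = "lower") -> float:
    """One-tailed standard normal p-value of a Z-score.

    ``lower``: P(Z <= z), used for distances (small distance = small p).
    ``upper``: P(Z >= z), used for Jaccard (large index = small p).
    """
    if tail == "lower":
        return float(norm.cdf(z))
    if tail == "upper":
        return float(norm.sf(z))
    raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
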