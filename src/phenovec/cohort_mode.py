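"""Cohort mode: all-to-all comparison producing a square matrix.

All individuals (possibly from several cohorts, whose ids are then
prefixed) share one vocabulary built from the union of their keys, so every
vector has the same layout and the N x N matrix is exactly symmetric.  Note
the Hamming distance is unaffected by vocabulary padding: positions where
both vectors are 0 do not differ, so the full-vocabulary distance equals
the pair-union-restricted one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .encoder import EncodedVector, GlobalVocabulary, build_vocabulary, encode
from .exceptions import UsageError, ValidationError
from .flattener import FlatProfile, flatten_record
from .formats_io import FormatDescriptor, RawRecord, WeightSpec


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric table of pairwise Hamming distances (integers) or
    Jaccard indexes (floats), with one row/column per individual."""

    ids: list[str]
    values: np.ndarray
    metric: str = "hamming"


@dataclass(frozen=True)
class CohortEncoding:
    """Everything cohort mode derives before filling the matrix."""

    ids: list[str]
    profiles: list[FlatProfile]
    vocab: GlobalVocabulary
    vectors: list[EncodedVector]


def encode_cohorts(
    cohorts: Sequence[Sequence[RawRecord]],
    descriptor: FormatDescriptor,
    include_terms: Sequence[str] | None = None,
    exclude_terms: Sequence[str] | None = None,
    weights: WeightSpec | None = None,
    max_number_var: int | None = None,
    seed: int | None = None,
    prefixes: Sequence[str] | None = None,
) -> CohortEncoding:
    """Flatten, build one shared vocabulary, and encode every individual.

    With more than one cohort, ids are prefixed (``C1_``, ``C2_``, ... by
    default) to guarantee uniqueness across cohorts.
    """
    if not cohorts or not any(len(c) for c in cohorts):
        raise UsageError("at least one non-empty cohort is required")
    multi = len(cohorts) > 1
    if prefixes is not None and len(prefixes) != len(cohorts):
        raise UsageError("one id prefix per cohort is required")

    ids: list[str] = []
    profiles: list[FlatProfile] = []
    seen: set[str] = set()
    for c_idx, cohort in enumerate(cohorts):
        prefix = ""
        if multi:
            prefix = prefixes[c_idx] if prefixes is not None else f"C{c_idx + 1}_"
        for record in cohort:
            flat = flatten_record(record, descriptor, include_terms, exclude_terms)
            full_id = prefix + record.id
            if full_id in seen:
                raise ValidationError(f"duplicate id after prefixing: {full_id!r}")
            seen.add(full_id)
            ids.append(full_id)
            profiles.append(FlatProfile(id=full_id, keys=flat.keys))

    vocab = build_vocabulary(profiles, max_number_var=max_number_var, seed=seed)
    weights = weights or WeightSpec()
    vectors = [encode(p, vocab, weights) for p in profiles]
    return CohortEncoding(ids=ids, profiles=profiles, vocab=vocab, vectors=vectors)


def _pairwise(vectors: Sequence[EncodedVector], metric: str) -> np.ndarray:
    """All-pairs Hamming or Jaccard via Gram products on the 0/1 matrix."""
    X = np.stack([v.as_array() for v in vectors]).astype(np.int64)
    gram = X @ X.T                       # pairwise intersections
    ones = np.diag(gram)                 # per-individual weighted '1' count
    union = ones[:, None] + ones[None, :] - gram
    if metric == "hamming":
        return union - gram
    if metric == "jaccard":
        with np.errstate(invalid="ignore", divide="ignore"):
            jac = np.where(union > 0, gram / np.maximum(union, 1), 1.0)
        return jac
    raise UsageError(f"unknown metric {metric!r}; use 'hamming' or 'jaccard'")


def compare_cohort(
    cohorts: Sequence[Sequence[RawRecord]],
    descriptor: FormatDescriptor,
    include_terms: Sequence[str] | None = None,
    exclude_terms: Sequence[str] | None = None,
    weights: WeightSpec | None = None,
    max_number_var: int | None = None,
    seed: int | None = None,
    metric: str = "hamming",
    prefixes: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All-to-all comparison of one or more cohorts.

    Returns the symmetric N x N matrix of pairwise Hamming distances
    (default) or Jaccard indexes over a vocabulary shared by all
    individuals.
    """
    enc = encode_cohorts(
        cohorts,
        descriptor,
        include_terms=include_terms,
        exclude_terms=exclude_terms,
        weights=weights,
        max_number_var=max_number_var,
        seed=seed,
        prefixes=prefixes,
    )
    if len(enc.ids) < 2:
        raise UsageError("cohort mode needs at least 2 individuals")
    values = _pairwise(enc.vectors, metric)
    return DistanceMatrix(ids=enc.ids, values=values, metric=metric)


def count_clusters(matrix: DistanceMatrix) -> int:
    """Number of zero-distance equivalence classes in a Hamming matrix.

    Two individuals belong to the same cluster when their distance is 0;
    the count is the number of connected components of the zero-distance
    graph (for Hamming, d=0 is transitive, so components are cliques of
    identical vectors).
    """
    if matrix.metric != "hamming":
        raise UsageError("count_clusters requires a Hamming matrix")
    adjacency = csr_matrix(matrix.values == 0)
    n_components, _ = connected_components(adjacency, directed=False)
    return int(n_components)
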