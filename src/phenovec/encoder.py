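"""Global vocabulary construction and weighted one-hot encoding.

The vocabulary ("global hash") is the sorted union of variable keys over the
reference cohort(s); its order fixes the layout of every binary vector.
Each key occupies ``w`` consecutive positions, where ``w`` is its integer
weight (default 1): all ``'1'`` if the individual has the key, all ``'0'``
otherwise.  A profile key absent from the vocabulary is silently dropped,
which is exactly the projection used to compare a new patient against a
cohort encoded beforehand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .flattener import FlatProfile
from .formats_io import WeightSpec

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GlobalVocabulary:
    """Sorted unique variable keys of the reference cohort(s).

    ``coverage`` counts, per key, how many cohort individuals possess it;
    every key is observed at least once by construction.
    """

    keys: tuple[str, ...]
    index: dict[str, int]
    coverage: dict[str, int]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.keys)


@dataclass(frozen=True)
class EncodedVector:
    """Weighted one-hot binary vector of one individual.

    ``bits`` is the canonical string representation; ``present`` is the
    subset of vocabulary keys the individual has.
    """

    id: str
    bits: str
    present: frozenset[str]

    def as_array(self) -> np.ndarray:
        """Boolean numpy view of ``bits``."""
        return np.frombuffer(self.bits.encode("ascii"), dtype=np.uint8) == ord("1")


def build_vocabulary(
    profiles: Sequence[FlatProfile],
    max_number_var: int | None = None,
    seed: int | None = None,
) -> GlobalVocabulary:
    """Union of all profile keys, byte-wise lexicographically sorted.

    When ``max_number_var`` is smaller than the union size, a uniform
    random subset of exactly that many keys is drawn with ``seed`` (then
    sorted).  Subsetting caps the vector length for very wide data, e.g.
    when genomic variables push the key count past 10,000.
    """
    coverage: dict[str, int] = {}
    for profile in profiles:
        for key in profile.keys:
            coverage[key] = coverage.get(key, 0) + 1
    if not coverage:
        raise ValidationError("no variables to compare (all profiles are empty)")
    keys = sorted(coverage)
    if max_number_var is not None:
        if max_number_var < 1:
            raise ValidationError("max_number_var must be >= 1")
        if max_number_var < len(keys):
            if seed is None:
                seed = int(np.random.default_rng().integers(2**31))
                log.warning("max-number-var subsetting with random seed %d", seed)
            rng = np.random.default_rng(seed)
            chosen = rng.choice(len(keys), size=max_number_var, replace=False)
            keys = sorted(keys[i] for i in chosen)
            coverage = {k: coverage[k] for k in keys}
    return GlobalVocabulary(
        keys=tuple(keys),
        index={k: i for i, k in enumerate(keys)},
        coverage=coverage,
    )


def encode(
    profile: FlatProfile,
    vocab: GlobalVocabulary,
    weights: WeightSpec | None = None,
) -> EncodedVector:
    """One-hot encode ``profile`` over ``vocab`` with optional weights."""
    weights = weights or WeightSpec()
    present = frozenset(k for k in profile.keys if k in vocab.index)
    bits = "".join(
        ("1" if k in present else "0") * weights.get(k) for k in vocab.keys
    )
    return EncodedVector(id=profile.id, bits=bits, present=present)


def encoded_length(vocab: GlobalVocabulary, weights: WeightSpec | None = None) -> int:
    """Total vector length: sum of key weights over the vocabulary."""
    weights = weights or WeightSpec()
    return sum(weights.get(k) for k in vocab.keys)


def export_intermediates(
    vocab: GlobalVocabulary,
    vectors: Sequence[EncodedVector],
    directory: str | Path,
) -> None:
    """Write vocabulary coverage, per-individual key sets, and binary
    vectors as JSON files into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "vocabulary.json").write_text(
        json.dumps(
            {"keys": list(vocab.keys), "coverage": vocab.coverage},
            indent=2,
            sort_keys=True,
        ),
        encoding="utf-8",
    )
    (directory / "key_sets.json").write_text(
        json.dumps(
            {v.id: sorted(v.present) for v in vectors}, indent=2, sort_keys=True
        ),
        encoding="utf-8",
    )
    (directory / "vectors.json").write_text(
        json.dumps({v.id: v.bits for v in vectors}, indent=2, sort_keys=True),
        encoding="utf-8",
    )


def load_vectors(directory: str | Path) -> list[EncodedVector]:
    """Reload vectors written by :func:`export_intermediates`."""
    directory = Path(directory)
    bits = json.loads((directory / "vectors.json").read_text(encoding="utf-8"))
    sets = json.loads((directory / "key_sets.json").read_text(encoding="utf-8"))
    return [
        EncodedVector(id=i, bits=b, present=frozenset(sets.get(i, ())))
        for i, b in bits.items()
    ]
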