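"""Flatten one hierarchical record into a set of variable keys.

Each scalar leaf becomes one variable key: the dotted path from the record
root down to the leaf, followed by the stringified leaf value, e.g.
``sex.id.NCIT:C20197``.  Because the value is part of the key, presence of a
key in two individuals means they share both the variable *and* its value —
exact-match semantics, with no ontology-aware or fuzzy matching.

For terms holding arrays of objects (``phenotypicFeatures``,
``diseases``, ...) the positional index of each element is replaced by the
CURIE found at the element's configured identifier path, so element order
never influences the keys:

    {"phenotypicFeatures": [{"featureType": {"id": "HP:0000118"}}]}
        -> phenotypicFeatures.HP:0000118.featureType.id.HP:0000118

CURIEs contain ``:`` and never ``.``, so the dot separator is unambiguous.
Keys matching the descriptor's exclusion patterns (record id, ``label``
leaves, free text, timestamps, ...) are dropped before encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fnmatch import fnmatchcase
from typing import Any, Iterable, Mapping, Sequence

from .exceptions import UsageError, ValidationError
from .formats_io import FormatDescriptor, RawRecord, _get_path

log = logging.getLogger(__name__)

#: Patterns applied to every dialect: ontology ``label`` leaves duplicate
#: the information carried by their ``id`` sibling, free-text and
#: date/timestamp leaves carry no comparable signal.
_COMMON_EXCLUSIONS: tuple[str, ...] = (
    "**.label",
    "**.description",
    "**.notes",
    "**.date*",
    "**.*Date*",
    "**.timestamp*",
)


def default_exclusions(format_name: str, id_path: str = "id") -> list[str]:
    """Built-in drop list of path patterns for a record dialect.

    The record identifier never contributes to similarity.  For ``pxf``,
    ``metaData`` (provenance) and ``files`` (attachments) are dropped as
    well.  ``generic`` drops only the configured id path; everything else is
    the caller's choice.
    """
    if format_name == "bff":
        return [id_path, *_COMMON_EXCLUSIONS]
    if format_name == "pxf":
        return [id_path, "metaData", "files", *_COMMON_EXCLUSIONS]
    if format_name == "generic":
        return [id_path]
    raise ValidationError(f"unknown format {format_name!r}")


@dataclass(frozen=True)
class FlatProfile:
    """The set of flattened variable keys representing one individual."""

    id: str
    keys: frozenset[str]


def _canon_scalar(value: Any) -> str | None:
    """Canonical string form of a leaf value; None for missing values."""
    if value is None:
        return None
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        # no trailing zeros, stable across platforms
        return format(value, ".12g")
    return str(value)


def _pattern_match(pattern: Sequence[str], path: Sequence[str]) -> bool:
    """Prefix-match glob segments against a path; ``**`` spans segments."""
    if not pattern:
        return True
    if pattern[0] == "**":
        return any(
            _pattern_match(pattern[1:], path[i:]) for i in range(len(path) + 1)
        )
    if not path:
        return False
    return fnmatchcase(path[0], pattern[0]) and _pattern_match(
        pattern[1:], path[1:]
    )


def _excluded(path: Sequence[str], patterns: Iterable[Sequence[str]]) -> bool:
    return any(_pattern_match(p, path) for p in patterns)


def flatten_record(
    record: RawRecord,
    descriptor: FormatDescriptor,
    include_terms: Sequence[str] | None = None,
    exclude_terms: Sequence[str] | None = None,
) -> FlatProfile:
    """Flatten ``record`` into a :class:`FlatProfile`.

    ``include_terms`` restricts flattening to the named top-level terms;
    ``exclude_terms`` drops the named terms.  The two are mutually
    exclusive.  Duplicate keys collapse (presence/absence semantics).
    """
    if include_terms and exclude_terms:
        raise UsageError("include_terms and exclude_terms are mutually exclusive")
    allowed = descriptor.allowed_terms
    for term in list(include_terms or []) + list(exclude_terms or []):
        if allowed and term not in allowed:
            raise ValidationError(
                f"unknown term {term!r}; allowed terms: {', '.join(allowed)}"
            )

    patterns = [p.split(".") for p in descriptor.exclude_paths]
    id_pattern = descriptor.id_path.split(".")
    if id_pattern not in patterns:
        patterns.append(id_pattern)

    body = record.body
    if not isinstance(body, Mapping):
        raise ValidationError(f"record {record.id!r}: body is not a mapping")

    keys: set[str] = set()

    def leaf(path: list[str], value: Any) -> None:
        text = _canon_scalar(value)
        if text is None:
            return
        if _excluded(path, patterns):
            return
        keys.add(".".join([*path, text]))

    def walk(node: Any, path: list[str], term: str) -> None:
        if isinstance(node, Mapping):
            for k, v in node.items():
                walk(v, [*path, str(k)], term)
        elif isinstance(node, (list, tuple)):
            id_rel = descriptor.array_id_paths.get(term) if len(path) == 1 else None
            for i, el in enumerate(node):
                if isinstance(el, Mapping):
                    seg = None
                    if id_rel is not None:
                        curie = _get_path(el, id_rel)
                        if curie is not None:
                            seg = str(curie)
                        else:
                            log.warning(
                                "record %s: %s[%d] lacks an id at %r; "
                                "falling back to the positional index",
                                record.id,
                                term,
                                i,
                                id_rel,
                            )
                    walk(el, [*path, seg if seg is not None else str(i)], term)
                elif isinstance(el, (list, tuple)):
                    walk(el, [*path, str(i)], term)
                else:
                    # scalar array elements are a value set; no index segment
                    leaf(path, el)
        else:
            leaf(path, node)

    for term, node in body.items():
        term = str(term)
        if allowed and term not in allowed:
            log.debug("record %s: skipping unknown term %r", record.id, term)
            continue
        if include_terms is not None and term not in include_terms:
            continue
        if exclude_terms and term in exclude_terms:
            continue
        walk(node, [term], term)

    return FlatProfile(id=record.id, keys=frozenset(keys))
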