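"""Input/output for cohorts, descriptors, weights and result tables.

Cohort files are JSON or YAML (sniffed by content, not extension) holding an
array of hierarchical individual records.  Two record dialects are built in:

* ``bff`` — the GA4GH Beacon v2 ``individuals`` entity serialized as the
  Beacon Friendly Format, with twelve top-level terms.
* ``pxf`` — GA4GH Phenopacket v2 records (Phenotype Exchange Format), with
  ten top-level terms.

Arbitrary JSON/YAML is handled through a user-supplied
:class:`FormatDescriptor` (``generic``).  All output tables are UTF-8 TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, TYPE_CHECKING

import yaml

from .exceptions import FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_mode import DistanceMatrix
    from .patient_mode import RankRow

log = logging.getLogger(__name__)

#: Top-level terms of the Beacon v2 ``individuals`` entity.  Some producers
#: spell the karyotype term ``karyotipicSex``, others ``karyotypicSex``;
#: both are accepted.
BFF_TERMS: tuple[str, ...] = (
    "diseases",
    "ethnicity",
    "exposures",
    "geographicOrigin",
    "id",
    "interventionsOrProcedures",
    "karyotipicSex",
    "karyotypicSex",
    "measures",
    "pedigrees",
    "phenotypicFeatures",
    "sex",
    "treatments",
)

#: Top-level terms of a Phenopacket v2 record.
PXF_TERMS: tuple[str, ...] = (
    "id",
    "subject",
    "phenotypicFeatures",
    "measurements",
    "biosamples",
    "interpretations",
    "diseases",
    "medicalActions",
    "files",
    "metaData",
)

# Relative path (within an array element) of the CURIE used to key that
# element during flattening.
_BFF_ARRAY_ID_PATHS: dict[str, str] = {
    "diseases": "diseaseCode.id",
    "exposures": "exposureCode.id",
    "interventionsOrProcedures": "procedureCode.id",
    "measures": "assayCode.id",
    "phenotypicFeatures": "featureType.id",
    "treatments": "treatmentCode.id",
}

_PXF_ARRAY_ID_PATHS: dict[str, str] = {
    "phenotypicFeatures": "type.id",
    "diseases": "term.id",
    "measurements": "assay.id",
    "medicalActions": "treatment.agent.id",
}


@dataclass(frozen=True)
class RawRecord:
    """One parsed hierarchical individual record.

    ``body`` is the record's key-value tree exactly as parsed; it must
    round-trip through serialization unchanged.
    """

    id: str
    body: Mapping[str, Any]


@dataclass
class FormatDescriptor:
    """Tells the flattener how to interpret one record dialect.

    Parameters
    ----------
    format_name
        ``bff``, ``pxf`` or ``generic``.
    id_path
        Dotted path to the record identifier (never contributes to
        similarity).
    allowed_terms
        Top-level term names the dialect defines; empty means "accept any".
    array_id_paths
        Term name -> relative dotted path of the CURIE identifying each
        element of that term's array.
    exclude_paths
        Glob-style dotted path patterns dropped before encoding (``**``
        matches any run of path segments, ``*`` one segment).
    """

    format_name: str
    id_path: str = "id"
    allowed_terms: tuple[str, ...] = ()
    array_id_paths: dict[str, str] = field(default_factory=dict)
    exclude_paths: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for term in self.array_id_paths:
            if self.allowed_terms and term not in self.allowed_terms:
                raise ValidationError(
                    f"array_id_paths term {term!r} is not an allowed term"
                )

    def to_dict(self) -> dict[str, Any]:
        return {
            "format_name": self.format_name,
            "id_path": self.id_path,
            "allowed_terms": list(self.allowed_terms),
            "array_id_paths": dict(self.array_id_paths),
            "exclude_paths": list(self.exclude_paths),
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "FormatDescriptor":
        return cls(
            format_name=str(data.get("format_name", "generic")),
            id_path=str(data.get("id_path", "id")),
            allowed_terms=tuple(data.get("allowed_terms", ()) or ()),
            array_id_paths=dict(data.get("array_id_paths", {}) or {}),
            exclude_paths=tuple(data.get("exclude_paths", ()) or ()),
        )


@dataclass(frozen=True)
class WeightSpec:
    """Positive integer weight per variable key; unlisted keys weigh 1.

    A weight *w* repeats the variable's character *w* times in the binary
    vector, so a mismatch on that variable contributes *w* to the Hamming
    distance and to the pair union length.
    """

    weights: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, w in self.weights.items():
            if isinstance(w, bool) or not isinstance(w, int) or w < 1:
                raise ValidationError(
                    f"weight for {key!r} must be an integer >= 1, got {w!r}"
                )

    def get(self, key: str) -> int:
        return self.weights.get(key, 1)


def builtin_descriptor(format_name: str) -> FormatDescriptor:
    """Return the built-in descriptor for ``bff`` or ``pxf``."""
    from .flattener import default_exclusions

    if format_name == "bff":
        return FormatDescriptor(
            format_name="bff",
            id_path="id",
            allowed_terms=BFF_TERMS,
            array_id_paths=dict(_BFF_ARRAY_ID_PATHS),
            exclude_paths=tuple(default_exclusions("bff")),
        )
    if format_name == "pxf":
        return FormatDescriptor(
            format_name="pxf",
            id_path="id",
            allowed_terms=PXF_TERMS,
            array_id_paths=dict(_PXF_ARRAY_ID_PATHS),
            exclude_paths=tuple(default_exclusions("pxf")),
        )
    raise ValidationError(
        f"unknown built-in format {format_name!r}; use 'bff' or 'pxf', "
        "or supply a descriptor for generic data"
    )


def load_descriptor(path: str | Path) -> FormatDescriptor:
    """Load a generic-format descriptor from a YAML/JSON file."""
    data = _parse_text(Path(path))
    if not isinstance(data, Mapping):
        raise FormatError(f"{path}: descriptor must be a mapping")
    desc = FormatDescriptor.from_dict(data)
    if not desc.exclude_paths:
        # the id must never contribute to similarity
        desc.exclude_paths = (desc.id_path,)
    return desc


def _parse_text(path: Path) -> Any:
    """Parse a file as JSON, falling back to YAML (content sniffing)."""
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    try:
        return json.loads(text)
    except json.JSONDecodeError as json_exc:
        try:
            return yaml.safe_load(text)
        except yaml.YAMLError as yaml_exc:
            mark = getattr(yaml_exc, "problem_mark", None)
            where = (
                f"line {mark.line + 1}, column {mark.column + 1}"
                if mark is not None
                else f"line {json_exc.lineno}, column {json_exc.colno}"
            )
            raise FormatError(
                f"{path}: not parseable as JSON or YAML (near {where})"
            ) from yaml_exc


def _get_path(tree: Any, dotted: str) -> Any:
    """Fetch a dotted path from a nested mapping; None when absent."""
    node = tree
    for seg in dotted.split("."):
        if not isinstance(node, Mapping) or seg not in node:
            return None
        node = node[seg]
    return node


def load_cohort(path: str | Path, descriptor: FormatDescriptor) -> list[RawRecord]:
    """Read a cohort file into a list of :class:`RawRecord`.

    A single top-level object (one patient) is promoted to a one-record
    cohort.  Input order is preserved.  Missing or duplicate identifiers
    raise :class:`ValidationError` naming the offending record index.
    """
    path = Path(path)
    data = _parse_text(path)
    if isinstance(data, Mapping):
        data = [data]
    if data is None:
        data = []
    if not isinstance(data, list):
        raise FormatError(f"{path}: top level must be an array of objects")
    records: list[RawRecord] = []
    seen: dict[str, int] = {}
    for i, obj in enumerate(data):
        if not isinstance(obj, Mapping):
            raise ValidationError(f"{path}: element {i} is not an object")
        rid = _get_path(obj, descriptor.id_path)
        if rid is None or str(rid) == "":
            raise ValidationError(
                f"{path}: record {i} has no id at path {descriptor.id_path!r}"
            )
        rid = str(rid)
        if rid in seen:
            raise ValidationError(
                f"{path}: duplicate id {rid!r} at index {i} "
                f"(first seen at index {seen[rid]})"
            )
        seen[rid] = i
        records.append(RawRecord(id=rid, body=obj))
    if not records:
        log.warning("%s: empty cohort", path)
    return records


def load_weights(path: str | Path) -> WeightSpec:
    """Read a variable-key -> positive-integer weights file (YAML/JSON)."""
    data = _parse_text(Path(path))
    if data is None:
        return WeightSpec()
    if not isinstance(data, Mapping):
        raise FormatError(f"{path}: weights file must be a mapping")
    return WeightSpec(weights={str(k): v for k, v in data.items()})


# ---------------------------------------------------------------------------
# output tables

#: Column order of the patient-mode ranking table.
RANK_COLUMNS: tuple[str, ...] = (
    "Reference(ID)",
    "Length",
    "Hamming-distance",
    "Distance-Z-score",
    "Distance-P-value",
    "Distance-Z-score(rand)",
    "Jaccard-index",
    "Jaccard-Z-score",
    "Jaccard-P-value",
)


def _fmt_float(x: float, places: int) -> str:
    import math

    if math.isnan(x):
        return "NaN"
    if math.isinf(x):
        return "Inf" if x > 0 else "-Inf"
    return f"{x:.{places}f}"


def write_rank_table(rows: list["RankRow"], path: str | Path) -> None:
    """Write a patient-mode ranking to TSV.

    Z-scores are printed to 3 decimals (the random-model Z to 4), p-values
    to 7 and the Jaccard index to 3.
    """
    path = Path(path)
    lines = ["\t".join(RANK_COLUMNS)]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.reference_id,
                    str(r.L),
                    str(r.d),
                    _fmt_float(r.z_d, 3),
                    _fmt_float(r.p_d, 7),
                    _fmt_float(r.z_rand_d, 4),
                    _fmt_float(r.J, 3),
                    _fmt_float(r.z_j, 3),
                    _fmt_float(r.p_j, 7),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_matrix(matrix: "DistanceMatrix", path: str | Path) -> None:
    """Write a square (dis)similarity matrix to TSV.

    First row and first column carry the individual ids.  Hamming entries
    are integers; Jaccard entries are printed to 6 decimals.
    """
    path = Path(path)
    is_int = matrix.metric == "hamming"
    lines = ["\t".join(["id", *matrix.ids])]
    for rid, row in zip(matrix.ids, matrix.values):
        cells = [str(int(v)) if is_int else f"{float(v):.6f}" for v in row]
        lines.append("\t".join([rid, *cells]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_matrix(path: str | Path) -> "DistanceMatrix":
    """Read a TSV matrix written by :func:`write_matrix`."""
    import pandas as pd

    from .cohort_mode import DistanceMatrix

    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy()
    metric = "hamming" if frame.dtypes.apply(
        lambda t: t.kind in "iu"
    ).all() else "jaccard"
    ids = [str(c) for c in frame.columns]
    if ids != [str(i) for i in frame.index]:
        raise ValidationError(f"{path}: row and column ids differ")
    return DistanceMatrix(ids=ids, values=values, metric=metric)
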