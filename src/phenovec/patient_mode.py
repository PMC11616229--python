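"""Patient mode: rank one target record against reference cohort(s).

The vocabulary is built from the reference cohort(s) only; encoding the
patient against it silently drops patient-unique variables (the
projection), so rankings can be computed against cohorts whose vectors
were produced beforehand.  Each reference yields one row with the pair
union length L, the Hamming distance d, the Jaccard index J, empirical
Z-scores and one-tailed normal p-values for d and J (standardized over the
patient's comparisons to *all* references, self-comparison never
included), and the random-model distance Z.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .cohort_mode import CohortEncoding, encode_cohorts
from .encoder import EncodedVector, GlobalVocabulary, encode
from .exceptions import UsageError, ValidationError
from .flattener import flatten_record
from .formats_io import FormatDescriptor, RawRecord, WeightSpec
from .metrics import RankingContext, empirical_z, p_from_z, pair_stats, z_rand


@dataclass(frozen=True)
class RankRow:
    """One patient-vs-reference result row."""

    reference_id: str
    L: int
    d: int
    z_d: float
    p_d: float
    z_rand_d: float
    J: float
    z_j: float
    p_j: float


@dataclass(frozen=True)
class PatientComparison:
    """Full patient-mode result: all rows plus the encodings behind them."""

    rows: list[RankRow]          # all references, sorted
    patient: EncodedVector
    references: list[EncodedVector]
    vocab: GlobalVocabulary
    weights: WeightSpec


def compare_patient(
    patient: RawRecord,
    cohorts: Sequence[Sequence[RawRecord]],
    descriptor: FormatDescriptor,
    include_terms: Sequence[str] | None = None,
    exclude_terms: Sequence[str] | None = None,
    weights: WeightSpec | None = None,
    max_number_var: int | None = None,
    seed: int | None = None,
    sort_by: str = "hamming",
) -> PatientComparison:
    """Compare ``patient`` with every reference individual.

    Rows are sorted ascending by distance (``sort_by='hamming'``, the
    default) or descending by Jaccard; ties break by descending J, then by
    ascending reference id — stable and deterministic.
    """
    if sort_by not in ("hamming", "jaccard"):
        raise UsageError(f"sort_by must be 'hamming' or 'jaccard', got {sort_by!r}")
    enc: CohortEncoding = encode_cohorts(
        cohorts,
        descriptor,
        include_terms=include_terms,
        exclude_terms=exclude_terms,
        weights=weights,
        max_number_var=max_number_var,
        seed=seed,
    )
    if len(enc.ids) < 2:
        raise UsageError(
            "patient mode needs a reference cohort of >= 2 individuals "
            "(the empirical Z-score needs a population)"
        )
    weights = weights or WeightSpec()
    flat = flatten_record(patient, descriptor, include_terms, exclude_terms)
    pvec = encode(flat, enc.vocab, weights)
    if not pvec.present:
        raise ValidationError(
            f"patient {patient.id!r} shares no variables with the cohort"
        )

    stats = [pair_stats(pvec, ref) for ref in enc.vectors]
    distances = [float(s.d) for s in stats]
    jaccards = [float(s.J) for s in stats]
    ctx = RankingContext.from_populations(distances, jaccards)

    def _z(x: float, mu: float, sigma: float, sample: Sequence[float]) -> float:
        if sigma == 0.0:
            return empirical_z(x, sample)  # degenerate-population handling
        return (x - mu) / sigma

    rows = []
    for rid, s in zip(enc.ids, stats):
        z_d = _z(s.d, ctx.mu_d, ctx.sigma_d, distances)
        z_j = _z(s.J, ctx.mu_j, ctx.sigma_j, jaccards)
        rows.append(
            RankRow(
                reference_id=rid,
                L=s.L,
                d=s.d,
                z_d=z_d,
                p_d=p_from_z(z_d, "lower"),
                z_rand_d=z_rand(s.d, s.L),
                J=s.J,
                z_j=z_j,
                p_j=p_from_z(z_j, "upper"),
            )
        )
    if sort_by == "hamming":
        rows.sort(key=lambda r: (r.d, -r.J, r.reference_id))
    else:
        rows.sort(key=lambda r: (-r.J, r.d, r.reference_id))
    return PatientComparison(
        rows=rows,
        patient=pvec,
        references=enc.vectors,
        vocab=enc.vocab,
        weights=weights,
    )


def rank_patient(
    patient: RawRecord,
    cohorts: Sequence[Sequence[RawRecord]],
    descriptor: FormatDescriptor,
    include_terms: Sequence[str] | None = None,
    exclude_terms: Sequence[str] | None = None,
    weights: WeightSpec | None = None,
    max_number_var: int | None = None,
    seed: int | None = None,
    sort_by: str = "hamming",
    top_n: int | None = 10,
) -> list[RankRow]:
    """Rank the references most similar to ``patient``.

    Returns the first ``top_n`` rows (default 10; ``None`` for all) of the
    sorted ranking produced by :func:`compare_patient`.
    """
    comparison = compare_patient(
        patient,
        cohorts,
        descriptor,
        include_terms=include_terms,
        exclude_terms=exclude_terms,
        weights=weights,
        max_number_var=max_number_var,
        seed=seed,
        sort_by=sort_by,
    )
    rows = comparison.rows
    return rows if top_n is None else rows[:top_n]


def export_alignment(
    comparison: PatientComparison,
    directory: str | Path,
    top_n: int | None = 10,
) -> None:
    """Write per-reference alignment files.

    For each ranked reference, one text table lists every key in the pair
    union with its weight, a patient mark, a reference mark, and a
    match/mismatch indicator; a trailing summary line repeats (L, d, J).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_id = {v.id: v for v in comparison.references}
    rows = comparison.rows if top_n is None else comparison.rows[:top_n]
    for row in rows:
        ref = by_id[row.reference_id]
        union = sorted(comparison.patient.present | ref.present)
        lines = ["key\tweight\tpatient\treference\tindicator"]
        for key in union:
            in_p = key in comparison.patient.present
            in_r = key in ref.present
            lines.append(
                "\t".join(
                    [
                        key,
                        str(comparison.weights.get(key)),
                        "1" if in_p else "0",
                        "1" if in_r else "0",
                        "match" if in_p == in_r else "mismatch",
                    ]
                )
            )
        lines.append(f"# L={row.L}\td={row.d}\tJ={row.J:.3f}")
        safe = "".join(c if c.isalnum() or c in "-_." else "_" for c in ref.id)
        (directory / f"alignment_{safe}.txt").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )
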