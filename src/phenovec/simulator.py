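"""Seeded synthetic BFF/PXF cohort generator.

Each simulated individual receives, per clinical term (diseases,
exposures, phenotypic features, procedures, treatments), ``k`` distinct
entries sampled without replacement from a fixed enumerable pool of ``P``
fabricated ontology terms, plus a uniformly drawn sex and ethnicity.  The
pools use deterministic CURIE-shaped identifiers (``HP:SIM0001`` ...) so
vocabularies are stable across runs and no ontology lookup is needed; sex
uses the real NCIt male/female codes so records mirror production data
(``sex.id.NCIT:C20197`` / ``sex.id.NCIT:C16576`` after flattening).

With without-replacement sampling, the per-term distance between two
individuals is ``2(k - X)`` with ``X`` hypergeometric, giving
``E[d] = 2k(1 - k/P)`` per term — the law the generator's tests check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .exceptions import ValidationError
from .formats_io import RawRecord

#: CURIE prefix per simulated term (BFF naming).
_POOL_PREFIXES: dict[str, str] = {
    "phenotypicFeatures": "HP:SIM",
    "diseases": "OMIM:SIM",
    "treatments": "RxNorm:SIM",
    "exposures": "CHEBI:SIM",
    "interventionsOrProcedures": "NCIT:SIM",
}

#: BFF term -> wrapper ontology-class field of each array element.
_BFF_CLASS_FIELDS: dict[str, str] = {
    "phenotypicFeatures": "featureType",
    "diseases": "diseaseCode",
    "treatments": "treatmentCode",
    "exposures": "exposureCode",
    "interventionsOrProcedures": "procedureCode",
}

#: PXF equivalents for the terms the PXF schema carries.
_PXF_TERMS: dict[str, tuple[str, str]] = {
    # BFF-named term -> (pxf term, element class field)
    "phenotypicFeatures": ("phenotypicFeatures", "type"),
    "diseases": ("diseases", "term"),
}

SEX_OPTIONS: tuple[tuple[str, str], ...] = (
    ("NCIT:C20197", "male"),
    ("NCIT:C16576", "female"),
)


def term_pool(term: str, size: int) -> list[tuple[str, str]]:
    """The first ``size`` (CURIE, label) entries of a term's fixed pool."""
    prefix = _POOL_PREFIXES[term]
    return [(f"{prefix}{i:04d}", f"{term}_{i}") for i in range(1, size + 1)]


def ethnicity_pool(size: int) -> list[tuple[str, str]]:
    return [(f"NCIT:SIMETH{i:04d}", f"ethnicity_{i}") for i in range(1, size + 1)]


@dataclass(frozen=True)
class SimConfig:
    """Design of one simulated cohort.

    ``term_counts`` gives k (entries per individual) and ``pool_sizes``
    gives P (pool cardinality) per term; 0 <= k <= P.  Defaults reproduce a
    fully random cohort: 10 entries from pools of 100 for each of the five
    clinical terms, binary sex, ethnicity pool of 100.
    """

    n: int = 100
    format: str = "bff"
    term_counts: Mapping[str, int] = field(
        default_factory=lambda: {t: 10 for t in _POOL_PREFIXES}
    )
    pool_sizes: Mapping[str, int] = field(
        default_factory=lambda: {t: 100 for t in _POOL_PREFIXES}
    )
    with_sex: bool = True
    with_ethnicity: bool = True
    ethnicity_pool_size: int = 100
    seed: int = 42
    id_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        if self.format not in ("bff", "pxf"):
            raise ValidationError(f"format must be 'bff' or 'pxf', got {self.format!r}")
        for term, k in self.term_counts.items():
            if term not in _POOL_PREFIXES:
                raise ValidationError(f"unknown simulated term {term!r}")
            pool = self.pool_sizes.get(term, 0)
            if not 0 <= k <= pool:
                raise ValidationError(
                    f"{term}: need 0 <= k <= P, got k={k}, pool={pool}"
                )

    @property
    def prefix(self) -> str:
        if self.id_prefix is not None:
            return self.id_prefix
        return "Beacon_" if self.format == "bff" else "Phenopacket_"


def _bff_element(term: str, curie: str, label: str) -> dict:
    return {_BFF_CLASS_FIELDS[term]: {"id": curie, "label": label}}


def _pxf_element(class_field: str, curie: str, label: str) -> dict:
    return {class_field: {"id": curie, "label": label}}


def simulate_cohort(config: SimConfig) -> list[RawRecord]:
    """Generate ``config.n`` records, fully reproducible from the seed.

    Ids are ``<prefix>1`` ... ``<prefix>n``.  Every array element carries
    its CURIE at the path the matching format descriptor expects, so the
    records flatten without positional-index fallbacks.
    """
    rng = np.random.default_rng(config.seed)
    records: list[RawRecord] = []
    for i in range(1, config.n + 1):
        body: dict = {"id": f"{config.prefix}{i}"}
        if config.format == "bff":
            for term, k in config.term_counts.items():
                if k == 0:
                    continue
                pool = term_pool(term, config.pool_sizes[term])
                picks = rng.choice(len(pool), size=k, replace=False)
                body[term] = [
                    _bff_element(term, *pool[j]) for j in sorted(picks)
                ]
            if config.with_sex:
                curie, label = SEX_OPTIONS[rng.integers(len(SEX_OPTIONS))]
                body["sex"] = {"id": curie, "label": label}
            if config.with_ethnicity:
                pool = ethnicity_pool(config.ethnicity_pool_size)
                curie, label = pool[rng.integers(len(pool))]
                body["ethnicity"] = {"id": curie, "label": label}
        else:  # pxf
            for bff_term, (pxf_term, class_field) in _PXF_TERMS.items():
                k = config.term_counts.get(bff_term, 0)
                if k == 0:
                    continue
                pool = term_pool(bff_term, config.pool_sizes[bff_term])
                picks = rng.choice(len(pool), size=k, replace=False)
                body[pxf_term] = [
                    _pxf_element(class_field, *pool[j]) for j in sorted(picks)
                ]
            k = config.term_counts.get("treatments", 0)
            if k:
                pool = term_pool("treatments", config.pool_sizes["treatments"])
                picks = rng.choice(len(pool), size=k, replace=False)
                body["medicalActions"] = [
                    {"treatment": {"agent": {"id": pool[j][0], "label": pool[j][1]}}}
                    for j in sorted(picks)
                ]
            subject: dict = {"id": f"{config.prefix}{i}"}
            if config.with_sex:
                _, label = SEX_OPTIONS[rng.integers(len(SEX_OPTIONS))]
                subject["sex"] = label.upper()
            body["subject"] = subject
        records.append(RawRecord(id=body["id"], body=body))
    return records


def write_cohort(records: list[RawRecord], path: str | Path) -> None:
    """Serialize simulated records as a JSON array (BFF/PXF file)."""
    Path(path).write_text(
        json.dumps([dict(r.body) for r in records], indent=2) + "\n",
        encoding="utf-8",
    )


def expected_exact_matches(cohort_size: int, k: int, P: int) -> float:
    """Expected number of references whose k-subset equals the patient's.

    With both patient and references drawing a uniform k-subset from a
    pool of P, a reference matches exactly with probability 1/C(P, k), so
    the expectation is ``cohort_size / C(P, k)`` — e.g. 1000/C(25,2) ≈ 3.33.
    """
    if not 0 <= k <= P:
        raise ValidationError(f"need 0 <= k <= P, got k={k}, P={P}")
    return cohort_size / math.comb(P, k)
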