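import json

import pytest

from phenovec import FormatDescriptor, RawRecord, builtin_descriptor


@pytest.fixture
def bff_descriptor() -> FormatDescriptor:
    return builtin_descriptor("bff")


@pytest.fixture
def generic_descriptor() -> FormatDescriptor:
    """Descriptor for records of the form {"id": ..., "traits": [...]}."""
    return FormatDescriptor(
        format_name="generic",
        id_path="id",
        allowed_terms=("id", "traits"),
        exclude_paths=("id",),
    )


def trait_record(rid: str, *traits: str) -> RawRecord:
    return RawRecord(id=rid, body={"id": rid, "traits": list(traits)})


@pytest.fixture
def toy_cohort() -> list[RawRecord]:
    """Three individuals with trait sets {x,y}, {y,z}, {x,y}.

    Hand-computed pairwise symmetric differences give the Hamming matrix
    rows (0,2,0), (2,0,2), (0,2,0) and the zero-distance classes
    {A,C}, {B}.
    """
    return [
        trait_record("A", "x", "y"),
        trait_record("B", "y", "z"),
        trait_record("C", "x", "y"),
    ]


@pytest.fixture
def bff_cohort() -> list[RawRecord]:
    bodies = [
        {
            "id": "Beacon_1",
            "sex": {"id": "NCIT:C20197", "label": "male"},
            "phenotypicFeatures": [
                {"featureType": {"id": "HP:0000118", "label": "Phenotypic abnormality"}}
            ],
        },
        {
            "id": "Beacon_2",
            "sex": {"id": "NCIT:C16576", "label": "female"},
            "diseases": [{"diseaseCode": {"id": "OMIM:154700", "label": "Marfan"}}],
        },
    ]
    return [RawRecord(id=b["id"], body=b) for b in bodies]


@pytest.fixture
def bff_cohort_file(tmp_path, bff_cohort):
    path = tmp_path / "cohort.json"
    path.write_text(json.dumps([dict(r.body) for r in bff_cohort]), encoding="utf-8")
    return path
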