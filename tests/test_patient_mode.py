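import numpy as np
import pytest

from conftest import trait_record
from phenovec import (
    UsageError,
    ValidationError,
    WeightSpec,
    compare_cohort,
    compare_patient,
    export_alignment,
    rank_patient,
)


@pytest.fixture
def reference_cohort():
    return [
        trait_record("R1", "x", "y"),       # exact match for patient {x,y}
        trait_record("R2", "y", "w"),
        trait_record("R3", "u", "v"),
        trait_record("R4", "x", "w"),
    ]


class TestRanking:
    def test_exact_match_ranks_first(self, reference_cohort, generic_descriptor):
        patient = trait_record("P", "x", "y")
        rows = rank_patient(patient, [reference_cohort], generic_descriptor)
        first = rows[0]
        assert first.reference_id == "R1"
        assert (first.d, first.J, first.L) == (0, 1.0, 2)

    def test_tie_break_prefers_higher_jaccard(self, generic_descriptor):
        # R5 and R6 both at d=2 from the patient, but R6's union is larger
        cohort = [
            trait_record("R5", "y", "w"),            # d=2, L=3, J=1/3
            trait_record("R6", "x", "y", "w", "v"),  # d=2, L=4, J=1/2
            trait_record("R7", "u", "t"),
        ]
        patient = trait_record("P", "x", "y")
        rows = rank_patient(patient, [cohort], generic_descriptor)
        assert [r.reference_id for r in rows[:2]] == ["R6", "R5"]
        assert rows[0].J > rows[1].J

    def test_equal_rows_tie_break_on_id(self, generic_descriptor):
        cohort = [
            trait_record("B", "y", "w"),
            trait_record("A", "y", "w"),
            trait_record("C", "u", "v"),
        ]
        rows = rank_patient(trait_record("P", "x", "y"), [cohort], generic_descriptor)
        assert [r.reference_id for r in rows[:2]] == ["A", "B"]

    def test_top_n_truncates(self, reference_cohort, generic_descriptor):
        patient = trait_record("P", "x", "y")
        rows = rank_patient(
            patient, [reference_cohort], generic_descriptor, top_n=2
        )
        assert len(rows) == 2

    def test_patient_unique_keys_are_projected_away(
        self, reference_cohort, generic_descriptor
    ):
        with_extra = trait_record("P", "x", "y", "only_in_patient")
        without = trait_record("P", "x", "y")
        rows_a = rank_patient(with_extra, [reference_cohort], generic_descriptor)
        rows_b = rank_patient(without, [reference_cohort], generic_descriptor)
        assert [(r.reference_id, r.d, r.L) for r in rows_a] == [
            (r.reference_id, r.d, r.L) for r in rows_b
        ]

    def test_disjoint_patient_rejected(self, reference_cohort, generic_descriptor):
        patient = trait_record("P", "nothing_shared")
        with pytest.raises(ValidationError, match="shares no variables"):
            rank_patient(patient, [reference_cohort], generic_descriptor)

    def test_single_reference_rejected(self, generic_descriptor):
        patient = trait_record("P", "x")
        with pytest.raises(UsageError):
            rank_patient(patient, [[trait_record("R", "x")]], generic_descriptor)

    def test_jaccard_sort_order(self, reference_cohort, generic_descriptor):
        patient = trait_record("P", "x", "y")
        rows = rank_patient(
            patient, [reference_cohort], generic_descriptor, sort_by="jaccard"
        )
        jaccards = [r.J for r in rows]
        assert jaccards == sorted(jaccards, reverse=True)


class TestStatistics:
    def test_z_scores_are_standardized(self, generic_descriptor):
        cohort = [
            trait_record(f"R{i}", f"k{i}", f"k{i + 1}", "shared") for i in range(20)
        ]
        patient = trait_record("P", "k0", "k1", "shared")
        rows = rank_patient(patient, [cohort], generic_descriptor, top_n=None)
        z = np.array([r.z_d for r in rows])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_p_values_match_z_tails(self, reference_cohort, generic_descriptor):
        from scipy.stats import norm

        patient = trait_record("P", "x", "y")
        rows = rank_patient(patient, [reference_cohort], generic_descriptor)
        for row in rows:
            assert row.p_d == pytest.approx(norm.cdf(row.z_d))
            assert row.p_j == pytest.approx(norm.sf(row.z_j))

    def test_unit_weight_jaccard_identity(self, reference_cohort, generic_descriptor):
        patient = trait_record("P", "x", "y")
        rows = rank_patient(patient, [reference_cohort], generic_descriptor)
        for row in rows:
            assert row.J == pytest.approx((row.L - row.d) / row.L)

    def test_distances_match_cohort_mode_row(
        self, reference_cohort, generic_descriptor
    ):
        """Patient-mode distances equal the patient's row of a joint
        cohort-mode matrix restricted to the reference columns."""
        patient = trait_record("P", "x", "y")
        rows = rank_patient(
            patient, [reference_cohort], generic_descriptor, top_n=None
        )
        joint = compare_cohort(
            [[patient, *reference_cohort]], generic_descriptor
        )
        p_idx = joint.ids.index("P")
        cohort_row = {
            rid: int(joint.values[p_idx, joint.ids.index(rid)])
            for rid in joint.ids
            if rid != "P"
        }
        assert {r.reference_id: r.d for r in rows} == cohort_row


class TestAlignment:
    def test_exact_match_all_rows_match(
        self, tmp_path, reference_cohort, generic_descriptor
    ):
        patient = trait_record("P", "x", "y")
        comparison = compare_patient(
            patient, [reference_cohort], generic_descriptor
        )
        export_alignment(comparison, tmp_path, top_n=1)
        text = (tmp_path / "alignment_R1.txt").read_text()
        body = text.strip().split("\n")
        assert all("match" in line and "mismatch" not in line for line in body[1:-1])
        assert "d=0" in body[-1]

    def test_partial_overlap_marks(self, tmp_path, generic_descriptor):
        # S carries x so the patient's x stays in the cohort vocabulary
        cohort = [trait_record("R", "y", "w"), trait_record("S", "u", "v", "x")]
        patient = trait_record("P", "x", "y")
        comparison = compare_patient(patient, [cohort], generic_descriptor)
        export_alignment(comparison, tmp_path)
        lines = (tmp_path / "alignment_R.txt").read_text().strip().split("\n")
        marks = {l.split("\t")[0]: l.split("\t")[4] for l in lines[1:-1]}
        assert marks == {
            "traits.x": "mismatch",
            "traits.y": "match",
            "traits.w": "mismatch",
        }
        assert lines[-1] == "# L=3\td=2\tJ=0.333"

    def test_weighted_mismatch_contributes_weight(
        self, tmp_path, generic_descriptor
    ):
        cohort = [trait_record("R", "y", "w"), trait_record("S", "u", "v", "x")]
        patient = trait_record("P", "x", "y")
        weights = WeightSpec({"traits.x": 3})
        comparison = compare_patient(
            patient, [cohort], generic_descriptor, weights=weights
        )
        row = next(r for r in comparison.rows if r.reference_id == "R")
        assert (row.d, row.L) == (4, 5)  # x mismatch now counts 3
        export_alignment(comparison, tmp_path)
        lines = (tmp_path / "alignment_R.txt").read_text().strip().split("\n")
        weight_of_x = {
            l.split("\t")[0]: l.split("\t")[1] for l in lines[1:-1]
        }["traits.x"]
        assert weight_of_x == "3"
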