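import pytest
from hypothesis import given, settings, strategies as st

from zfpkit.seq_io import ProteinRecord
from zfpkit.motif_scan import scan_c2h2, scan_ear
from zfpkit.family_annotate import (
    call_tandem_arrays,
    classify_architecture,
    family_summary,
    render_architecture,
)

FINGER = "AACAACAAAAAAAAAAAAHAAAH"  # minimal 23-residue finger


def protein_with_linkers(linkers, pid="p", n_term=5, c_term=10):
    seq = "G" * n_term + FINGER
    for l in linkers:
        seq += "G" * l + FINGER
    seq += "G" * c_term
    rec = ProteinRecord(id=pid, sequence=seq)
    motifs = scan_c2h2(rec)
    assert len(motifs) == len(linkers) + 1
    return rec, motifs


class TestTandemArrays:
    def test_zero_linker_makes_an_array(self):
        _, motifs = protein_with_linkers([0])
        arrays = call_tandem_arrays(motifs)
        assert len(arrays) == 1 and arrays[0].size == 2
        assert arrays[0].linker_lengths == (0,)

    def test_three_fingers_with_ten_residue_links(self):
        _, motifs = protein_with_linkers([10, 10])
        (array,) = call_tandem_arrays(motifs)
        assert array.size == 3

    def test_fourth_finger_isolated(self):
        _, motifs = protein_with_linkers([10, 9, 65])
        (array,) = call_tandem_arrays(motifs)
        assert array.size == 3 and array.member_indices == (0, 1, 2)

    def test_single_motif_no_arrays(self):
        _, motifs = protein_with_linkers([])
        assert call_tandem_arrays(motifs) == []

    def test_boundary_linker_11_is_not_tandem(self):
        _, motifs = protein_with_linkers([11])
        assert call_tandem_arrays(motifs) == []
        assert len(call_tandem_arrays(motifs, threshold=12)) == 1

    def test_overlapping_motifs_rejected(self):
        from dataclasses import replace

        rec = ProteinRecord(id="p", sequence="GG" + FINGER + "G" * 30)
        (m,) = scan_c2h2(rec)
        fake = replace(m, start=m.start + 5, end=m.end + 5)
        with pytest.raises(ValueError):
            call_tandem_arrays([m, fake])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=6),
           st.integers(min_value=1, max_value=30))
    def test_threshold_monotonicity_and_maximality(self, linkers, threshold):
        """Lowering the threshold never enlarges arrays; arrays are maximal
        and disjoint."""
        _, motifs = protein_with_linkers(linkers)
        lo = call_tandem_arrays(motifs, threshold)
        hi = call_tandem_arrays(motifs, threshold + 5)
        # every low-threshold array is contained in one high-threshold array
        for a in lo:
            assert any(set(a.member_indices) <= set(b.member_indices) for b in hi)
        # disjoint
        seen = set()
        for a in lo:
            assert not (set(a.member_indices) & seen)
            seen |= set(a.member_indices)
        # maximality: neighbours outside an array are >= threshold away
        for a in lo:
            first, last = a.member_indices[0], a.member_indices[-1]
            if first > 0:
                assert motifs[first].start - motifs[first - 1].end >= threshold
            if last < len(motifs) - 1:
                assert motifs[last + 1].start - motifs[last].end >= threshold


def annotate(seq, pid="p"):
    rec = ProteinRecord(id=pid, sequence=seq)
    return classify_architecture(pid, len(rec), scan_c2h2(rec), scan_ear(rec))


EAR = "LGLGL"


class TestArchitecture:
    def test_palm1_like_layout(self):
        """Finger near the N-terminus, EAR at the C-terminus."""
        ann = annotate("GG" + FINGER + "G" * 50 + EAR + "GG")
        assert ann.count_class == "single"
        assert ann.ear_class == "one_EAR"
        assert ann.arrangement == "C2H2_then_EAR"

    def test_jagged_like_upstream_ear(self):
        ann = annotate("GG" + EAR + "G" * 40 + FINGER + "G" * 10)
        assert ann.arrangement == "EAR_then_C2H2"

    def test_no_ear_single_finger(self):
        ann = annotate("GG" + FINGER + "G" * 20)
        assert ann.ear_class == "no_EAR"
        assert ann.arrangement == "not_applicable"
        assert ann.array_class == "single_finger"

    def test_finger_between_two_ears(self):
        ann = annotate("G" + EAR + "G" * 20 + FINGER + "G" * 20 + EAR + "G")
        assert ann.ear_class == "multi_EAR"
        assert ann.arrangement == "C2H2_between_EARs"

    def test_two_ears_same_side(self):
        ann = annotate("GG" + FINGER + "G" * 10 + EAR + "GGG" + EAR + "GG")
        assert ann.arrangement == "EARs_flanking_other"

    def test_ear_inside_finger_is_flagged_overlap(self):
        # LKLHLK embedded in the 12-residue gap, as in the TRM1 fifth finger
        finger = "AAC" + "AA" + "C" + "GG" + "LKLHLK" + "GGGG" + "H" + "AAA" + "H"
        ann = annotate("GG" + finger + "G" * 20)
        assert len(ann.ear_overlaps) == 1
        assert ann.arrangement == "not_applicable"  # overlap excluded from ordering
        assert ann.ear_class == "one_EAR"  # but still counted

    def test_multi_finger_all_ears_downstream(self):
        ann = annotate("G" + FINGER + "G" * 20 + FINGER + "G" * 10 + EAR + "GG")
        assert ann.arrangement == "C2H2_then_EAR"

    def test_count_classes(self):
        rec, motifs = protein_with_linkers([20, 20, 20])
        assert classify_architecture(rec.id, len(rec), motifs, []).count_class == "four"
        rec7, m7 = protein_with_linkers([20] * 6)
        assert classify_architecture("p", len(rec7), m7, []).count_class == "other-7"

    def test_no_motifs_rejected(self):
        with pytest.raises(ValueError):
            classify_architecture("p", 100, [], [])


class TestFamilySummary:
    def test_planted_mix(self):
        anns = [annotate("GG" + FINGER + "G" * 20, pid=f"s{i}") for i in range(7)]
        anns += [
            annotate("GG" + FINGER + "G" * 20 + FINGER + "G" * 9, pid=f"d{i}")
            for i in range(3)
        ]
        s = family_summary(anns)
        assert s.count_class_counts == {"single": 7, "two": 3}
        assert s.fraction_single == pytest.approx(0.7)
        assert sum(s.count_class_counts.values()) == s.total

    def test_empty(self):
        s = family_summary([])
        assert s.total == 0 and s.count_class_counts == {}


class TestRender:
    def test_rectangles_and_determinism(self):
        ann = annotate("GG" + FINGER + "G" * 50 + EAR + "GG")
        layout = render_architecture(ann)
        assert layout["length"] == len("GG" + FINGER + "G" * 50 + EAR + "GG")
        kinds = [f["kind"] for f in layout["features"]]
        assert kinds == ["C2H2", "EAR"]  # finger rectangle before EAR rectangle
        assert layout["features"][0]["color"] == "black"
        assert layout["features"][1]["color"] == "red"
        assert render_architecture(ann) == layout
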