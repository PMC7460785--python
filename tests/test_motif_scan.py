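import re

import pytest
from hypothesis import given, settings, strategies as st

from zfpkit.seq_io import ProteinRecord
from zfpkit.motif_scan import (
    C2H2_PATTERNS,
    attach_confirmation,
    is_c2h2_window,
    scan_c2h2,
    scan_ear,
)


def rec(seq, pid="p"):
    return ProteinRecord(id=pid, sequence=seq)


class TestScanC2H2:
    def test_no_cys_his_no_match(self):
        assert scan_c2h2(rec("A" * 100)) == []

    def test_known_single_finger(self):
        """Oracle case: the exhaustive window check finds one unique match."""
        motifs = scan_c2h2(rec("MAAYKCPDCGASFSRSQALGGHQNAHRRAA"))
        assert len(motifs) == 1
        m = motifs[0]
        assert (m.start, m.end) == (3, 26)
        assert (m.cys_gap, m.his_gap) == (2, 3)
        assert m.core6 == "QALGGH"
        assert m.inter_his == "QNA"
        # exhaustive agrees
        ex = scan_c2h2(rec("MAAYKCPDCGASFSRSQALGGHQNAHRRAA"), mode="exhaustive")
        assert [(m.start, m.end)] == [(x.start, x.end) for x in ex]

    def test_shortest_match_is_23(self):
        # cys_gap=2, his_gap=3 gives the minimal geometry
        minimal = "AACAACAAAAAAAAAAAAHAAAH"
        assert len(minimal) == 23
        motifs = scan_c2h2(rec(minimal))
        assert len(motifs) == 1 and motifs[0].length == 23

    def test_two_planted_motifs_in_order(self):
        f = "AACAACAAAAAAAAAAAAHAAAH"
        seq = "GG" + f + "G" * 40 + f + "GG"
        motifs = scan_c2h2(rec(seq))
        assert [(m.start, m.end) for m in motifs] == [(2, 25), (65, 88)]

    def test_greedy_his_gap(self):
        # both gap-3 and gap-5 complete at the same anchor: regex keeps 5
        seq = "AACAACAAAAAAAAAAAAHAAAHAH"
        (m,) = scan_c2h2(rec(seq))
        assert m.his_gap == 5

    def test_cys_gap2_preferred_on_overlap(self):
        # both spacings anchor overlapping calls; the gap-2 call wins
        seq = "AACAACAAAACAAAAAAAHAAAHHAAAHAA"
        motifs = scan_c2h2(rec(seq))
        assert [(m.start, m.cys_gap) for m in motifs] == [(0, 2)]
        ex = scan_c2h2(rec(seq), mode="exhaustive")
        assert any(m.cys_gap == 4 for m in ex)  # the gap-4 call exists but loses

    def test_leading_cys_cannot_anchor(self):
        # the pattern demands two residues before the first Cys
        seq = "CAACAAAAAAAAAAAAHAAAH"
        assert scan_c2h2(rec(seq)) == []
        assert scan_c2h2(rec("AA" + seq)) != []

    def test_published_calls_validate_and_do_not_overlap(self, study_truth):
        for record in study_truth.records[:80]:
            motifs = scan_c2h2(record)
            for m in motifs:
                assert is_c2h2_window(record.sequence, m.start, m.cys_gap, m.his_gap)
            for a, b in zip(motifs, motifs[1:]):
                assert a.end <= b.start

    def test_scan_is_idempotent(self):
        r = rec("GG" + "AACAACAAAAAAAAAAAAHAAAH" + "GG")
        assert scan_c2h2(r) == scan_c2h2(r)

    def test_concatenation_is_not_separate_scans(self):
        """Joining two proteins can create a boundary motif neither has."""
        left = "AAAAC"  # supplies ..C
        right = "AACAAAAAAAAAAAAHAAAHAA"
        assert scan_c2h2(rec(left)) == [] and scan_c2h2(rec(right)) == []
        assert len(scan_c2h2(rec(left + right))) == 1


@settings(derandomize=True, max_examples=200)
@given(st.text(alphabet="ACHGLKD", min_size=0, max_size=120))
def test_published_subset_of_exhaustive(seq):
    """Published-mode calls are always a subset of exhaustive windows."""
    if not seq:
        return
    r = rec(seq)
    pub = {(m.start, m.cys_gap, m.his_gap) for m in scan_c2h2(r)}
    ex = {(m.start, m.cys_gap, m.his_gap) for m in scan_c2h2(r, mode="exhaustive")}
    assert pub <= ex
    # and every exhaustive window passes the independent validator trivially
    for s, cg, hg in ex:
        assert is_c2h2_window(seq, s, cg, hg)


@settings(derandomize=True, max_examples=200)
@given(st.text(alphabet="ACHGLKDN", min_size=0, max_size=120))
def test_exhaustive_equals_brute_force_regex(seq):
    """Exhaustive mode agrees with an anchored-regex sweep (independent oracle)."""
    expected = set()
    for cg, pat in C2H2_PATTERNS.items():
        for start in range(len(seq)):
            for hg in (3, 4, 5):
                window = seq[start : start + 18 + cg + hg]
                if len(window) == 18 + cg + hg and re.fullmatch(
                    rf".{{2}}C.{{{cg}}}C.{{12}}H.{{{hg}}}H", window
                ):
                    expected.add((start, cg, hg))
    if not seq:
        return
    got = {(m.start, m.cys_gap, m.his_gap) for m in scan_c2h2(rec(seq), mode="exhaustive")}
    assert got == expected


class TestScanEAR:
    def test_lklhlk_is_an_ear(self):
        sites = scan_ear(rec("LKLHLK"))
        assert len(sites) == 1
        assert sites[0].pattern_id == "LxLxL"
        assert (sites[0].start, sites[0].matched) == (0, "LKLHL")

    def test_poly_a_empty(self):
        assert scan_ear(rec("A" * 50)) == []

    def test_dlnxxp_site(self):
        sites = scan_ear(rec("AADLNTTPAA"))
        assert len(sites) == 1
        assert (sites[0].start, sites[0].pattern_id) == (2, "DLNxxP")

    def test_patterns_merged_and_sorted(self):
        sites = scan_ear(rec("DLNAAP" + "GGG" + "LALAL"))
        assert [s.pattern_id for s in sites] == ["DLNxxP", "LxLxL"]
        assert [s.start for s in sites] == [0, 9]

    def test_l_positions_must_be_exact(self):
        assert scan_ear(rec("IKIHI")) == []


class TestAttachConfirmation:
    def _calls(self, n):
        f = "AACAACAAAAAAAAAAAAHAAAH"
        return {
            f"p{i:03d}": scan_c2h2(rec("GG" + f, pid=f"p{i:03d}")) for i in range(n)
        }

    def test_no_list_is_identity(self):
        calls = self._calls(5)
        filtered, dropped = attach_confirmation(calls, None)
        assert filtered == calls and dropped == 0

    def test_dropping_55_of_272_leaves_217(self):
        calls = self._calls(272)
        verdicts = {pid: ("drop" if i < 55 else "keep") for i, pid in enumerate(sorted(calls))}
        filtered, dropped = attach_confirmation(calls, verdicts)
        assert dropped == 55 and len(filtered) == 217

    def test_unknown_id_warns_but_keeps_output(self):
        calls = self._calls(3)
        with pytest.warns(UserWarning):
            filtered, dropped = attach_confirmation(calls, {"nope": "drop"})
        assert filtered == calls and dropped == 0

    def test_bad_verdict_rejected(self):
        with pytest.raises(ValueError):
            attach_confirmation(self._calls(1), {"p000": "maybe"})
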