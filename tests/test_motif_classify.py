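import pytest
from hypothesis import given, settings, strategies as st

from zfpkit.seq_io import ProteinRecord
from zfpkit.motif_scan import scan_c2h2
from zfpkit.motif_classify import (
    ClassifierRules,
    SYNTHETIC_IDD_REFERENCE,
    build_idd_profile,
    classify_all,
    classify_motif,
    default_rules,
    load_rules,
)


def motif_from(core6, inter_his, prefix="MA", pid="p"):
    """Build a minimal finger with chosen core and inter-His segment."""
    seq = prefix + "C" + "AA" + "C" + "AAAAAAA" + core6[:5] + "H" + inter_his + "H"
    (m,) = scan_c2h2(ProteinRecord(id=pid, sequence=seq), mode="exhaustive")
    return m


RULES = default_rules()


class TestQTyping:
    @pytest.mark.parametrize(
        "inter,expected_sub",
        [
            ("QNA", "Q1"),
            ("KAS", "Q2"),
            ("RAS", "Q2"),
            ("MRR", "Q3"),
            ("MRK", "Q3"),
            ("MNI", "Q4"),
            ("MNV", "Q4"),
            ("KRC", "Q5"),
            ("KRS", "Q5"),
            ("TTT", "Q6"),
        ],
    )
    def test_q_subgroups(self, inter, expected_sub):
        m = classify_motif(motif_from("QALGGH", inter), RULES)
        assert (m.mtype, m.subgroup) == ("Q", expected_sub)

    def test_his_gap_above_3_falls_to_q6(self):
        m = classify_motif(motif_from("QALGGH", "QNAA"), RULES)
        assert (m.mtype, m.subgroup) == ("Q", "Q6")

    def test_q_depends_only_on_core(self):
        a = classify_motif(motif_from("QALGGH", "QNA", prefix="MA"), RULES)
        b = classify_motif(motif_from("QALGGH", "QNA", prefix="WW"), RULES)
        assert (a.mtype, a.subgroup) == (b.mtype, b.subgroup)


class TestQMTyping:
    @pytest.mark.parametrize("core", ["RALGGH", "QGLGGH", "KALGGH", "RGLGGH"])
    def test_modified_cores_are_qm(self, core):
        m = classify_motif(motif_from(core, "TTT"), RULES)
        assert m.mtype == "QM"

    def test_qm_signature_subgroup(self):
        m = classify_motif(motif_from("RALGGH", "TTT"), RULES)
        assert m.subgroup == "P1:R"

    def test_three_mismatches_is_not_qm(self):
        m = classify_motif(motif_from("RRRGGH", "TTT"), RULES)
        assert m.mtype != "QM"

    def test_override_table_renames_subgroup(self):
        rules = ClassifierRules(qm_subgroup_overrides={"P1:R": "QM1"})
        m = classify_motif(motif_from("RALGGH", "TTT"), rules)
        assert m.subgroup == "QM1"

    def test_no_motif_is_both_q_and_qm(self):
        # exact core goes to Q even though Hamming distance 0 <= max_mismatch
        m = classify_motif(motif_from("QALGGH", "TTT"), RULES)
        assert m.mtype == "Q"


class TestIDDProfile:
    def test_identical_references_all_invariant(self):
        profile = build_idd_profile([SYNTHETIC_IDD_REFERENCE[0]] * 3)
        assert all(profile.invariant)

    def test_one_difference_leaves_22_invariant(self):
        a = SYNTHETIC_IDD_REFERENCE[0]
        b = a[:10] + ("G" if a[10] != "G" else "A") + a[11:]
        profile = build_idd_profile([a, b])
        assert sum(profile.invariant) == 22

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_idd_profile(["ABC", "ABCD"])

    def test_reference_motifs_classify_as_idd(self):
        for seq in SYNTHETIC_IDD_REFERENCE:
            (m,) = scan_c2h2(ProteinRecord(id="p", sequence=seq), mode="exhaustive")
            assert classify_motif(m, RULES).mtype == "IDD"

    def test_first_residue_f_required(self):
        seq = "A" + SYNTHETIC_IDD_REFERENCE[0][1:]
        (m,) = scan_c2h2(ProteinRecord(id="p", sequence=seq), mode="exhaustive")
        assert classify_motif(m, RULES).mtype != "IDD"


class TestZAndC:
    def test_z_core_table_match(self):
        m = classify_motif(motif_from("RKFANH", "TTT"), RULES)
        assert (m.mtype, m.subgroup) == ("Z", "Z1")

    def test_residual_is_c(self):
        m = classify_motif(motif_from("WWWWWH", "TTT"), RULES)
        assert (m.mtype, m.subgroup) == ("C", "")

    def test_z_fallback_clustering(self):
        """Without a core table, similar unassigned motifs cluster into Z."""
        rules = ClassifierRules(z_subgroup_cores=None)
        near = [motif_from("WWWWWH", "TTT", pid=f"p{i}") for i in range(3)]
        lone_seq = "MA" + "C" + "GG" + "C" + "DEDEDED" + "KIKIK" + "H" + "WWW" + "H"
        (lone,) = scan_c2h2(ProteinRecord(id="zz", sequence=lone_seq), mode="exhaustive")
        typed, summary = classify_all(near + [lone], rules)
        assert [m.mtype for m in typed[:3]] == ["Z", "Z", "Z"]
        assert len({m.subgroup for m in typed[:3]}) == 1
        assert typed[3].mtype == "C"


class TestClassifyAll:
    def test_empty_input(self):
        typed, summary = classify_all([])
        assert typed == [] and summary.total == 0 and summary.type_counts == {}

    def test_partition_and_conservation(self, study_truth):
        records = [r for r in study_truth.records if r.variant_of is None]
        motifs = [m for r in records for m in scan_c2h2(r)]
        typed, summary = classify_all(motifs)
        assert sum(summary.type_counts.values()) == summary.total == len(motifs)
        for mtype, subs in summary.subgroup_counts.items():
            assert sum(subs.values()) <= summary.type_counts[mtype]
        # Q subgroups exactly partition Q
        assert sum(summary.subgroup_counts["Q"].values()) == summary.type_counts["Q"]

    def test_planted_type_counts_recovered(self, study_truth):
        """Construction guarantees the planted labels; scanning+typing must
        reproduce them exactly."""
        records = {r.id: r for r in study_truth.records if r.variant_of is None}
        confirmed = study_truth.family_ids
        motifs = [m for pid in confirmed for m in scan_c2h2(records[pid])]
        motifs += scan_c2h2(study_truth.tfiiia)
        typed, summary = classify_all(motifs)
        truth = study_truth.motifs[study_truth.motifs.record_set != "false_candidate"]
        expected = truth.groupby("mtype").size().to_dict()
        assert summary.type_counts == expected
        q_truth = truth[truth.mtype == "Q"].groupby("subgroup").size().to_dict()
        assert summary.subgroup_counts["Q"] == q_truth

    def test_rules_round_trip_yaml(self, tmp_path, study_truth):
        """Serializing and reloading the rules leaves every label unchanged."""
        import yaml

        rules = default_rules()
        doc = {
            "classify": {
                "qm_max_mismatch": rules.qm_max_mismatch,
                "idd_min_matches": rules.idd_min_matches,
                "q_subgroups": {k: sorted(v) for k, v in rules.q_subgroups.items()},
                "z_subgroup_cores": {k: sorted(v) for k, v in rules.z_subgroup_cores.items()},
                "idd_reference_motifs": list(SYNTHETIC_IDD_REFERENCE),
            }
        }
        path = tmp_path / "rules.yaml"
        path.write_text(yaml.safe_dump(doc))
        reloaded = load_rules(path)
        records = [r for r in study_truth.records if r.variant_of is None][:100]
        motifs = [m for r in records for m in scan_c2h2(r)]
        a, _ = classify_all(motifs, rules)
        b, _ = classify_all(motifs, reloaded)
        assert [(m.mtype, m.subgroup) for m in a] == [(m.mtype, m.subgroup) for m in b]


@settings(derandomize=True, max_examples=100)
@given(st.sampled_from(["QALGGH", "RALGGH", "WWWWWH", "RKFANH"]),
       st.text(alphabet="AKQNR", min_size=3, max_size=3))
def test_typing_is_a_function_of_core_and_inter(core, inter):
    m1 = classify_motif(motif_from(core, inter, prefix="MA"), RULES)
    m2 = classify_motif(motif_from(core, inter, prefix="GG"), RULES)
    assert (m1.mtype, m1.subgroup) == (m2.mtype, m2.subgroup)
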