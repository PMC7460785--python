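"""Type a set of fingers with the Q / QM / IDD / Z / C scheme.

Q-type fingers carry the exact plant-specific QALGGH core; QM cores are
1-2 substitutions away; IDD fingers are 23-mers starting with Phe that
match the INDETERMINATE-DOMAIN profile; Z-type cores come from a
configurable signature table; C is the residual class.
"""

from zfpkit import ProteinRecord, classify_all, scan_c2h2

examples = {
    "Q1-type": "MAAYKCPDCGASFSRSQALGGHQNAHRRAA",
    "QM-type": "MAAYKCPDCGASFSRSRALGGHTTTHRRAA",  # RALGGH: one substitution
    "C-type": "MAAYKCPDCGASFSRSWDWTWHTTTHRRAA",  # no conserved core
}

motifs = []
for name, seq in examples.items():
    motifs += scan_c2h2(ProteinRecord(id=name, sequence=seq))

typed, summary = classify_all(motifs)
for m in typed:
    print(f"{m.protein_id}: core={m.core6} -> {m.mtype} {m.subgroup}")
print("type counts:", summary.type_counts)

# Expected: the QALGGH core is Q (subgroup Q1 via the QNA inter-His
# segment), RALGGH is QM with mismatch signature P1:R, and the third
# core falls through every rule to C.
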