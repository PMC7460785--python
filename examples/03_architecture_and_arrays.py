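"""Per-protein architecture: finger counts, tandem arrays, EAR layout.

Fingers joined by linkers shorter than 11 residues form tandem arrays
(the TFIIIA nine-finger protein is the classic case: finger 1 isolated,
fingers 2-4 and 5-9 in two arrays).
"""

from zfpkit import ProteinRecord, classify_architecture, render_architecture
from zfpkit.motif_scan import scan_c2h2, scan_ear

FINGER = "AACAACAAAAAAAAAAAAHAAAH"  # a minimal 23-residue finger

# three fingers: the first two joined by a 10-residue linker (an array),
# the third 40 residues away (isolated)
seq = "GGGGG" + FINGER + "G" * 10 + FINGER + "G" * 40 + FINGER + "G" * 20
rec = ProteinRecord(id="demo", sequence=seq)
ann = classify_architecture(rec.id, len(rec), scan_c2h2(rec), scan_ear(rec))

print("finger count:", ann.finger_count, "->", ann.count_class)
print("array class:", ann.array_class)
for arr in ann.arrays:
    print("  tandem array of", arr.size, "fingers, linkers", arr.linker_lengths)
print("EAR class:", ann.ear_class, "| arrangement:", ann.arrangement)

layout = render_architecture(ann)
print("diagram features (black=C2H2, red=EAR):")
for f in layout["features"]:
    print(f"  {f['kind']:5s} {f['start']:4d}-{f['end']:<4d} {f['color']}")

# Expected: a 'three'-finger protein with one tandem array of 2 (linker
# 10 < 11) and the third finger isolated; no EAR sites.
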