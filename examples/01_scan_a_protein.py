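"""Scan one protein for C2H2 zinc fingers and EAR repression sites.

The scanner matches the classical finger geometry
X2-Cys-X2,4-Cys-X12-His-X3,4,5-His and the two canonical EAR classes
(LxLxL, DLNxxP).  Coordinates printed are 0-based half-open.
"""

from zfpkit import ProteinRecord, scan_c2h2, scan_ear

# a PALM1/RSD-style layout: one finger near the N-terminus, an EAR at the
# C-terminus (the classic single-finger transcriptional-repressor design)
seq = (
    "MAAYKCPDCGASFSRSQALGGHQNAHRRAA"
    + "GSTNDEGSTNDEGSTNDEGSTNDEGSTNDE"
    + "LDLNLKA"
)
record = ProteinRecord(id="demo", sequence=seq)

for m in scan_c2h2(record):
    print(
        f"C2H2 finger {m.start}-{m.end} ({m.length} aa): "
        f"Cys gap {m.cys_gap}, His gap {m.his_gap}, "
        f"core {m.core6}, inter-His {m.inter_his}"
    )
for e in scan_ear(record):
    print(f"EAR site {e.start}-{e.end}: {e.pattern_id} ({e.matched})")

# The finger spans residues 3-26: the QALGGH core marks it as a plant
# Q-type finger, and QNA between the histidines places it in subgroup Q1.
# The LDLNL near the C-terminus is an LxLxL-class repression motif.
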