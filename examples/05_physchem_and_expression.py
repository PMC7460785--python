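"""Physicochemical profiling and expression tiering.

pI is found by bisecting the Bjellqvist-table net-charge curve (the
table the ExPASy Compute pI/Mw service uses); MW is the sum of average
residue masses plus one water.  Expression tiers are tertiles of mean
log2 abundance; induction is a fold-change over the non-target mean.
"""

import pandas as pd

from zfpkit import compute_mw, compute_pi
from zfpkit.expression import abundance_tiers, log2_matrix, tissue_induction

seq = "MAAYKCPDCGASFSRSQALGGHQNAHRRAA"
print(f"MW  = {compute_mw(seq)/1000:.1f} kDa")
print(f"pI  = {compute_pi(seq):.2f}")

# a toy gene x tissue abundance matrix
matrix = pd.DataFrame(
    {
        "root":   [900.0, 28.0, 2.0],
        "leaf":   [1100.0, 35.0, 3.0],
        "nodule": [1000.0, 30.0, 60.0],
    },
    index=["housekeeper", "moderate", "nodulin"],
)
tiers, cuts = abundance_tiers(log2_matrix(matrix))
print("tiers:", tiers.to_dict(), "| cuts:", [round(c, 2) for c in cuts])

induction = tissue_induction(matrix, ["nodule"], fold=2.0)
print(induction.round(2).to_string())

# Expected: the three genes land one per tier; only 'nodulin' (nodule
# abundance 24x its mean elsewhere) is flagged as nodule-induced.
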