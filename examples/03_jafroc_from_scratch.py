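"""The JAFROC1 figure of merit on a tiny hand-built rating table.

theta is the probability-like score that a randomly chosen lesion's rating
exceeds the highest false-positive rating of a randomly chosen case: 1.0
for a reader whose every lesion outranks every false positive, 0 for a
reader who marks nothing.
"""

import numpy as np

from hepafroc import RatingTable, jafroc1_fom, jackknife_pseudovalues

NEG = -np.inf
# 2 cases, 1 lesion each; the reader rated lesion 1 at 60, missed lesion 2,
# and left false positives rated 50 (case 1) and 70 (case 2).
table = RatingTable(
    modalities=["without_AI"],
    readers=["r1"],
    case_ids=["c1", "c2"],
    lesion_ids=["L1", "L2"],
    lesion_case_idx=np.array([0, 1]),
    ll=np.array([[[60.0, NEG]]]),
    nl=np.array([[[50.0, 70.0]]]),
)
theta = jafroc1_fom(table, "r1", "without_AI")
print(f"theta = {theta}")   # 1 win of 4 (case, lesion) pairs -> 0.25
pv = jackknife_pseudovalues(table, "r1", "without_AI")
print(f"jackknife pseudovalues per case: {pv}, mean = {pv.mean()}")
# The centered pseudovalues average back to theta; their spread feeds the
# DBM ANOVA when several readers and two modalities are compared.
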