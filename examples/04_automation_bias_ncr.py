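"""Automation bias and the negative consultation ratio.

A negative consultation flips a correct call to an incorrect one between
the two sessions: a detected lesion dropped (TP->FN) or an AI false
positive adopted (TN->FP).  Readers who trust the AI too much accumulate
both; the study convention flags readers with NCR >= 10%.
"""

import numpy as np

from hepafroc import (
    LesionPopulationSpec,
    ObserverProfile,
    compute_ncr,
    default_ai_profile,
    gen_ai_marks,
    gen_ground_truth,
    gen_reader_marks,
    link_findings_across_sessions,
    match_marks,
    WITH_AI,
    WITHOUT_AI,
)

gts = gen_ground_truth(LesionPopulationSpec(n_cases=10, seed=0))
ai = gen_ai_marks(gts, default_ai_profile(), rng=0)

for label, fp_adopt, drop in (("careful reader", 0.005, 0.0),
                              ("biased reader", 0.06, 0.15)):
    vals = []
    for seed in range(20):
        profile = ObserverProfile(accept_ai_tp=0.5, accept_ai_fp=fp_adopt,
                                  drop_own_tp_when_unflagged=drop)
        marks = gen_reader_marks(gts, ai, profile, rng=seed)
        matched = match_marks(marks, gts,
                              blocks=[("reader01", WITHOUT_AI),
                                      ("reader01", WITH_AI)])
        linked = link_findings_across_sessions(
            matched.select("reader01", WITHOUT_AI),
            matched.select("reader01", WITH_AI),
        )
        vals.append(compute_ncr(linked).ncr)
    print(f"{label}: mean NCR over 20 simulated readings = {np.mean(vals):.3f}")
# The biased profile adopts AI false positives and drops unflagged
# detections, pushing its NCR past the 10% stratification threshold.
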