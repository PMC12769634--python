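"""How many readers does a paired reader study need?

The study design compares per-reader lesion localization fractions with and
without AI assistance using a Wilcoxon signed-rank test.  The A.R.E. method
evaluates the test's power through the paired t-test at an efficiency-
reduced effective sample size.
"""

from hepafroc import PowerSpec, wilcoxon_sample_size
from hepafroc.observer import wilcoxon_power

spec = PowerSpec(dz=1.15, alpha=0.05, power=0.80, tails=2, parent="normal")
n = wilcoxon_sample_size(spec)
print(f"effect size dz = {spec.dz}, alpha = {spec.alpha} (two-tailed), "
      f"target power = {spec.power}")
print(f"minimum number of readers: {n}")
print(f"achieved power at n = {n}: {wilcoxon_power(n, spec):.3f}")
print(f"power at n = {n - 1}:      {wilcoxon_power(n - 1, spec):.3f}")
# The returned n is the first sample size whose Wilcoxon power reaches the
# 80% target; one reader fewer falls short.
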