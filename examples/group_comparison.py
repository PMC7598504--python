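"""Compare RSU measurements across strains with Tukey's HSD letter display.

Three simulated strains with replicate RSU values: a wild type, a mutant
with slightly raised supercoiling, and one clearly hyper-supercoiled.
Groups that share a lowercase letter are not significantly different
(Tukey's HSD at alpha = 0.05); distinct letters mark significant pairs, the
display used on supercoiling figures.
"""

import numpy as np

from topoquant.scstats import compare_groups

rng = np.random.default_rng(2)
groups = {
    "wild_type": rng.normal(1.0, 0.15, 7),
    "speE": rng.normal(1.25, 0.15, 4),
    "speE_oat": rng.normal(2.0, 0.15, 4),
}
result = compare_groups(groups, method="tukey", alpha=0.05)

print(result.summary.to_string(index=False))
print("\npairwise adjusted p-values:")
print(result.pairwise.to_string(index=False))
print("\ngroups sharing a letter are statistically indistinguishable at p < 0.05")
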