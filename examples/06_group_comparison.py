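"""Group comparison with the reporting conventions of the analysis.

Two samples of per-cell shape indices (e.g. a window-proximal region versus
the bulk) are compared with the two-sided Wilcoxon rank-sum test after a
Shapiro-Wilk normality screen; p-values map to the figure bands
* / ** / *** / ns.
"""

import numpy as np

from epifluid import compare_groups, summarize

rng = np.random.default_rng(0)
bulk = rng.normal(3.85, 0.10, size=40)      # solid-like region
proximal = rng.normal(4.30, 0.25, size=25)  # fluidized region near the edge

for name, sample in (("bulk", bulk), ("proximal", proximal)):
    med, mean, sd = summarize(sample)
    print(f"{name:9s}: n={len(sample)} median={med:.3f} mean={mean:.3f} sd={sd:.3f}")

res = compare_groups(proximal, bulk, labels=("proximal", "bulk"))
print()
print(f"{res.test_name}: statistic={res.statistic:.1f}, p={res.p_value:.2e} [{res.significance_band}]")
print(f"normality (Shapiro-Wilk) p per group: {res.normality_p_per_group[0]:.2f}, {res.normality_p_per_group[1]:.2f}")
print()
print("The fluidized region's shape indices are significantly higher (***).")
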