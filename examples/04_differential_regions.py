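"""Find spectral regions that differ between two groups with the BW-ratio.

Simulates a 2 x 10 cohort in which one peak's columns carry a 3-standard-
deviation intensity offset in group B, computes the per-column ratio of the
between-group to the within-group sum of squares, bootstraps its null
distribution from group-mean-centred data, and reports the contiguous
regions exceeding the Bonferroni-adjusted critical value. The reported
region should cover the true effect columns (195-203).
"""

import numpy as np

from clupaq import Peak, bw_analysis, make_group_effect_cohort

cohort, design, truth = make_group_effect_cohort(
    [Peak(200, 80.0, 6.0), Peak(320, 60.0, 7.0)],
    n_per_group=10,
    length=400,
    effect_columns=np.arange(195, 204),
    effect_size=3.0,
    noise_sd=2.0,
    seed=8,
)
profile = bw_analysis(cohort, design, alpha=0.05, n_peaks=2, n_bootstrap=500, seed=9)

print(f"true effect columns:   [195, 204)")
print(f"max BW-ratio:          {np.nanmax(profile.bw):.2f} at column {int(np.nanargmax(profile.bw))}")
print(f"critical value (mean): {profile.critical.mean():.2f} "
      f"(alpha {profile.alpha} / {profile.n_peaks} peaks, {profile.n_bootstrap} bootstrap draws)")
widest = max(profile.regions, key=lambda r: r[1] - r[0])
print(f"significant regions:   {len(profile.regions)}, widest {widest}")
print("the widest region covers the injected effect; with only 2 detected "
      "peaks the per-column level is a lenient alpha/2 = 0.025, so isolated "
      "single-column flags (~2.5% of the 400 columns) are the expected "
      "false-positive background")
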