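"""Pixel-wise group comparison: proportional maps -> z map -> permutation
p values -> cluster-extent correction.

A planted-effect cohort (concern probability 0.6 vs 0.2 in one elliptical
region, 40 subjects per group on a 64x128 raster) is analyzed with 500
relabelings; the surviving mask is compared with the planted ground truth.
"""

import numpy as np

from bodymap import (
    cluster_correct,
    generate_cohort,
    permutation_pmap,
    planted_effect_config,
    proportional_map,
    region_mask,
    subject_concern_mask,
)

cfg = planted_effect_config(p_a=0.6, p_b=0.2, n_a=40, n_b=40, seed=5)
cohort = generate_cohort(cfg)
masks = [subject_concern_mask(s.concerns, cohort.raster_dims) for s in cohort.subjects]
labels = [s.group for s in cohort.subjects]

for g in ("a", "b"):
    pm = proportional_map([m for m, l in zip(masks, labels) if l == g])
    print(f"group {g}: peak proportion {pm.grid.max():.2f} over n={pm.n}")

res = cluster_correct(permutation_pmap(masks, labels, B=500, seed=1, fwhm_px=3.0))
planted = region_mask(cfg, "planted") > 0
surv = res.surviving > 0
jaccard = (surv & planted).sum() / (surv | planted).sum()

print(f"max |z| = {np.abs(res.z).max():.2f}, min p = {res.p_uncorrected.min():.4f}")
print(f"clusters found: {res.clusters.max()}, "
      f"null 95% max-extent = {res.cluster_extent_threshold} px")
print(f"surviving pixels: {int(surv.sum())}, Jaccard vs planted region: {jaccard:.2f}")
print("\nA Jaccard well above 0 means the cluster-corrected map localized the")
print("planted group difference rather than scattered false positives.")
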