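"""Masked colocalization on synthetic two-channel junction images.

Generates junction-like image pairs at three colocalization levels, builds
the contact mask by isodata thresholding of channel 1, and reports the
masked Pearson coefficient, the contact/cytoplasm enrichment ratio and the
group comparison across levels.
"""

import numpy as np

from desmokit.coloc import (compare_coloc_groups, contact_cytoplasm_ratio,
                            cytoplasm_mask, foreground_mask, pearson_in_mask)
from desmokit.synthetic import gen_two_channel_image

groups = {}
for level in (0.9, 0.6, 0.1):
    rs = []
    for rep in range(4):
        ch1, ch2, truth_mask = gen_two_channel_image(
            coloc_level=level, noise_sd=30.0, seed=100 * rep + int(10 * level))
        mask = foreground_mask(ch1)
        res = pearson_in_mask(ch1, ch2, mask)
        rs.append(res.pearson_r)
    groups[f"level_{level}"] = rs
    ratio = contact_cytoplasm_ratio(ch1, mask, cytoplasm_mask(ch1, mask))
    print(f"coloc level {level}: Pearson r = {np.mean(rs):.3f} "
          f"(n={len(rs)} images), contact/cytoplasm ratio = {ratio:.1f}")

out = compare_coloc_groups(groups)
print(f"\none-way ANOVA: F = {out['anova_f']:.1f}, p = {out['anova_p']:.2g}")
print("letter display:", out["letters"])
print("\nGroups sharing a letter are statistically indistinguishable "
      "(Tukey all-pairs, alpha 0.05); the masked Pearson tracks the "
      "planted correlation (attenuated by read noise) and the ratio "
      "tracks contact enrichment.")
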