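"""Extract the 25 per-region univariate features from a small cohort.

Each region's series is summarized by the canonical 22-feature set (on the
z-scored signal) plus the raw mean, raw SD, and fALFF. The printed table
shows how the planted timescale shift (a higher AR coefficient in region 0)
surfaces in the autocorrelation-based features.
"""

import numpy as np

from dynsig import CohortSpec, compute_feature_tensor, generate_cohort

spec = CohortSpec(
    n_per_group=(10, 10), n_regions=4, n_timepoints=152, tr_seconds=2.0,
    base_ar=0.2, ar_shift=((0,), 0.5), seed=7,
)
cohort = generate_cohort(spec)
feats = compute_feature_tensor(cohort)
groups = np.array(cohort.group_labels())

print(f"feature tensor: {feats.values.shape}  (subjects x regions x features)")
for name in ("ACF_timescale", "fALFF", "SD"):
    fi = feats.feature_index(name)
    case = feats.values[groups == "case", 0, fi].mean()
    ctrl = feats.values[groups == "control", 0, fi].mean()
    print(f"{name:14s} region_0  case {case:7.3f}  control {ctrl:7.3f}")
print("A longer autocorrelation timescale in the case group (the planted "
      "AR shift) raises ACF_timescale and the low-frequency power share (fALFF).")
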