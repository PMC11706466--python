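"""Case-control classification across the five representation families.

A planted coupling effect (stronger region-0/region-1 interaction in cases)
is classified from: single-region features, single-feature maps, the full
region x feature block, the Pearson coupling map, and coupling + features.
Balanced accuracy of 50% is chance for any class ratio.
"""

from dynsig import (
    CohortSpec,
    build_representation,
    compute_coupling_tensor,
    compute_feature_tensor,
    generate_cohort,
    make_fold_plan,
    run_repeated_cv,
)

spec = CohortSpec(
    n_per_group=(25, 25), n_regions=5, n_timepoints=120, seed=3,
    coupling_shift=(((0, 1), (1, 0)), 0.4),
)
cohort = generate_cohort(spec)
groups = cohort.group_labels()
feats = compute_feature_tensor(cohort)
pearson = compute_coupling_tensor(cohort, ["Pearson"])[0]

reps = [
    build_representation("A_region", feature_tensor=feats, groups=groups, region="region_0"),
    build_representation("A_feature", feature_tensor=feats, groups=groups, feature="SD"),
    build_representation("A_uni_combo", feature_tensor=feats, groups=groups),
    build_representation("A_FC", coupling_tensor=pearson, groups=groups),
    build_representation("A_FC_combo", feature_tensor=feats, coupling_tensor=pearson, groups=groups),
]
plan = make_fold_plan(reps[0].y, k=10, repeats=10, seed=1)  # shared folds
for rep in reps:
    ev = run_repeated_cv(rep, plan=plan)
    print(f"{rep.tag:24s} D={rep.n_features:4d}  "
          f"balanced accuracy {ev.mean_ba:5.1f} ± {ev.sd_ba:4.1f}%")
print("\nThe coupling-based representations see the planted interaction "
      "directly; purely regional features detect only its weak marginal echo.")
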