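"""Generate a synthetic resequencing cohort and recover its planted truth.

The generator plants fixed divergence SNPs between two sample groups,
genuine heteroplasmic sites, and three artifact classes (coverage inflation
over shared DNA, repeat-associated candidates, clustered candidate pairs,
plus positions whose reference-allele coverage betrays cross-mapping).  The
filtering pipeline should recover the truth exactly and reject each artifact
with the filter built for it.
"""

import pandas as pd

from odrift import (
    CohortConfig,
    call_fixed,
    call_heteroplasmic,
    evaluate_calls,
    generate_cohort,
    genetic_distance,
    neutral_mask,
    sample_and_position_qc,
    substitution_rate,
)

config = CohortConfig(
    mt_length=20_000, pt_length=15_000, group_sizes=(2, 2),
    divergence_snps_mt=20, divergence_snps_pt=8,
    n_repeats=6, n_shared=4,
    median_coverage_mt=900.0, median_coverage_pt=3000.0, seed=5,
)
records, truth = generate_cohort(config)

hets, fixeds, rejs = [], [], []
for org in ("mt", "pt"):
    ann = truth.annotations[org]
    qcd, log = sample_and_position_qc(records, ann, org)
    print(log.summary())
    fixeds.append(call_fixed(qcd, neutral_mask(ann, org, "fixed")))
    het, rej = call_heteroplasmic(qcd, neutral_mask(ann, org, "heteroplasmy"), ann)
    hets.append(het)
    rejs.append(rej)

report = evaluate_calls(pd.concat(hets), pd.concat(fixeds), truth,
                        rejected=pd.concat(rejs))
print()
print("heteroplasmy:", report["heteroplasmy"])
print("fixed       :", report["fixed"])
for art in report["artifacts"]:
    print(f"  artifact {art['class']:<12} caught={art['caught']} "
          f"by={art['caught_by']}")

ann = truth.annotations["mt"]
qcd, _ = sample_and_position_qc(records, ann, "mt")
mask = neutral_mask(ann, "mt", "fixed")
d, sd = genetic_distance(qcd, mask, truth.samples["A"], truth.samples["B"])
sr = substitution_rate(d, int(mask.sum()), 243_300)
print()
print(f"mt genetic distance {d:.1f} SNPs over {int(mask.sum())} neutral bp")
print(f"-> substitution rate {sr.rate:.2e} per bp per year")
print("Precision and recall of 1.0 mean every planted variant was recovered")
print("and every artifact was filtered out before calling.")
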