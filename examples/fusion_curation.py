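"""Filter fusion calls through the four artifact rules.

The synthetic cohort plants real fusions plus the four artifact classes:
same-family partners, unofficial symbols, near-ubiquitous cohort
frequency, and presence in normal tissue.
"""

from collections import Counter

from canthyro.fusions import filter_fusions
from canthyro.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=6, n_genes=250, n_tumors_subtype1=10,
                                      n_tumors_subtype2=10, n_normals=5,
                                      n_marker_genes_per_subtype=30))

report = filter_fusions(
    cohort.fusion_calls,
    normal_sample_ids=set(cohort.normal_samples),
    n_tumor_samples=len(cohort.tumor_samples),
)

print(f"tumor calls retained: {len(report.retained)}, removed: {len(report.removed)}")
print("removal reasons:", dict(Counter(reason for _, reason in report.removed)))
print("recurrence of retained fusions (distinct samples):")
for (g5, g3), n in sorted(report.recurrence.items(), key=lambda kv: -kv[1]):
    print(f"  {g5}--{g3}: {n}")
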