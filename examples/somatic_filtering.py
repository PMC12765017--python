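"""Germline subtraction, RNA variant rules, TMB and oncoplot genes.

Runs the tumor-WES somatic cascade with complete germline resources, the
stricter RNA-seq rule set, computes the per-sample mutational burden and
selects oncoplot genes.
"""

from collections import Counter

from canthyro.synthetic import CohortConfig, generate_cohort, resources_from_truth, variant_id
from canthyro.variants import (
    compute_tmb,
    rna_variant_filter,
    select_oncoplot_genes,
    wes_somatic_filter,
)

cohort = generate_cohort(CohortConfig(seed=5, n_genes=250, n_tumors_subtype1=10,
                                      n_tumors_subtype2=10, n_normals=5,
                                      n_marker_genes_per_subtype=30,
                                      n_somatic_per_sample=40, n_germline_per_sample=60,
                                      reference_length=30000))
resources = resources_from_truth(cohort)

somatic = wes_somatic_filter(cohort.wes_tumor_variants, resources)
truth = {k for k, g in cohort.truth_genotype.items() if g == "somatic"}
print(f"WES calls {len(cohort.wes_tumor_variants)} -> somatic {len(somatic)} "
      f"(truth {len(truth)}, errors {len({variant_id(v) for v in somatic} ^ truth)})")

rna_kept = rna_variant_filter(cohort.rna_variants, resources)
print(f"RNA calls {len(cohort.rna_variants)} -> retained {len(rna_kept)}")

mb = len(cohort.reference_sequence) / 1e6
for sample in cohort.tumor_samples[:3]:
    tmb = compute_tmb([v for v in somatic if v.sample_id == sample], mb)
    print(f"  {sample}: TMB {tmb:.1f} nonsynonymous/Mb over {mb:.2f} Mb")

counts = Counter(v.gene_id for v in somatic)
cancer_genes = {g for g, _ in counts.most_common(5)}
selection = select_oncoplot_genes(somatic, cancer_genes, {}, set(),
                                  n_samples=len(cohort.tumor_samples))
print(f"oncoplot genes: {selection.selected_genes}")
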