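"""96-type spectra and de novo signature extraction.

Builds trinucleotide-context spectra for the synthetic cohort's somatic
variants, extracts two de novo signatures with KL-divergence NMF and
matches them against the generator's own catalog.
"""

import pandas as pd

from canthyro.signatures import build_spectrum, extract_signatures, match_reference, CHANNELS_96
from canthyro.synthetic import BUILTIN_SIGNATURES, CohortConfig, generate_cohort, variant_id

cohort = generate_cohort(CohortConfig(seed=2, n_genes=250, n_tumors_subtype1=10,
                                      n_tumors_subtype2=10, n_normals=5,
                                      n_marker_genes_per_subtype=30,
                                      n_somatic_per_sample=80, reference_length=60000))

somatic = [v for v in cohort.wes_tumor_variants
           if cohort.truth_genotype[variant_id(v)] == "somatic"]
spectra = build_spectrum(somatic, cohort.reference_context)
print(f"spectra: {spectra.shape[0]} samples x {spectra.shape[1]} channels, "
      f"{int(spectra.to_numpy().sum())} SNVs")

extracted = extract_signatures(spectra, k=2, seed=0, n_restarts=5)
print(f"reconstruction error (KL): {extracted.reconstruction_error:.1f}")

catalog = pd.DataFrame(
    {name: vec for name, vec in BUILTIN_SIGNATURES.items()}, index=list(CHANNELS_96)
)
matches = match_reference(extracted, catalog, novelty_threshold=0.80)
print(matches)
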