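"""Project protein variant positions across an ortholog pair.

Aligns a synthetic ortholog pair (substitutions plus indels) and lifts
single-residue substitutions over the alignment, flagging residues that
sit opposite gaps or carry a discordant reference residue.
"""

from canthyro.orthomap import align_pair, project_hgvsp
from canthyro.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=4, n_genes=250, n_tumors_subtype1=10,
                                      n_tumors_subtype2=10, n_normals=5,
                                      n_marker_genes_per_subtype=30))
gene, src, tgt, truth = cohort.ortholog_pairs[0]

amap = align_pair(src, tgt, source_id=gene, target_id=gene + "_target")
print(f"{gene}: {amap.source_length} aa vs {amap.target_length} aa, "
      f"identity {amap.identity_fraction:.2f}, score {amap.score:.0f}")

correct = sum(amap.source_to_target().get(s) == t for s, t in truth.items())
print(f"truth positions recovered: {correct}/{len(truth)}")

for pos in (10, 50, 120):
    hgvsp = f"p.{src[pos - 1]}{pos}A"
    out = project_hgvsp(amap, hgvsp, tgt)
    if out.target_pos is None:
        print(f"  {hgvsp}: unmapped ({out.reason})")
    else:
        tag = "concordant" if out.concordant else "discordant reference"
        print(f"  {hgvsp} -> {out.target_hgvsp} ({tag})")
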