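"""Thyroid differentiation (TDS), MAPK activity (MPAS) and ERK scores.

Scores a synthetic cohort and shows that TDS tracks the planted
differentiation gradient while MPAS is the z-score sum over the ten MAPK
target genes divided by sqrt(10).
"""

from scipy.stats import spearmanr

from canthyro.expression import log2_layer
from canthyro.scores import ScoreGeneSets, score_table
from canthyro.synthetic import CohortConfig, ERK_GENES, TDS_GENES, generate_cohort

cohort = generate_cohort(CohortConfig(seed=3, n_genes=250, n_tumors_subtype1=10,
                                      n_tumors_subtype2=10, n_normals=5,
                                      n_marker_genes_per_subtype=30))
log = log2_layer(cohort.expression)[cohort.tumor_samples]
sets = ScoreGeneSets(tds_genes=TDS_GENES, erk_genes=ERK_GENES)

table = score_table(log, sets)
print(table.head())

planted = log.loc[list(TDS_GENES)].mean(axis=0)
rho = spearmanr(table["TDS"], planted).statistic
print(f"\nTDS vs planted differentiation gradient: Spearman rho = {rho:.3f}")
print(f"MPAS range across tumors: [{table['MPAS'].min():.2f}, {table['MPAS'].max():.2f}]")
print(f"genes used per score: {table.attrs['n_genes_used']}")
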