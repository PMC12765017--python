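# Methods note

This note records the models, conventions and parameter choices behind each
module, including decisions on points where common practice varies.

## Expression normalization and clustering (`canthyro.expression`)

**Median-of-ratios.** Reference genes are those with a strictly positive
count in every sample. For sample *j*, the size factor is the plain median
over reference genes of `count(g,j) / geomean_s(count(g,s))`. At an even
reference-gene count this is the arithmetic midpoint of the two central
ratios (some implementations take the geometric midpoint via
`exp(median(log ratio))`; both agree at odd counts). Size factors are defined
only up to the pseudo-reference scale: rescaling one library by *c* moves its
size factor relative to the others by *c* but also shifts every geometric
mean, so only size-factor ratios are equivariant.

**Filtering.** The low-expression filter keeps genes with ≥ `min_reads`
(default 10) in ≥ `min_samples` (default 5) samples, both inclusive.
Variable-gene selection uses strict thresholds: mean of log2(normalized + 1)
**>** 2 and sample variance (ddof = 1) **>** 6. "Mean log2 expression" is
read as the mean of the log-transformed values, not the log of the mean; the
two differ and the source material does not disambiguate. The default
variance cutoff of 6 reflects bulk RNA-seq scale; desk-scale synthetic
cohorts need a lower cutoff (the examples use 1.0) because their
negative-binomial dispersion produces smaller log-scale variances.

**Clustering.** Genes are z-scored, samples embedded with UMAP
(2 components, `n_neighbors = min(15, n−1)`, `min_dist = 0.1`, fixed
`random_state`, single-threaded) and clustered with k-means (`n_init = 10`)
on the embedding. Clustering on the 2-D embedding, rather than the full
matrix, mirrors the visualization-driven cluster definition used in
practice. Results are deterministic given the seed.

## Signature scores (`canthyro.scores`)

- **TDS**: sum over 16 thyroid genes of the sample's log2 expression minus
  the cohort median for that gene. A sample sitting at every gene median
  scores exactly 0.
- **MPAS**: `Σ z / √10` over the 10 MAPK target genes (CCND1, DUSP4, DUSP6,
  EPHA2, EPHA4, ETV4, ETV5, PHLDA1, SPRY2, SPRY4); unit z-scores give √10.
  Genes are z-scored with ddof = 1; constant genes map to z = 0.
- **ERK score**: mean z over the ERK target panel. The full panel has 52
  genes; 11 are not resolvable in the dog annotation, so scoring uses the 41
  available ones when an availability mask is supplied (`n_genes_used` is
  recorded on the result).

Score–expression correlation screens use rank (Spearman) or linear
correlation with a t-approximation p-value, switching to the exact
permutation null for n ≤ 8, and Benjamini-Hochberg adjustment. BH was chosen
over the local-FDR approach used by some pipelines because it is
deterministic, assumption-light, and reproducible without a fitted mixture
model. Pre-ranked enrichment uses the weighted running-sum statistic
(weight = |score|), gene-label permutations, and a two-sided p on |ES| with
the (1 + hits)/(n + 1) estimator.

## Variant filtering (`canthyro.variants`)

The tumor-exome somatic cascade keeps a call iff it is PASS **and** absent
from the sample's matched-normal index **and** absent from the panel of
normals **and** absent from the population germline resource. A tumor sample
without a matched normal is an error, not a silent pass-through. The RNA
rule set is deliberately stricter and never consults the matched normal:
depth **> 10** and alt reads **> 5** (strict inequalities), non-splice
consequence (splice acceptor/donor/region), allele fraction in the
**inclusive** window [0.25, 0.85]. Strictness and inclusivity at the
boundaries follow the wording "more than" and "between" in the protocol
text; both are unit-tested at the exact boundary values.

TMB counts nonsynonymous coding variants (missense, nonsense, start/stop
loss, frameshift, inframe indels, splice acceptor/donor) per megabase.

Oncoplot selection admits a gene when (a) it is a cancer-associated gene
mutated in ≥ ⌈0.10 · n⌉ samples, (b) it is mutated in **exactly one** sample
with a driver-predicted variant — two-sample driver genes do not qualify
under this rule and must enter via recurrence — or (c) it is a thyroid-panel
gene passing the same recurrence bar.

## Mutational signatures (`canthyro.signatures`)

Spectra use the 96 pyrimidine-frame channels in lexicographic
(substitution class, 5' base, 3' base) order; purine-reference calls are
reverse-complemented. Factorization is scikit-learn NMF with
`solver="mu"`, `beta_loss="kullback-leibler"`, random initialization, and
`n_restarts` (default 10) sub-seeded restarts keeping the best objective;
signature columns are renormalized to sum 1 with exposures rescaled.
Catalog matching is best-cosine; below 0.80 a signature is reported novel.

A factorization caveat verified during development: if every sample carries
substantial exposure to every signature (exposures bounded away from zero),
the KL factorization is non-identifiable — mass can leak between components
without changing the fit — and recovery cosine plateaus around 0.95-0.97 no
matter how deep the counts. Recovery tests therefore plant sparse
(gamma-distributed) exposures so some samples are dominated by each
signature, which restores identifiability; real cohorts typically satisfy
this naturally.

## Ortholog liftover (`canthyro.orthomap`)

One **global** pairwise alignment per ortholog pair (BLOSUM62, affine gaps:
first gap position −11, each further position −1, end gaps penalized) defines
a monotone residue correspondence. Global rather than local alignment was
chosen because liftover needs every residue assigned a fate; local alignment
would leave flanking regions silently unmapped. Positions opposite gaps are
reported unmapped rather than interpolated. Single-residue substitutions in
HGVSp notation are projected; frameshifts, indels and stop-affecting changes
pass through unprojected with a reason. The projected record keeps a
concordance flag for whether the target holds the same reference residue;
discordant projections are flagged, not dropped.

## Fusion curation (`canthyro.fusions`)

Four removal rules, evaluated in order with the first match recorded:
(a) same gene family (identical symbol stem after stripping trailing
digits), (b) unofficial symbol (explicit allow-list, or placeholder-prefix
heuristic: LOC/ENSCAF/ENSG), (c) called in **> 80%** of tumor samples
(strict; the denominator counts tumor samples only, so normal-tissue calls
cannot dilute the fraction), (d) identical ordered fusion present in normal
tissue. Calls from normal samples are evidence for rule (d) only and are
returned separately. Recurrence counts distinct samples per ordered
5'→3' partner pair.

## DNA repair pathways (`canthyro.dnarepair`)

Genotype is a pure function of the detection pattern: matched-normal
presence → germline; else tumor-exome presence → somatic; else (RNA only) →
unassigned. Variant identity for deduplication is (sample, gene, protein
change). The packaged table of 26 curated repair-gene variants summarizes to
24 genes, 18/30 tumors (60%), and 11 germline / 8 somatic / 7 unassigned.

One documented inconsistency is preserved rather than resolved: the source
material states 17 tumors carry DSBR and/or MMR variants in the text, but a
figure caption implies 16 carriers vs 11 non-carriers (16 + 11 = 27, the
exome cohort). Applying this package's carrier definition to the packaged
table yields 17 carriers among the 30 sequenced tumors, consistent with the
text; the 16/11 split is consistent with restricting to the 27 exome-bearing
tumors. The MSI association test is an exact rank-sum comparison of MSI
scores between carriers and non-carriers.

## Cohort statistics (`canthyro.stats`)

Ordinal categories are scored by their printed order (e.g. follicular <
follicular-compact < compact; differentiation well < moderate < poor) with
midranks for ties. The exact two-sided Mann-Whitney p sums null
probabilities of outcomes with |U − E[U]| ≥ observed ("symmetric"
convention; a tail-doubling convention is available by flag). The null
enumerates group-1 category compositions under the multivariate
hypergeometric; `auto` mode uses the exact path when total n ≤ 60 **and**
the enumeration is small (heavily tied tables), falling back to the
tie-corrected normal approximation for effectively continuous data, where
the composition count grows exponentially. Under the symmetric convention
the packaged clinical fixture reproduces the reported comparisons:
histologic pattern p = 0.001498 (reported 0.0015), differentiation
p = 0.001504, HER2 p = 0.000722 (reported 0.0007), calcitonin p ≈ 1.1e-6
(reported < 0.0001). Which convention the original software used is unknown;
these are reproduction-within-convention results, not exact-match claims.

Survival uses Kaplan-Meier medians (reported "not reached" when the curve
never crosses 0.5), the two-sided log-rank test, and a single-covariate Cox
fit for the hazard ratio (reference group first lexicographically unless
overridden; 95% CI by normal approximation on the log hazard, with infinite
bounds under complete separation).

## Synthetic cohort generator (`canthyro.synthetic`)

The generator emulates the statistical structure the pipeline assumes, not
the biology: negative-binomial counts (dispersion 0.15, i.e. r = 1/0.15)
with 50 planted marker genes per subtype at +2 log2 and a per-tumor
differentiation gradient on the TDS genes; germline and somatic SNVs placed
on a single synthetic chromosome at positions whose reference trinucleotide
matches the channel drawn from a signature mixture (forward or
reverse-complement strand); germline calls mirrored into per-sample normal
VCFs; fusion calls including all four artifact classes with truth labels;
ortholog protein pairs with recorded residue correspondences; exponential
survival with a tumor-size-dependent log hazard and exponential censoring.

It does **not** emulate: linked mutational processes (each variant's channel
is i.i.d. from the mixture), copy number, subclonal allele-fraction
structure, batch effects, or realistic gene-gene correlation. Determinism:
each modality draws from `numpy.random.default_rng([seed, modality_index])`,
so changing, say, the variant budget cannot perturb the expression draw.

## Numerical conventions

- Variances and z-scores use ddof = 1 throughout; constant vectors give
  z = 0 rather than NaN.
- Exact-test probabilities are computed in log space (`lgamma`) and compared
  with a 1e-9 slack to absorb floating-point ties.
- log2 transforms use a +1 pseudocount.
- Seeds are plain integers; restart/sub-stream seeds derive from
  `numpy.random.SeedSequence.spawn`.

## Problem sizes used in validation

Unit and acceptance tests run at desk scale: 20-25 tumor cohorts with 250
genes and 40-80 variants per sample; all 17,655 3-category/2-group ordinal
tables with n ≤ 12 against a full subject-subset enumeration oracle; 100
random 60-residue protein pairs against an independent affine-gap DP oracle;
20-seed clustering recovery; 200-seed Cox recovery of a true hazard ratio of
3.0; 200-draw enrichment calibration and 2000-draw exact rank-sum type-I
checks. Cohort-scale quantities that require the original sequencing data
(per-sample TMB near 2.9/Mb, genome-wide differential-expression counts)
are out of scope and covered instead by the property checks above.
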