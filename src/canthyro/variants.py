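"""Somatic variant post-processing.

Implements the germline-subtraction cascade used for tumor whole-exome
calls (PASS filter, matched normal, panel of normals, population germline
resource), the stricter rule set applied to RNA-seq variant calls (depth,
alternate allele count, splice-term removal and an allele-fraction window),
canonical-isoform consequence mapping, tumor mutational burden, and the
gene-selection rules used to build a cohort oncoplot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VariantRecord",
    "GermlineResources",
    "OncoplotSelection",
    "SPLICE_TERMS",
    "NONSYNONYMOUS_TERMS",
    "normalize_site",
    "wes_somatic_filter",
    "rna_variant_filter",
    "map_canonical",
    "compute_tmb",
    "select_oncoplot_genes",
]

#: Consequence terms treated as splice variants by the RNA filter.
SPLICE_TERMS = frozenset({"splice_acceptor", "splice_donor", "splice_region"})

#: Protein-altering consequence terms counted by the mutational burden.
NONSYNONYMOUS_TERMS = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift",
        "inframe_insertion",
        "inframe_deletion",
        "splice_acceptor",
        "splice_donor",
    }
)


@dataclass
class VariantRecord:
    """A single called variant with its sample, position, allele evidence
    and annotated consequence.  ``source`` records the detection assay."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    filter_status: frozenset = frozenset({"PASS"})
    depth: int = None
    alt_count: int = None
    allele_fraction: float = None
    consequence: str = ""
    gene_id: str = ""
    transcript_id: str = ""
    hgvsp: str = ""
    source: str = "wes_tumor"  # wes_tumor | wes_normal | rna

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if isinstance(self.filter_status, str):
            self.filter_status = frozenset(self.filter_status.split(";"))
        else:
            self.filter_status = frozenset(self.filter_status)
        if self.depth is not None and self.alt_count is not None:
            if self.alt_count > self.depth:
                raise ValueError(f"alt_count {self.alt_count} > depth {self.depth}")
            if self.allele_fraction is None and self.depth > 0:
                self.allele_fraction = self.alt_count / self.depth

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref != self.alt

    def site_key(self):
        return normalize_site(self.chrom, self.pos, self.ref, self.alt)

    def sample_site_key(self):
        return (self.sample_id,) + self.site_key()


def normalize_site(chrom: str, pos: int, ref: str, alt: str):
    """Normalized site identity: uppercase alleles, redundant padding
    trimmed from the right then the left (left-aligned representation)."""
    ref, alt = ref.upper(), alt.upper()
    # trim shared suffix, keeping at least one base on each allele
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix, advancing the position
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


@dataclass
class GermlineResources:
    """Germline evidence used to subtract non-somatic variants.

    ``matched_normal_index`` holds per-sample sites seen in that sample's
    matched normal; ``panel_of_normals`` and ``population_sites`` are
    sample-agnostic site blacklists.  ``normal_samples`` lists the tumor
    samples for which a matched normal exists (a tumor sample absent from
    it cannot go through the WES cascade).
    """

    matched_normal_index: set = field(default_factory=set)  # (sample, chrom, pos, ref, alt)
    panel_of_normals: set = field(default_factory=set)  # (chrom, pos, ref, alt)
    population_sites: set = field(default_factory=set)
    normal_samples: set = None

    def __post_init__(self):
        if self.normal_samples is None:
            self.normal_samples = {k[0] for k in self.matched_normal_index}


class MissingNormalError(ValueError):
    pass


def wes_somatic_filter(tumor_variants, resources: GermlineResources):
    """Germline-subtraction cascade for tumor WES calls.

    A call survives iff it carries PASS, is absent from the sample's
    matched-normal index, absent from the panel of normals and absent from
    the population germline resource.  Input order is preserved; a tumor
    sample without a matched normal raises.
    """
    out = []
    for v in tumor_variants:
        if v.sample_id not in resources.normal_samples:
            raise MissingNormalError(f"no matched normal for sample {v.sample_id!r}")
        if "PASS" not in v.filter_status:
            continue
        key = v.site_key()
        if (v.sample_id,) + key in resources.matched_normal_index:
            continue
        if key in resources.panel_of_normals or key in resources.population_sites:
            continue
        out.append(v)
    return out


def rna_variant_filter(
    rna_variants,
    resources: GermlineResources,
    min_depth: int = 10,
    min_alt_count: int = 5,
    af_range=(0.25, 0.85),
    depth_strict: bool = True,
    af_inclusive: bool = True,
):
    """RNA-seq variant rule set (no matched normal is used).

    Retains calls with depth > ``min_depth`` and alternate count >
    ``min_alt_count`` (strict by default), a non-splice consequence, an
    allele fraction inside ``af_range`` (inclusive by default), that are
    absent from the panel of normals and the population resource.
    """
    lo, hi = af_range
    out = []
    for v in rna_variants:
        if v.depth is None or v.alt_count is None or v.allele_fraction is None:
            raise ValueError(f"RNA variant at {v.chrom}:{v.pos} lacks DP/AD evidence")
        if depth_strict:
            if not (v.depth > min_depth and v.alt_count > min_alt_count):
                continue
        else:
            if not (v.depth >= min_depth and v.alt_count >= min_alt_count):
                continue
        if v.consequence in SPLICE_TERMS:
            continue
        af = v.allele_fraction
        if af_inclusive:
            if not (lo <= af <= hi):
                continue
        else:
            if not (lo < af < hi):
                continue
        key = v.site_key()
        if key in resources.panel_of_normals or key in resources.population_sites:
            continue
        out.append(v)
    return out


def map_canonical(variants, transcript_table: dict):
    """Collapse multi-transcript annotations to one row per variant using
    the canonical isoform.

    ``variants`` may contain several records per (sample, site) differing
    only in transcript annotation.  For each variant the row whose
    ``transcript_id`` equals the gene's canonical transcript is kept; when
    the gene is absent from the table, or no row matches the canonical
    transcript, the first row is passed through and its key is reported in
    the returned ``flagged`` list instead of being dropped.

    Returns ``(mapped_records, flagged_keys)``.
    """
    groups: dict = {}
    order = []
    for v in variants:
        key = v.sample_site_key()
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(v)

    mapped, flagged = [], []
    for key in order:
        rows = groups[key]
        gene = rows[0].gene_id
        canonical = transcript_table.get(gene)
        chosen = None
        if canonical is not None:
            for r in rows:
                if r.transcript_id == canonical:
                    chosen = r
                    break
        if chosen is None:
            chosen = rows[0]
            flagged.append(key)
        mapped.append(chosen)
    return mapped, flagged


def compute_tmb(somatic_coding_variants, megabases_sequenced: float) -> float:
    """Tumor mutational burden: non-synonymous protein-coding somatic
    variants per megabase of sequenced target."""
    if megabases_sequenced <= 0:
        raise ValueError("megabases_sequenced must be positive")
    n = sum(1 for v in somatic_coding_variants if v.consequence in NONSYNONYMOUS_TERMS)
    return n / megabases_sequenced


@dataclass
class OncoplotSelection:
    selected_genes: list
    reasons: dict  # gene -> set of reasons


def select_oncoplot_genes(
    variants,
    cancer_genes: set,
    driver_predictions: dict,
    thyroid_genes: set,
    n_samples: int,
    recurrence_fraction: float = 0.10,
) -> OncoplotSelection:
    """Oncoplot gene-selection rules.

    A gene enters the plot when it is (a) a cancer-associated gene mutated
    in at least ``ceil(recurrence_fraction * n_samples)`` samples, (b)
    mutated in exactly one sample with at least one variant predicted to
    be a driver (``driver_predictions`` maps a variant's
    ``sample_site_key()`` to ``"driver"``/``"passenger"``; unscored
    variants default to passenger), or (c) a thyroid-panel gene mutated
    recurrently as in (a).  Every selected gene records its reasons.
    """
    min_recurrent = math.ceil(recurrence_fraction * n_samples)
    by_gene_samples: dict = {}
    by_gene_driver: dict = {}
    for v in variants:
        if not v.gene_id:
            continue
        by_gene_samples.setdefault(v.gene_id, set()).add(v.sample_id)
        pred = driver_predictions.get(v.sample_site_key(), "passenger")
        if pred == "driver":
            by_gene_driver[v.gene_id] = True

    reasons: dict = {}
    for gene, samples in by_gene_samples.items():
        r = set()
        if gene in cancer_genes and len(samples) >= min_recurrent:
            r.add("recurrent_cancer_gene")
        if len(samples) == 1 and by_gene_driver.get(gene, False):
            r.add("singleton_driver")
        if gene in thyroid_genes and len(samples) >= min_recurrent:
            r.add("recurrent_thyroid_gene")
        if r:
            reasons[gene] = r
    return OncoplotSelection(selected_genes=sorted(reasons), reasons=reasons)
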