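"""DNA-repair-pathway variant classification and cohort summaries.

Variants in genes of four repair pathways — mismatch repair (MMR), base
excision repair (BER), nucleotide excision repair (NER) and double-strand
break repair (DSBR) — are classified by where they were detected:
presence in the matched normal means germline; presence in tumor WES
and/or RNA but not the normal means somatic; RNA-only detections cannot be
confidently assigned.  The module ships the cohort's curated repair-gene
variant table and pathway gene sets as editable fixtures, and tests
whether repair-mutant tumors carry higher microsatellite-instability (MSI)
scores via an exact rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _res

import pandas as pd

from .stats import mann_whitney_values

__all__ = [
    "PATHWAYS",
    "RepairPathwaySets",
    "DrpSummary",
    "load_pathway_sets",
    "load_drp_variant_table",
    "map_pathways",
    "assign_genotype",
    "summarize_drp",
    "msi_association",
]

PATHWAYS = ("MMR", "BER", "NER", "DSBR")


@dataclass
class RepairPathwaySets:
    """Gene sets per pathway; a gene may belong to several pathways."""

    sets: dict  # pathway -> frozenset of gene ids

    def __post_init__(self):
        if set(self.sets) != set(PATHWAYS):
            raise ValueError(f"expected exactly the pathways {PATHWAYS}")
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}

    def pathways_of(self, gene: str) -> tuple:
        return tuple(p for p in PATHWAYS if gene in self.sets[p])


@dataclass
class DrpSummary:
    n_variants: int
    n_genes: int
    n_samples_mutated: int
    fraction_of_cohort: float
    genotype_counts: dict
    pathway_counts: dict


def _read_gmt_text(text: str) -> dict:
    sets = {}
    for line in text.strip().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            continue
        sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def load_pathway_sets(path=None) -> RepairPathwaySets:
    """Pathway gene sets from a GMT file (packaged fixture by default)."""
    if path is None:
        text = _res.files("canthyro.data").joinpath("dna_repair_pathways.gmt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return RepairPathwaySets(sets=_read_gmt_text(text))


def load_drp_variant_table(path=None) -> pd.DataFrame:
    """The curated cohort table of repair-gene variants.

    Columns: sample, gene, hgvsp, pipeline, pathways (comma list),
    detection_sources (semicolon list over rna/wes_tumor/wes_normal),
    breed.
    """
    if path is None:
        with _res.files("canthyro.data").joinpath("drp_variants.tsv").open() as fh:
            return pd.read_csv(fh, sep="\t")
    return pd.read_csv(path, sep="\t")


def map_pathways(variants: pd.DataFrame, sets: RepairPathwaySets, gene_col: str = "gene") -> pd.DataFrame:
    """Annotate each variant row with every pathway containing its gene;
    rows whose gene belongs to no pathway are dropped (they do not enter
    repair-pathway summaries)."""
    ann = variants.copy()
    ann["pathways"] = [",".join(sets.pathways_of(g)) for g in ann[gene_col]]
    return ann[ann["pathways"] != ""].reset_index(drop=True)


def assign_genotype(detection_sources) -> str:
    """Genotype from detection pattern across assays.

    matched normal seen -> germline; else tumor WES seen -> somatic;
    else (RNA only) -> unassigned.
    """
    sources = set(detection_sources)
    if not sources:
        raise ValueError("detection_sources must be non-empty")
    unknown = sources - {"rna", "wes_tumor", "wes_normal"}
    if unknown:
        raise ValueError(f"unknown detection sources: {sorted(unknown)}")
    if "wes_normal" in sources:
        return "germline"
    if "wes_tumor" in sources:
        return "somatic"
    return "unassigned"


def _sources_of(cell) -> set:
    if isinstance(cell, str):
        return {s for s in cell.split(";") if s}
    return set(cell)


def summarize_drp(annotated: pd.DataFrame, cohort_sample_ids) -> DrpSummary:
    """Cohort summary of repair-pathway variants.

    Variant identity for deduplication is (sample, gene, hgvsp); the
    summary counts distinct variants, distinct genes, and the fraction of
    the cohort roster with at least one variant, plus genotype and
    pathway breakdowns (a multi-pathway variant counts once per pathway).
    """
    cohort = set(cohort_sample_ids)
    if not cohort:
        raise ValueError("cohort_sample_ids must be non-empty")
    dedup = annotated.drop_duplicates(subset=["sample", "gene", "hgvsp"])
    genotype_counts = {"germline": 0, "somatic": 0, "unassigned": 0}
    pathway_counts = {p: 0 for p in PATHWAYS}
    for _, row in dedup.iterrows():
        genotype_counts[assign_genotype(_sources_of(row["detection_sources"]))] += 1
        for p in str(row["pathways"]).split(","):
            if p in pathway_counts:
                pathway_counts[p] += 1
    mutated = set(dedup["sample"]) & cohort
    return DrpSummary(
        n_variants=len(dedup),
        n_genes=dedup["gene"].nunique(),
        n_samples_mutated=len(mutated),
        fraction_of_cohort=len(mutated) / len(cohort),
        genotype_counts=genotype_counts,
        pathway_counts=pathway_counts,
    )


def dsbr_mmr_carriers(annotated: pd.DataFrame) -> set:
    """Samples carrying at least one DSBR and/or MMR pathway variant."""
    carriers = set()
    for _, row in annotated.iterrows():
        pw = set(str(row["pathways"]).split(","))
        if pw & {"DSBR", "MMR"}:
            carriers.add(row["sample"])
    return carriers


def msi_association(msi_scores: dict, drp_groups: dict, mode: str = "auto"):
    """Rank-sum comparison of MSI scores between repair-mutant and
    non-mutant tumors.

    ``msi_scores`` maps sample -> score; ``drp_groups`` maps sample ->
    'mutant' | 'nonmutant' (by convention, carriers of DSBR and/or MMR
    variants).  Returns (U, two-sided p) for the mutant group.
    """
    mutant = [msi_scores[s] for s, g in drp_groups.items() if g == "mutant" and s in msi_scores]
    nonmut = [msi_scores[s] for s, g in drp_groups.items() if g == "nonmutant" and s in msi_scores]
    if not mutant or not nonmut:
        raise ValueError("both mutant and nonmutant groups must be non-empty")
    return mann_whitney_values(mutant, nonmut, mode=mode)
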