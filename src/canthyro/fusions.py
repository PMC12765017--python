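"""Fusion-call curation.

Caller output (STAR-fusion style partner pairs with junction/spanning
support) is cleaned with four artifact filters applied in order: (a) both
partners from the same gene family, (b) a partner without an official gene
symbol, (c) a fusion called in more than a cohort fraction of tumor
samples, and (d) a fusion also present in normal thyroid tissue.  Retained
fusions can be cross-referenced against a cancer-gene list and counted for
recurrence across distinct samples.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "FusionCall",
    "FusionFilterReport",
    "same_family",
    "filter_fusions",
    "crossref_cancer_fusions",
    "count_recurrence",
]

_TRAILING_DIGITS = re.compile(r"\d+$")
_PLACEHOLDER_PREFIXES = ("LOC", "ENSCAF", "ENSCAFG", "ENSG")


@dataclass
class FusionCall:
    sample_id: str
    gene_5p: str
    gene_3p: str
    junction_reads: int = 0
    spanning_frags: int = 0
    breakpoint_5p: tuple = None  # (chrom, pos, strand)
    breakpoint_3p: tuple = None

    def __post_init__(self):
        if not self.gene_5p or not self.gene_3p:
            raise ValueError("both fusion partners must be named")
        if self.junction_reads < 0 or self.spanning_frags < 0:
            raise ValueError("support counts must be nonnegative")

    def identity(self) -> tuple:
        """Ordered 5'->3' fusion identity used for recurrence."""
        return (self.gene_5p, self.gene_3p)


@dataclass
class FusionFilterReport:
    retained: list
    removed: list  # (FusionCall, reason)
    recurrence: dict  # identity -> distinct tumor sample count
    normal_calls: list = field(default_factory=list)


def same_family(gene_a: str, gene_b: str) -> bool:
    """Approximate same-gene-family predicate: identical symbol stem after
    stripping trailing digits (PBX2 / PBX3 -> PBX)."""
    stem_a = _TRAILING_DIGITS.sub("", gene_a.upper())
    stem_b = _TRAILING_DIGITS.sub("", gene_b.upper())
    return bool(stem_a) and stem_a == stem_b


def _official(symbol: str, official_symbols) -> bool:
    if official_symbols is not None:
        return symbol in official_symbols
    up = symbol.upper()
    return not any(up.startswith(p) for p in _PLACEHOLDER_PREFIXES)


def filter_fusions(
    calls,
    normal_sample_ids,
    official_symbols=None,
    n_tumor_samples: int = None,
    cohort_fraction: float = 0.80,
    family_predicate=same_family,
) -> FusionFilterReport:
    """Partition tumor fusion calls into retained and removed-with-reason.

    Calls from samples in ``normal_sample_ids`` serve only as evidence for
    the present-in-normals criterion and are returned separately in
    ``normal_calls``.  Removal reasons are evaluated in order
    same_family -> unofficial_name -> cohort_frequency ->
    present_in_normals, recording the first match; retained calls preserve
    input order.  The cohort-frequency denominator counts tumor samples
    only and the threshold is strict (> ``cohort_fraction``).
    """
    normal_ids = set(normal_sample_ids)
    tumor_calls = [c for c in calls if c.sample_id not in normal_ids]
    normal_calls = [c for c in calls if c.sample_id in normal_ids]

    if n_tumor_samples is None:
        n_tumor_samples = len({c.sample_id for c in tumor_calls})
    normal_identities = {c.identity() for c in normal_calls}
    samples_per_identity: dict = {}
    for c in tumor_calls:
        samples_per_identity.setdefault(c.identity(), set()).add(c.sample_id)

    retained, removed = [], []
    for c in tumor_calls:
        if family_predicate(c.gene_5p, c.gene_3p):
            removed.append((c, "same_family"))
        elif not (_official(c.gene_5p, official_symbols) and _official(c.gene_3p, official_symbols)):
            removed.append((c, "unofficial_name"))
        elif (
            n_tumor_samples > 0
            and len(samples_per_identity[c.identity()]) / n_tumor_samples > cohort_fraction
        ):
            removed.append((c, "cohort_frequency"))
        elif c.identity() in normal_identities:
            removed.append((c, "present_in_normals"))
        else:
            retained.append(c)
    return FusionFilterReport(
        retained=retained,
        removed=removed,
        recurrence=count_recurrence(retained),
        normal_calls=normal_calls,
    )


def crossref_cancer_fusions(retained, cancer_genes) -> list:
    """Annotate fusions whose 5' or 3' partner is a known cancer gene.

    Returns ``(call, is_cancer_fusion)`` tuples preserving order."""
    cancer = set(cancer_genes)
    return [(c, c.gene_5p in cancer or c.gene_3p in cancer) for c in retained]


def count_recurrence(retained) -> dict:
    """Distinct-sample count per ordered fusion identity (a fusion called
    twice in one sample counts once)."""
    samples: dict = {}
    for c in retained:
        samples.setdefault(c.identity(), set()).add(c.sample_id)
    return {ident: len(s) for ident, s in samples.items()}
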