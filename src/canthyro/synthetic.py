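"""Fully in-silico cohort generator.

Generates a two-subtype tumor cohort with matched normals carrying the
statistical structure the analysis stages assume, so the whole pipeline is
exercisable without any sequencing download: negative-binomial expression
with planted subtype markers and a differentiation gradient, germline and
somatic variants on a self-contained synthetic chromosome with
trinucleotide-context-biased substitutions, fusion calls including the
four artifact classes the curation step removes, ortholog protein pairs
with indels and a known residue correspondence, and censored survival
times with a tumor-size-dependent hazard.

One master seed drives everything; each data modality draws from its own
fixed sub-stream so adding a modality never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .fusions import FusionCall
from .scores import MPAS_GENES
from .variants import GermlineResources, VariantRecord

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "ConfigError",
    "BUILTIN_SIGNATURES",
    "generate_cohort",
    "write_cohort",
    "resources_from_truth",
    "simulate_two_group_survival",
    "plant_msi_scores",
]

_CHROM = "chrS"

TDS_GENES = tuple(f"TDSG{i:02d}" for i in range(1, 17))
ERK_GENES = tuple(f"ERKG{i:02d}" for i in range(1, 53))
#: 11 of the 52 ERK signature genes are treated as unresolvable in the
#: annotation, mirroring a platform where only 41 can be scored.
ERK_UNAVAILABLE = tuple(f"ERKG{i:02d}" for i in range(42, 53))


class ConfigError(ValueError):
    pass


def _builtin_signatures() -> dict:
    """Three 96-channel signature vectors used as planted mixtures:
    a flat clock-like background, a C>T-dominated deamination-style
    signature, and an MMR-deficiency-style signature concentrated in
    C>T and T>C channels."""
    from .signatures import CHANNELS_96

    flat = np.ones(96)
    flat /= flat.sum()

    c_to_t = np.array([1.0 if "[C>T]" in ch else 0.0 for ch in CHANNELS_96])
    c_to_t /= c_to_t.sum()

    mmr = np.array(
        [3.0 if "[C>T]" in ch else (2.0 if "[T>C]" in ch else 0.2) for ch in CHANNELS_96]
    )
    mmr /= mmr.sum()
    return {"flat": flat, "c_to_t_only": c_to_t, "mmr_like": mmr}


BUILTIN_SIGNATURES = _builtin_signatures()


@dataclass
class CohortConfig:
    """Study conditions for the generated cohort.

    Defaults mirror the real cohort's composition (25 + 5 tumors, 5
    normals, 27 with matched-normal exomes is approximated by giving every
    tumor a matched normal) at a desk-scale gene count.
    """

    n_tumors_subtype1: int = 25
    n_tumors_subtype2: int = 5
    n_normals: int = 5
    n_genes: int = 2000
    nb_dispersion: float = 0.15
    marker_log2_effect: float = 2.0
    n_marker_genes_per_subtype: int = 50
    tds_gradient_sd: float = 1.0
    n_somatic_per_sample: int = 80
    n_germline_per_sample: int = 120
    signature_mixture: tuple = (("flat", 0.5), ("mmr_like", 0.3), ("c_to_t_only", 0.2))
    fusion_artifact_rates: dict = field(
        default_factory=lambda: {
            "same_family": 0.3,
            "unofficial_name": 0.3,
            "high_frequency": 0.9,
            "in_normals": 0.4,
        }
    )
    survival_baseline_hazard: float = 1.0 / 1800.0  # per day
    size_log_hazard_ratio: float = 0.25  # per cm of tumor diameter
    censoring_rate: float = 0.5
    reference_length: int = 60000
    seed: int = 0

    def validate(self) -> None:
        for f in ("n_tumors_subtype1", "n_tumors_subtype2", "n_normals", "n_genes",
                  "n_marker_genes_per_subtype", "n_somatic_per_sample", "n_germline_per_sample"):
            if int(getattr(self, f)) < 1:
                raise ConfigError(f"{f} must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.survival_baseline_hazard <= 0:
            raise ConfigError("survival_baseline_hazard must be positive")
        if not (0.0 <= self.censoring_rate <= 1.0):
            raise ConfigError("censoring_rate must lie in [0, 1]")
        weights = [w for _, w in self.signature_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigError("signature_mixture weights must sum to 1")
        for name, _ in self.signature_mixture:
            if name not in BUILTIN_SIGNATURES and not isinstance(name, np.ndarray):
                raise ConfigError(f"signature_mixture references unknown signature {name!r}")
        reserved = len(MPAS_GENES) + len(ERK_GENES) + len(TDS_GENES) + 2 * self.n_marker_genes_per_subtype
        if self.n_genes < reserved + 10:
            raise ConfigError(f"n_genes must be >= {reserved + 10} to hold score/marker genes")

    def mixture_vector(self) -> np.ndarray:
        v = np.zeros(96)
        for name, w in self.signature_mixture:
            if isinstance(name, str):
                if name not in BUILTIN_SIGNATURES:
                    raise ConfigError(f"signature_mixture references unknown signature {name!r}")
                sig = BUILTIN_SIGNATURES[name]
            else:
                sig = np.asarray(name, dtype=float)
            v += w * sig / sig.sum()
        return v / v.sum()


@dataclass
class SyntheticCohort:
    config: CohortConfig
    expression: ExpressionMatrix
    wes_tumor_variants: list
    wes_normal_variants: list
    rna_variants: list
    truth_genotype: dict  # variant id -> germline | somatic
    fusion_calls: list
    truth_fusion_class: dict  # fusion id -> real | artifact-a..d
    ortholog_pairs: list  # (gene, source_seq, target_seq, truth_map)
    clinical: pd.DataFrame
    reference_sequence: str
    reference_context: dict  # (chrom, pos) -> trinucleotide
    truth_subtype: dict  # sample -> subtype1 | subtype2 | normal
    marker_genes: dict  # subtype -> gene list

    @property
    def tumor_samples(self) -> list:
        return [s for s, g in self.truth_subtype.items() if g != "normal"]

    @property
    def normal_samples(self) -> list:
        return [s for s, g in self.truth_subtype.items() if g == "normal"]


def _rng(seed: int, modality: int) -> np.random.Generator:
    return np.random.default_rng([seed, modality])


def variant_id(v: VariantRecord) -> str:
    return f"{v.sample_id}:{v.chrom}:{v.pos}:{v.ref}>{v.alt}"


def _gene_catalog(config: CohortConfig):
    markers1 = [f"MK1G{i:03d}" for i in range(1, config.n_marker_genes_per_subtype + 1)]
    markers2 = [f"MK2G{i:03d}" for i in range(1, config.n_marker_genes_per_subtype + 1)]
    named = list(MPAS_GENES) + list(ERK_GENES) + list(TDS_GENES) + markers1 + markers2
    filler = [f"GF{i:04d}" for i in range(1, config.n_genes - len(named) + 1)]
    return named + filler, markers1, markers2


def _generate_expression(config: CohortConfig, sample_ids, subtype_of):
    rng = _rng(config.seed, 1)
    gene_ids, markers1, markers2 = _gene_catalog(config)
    n_genes, n_samples = len(gene_ids), len(sample_ids)

    base_log2 = rng.normal(5.0, 2.0, n_genes).clip(0.5, None)
    log2_mu = np.tile(base_log2[:, None], (1, n_samples))

    idx = {g: i for i, g in enumerate(gene_ids)}
    m1 = [idx[g] for g in markers1]
    m2 = [idx[g] for g in markers2]
    tds_idx = [idx[g] for g in TDS_GENES]

    gradients = {}
    for j, s in enumerate(sample_ids):
        group = subtype_of[s]
        if group == "subtype1":
            log2_mu[m1, j] += config.marker_log2_effect
        elif group == "subtype2":
            log2_mu[m2, j] += config.marker_log2_effect
        if group != "normal":
            g = rng.normal(0.0, config.tds_gradient_sd)
            gradients[s] = g
            log2_mu[tds_idx, j] += g

    mu = 2.0**log2_mu
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    mat = ExpressionMatrix(counts=counts, gene_ids=gene_ids, sample_ids=list(sample_ids))
    return mat, gradients, {"subtype1": markers1, "subtype2": markers2}


def _context_positions(reference: str):
    by_context: dict = {}
    for i in range(1, len(reference) - 1):
        by_context.setdefault(reference[i - 1 : i + 2], []).append(i + 1)  # 1-based center
    return by_context


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def _generate_variants(config: CohortConfig, tumor_samples, reference: str):
    from .signatures import CHANNELS_96

    rng = _rng(config.seed, 2)
    by_context = _context_positions(reference)
    mixture = config.mixture_vector()

    consequences = ("missense", "synonymous", "stop_gained", "splice_region")
    cons_w = np.array([0.6, 0.25, 0.1, 0.05])
    gene_ids, _, _ = _gene_catalog(config)

    wes_tumor, wes_normal, rna = [], [], []
    truth = {}
    context_map = {}

    for sample in tumor_samples:
        used_pos: set = set()
        n_total = config.n_germline_per_sample + config.n_somatic_per_sample
        channels = rng.choice(96, size=n_total, p=mixture)
        for k in range(n_total):
            is_germline = k < config.n_germline_per_sample
            ch = CHANNELS_96[channels[k]]
            five, sub, three = ch[0], ch[2:5], ch[6]
            pyr_tri = five + sub[0] + three
            pur_tri = _revcomp(pyr_tri)
            # choose forward (pyrimidine ref) or reverse-strand representation
            candidates = []
            for tri, ref_b, alt_b in (
                (pyr_tri, sub[0], sub[2]),
                (pur_tri, _COMP[sub[0]], _COMP[sub[2]]),
            ):
                for pos in by_context.get(tri, ()):
                    candidates.append((pos, ref_b, alt_b, tri))
            free = [c for c in candidates if c[0] not in used_pos]
            if not free:
                continue
            pos, ref_b, alt_b, tri = free[rng.integers(len(free))]
            used_pos.add(pos)
            context_map[(_CHROM, pos)] = tri

            depth = int(rng.poisson(100)) + 20
            af = float(np.clip(rng.normal(0.5, 0.05) if is_germline else rng.uniform(0.2, 0.6), 0.05, 0.95))
            alt_count = max(1, int(round(af * depth)))
            cons = consequences[rng.choice(len(consequences), p=cons_w)]
            gene = gene_ids[rng.integers(len(gene_ids))]
            common = dict(
                chrom=_CHROM, pos=pos, ref=ref_b, alt=alt_b, depth=depth,
                alt_count=alt_count, consequence=cons, gene_id=gene,
            )
            vt = VariantRecord(sample_id=sample, source="wes_tumor", **common)
            wes_tumor.append(vt)
            truth[variant_id(vt)] = "germline" if is_germline else "somatic"
            if is_germline:
                wes_normal.append(VariantRecord(sample_id=sample, source="wes_normal", **common))
            if rng.random() < 0.3 and cons != "splice_region":
                rna_depth = int(rng.poisson(60)) + 15
                rna_alt = max(6, min(rna_depth, int(round(af * rna_depth))))
                rna.append(
                    VariantRecord(
                        sample_id=sample, source="rna", chrom=_CHROM, pos=pos, ref=ref_b,
                        alt=alt_b, depth=rna_depth, alt_count=rna_alt, consequence=cons,
                        gene_id=gene,
                    )
                )
    return wes_tumor, wes_normal, rna, truth, context_map


def _generate_fusions(config: CohortConfig, tumor_samples, normal_samples):
    rng = _rng(config.seed, 3)
    rates = config.fusion_artifact_rates
    calls, truth = [], {}

    def add(sample, g5, g3, cls):
        c = FusionCall(
            sample_id=sample, gene_5p=g5, gene_3p=g3,
            junction_reads=int(rng.poisson(12)) + 1, spanning_frags=int(rng.poisson(6)),
        )
        calls.append(c)
        truth[f"{sample}|{g5}--{g3}"] = cls

    # real fusions: one recurrent, one singleton driver-style
    for s in tumor_samples[: min(3, len(tumor_samples))]:
        add(s, "RRH", "GAR1", "real")
    add(tumor_samples[-1], "FGFR2", "EBF2", "real")

    n_high = math.ceil(rates.get("high_frequency", 0.9) * len(tumor_samples))
    for s in tumor_samples[:n_high]:
        add(s, "ACTB", "GAPDH", "artifact-c")
    for s in tumor_samples:
        if rng.random() < rates.get("same_family", 0.0):
            add(s, "PBX2", "PBX3", "artifact-a")
        if rng.random() < rates.get("unofficial_name", 0.0):
            add(s, "LOC102151", "TP53", "artifact-b")
        if rng.random() < rates.get("in_normals", 0.0):
            add(s, "MYH9", "TXN", "artifact-d")
    if normal_samples:
        add(normal_samples[0], "MYH9", "TXN", "artifact-d")
    return calls, truth


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _generate_orthologs(config: CohortConfig, n_pairs: int = 5):
    rng = _rng(config.seed, 4)
    pairs = []
    for i in range(n_pairs):
        length = int(rng.integers(150, 400))
        src = "".join(_AA20[j] for j in rng.integers(0, 20, length))
        # build target by substitutions plus indels, recording the truth map
        tgt_chars = []
        truth_map = {}
        tpos = 0
        spos = 0
        while spos < length:
            r = rng.random()
            if r < 0.02:  # deletion in target: source residue unmapped
                truth_map[spos + 1] = None
                spos += 1
            elif r < 0.04:  # insertion in target
                tgt_chars.append(_AA20[rng.integers(20)])
                tpos += 1
            else:
                c = src[spos]
                if rng.random() < 0.08:
                    c = _AA20[rng.integers(20)]
                tgt_chars.append(c)
                tpos += 1
                truth_map[spos + 1] = tpos
                spos += 1
        pairs.append((f"ORTH{i + 1}", src, "".join(tgt_chars), truth_map))
    return pairs


def _generate_clinical(config: CohortConfig, tumor_samples, subtype_of):
    rng = _rng(config.seed, 5)
    rows = []
    for s in tumor_samples:
        diam = float(np.round(rng.lognormal(math.log(4.25), 0.35), 2))
        hazard = config.survival_baseline_hazard * math.exp(
            config.size_log_hazard_ratio * (diam - 4.25)
        )
        death = rng.exponential(1.0 / hazard)
        if 0 < config.censoring_rate < 1:
            c_rate = config.survival_baseline_hazard * config.censoring_rate / (1 - config.censoring_rate)
            censor = rng.exponential(1.0 / c_rate)
        else:
            censor = math.inf if config.censoring_rate == 0 else 0.0
        time = max(1.0, min(death, censor))
        rows.append(
            {
                "sample_id": s,
                "subtype": subtype_of[s],
                "tumor_diameter_cm": diam,
                "survival_days": float(np.round(time, 1)),
                "event": bool(death <= censor),
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig = None) -> SyntheticCohort:
    """Generate the full synthetic cohort; deterministic given config.seed."""
    config = config or CohortConfig()
    config.validate()

    ref_rng = _rng(config.seed, 0)
    reference = "".join("ACGT"[i] for i in ref_rng.integers(0, 4, config.reference_length))

    s1 = [f"S1_{i:02d}" for i in range(1, config.n_tumors_subtype1 + 1)]
    s2 = [f"S2_{i:02d}" for i in range(1, config.n_tumors_subtype2 + 1)]
    norm = [f"N_{i:02d}" for i in range(1, config.n_normals + 1)]
    subtype_of = {**{s: "subtype1" for s in s1}, **{s: "subtype2" for s in s2}, **{s: "normal" for s in norm}}
    samples = s1 + s2 + norm
    tumors = s1 + s2

    expression, _gradients, markers = _generate_expression(config, samples, subtype_of)
    wes_t, wes_n, rna, truth_geno, context_map = _generate_variants(config, tumors, reference)
    fusions, truth_fus = _generate_fusions(config, tumors, norm)
    orthologs = _generate_orthologs(config)
    clinical = _generate_clinical(config, tumors, subtype_of)

    return SyntheticCohort(
        config=config,
        expression=expression,
        wes_tumor_variants=wes_t,
        wes_normal_variants=wes_n,
        rna_variants=rna,
        truth_genotype=truth_geno,
        fusion_calls=fusions,
        truth_fusion_class=truth_fus,
        ortholog_pairs=orthologs,
        clinical=clinical,
        reference_sequence=reference,
        reference_context=context_map,
        truth_subtype=subtype_of,
        marker_genes=markers,
    )


def resources_from_truth(cohort: SyntheticCohort, population_fraction: float = 0.0, seed: int = 0) -> GermlineResources:
    """Complete germline resources for the generated cohort: the
    matched-normal index from the normal-WES calls, optionally moving a
    fraction of germline sites into the population resource as well."""
    matched = {v.sample_site_key() for v in cohort.wes_normal_variants}
    population = set()
    if population_fraction > 0:
        rng = np.random.default_rng(seed)
        sites = sorted({v.site_key() for v in cohort.wes_normal_variants})
        k = int(round(population_fraction * len(sites)))
        idx = rng.choice(len(sites), size=k, replace=False)
        population = {sites[i] for i in idx}
    return GermlineResources(
        matched_normal_index=matched,
        panel_of_normals=set(),
        population_sites=population,
        normal_samples=set(cohort.tumor_samples),
    )


def simulate_two_group_survival(
    n_per_group: int, hazard_ratio: float, baseline_hazard: float = 1.0 / 1000.0,
    censoring_rate: float = 0.2, seed: int = 0,
):
    """Two-group exponential survival simulation (group 'b' has the given
    hazard ratio vs 'a'), with independent exponential censoring tuned to
    the requested censored fraction."""
    from .stats import SurvivalData

    rng = np.random.default_rng(seed)
    h = np.repeat([baseline_hazard, baseline_hazard * hazard_ratio], n_per_group)
    death = rng.exponential(1.0 / h)
    c_rate = baseline_hazard * censoring_rate / max(1e-12, 1 - censoring_rate)
    censor = rng.exponential(1.0 / c_rate, size=2 * n_per_group)
    time = np.minimum(death, censor).clip(1e-6, None)
    event = death <= censor
    group = np.repeat(["a", "b"], n_per_group)
    return SurvivalData(time=time, event=event, group=group)


def plant_msi_scores(samples, mutant_samples, shift: float = 2.0, sd: float = 1.0, seed: int = 0) -> dict:
    """Per-sample MSI scores with a planted location shift (in units of
    ``sd``) for the repair-mutant group."""
    rng = np.random.default_rng(seed)
    mutant = set(mutant_samples)
    return {
        s: float(rng.normal(shift * sd if s in mutant else 0.0, sd)) for s in samples
    }


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort to disk and return a manifest of files with
    sha256 checksums."""
    from . import io as cio

    os.makedirs(directory, exist_ok=True)
    contigs = {_CHROM: len(cohort.reference_sequence)}
    paths = {}

    paths["counts"] = os.path.join(directory, "counts.tsv")
    cio.write_counts_tsv(cohort.expression, paths["counts"])

    for name, records in (
        ("wes_tumor", cohort.wes_tumor_variants),
        ("wes_normal", cohort.wes_normal_variants),
        ("rna", cohort.rna_variants),
    ):
        paths[name] = os.path.join(directory, f"{name}.vcf")
        cio.write_vcf(records, paths[name], contigs)

    paths["fusions"] = os.path.join(directory, "fusions.tsv")
    cio.write_fusions_tsv(cohort.fusion_calls, paths["fusions"])

    paths["proteins"] = os.path.join(directory, "orthologs.fasta")
    seqs = {}
    for gene, src, tgt, _ in cohort.ortholog_pairs:
        seqs[f"{gene}|source"] = src
        seqs[f"{gene}|target"] = tgt
    cio.write_fasta(seqs, paths["proteins"])

    paths["clinical"] = os.path.join(directory, "clinical.csv")
    cohort.clinical.to_csv(paths["clinical"], index=False)

    paths["truth_genotype"] = os.path.join(directory, "truth_genotype.tsv")
    pd.DataFrame(
        [{"variant_id": k, "genotype": v} for k, v in sorted(cohort.truth_genotype.items())]
    ).to_csv(paths["truth_genotype"], sep="\t", index=False)

    paths["truth_fusion_class"] = os.path.join(directory, "truth_fusion_class.tsv")
    pd.DataFrame(
        [{"fusion_id": k, "class": v} for k, v in sorted(cohort.truth_fusion_class.items())]
    ).to_csv(paths["truth_fusion_class"], sep="\t", index=False)

    manifest = {}
    for name, path in paths.items():
        with open(path, "rb") as fh:
            manifest[name] = {
                "file": os.path.basename(path),
                "sha256": hashlib.sha256(fh.read()).hexdigest(),
            }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
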