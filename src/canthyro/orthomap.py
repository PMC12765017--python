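"""Cross-species protein-position mapping.

Variant amino-acid positions called on one species' protein (e.g. dog) are
projected onto the orthologous position of the other species' protein
(e.g. human) through one global pairwise alignment of the full-length
sequences (BLOSUM62, affine gaps).  Residues that align to a gap are
reported as unmapped rather than guessed, so every projected position is
directly supported by the alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "AlignmentMap",
    "ProjectedVariant",
    "align_pair",
    "project_position",
    "project_hgvsp",
    "invert_map",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")
_HGVSP_SUBST = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")


@dataclass
class AlignmentMap:
    """Residue-level correspondence between an ortholog pair.

    ``pairs`` is the alignment column list of 1-based residue indices,
    ``(source_pos or None, target_pos or None)``; None marks a gap in that
    sequence.
    """

    source_id: str
    target_id: str
    pairs: list
    score: float
    identity_fraction: float
    source_length: int
    target_length: int

    def __post_init__(self):
        src = [s for s, _ in self.pairs if s is not None]
        tgt = [t for _, t in self.pairs if t is not None]
        if src != sorted(src) or tgt != sorted(tgt):
            raise ValueError("alignment positions must be strictly increasing")

    def source_to_target(self) -> dict:
        return {s: t for s, t in self.pairs if s is not None}


@dataclass
class ProjectedVariant:
    source_hgvsp: str
    target_pos: int = None  # None = unmapped / not projected
    target_ref_residue: str = ""
    target_hgvsp: str = ""
    concordant: bool = False
    reason: str = ""


def _validate_protein(seq: str, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"{label} sequence has invalid residues: {sorted(bad)}")
    return seq


def align_pair(
    source_seq: str,
    target_seq: str,
    source_id: str = "source",
    target_id: str = "target",
    mode: str = "global",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentMap:
    """Pairwise protein alignment with BLOSUM62 and affine gaps.

    Global mode aligns full-length sequences end to end (end gaps are
    penalized); local mode is provided for comparison with HSP-style
    behavior.  The first gap position costs ``gap_open`` and each further
    position ``gap_extend``.  Deterministic: the aligner's first optimal
    traceback is used.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    src = _validate_protein(source_seq, "source")
    tgt = _validate_protein(target_seq, "target")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    aligner.mode = mode

    aln = aligner.align(src, tgt)[0]
    indices = aln.indices  # 2 x columns, -1 for gaps
    pairs = []
    n_ident = 0
    n_aligned = 0
    for si, ti in zip(indices[0], indices[1]):
        s = None if si < 0 else int(si) + 1
        t = None if ti < 0 else int(ti) + 1
        pairs.append((s, t))
        if s is not None and t is not None:
            n_aligned += 1
            if src[s - 1] == tgt[t - 1]:
                n_ident += 1
    identity = n_ident / n_aligned if n_aligned else 0.0
    return AlignmentMap(
        source_id=source_id,
        target_id=target_id,
        pairs=pairs,
        score=float(aln.score),
        identity_fraction=identity,
        source_length=len(src),
        target_length=len(tgt),
    )


def project_position(amap: AlignmentMap, source_pos: int):
    """Aligned target residue index for a 1-based source position, or
    None when the source residue sits opposite a gap (or, in local mode,
    outside the aligned region)."""
    if not (1 <= source_pos <= amap.source_length):
        raise ValueError(f"source position {source_pos} outside 1..{amap.source_length}")
    return amap.source_to_target().get(source_pos)


def project_hgvsp(amap: AlignmentMap, hgvsp: str, target_seq: str) -> ProjectedVariant:
    """Project a single-residue protein substitution onto the target.

    Frameshifts, deletions and stop-introducing changes are passed through
    unprojected with a reason (the downstream driver predictor only takes
    missense input).  ``concordant`` records whether the target holds the
    same reference residue at the projected position; discordant variants
    are still projected but flagged.
    """
    raw = hgvsp.strip()
    if not raw:
        raise ValueError("empty HGVSp string")
    m = _HGVSP_SUBST.match(raw)
    if m is None:
        if re.search(r"(fs|del|dup|ins|ext|\*)", raw):
            return ProjectedVariant(source_hgvsp=hgvsp, reason="not a single-residue substitution")
        raise ValueError(f"unparseable HGVSp {hgvsp!r}")
    ref_res, pos, alt_res = m.group(1), int(m.group(2)), m.group(3)
    tpos = project_position(amap, pos)
    if tpos is None:
        return ProjectedVariant(source_hgvsp=hgvsp, reason="source residue aligns to a gap")
    tres = target_seq[tpos - 1].upper()
    return ProjectedVariant(
        source_hgvsp=hgvsp,
        target_pos=tpos,
        target_ref_residue=tres,
        target_hgvsp=f"p.{tres}{tpos}{alt_res}",
        concordant=(tres == ref_res),
    )


def invert_map(amap: AlignmentMap) -> AlignmentMap:
    """Swap the roles of source and target (gap roles exchange)."""
    return AlignmentMap(
        source_id=amap.target_id,
        target_id=amap.source_id,
        pairs=[(t, s) for s, t in amap.pairs],
        score=amap.score,
        identity_fraction=amap.identity_fraction,
        source_length=amap.target_length,
        target_length=amap.source_length,
    )
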