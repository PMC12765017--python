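"""Mutational spectra and de novo signature extraction.

Single-nucleotide substitutions are binned into the conventional 96 types:
six pyrimidine-frame substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 5' and 3' flanking reference bases.  Substitutions called
on a purine reference base are reverse-complemented into the pyrimidine
frame first.  De novo signatures are extracted from cohort spectra with
multiplicative-update NMF under the generalized Kullback-Leibler
divergence and matched against a reference catalog by cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SUBSTITUTION_CLASSES",
    "CHANNELS_96",
    "DataIntegrityError",
    "channel_of",
    "channel_index",
    "build_spectrum",
    "SignatureSet",
    "extract_signatures",
    "match_reference",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 96 channels in lexicographic (class, 5' base, 3' base) order,
#: written COSMIC-style, e.g. ``"A[C>T]G"``.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTION_CLASSES for five in _BASES for three in _BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


class DataIntegrityError(ValueError):
    pass


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def channel_of(ref: str, alt: str, trinucleotide: str) -> str:
    """Pyrimidine-frame channel of a substitution given its reference
    trinucleotide context (context middle base must equal ``ref``)."""
    ref, alt, tri = ref.upper(), alt.upper(), trinucleotide.upper()
    if len(tri) != 3 or any(b not in _COMPLEMENT for b in tri):
        raise DataIntegrityError(f"invalid trinucleotide {trinucleotide!r}")
    if tri[1] != ref:
        raise DataIntegrityError(f"context {tri!r} middle base != ref {ref!r}")
    if ref in ("G", "A"):  # purine frame: reverse-complement
        tri = _revcomp(tri)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def channel_index(ref: str, alt: str, trinucleotide: str) -> int:
    return _CHANNEL_INDEX[channel_of(ref, alt, trinucleotide)]


def build_spectrum(snvs, reference_context) -> pd.DataFrame:
    """96-type spectra per sample.

    ``snvs`` is an iterable of variant records (non-SNVs are skipped);
    ``reference_context`` maps ``(chrom, pos)`` to the reference
    trinucleotide centered on the site (a dict or a callable).  Returns a
    samples x 96 frame of counts whose row sums equal the per-sample SNV
    count entering the spectrum.
    """
    lookup = reference_context if callable(reference_context) else reference_context.__getitem__
    rows: dict = {}
    for v in snvs:
        if not v.is_snv:
            continue
        try:
            tri = lookup((v.chrom, v.pos))
        except KeyError:
            raise DataIntegrityError(f"no reference context for {v.chrom}:{v.pos}")
        try:
            idx = channel_index(v.ref, v.alt, tri)
        except DataIntegrityError as e:
            raise DataIntegrityError(f"{v.chrom}:{v.pos}: {e}") from e
        rows.setdefault(v.sample_id, np.zeros(96, dtype=int))[idx] += 1
    return pd.DataFrame(rows, index=list(CHANNELS_96)).T.sort_index()


@dataclass
class SignatureSet:
    signatures: pd.DataFrame  # 96 x k, columns sum to 1
    exposures: pd.DataFrame  # samples x k, nonnegative
    rank: int
    reconstruction_error: float  # generalized KL divergence


def extract_signatures(spectra: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 10,
                       max_iter: int = 2000, tol: float = 1e-6) -> SignatureSet:
    """De novo signatures via KL-divergence multiplicative-update NMF.

    ``spectra`` is samples x 96.  Runs ``n_restarts`` random
    initializations (sub-seeded from ``seed``) and keeps the best
    objective; signature columns are renormalized to sum 1 with exposures
    rescaled accordingly.  Deterministic given ``seed``.
    """
    from sklearn.decomposition import NMF

    V = spectra.to_numpy(dtype=float).T  # 96 x samples
    nonzero = (V.sum(axis=0) > 0).sum()
    if k > V.shape[1]:
        raise ValueError(f"rank {k} exceeds number of samples {V.shape[1]}")
    if nonzero < k:
        raise ValueError(f"need >= {k} samples with nonzero spectra (have {nonzero})")

    best = None
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_restarts):
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        model = NMF(
            n_components=k, init="random", solver="mu", beta_loss="kullback-leibler",
            max_iter=max_iter, tol=tol, random_state=rs,
        )
        W = model.fit_transform(V)  # 96 x k
        H = model.components_  # k x samples
        err = model.reconstruction_err_
        if best is None or err < best[0]:
            best = (err, W, H)
    err, W, H = best
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    W = W / col[None, :]
    H = H * col[:, None]
    names = [f"denovo_{i + 1}" for i in range(k)]
    return SignatureSet(
        signatures=pd.DataFrame(W, index=spectra.columns, columns=names),
        exposures=pd.DataFrame(H.T, index=spectra.index, columns=names),
        rank=k,
        reconstruction_error=float(err),
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def match_reference(signatures: SignatureSet, catalog: pd.DataFrame, novelty_threshold: float = 0.80) -> pd.DataFrame:
    """Best cosine match of each extracted signature in a reference
    catalog (96 rows x named columns); matches below the threshold are
    labeled novel."""
    if catalog.shape[1] == 0:
        raise ValueError("catalog is empty")
    if catalog.shape[0] != 96:
        raise ValueError("catalog vectors must have length 96")
    rows = []
    for name in signatures.signatures.columns:
        sig = signatures.signatures[name].to_numpy()
        sims = {c: cosine_similarity(sig, catalog[c].to_numpy()) for c in catalog.columns}
        best = max(sims, key=sims.get)
        rows.append(
            {
                "signature": name,
                "best_match": best,
                "cosine": sims[best],
                "novel": sims[best] < novelty_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("signature")
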