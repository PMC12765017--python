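"""96-type spectra, NMF signature extraction and catalog matching."""

import numpy as np
import pandas as pd
import pytest

from canthyro.signatures import (
    CHANNELS_96,
    SUBSTITUTION_CLASSES,
    DataIntegrityError,
    build_spectrum,
    channel_index,
    channel_of,
    cosine_similarity,
    extract_signatures,
    match_reference,
)
from canthyro.variants import VariantRecord


class TestChannels:
    def test_96_unique_channels(self):
        assert len(CHANNELS_96) == 96
        assert len(set(CHANNELS_96)) == 96

    def test_lexicographic_block_structure(self):
        # first block is C>A with 5' base A: A[C>A]A, A[C>A]C, ...
        assert CHANNELS_96[0] == "A[C>A]A"
        assert CHANNELS_96[3] == "A[C>A]T"
        assert CHANNELS_96[16] == "A[C>G]A"
        assert CHANNELS_96[95] == "T[T>G]T"

    def test_pyrimidine_reference_passthrough(self):
        assert channel_of("C", "T", "ACG") == "A[C>T]G"

    def test_purine_reference_reverse_complemented(self):
        # G>A on reference context TGC is C>T on the opposite strand
        # with context revcomp(TGC) = GCA
        assert channel_of("G", "A", "TGC") == "G[C>T]A"

    def test_strand_symmetry_exhaustive(self):
        # every purine-frame substitution maps to the same channel as
        # the pyrimidine-frame description of the opposite strand
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for ch in CHANNELS_96:
            five, ref, alt, three = ch[0], ch[2], ch[4], ch[6]
            tri = five + ref + three
            rc_tri = "".join(comp[b] for b in reversed(tri))
            assert channel_of(comp[ref], comp[alt], rc_tri) == ch
            assert channel_of(ref, alt, tri) == ch

    def test_context_mismatch_is_error(self):
        with pytest.raises(DataIntegrityError):
            channel_of("C", "T", "AAG")

    def test_invalid_context_rejected(self):
        with pytest.raises(DataIntegrityError):
            channel_of("C", "T", "ANG")


class TestBuildSpectrum:
    def make(self, sample, pos, ref, alt):
        return VariantRecord(sample_id=sample, chrom="chrS", pos=pos, ref=ref, alt=alt)

    def test_counts_land_in_expected_channel(self):
        ctx = {("chrS", 10): "ACG", ("chrS", 20): "TGC"}
        spec = build_spectrum([self.make("s1", 10, "C", "T"), self.make("s1", 20, "G", "A")], ctx)
        assert spec.loc["s1", "A[C>T]G"] == 1
        assert spec.loc["s1", "G[C>T]A"] == 1
        assert spec.loc["s1"].sum() == 2

    def test_non_snvs_skipped(self):
        ctx = {("chrS", 10): "ACG"}
        spec = build_spectrum(
            [self.make("s1", 10, "C", "T"), self.make("s1", 10, "CA", "C")], ctx
        )
        assert spec.loc["s1"].sum() == 1

    def test_missing_context_is_error(self):
        with pytest.raises(DataIntegrityError, match="chrS:99"):
            build_spectrum([self.make("s1", 99, "C", "T")], {})

    def test_callable_context_supported(self):
        spec = build_spectrum([self.make("s1", 10, "C", "T")], lambda key: "ACG")
        assert spec.loc["s1", "A[C>T]G"] == 1

    def test_cohort_spectrum_matches_planted_mixture(self, small_cohort):
        from canthyro.synthetic import BUILTIN_SIGNATURES

        somatic = [
            v
            for v in small_cohort.wes_tumor_variants
            if small_cohort.truth_genotype[f"{v.sample_id}:{v.chrom}:{v.pos}:{v.ref}>{v.alt}"]
            == "somatic"
        ]
        spec = build_spectrum(somatic, small_cohort.reference_context)
        total = spec.sum(axis=0).to_numpy(dtype=float)
        mixture = small_cohort.config.mixture_vector()
        sim = cosine_similarity(total / total.sum(), mixture)
        assert sim >= 0.9


class TestExtractSignatures:
    def planted(self, n_samples=40, scale=20000, seed=5):
        rng = np.random.default_rng(seed)
        sigs = np.zeros((96, 2))
        sigs[:48, 0] = rng.dirichlet(np.ones(48))
        sigs[48:, 1] = rng.dirichlet(np.ones(48))
        # sparse exposures (some samples dominated by each signature) keep
        # the factorization identifiable up to permutation
        expo = rng.gamma(shape=0.5, scale=1.0, size=(n_samples, 2)) * scale
        V = rng.poisson(expo @ sigs.T)
        spectra = pd.DataFrame(V, index=[f"s{j}" for j in range(n_samples)],
                               columns=list(CHANNELS_96))
        return sigs, spectra

    def test_recovers_disjoint_support_signatures(self):
        sigs, spectra = self.planted()
        res = extract_signatures(spectra, k=2, seed=0, n_restarts=5)
        got = res.signatures.to_numpy()
        sims = [max(cosine_similarity(got[:, j], sigs[:, t]) for j in range(2)) for t in range(2)]
        assert min(sims) >= 0.98

    def test_signature_columns_sum_to_one(self):
        _, spectra = self.planted(n_samples=10)
        res = extract_signatures(spectra, k=2, seed=1, n_restarts=3)
        np.testing.assert_allclose(res.signatures.sum(axis=0), 1.0, rtol=1e-9)

    def test_reconstruction_preserved_after_rescaling(self):
        _, spectra = self.planted(n_samples=10)
        res = extract_signatures(spectra, k=2, seed=1, n_restarts=3)
        approx = res.exposures.to_numpy() @ res.signatures.to_numpy().T
        rel = np.abs(approx - spectra.to_numpy()).sum() / spectra.to_numpy().sum()
        assert rel < 0.25

    def test_deterministic_given_seed(self):
        _, spectra = self.planted(n_samples=8)
        a = extract_signatures(spectra, k=2, seed=7, n_restarts=3)
        b = extract_signatures(spectra, k=2, seed=7, n_restarts=3)
        np.testing.assert_array_equal(a.signatures.to_numpy(), b.signatures.to_numpy())

    def test_rank_above_samples_rejected(self):
        _, spectra = self.planted(n_samples=3)
        with pytest.raises(ValueError):
            extract_signatures(spectra, k=4)


class TestMatchReference:
    def catalog(self, sigs):
        return pd.DataFrame(sigs, index=list(CHANNELS_96),
                            columns=[f"REF{j + 1}" for j in range(sigs.shape[1])])

    def test_identical_signature_matches_with_cosine_one(self):
        sigs, spectra = self.planted = TestExtractSignatures().planted(n_samples=20)
        res = extract_signatures(spectra, k=2, seed=0, n_restarts=5)
        cat = self.catalog(res.signatures.to_numpy())
        out = match_reference(res, cat)
        assert (out["cosine"] > 0.999).all()
        assert not out["novel"].any()

    def test_orthogonal_catalog_flags_novel(self):
        rng = np.random.default_rng(0)
        sigs, spectra = TestExtractSignatures().planted(n_samples=20)
        res = extract_signatures(spectra, k=2, seed=0, n_restarts=3)
        # a catalog supported only where the extracted signatures are near zero
        flat = np.full((96, 1), 1e-9)
        flat[94] = 1.0
        out = match_reference(res, self.catalog(flat), novelty_threshold=0.80)
        assert out["novel"].all()

    def test_wrong_catalog_length_rejected(self):
        sigs, spectra = TestExtractSignatures().planted(n_samples=5)
        res = extract_signatures(spectra, k=1, seed=0, n_restarts=2)
        with pytest.raises(ValueError):
            match_reference(res, pd.DataFrame(np.ones((95, 1))))
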