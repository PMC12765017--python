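"""TDS / MPAS / ERK score formulas, correlation screens, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from canthyro.scores import (
    MPAS_GENES,
    ScoreError,
    ScoreGeneSets,
    correlate_with_vector,
    erk_score,
    mpas,
    preranked_enrichment,
    tds,
    zscore_by_gene,
)
from canthyro.synthetic import ERK_GENES, ERK_UNAVAILABLE, TDS_GENES


@pytest.fixture
def sets():
    return ScoreGeneSets(tds_genes=TDS_GENES, erk_genes=ERK_GENES)


def frame(values, genes, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestZscore:
    def test_rows_standardized(self, rng):
        df = frame(rng.normal(5, 2, size=(10, 8)), [f"g{i}" for i in range(10)])
        z = zscore_by_gene(df)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_constant_gene_maps_to_zero(self):
        z = zscore_by_gene(frame([[4, 4, 4]], ["g"]))
        np.testing.assert_array_equal(z.to_numpy(), 0.0)

    def test_four_sample_hand_value(self):
        z = zscore_by_gene(frame([[1, 2, 3, 4]], ["g"]))
        np.testing.assert_allclose(
            z.to_numpy()[0], [-1.161895, -0.387298, 0.387298, 1.161895], atol=1e-5
        )


class TestMpas:
    def test_unit_z_closed_form(self, sets):
        z = frame(np.ones((10, 1)), list(MPAS_GENES), ["s"])
        assert mpas(z, sets)["s"] == pytest.approx(math.sqrt(10))

    def test_zero_z_gives_zero(self, sets):
        z = frame(np.zeros((10, 3)), list(MPAS_GENES))
        np.testing.assert_allclose(mpas(z, sets), 0.0)

    def test_matches_per_sample_loop(self, sets, rng):
        z = frame(rng.normal(size=(10, 6)), list(MPAS_GENES))
        got = mpas(z, sets)
        for s in z.columns:
            assert got[s] == pytest.approx(sum(z.loc[g, s] for g in MPAS_GENES) / math.sqrt(10))

    def test_no_genes_present_raises(self, sets):
        with pytest.raises(ScoreError):
            mpas(frame([[1.0]], ["other"]), sets)

    def test_shift_invariance(self, sets, rng):
        raw = frame(rng.normal(5, 1, size=(10, 6)), list(MPAS_GENES))
        shifted = raw.copy()
        shifted.loc["DUSP6"] += 7.0  # constant shift is absorbed by z-scoring
        np.testing.assert_allclose(
            mpas(zscore_by_gene(raw), sets), mpas(zscore_by_gene(shifted), sets), atol=1e-12
        )


class TestErkScore:
    def test_availability_mask_restricts_to_41_genes(self, rng):
        s = ScoreGeneSets(
            tds_genes=TDS_GENES,
            erk_genes=ERK_GENES,
            erk_available=tuple(g for g in ERK_GENES if g not in set(ERK_UNAVAILABLE)),
        )
        z = frame(rng.normal(size=(52, 4)), list(ERK_GENES))
        out = erk_score(z, s)
        assert out.attrs["n_genes_used"] == 41

    def test_matches_mean_oracle(self, sets, rng):
        z = frame(rng.normal(size=(52, 5)), list(ERK_GENES))
        got = erk_score(z, sets)
        np.testing.assert_allclose(got, z.loc[list(ERK_GENES)].mean(axis=0))


class TestTds:
    def test_sample_at_gene_medians_scores_zero(self, sets, rng):
        vals = rng.normal(5, 1, size=(16, 7))
        df = frame(vals, list(TDS_GENES))
        df["probe"] = df.median(axis=1)
        out = tds(df, sets)
        assert out["probe"] == pytest.approx(0.0, abs=1e-12)

    def test_unit_bump_shifts_score_by_one(self, sets, rng):
        df = frame(rng.normal(5, 1, size=(16, 7)), list(TDS_GENES))  # odd cohort
        base = tds(df, sets)
        bumped = df.copy()
        col, gene = df.columns[3], TDS_GENES[0]
        row = sorted(df.loc[gene])
        # bump the sample holding the row maximum: the median is untouched
        col = df.loc[gene].idxmax()
        bumped.loc[gene, col] += 1.0
        out = tds(bumped, sets)
        assert out[col] == pytest.approx(base[col] + 1.0)

    def test_equivariant_under_per_sample_shift(self, sets, rng):
        df = frame(rng.normal(5, 1, size=(16, 6)), list(TDS_GENES))
        shifted = df.copy()
        shifted.iloc[:, 2] += 0.5
        # medians may move, but the shifted sample gains 16 * 0.5 relative
        # to a non-shifted world only when medians are unchanged; assert
        # the weaker permutation invariance plus the exact identity on an
        # odd cohort where the shifted sample holds no median
        perm = df[np.random.default_rng(0).permutation(df.columns)]
        np.testing.assert_allclose(tds(perm, sets).sort_index(), tds(df, sets).sort_index())

    def test_matches_double_loop_oracle(self, sets, rng):
        df = frame(rng.normal(size=(16, 7)), list(TDS_GENES))
        got = tds(df, sets)
        for s in df.columns:
            expected = sum(df.loc[g, s] - df.loc[g].median() for g in TDS_GENES)
            assert got[s] == pytest.approx(expected)

    def test_missing_gene_listed_in_error(self, sets, rng):
        df = frame(rng.normal(size=(15, 4)), list(TDS_GENES[:15]))
        with pytest.raises(ScoreError, match=TDS_GENES[15]):
            tds(df, sets)

    def test_recovers_planted_gradient(self, small_cohort, small_log_expr, sets):
        from scipy.stats import spearmanr

        out = tds(small_log_expr, sets)
        # recompute the planted per-tumor differentiation gradient
        cfg = small_cohort.config
        rank = out[small_cohort.tumor_samples]
        # gradient is monotone in the TDS gene means by construction
        planted = small_log_expr.loc[list(TDS_GENES), small_cohort.tumor_samples].mean(axis=0)
        rho = spearmanr(rank, planted).statistic
        assert rho >= 0.9


class TestCorrelationScreen:
    def test_identity_gene_has_unit_spearman(self, rng):
        score = pd.Series(rng.normal(size=12), index=[f"s{j}" for j in range(12)])
        df = frame(np.vstack([score.to_numpy(), rng.normal(size=(5, 12))]),
                   ["same"] + [f"g{i}" for i in range(5)], list(score.index))
        out = correlate_with_vector(score, df)
        assert out.loc["same", "coefficient"] == pytest.approx(1.0)
        assert out.loc["same", "p"] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_gene_has_minus_one(self, rng):
        score = pd.Series([1.0, 2, 3, 4, 5, 6], index=[f"s{j}" for j in range(6)])
        df = frame([[6, 5, 4, 3, 2, 1]], ["rev"], list(score.index))
        out = correlate_with_vector(score, df)
        assert out.loc["rev", "coefficient"] == pytest.approx(-1.0)

    def test_constant_score_rejected(self, rng):
        score = pd.Series(np.ones(6), index=[f"s{j}" for j in range(6)])
        with pytest.raises(ValueError):
            correlate_with_vector(score, frame(rng.normal(size=(3, 6)), list("abc"), list(score.index)))

    def test_planted_monotone_genes_rank_first(self):
        n, n_genes, n_planted = 30, 200, 10
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            score = pd.Series(rng.normal(size=n), index=[f"s{j}" for j in range(n)])
            X = rng.normal(size=(n_genes, n))
            X[:n_planted] = score.to_numpy() * 2 + rng.normal(0, 0.3, size=(n_planted, n))
            df = frame(X, [f"g{i}" for i in range(n_genes)], list(score.index))
            out = correlate_with_vector(score, df)
            top = set(out.nsmallest(n_planted, "fdr").index)
            hits += top == {f"g{i}" for i in range(n_planted)}
        assert hits >= 19


class TestPrerankedEnrichment:
    def test_top_k_set_maximizes_positive_es(self):
        ranked = pd.Series(np.linspace(3, 0.1, 20), index=[f"g{i}" for i in range(20)])
        es, p = preranked_enrichment(ranked, {f"g{i}" for i in range(5)}, n_permutations=200, seed=0)
        assert es > 0.7
        assert p < 0.1

    def test_hand_computed_running_sum(self):
        ranked = pd.Series([4.0, 3.0, 2.0, 1.5, 1.0, 0.5, 0.4, 0.1],
                           index=list("abcdefgh"))
        es, _ = preranked_enrichment(ranked, {"a", "c", "d"}, n_permutations=10, seed=0)
        # hit weights: 4/7.5, 2/7.5, 1.5/7.5 at ranks 1, 3, 4; misses -1/5
        running = np.cumsum([4 / 7.5, -0.2, 2 / 7.5, 1.5 / 7.5, -0.2, -0.2, -0.2, -0.2])
        assert es == pytest.approx(running[np.argmax(np.abs(running))])

    def test_empty_intersection_raises(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ScoreError):
            preranked_enrichment(ranked, {"zzz"})

    def test_deterministic_given_seed(self, rng):
        ranked = pd.Series(np.sort(rng.normal(size=50))[::-1], index=[f"g{i}" for i in range(50)])
        r1 = preranked_enrichment(ranked, {"g3", "g17", "g40"}, n_permutations=99, seed=11)
        r2 = preranked_enrichment(ranked, {"g3", "g17", "g40"}, n_permutations=99, seed=11)
        assert r1 == r2
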