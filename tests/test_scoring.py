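"""Gene selection, neighbor pooling, phase-portrait fits and splicing scores."""

import numpy as np
import pytest

from oracles import dispersion_bf, knn_pool_bf, zero_intercept_slope_bf
from sansara.io_counts import SplicedUnsplicedMatrix
from sansara.sagex import log_normalize
from sansara.scoring import (
    PooledLayers,
    compute_scores,
    fit_all_genes,
    fit_phase_portrait,
    pool_neighbors,
    select_hvg,
    standardized_dispersion,
)
from sansara.synthetic_data import (
    GeneKinetics,
    PopulationSpec,
    SimulationConfig,
    simulate_matched_expression_pair,
    simulate_steady_state,
)


def _matrix_from_counts(spliced, unspliced, gene_names=None):
    s = np.asarray(spliced)
    ids = [f"g{j}" for j in range(s.shape[1])]
    return SplicedUnsplicedMatrix(
        spliced=s, unspliced=np.asarray(unspliced),
        gene_ids=ids, barcodes=[f"c{i}" for i in range(s.shape[0])],
        gene_names=gene_names or ids,
    )


class TestSelectHVG:
    def test_constant_gene_ranks_last(self):
        # equal library sizes, so a count-constant gene stays constant after
        # normalization: zero dispersion must rank below any real spread
        rng = np.random.default_rng(0)
        s = rng.poisson(5, size=(50, 6))
        s[:, 2] = 4  # constant gene
        s[:, 5] = 60 - s[:, :5].sum(axis=1)  # filler equalizes cell totals
        assert np.all(s >= 0)
        m = _matrix_from_counts(s, np.zeros_like(s))
        ranked = select_hvg(m, n_top=6)
        assert ranked[-1] == "g2"

    def test_ranking_matches_brute_force(self):
        rng = np.random.default_rng(1)
        s = rng.poisson(rng.uniform(1, 20, size=5), size=(80, 5))
        m = _matrix_from_counts(s, np.zeros_like(s))
        e = log_normalize(m).e.toarray()
        expected = np.argsort(-dispersion_bf(e), kind="stable")
        got = select_hvg(m, n_top=5)
        assert got == [m.gene_ids[i] for i in expected]

    def test_tcr_genes_excluded_by_default(self):
        rng = np.random.default_rng(2)
        s = rng.poisson(10, size=(40, 3))
        m = _matrix_from_counts(s, np.zeros_like(s), gene_names=["CD4", "TRAV1-2", "FOXP3"])
        ranked = select_hvg(m, n_top=3)
        assert "g1" not in ranked  # TRAV1-2 removed before ranking

    def test_requesting_too_many_warns_returns_all(self):
        rng = np.random.default_rng(3)
        s = rng.poisson(5, size=(30, 4))
        m = _matrix_from_counts(s, np.zeros_like(s))
        with pytest.warns(UserWarning, match="returning all"):
            ranked = select_hvg(m, n_top=100)
        assert sorted(ranked) == sorted(m.gene_ids)


class TestPoolNeighbors:
    def test_k1_is_identity(self, small_sim):
        m, _, _ = small_sim
        pooled = pool_neighbors(m, m.gene_ids, k=1)
        assert np.array_equal(pooled.u, m.unspliced.toarray())
        assert np.array_equal(pooled.s, m.spliced.toarray())

    def test_identical_cells_unchanged_k2(self):
        s = np.array([[5, 2], [5, 2]])
        u = np.array([[1, 3], [1, 3]])
        m = _matrix_from_counts(s, u)
        pooled = pool_neighbors(m, m.gene_ids, k=2)
        assert np.array_equal(pooled.u, u)
        assert np.array_equal(pooled.s, s)

    def test_matches_brute_force_on_toy(self):
        rng = np.random.default_rng(4)
        s = rng.poisson(8, size=(10, 12))
        u = rng.poisson(3, size=(10, 12))
        m = _matrix_from_counts(s, u)
        pooled = pool_neighbors(m, m.gene_ids, k=3)
        # with all components kept, PCA is a rigid rotation of the centered
        # log-normalized data, so neighborhoods can be recomputed directly
        e = log_normalize(m).e.toarray()
        coords = e - e.mean(axis=0)
        assert np.allclose(pooled.u, knn_pool_bf(coords, u.astype(float), 3))
        assert np.allclose(pooled.s, knn_pool_bf(coords, s.astype(float), 3))

    def test_k_exceeding_cells_rejected(self, small_sim):
        m, _, _ = small_sim
        with pytest.raises(ValueError, match="exceeds"):
            pool_neighbors(m, m.gene_ids, k=m.n_cells + 1)


class TestFitPhasePortrait:
    def test_exact_line_through_origin(self):
        fit = fit_phase_portrait(
            u=np.array([0.5, 1.0, 1.5, 2.0]), s=np.array([1.0, 2.0, 3.0, 4.0]),
            quantile=0.5,
        )
        assert fit.gamma_hat == pytest.approx(0.5)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.passed_qc

    def test_zero_unspliced_fails_qc(self):
        fit = fit_phase_portrait(u=np.zeros(10), s=np.arange(10, dtype=float))
        assert fit.gamma_hat == 0.0 and not fit.passed_qc

    def test_all_zero_spliced_no_exception(self):
        fit = fit_phase_portrait(u=np.ones(10), s=np.zeros(10))
        assert fit.gamma_hat == 0.0 and not fit.passed_qc

    def test_recovers_steady_state_ratio_and_matches_closed_form(self):
        kin = [GeneKinetics(alpha=50.0, beta=1.0, gamma=0.5)]
        cfg = SimulationConfig(
            populations=[PopulationSpec(200, kin, "p", depth_sigma=0.3)], seed=9
        )
        m, _ = simulate_steady_state(cfg)
        u = m.unspliced.toarray()[:, 0].astype(float)
        s = m.spliced.toarray()[:, 0].astype(float)
        fit = fit_phase_portrait(u, s, quantile=0.05)
        # independent closed-form slope on the same quantile cells
        lo, hi = np.quantile(s, [0.05, 0.95])
        mask = (s <= lo) | (s >= hi)
        assert fit.gamma_hat == pytest.approx(
            zero_intercept_slope_bf(u[mask], s[mask]), abs=1e-10
        )
        assert fit.gamma_hat == pytest.approx(0.5, rel=0.15)  # true gamma/beta

    def test_quantile_validation(self):
        with pytest.raises(ValueError, match="quantile"):
            fit_phase_portrait(np.ones(4), np.ones(4), quantile=0.7)

    def test_qc_insensitive_to_other_genes(self, small_sim):
        # adding a constant-zero unspliced gene does not perturb other fits
        m, _, _ = small_sim
        pooled = pool_neighbors(m, m.gene_ids, k=5)
        fits_before = fit_all_genes(pooled)
        extended = PooledLayers(
            u=np.hstack([pooled.u, np.zeros((m.n_cells, 1))]),
            s=np.hstack([pooled.s, np.ones((m.n_cells, 1))]),
            gene_ids=pooled.gene_ids + ["dead"],
            barcodes=pooled.barcodes,
        )
        fits_after = fit_all_genes(extended)
        assert not fits_after[-1].passed_qc
        for fa, fb in zip(fits_before, fits_after[:-1]):
            assert fa.gamma_hat == fb.gamma_hat and fa.r2 == fb.r2


class TestComputeScores:
    def _pooled(self, u, s):
        u, s = np.atleast_2d(np.asarray(u, float)), np.atleast_2d(np.asarray(s, float))
        return PooledLayers(
            u=u, s=s, gene_ids=[f"g{j}" for j in range(u.shape[1])],
            barcodes=[f"c{i}" for i in range(u.shape[0])],
        )

    def test_on_line_score_zero_and_formula(self):
        from sansara.scoring import PhasePortraitFit

        pooled = self._pooled(u=[[1.0], [2.0]], s=[[2.0], [1.0]])
        fits = [PhasePortraitFit("g0", gamma_hat=0.5, r2=1, n_support=2, passed_qc=True)]
        scores = compute_scores(pooled, fits, scale_scores=False)
        assert scores.values[0, 0] == pytest.approx(0.0)   # 1 - 0.5*2
        assert scores.values[1, 0] == pytest.approx(1.5)   # 2 - 0.5*1, unspliced-leaning

    def test_maxabs_scaling_range(self, small_sim):
        m, _, _ = small_sim
        pooled = pool_neighbors(m, m.gene_ids, k=10)
        fits = fit_all_genes(pooled)
        scores = compute_scores(pooled, fits, scale_scores=True)
        amax = np.abs(scores.values).max(axis=0)
        assert np.all(amax <= 1.0 + 1e-12)
        nonzero_cols = np.abs(scores.values).sum(axis=0) > 0
        assert np.allclose(amax[nonzero_cols], 1.0)

    def test_missing_gene_rejected(self):
        from sansara.scoring import PhasePortraitFit

        pooled = self._pooled(u=[[1.0]], s=[[1.0]])
        fits = [PhasePortraitFit("absent", 1.0, 1.0, 1, True)]
        with pytest.raises(KeyError, match="absent"):
            compute_scores(pooled, fits)

    def test_population_sign_separation(self):
        # spliced-rich population gets negative mean score on designated genes,
        # unspliced-rich positive — the sign convention of the score
        m, labels = simulate_matched_expression_pair(300, 60, 0.6, seed=1, n_designated=15)
        labels = np.asarray(labels)
        pooled = pool_neighbors(m, m.gene_ids, k=1)
        # slope fitted on heavily pooled layers (global parameter, avoids
        # noise attenuation); per-cell scores stay unpooled
        fits = fit_all_genes(pool_neighbors(m, m.gene_ids, k=100))
        scores = compute_scores(pooled, fits, scale_scores=True)
        designated = {
            g for g, f in zip(m.gene_ids, m.gene_flags) if f == "designated"
        } & set(scores.gene_ids)
        cols = [scores.gene_ids.index(g) for g in designated]
        mean_a = scores.values[labels == "popA"][:, cols].mean()
        mean_b = scores.values[labels == "popB"][:, cols].mean()
        assert mean_a < 0 < mean_b  # popA is spliced-rich

    def test_sign_coherence_within_population(self, small_sim):
        # cells whose realized spliced fraction exceeds the gene's overall
        # fraction should lean negative (spliced excess), and conversely
        m, _, kin = small_sim
        pooled = pool_neighbors(m, m.gene_ids, k=1)
        fits = fit_all_genes(pooled)
        scores = compute_scores(pooled, fits, scale_scores=False)
        checked = 0
        for j, g in enumerate(scores.gene_ids):
            col = m.gene_ids.index(g)
            s = m.spliced.toarray()[:, col].astype(float)
            u = m.unspliced.toarray()[:, col].astype(float)
            tot = s + u
            ok = tot >= 5  # enough molecules for a meaningful fraction
            if ok.sum() < 50:
                continue
            frac = s[ok] / tot[ok]
            v = scores.values[ok, j]
            hi = frac > np.median(frac)
            if hi.sum() and (~hi).sum():
                assert v[hi].mean() < v[~hi].mean()
                checked += 1
        assert checked >= 5
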