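"""Normalization, score multiplication, sign-splitting and diagnostics."""

import logging

import numpy as np
import pytest

from oracles import log_normalize_bf
from sansara.io_counts import SplicedUnsplicedMatrix
from sansara.sagex import (
    build_sagex,
    distribution_diagnostics,
    log_normalize,
    sagex_log_normalize,
)
from sansara.scoring import ScoreMatrix


def _matrix(totals):
    t = np.asarray(totals)
    return SplicedUnsplicedMatrix(
        spliced=t, unspliced=np.zeros_like(t),
        gene_ids=[f"g{j}" for j in range(t.shape[1])],
        barcodes=[f"c{i}" for i in range(t.shape[0])],
    )


class TestLogNormalize:
    def test_single_cell_formula(self):
        e = log_normalize(_matrix([[2, 0, 8]]), scale_factor=1e4).e.toarray()
        assert e[0, 0] == pytest.approx(np.log(2001), abs=1e-4)
        assert e[0, 1] == 0.0
        assert e[0, 2] == pytest.approx(np.log(8001), abs=1e-4)

    def test_depth_invariance(self):
        a = log_normalize(_matrix([[2, 3, 5]])).e.toarray()
        b = log_normalize(_matrix([[4, 6, 10]])).e.toarray()
        assert np.allclose(a, b)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(4, size=(4, 6)) + 1
        e = log_normalize(_matrix(counts)).e.toarray()
        assert np.allclose(e, log_normalize_bf(counts))

    def test_zero_total_cell_rejected_with_barcode(self):
        with pytest.raises(ValueError, match="c1"):
            log_normalize(_matrix([[1, 2], [0, 0]]))

    def test_zero_iff_count_zero(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(1, size=(20, 10))
        counts[0, 0] = 1  # guard against an all-zero cell
        counts[:, 0] += 1
        e = log_normalize(_matrix(counts)).e.toarray()
        assert np.array_equal(e == 0, counts == 0)


def _escore(e_vals, v_vals):
    e_vals = np.asarray(e_vals, float)
    v_vals = np.asarray(v_vals, float)
    gids = [f"g{j}" for j in range(e_vals.shape[1])]
    bcs = [f"c{i}" for i in range(e_vals.shape[0])]
    from sansara.sagex import NormalizedExpression
    import scipy.sparse as sp

    e = NormalizedExpression(e=sp.csr_matrix(e_vals), gene_ids=gids, barcodes=bcs)
    v = ScoreMatrix(values=v_vals, gene_ids=gids, barcodes=bcs, scaling="none")
    return e, v


class TestBuildSagex:
    @pytest.mark.parametrize(
        "e_val,v_val,expect_s,expect_u",
        [
            (2.0, -0.5, 1.0, 0.0),
            (3.0, 0.25, 0.0, 0.75),
            (1.5, 0.0, 0.0, 0.0),
        ],
    )
    def test_sign_split_examples(self, e_val, v_val, expect_s, expect_u):
        e, v = _escore([[e_val]], [[v_val]])
        sx = build_sagex(e, v)
        assert sx.values[0, 0] == pytest.approx(expect_s)
        assert sx.values[0, 1] == pytest.approx(expect_u)

    def test_conservation_and_exclusivity(self):
        rng = np.random.default_rng(2)
        e_vals = rng.uniform(0, 3, size=(40, 12))
        v_vals = rng.uniform(-1, 1, size=(40, 12))
        e, v = _escore(e_vals, v_vals)
        sx = build_sagex(e, v)
        dense = sx.values.toarray()
        s_part, u_part = dense[:, 0::2], dense[:, 1::2]
        assert np.array_equal(s_part + u_part, np.abs(e_vals * v_vals))
        assert np.all(s_part * u_part == 0)
        assert dense.min() >= 0

    def test_misaligned_genes_rejected(self):
        e, v = _escore([[1.0]], [[0.5]])
        v.gene_ids = ["other"]
        with pytest.raises(ValueError, match="absent"):
            build_sagex(e, v)

    def test_feature_naming(self):
        e, v = _escore([[1.0, 2.0]], [[0.5, -0.5]])
        sx = build_sagex(e, v)
        assert sx.feature_names == ["g0.s", "g0.u", "g1.s", "g1.u"]


class TestSagexLogNormalize:
    def test_single_feature_cell(self):
        e, v = _escore([[2.0], [1.0]], [[-0.7], [-0.2]])
        sx = build_sagex(e, v)
        out = sagex_log_normalize(sx, scale_factor=1e4)
        # one nonzero feature: value/total == 1 regardless of magnitude
        for i in range(2):
            assert out.values[i, 0] == pytest.approx(np.log1p(1e4))

    def test_all_zero_cell_dropped_and_logged(self, caplog):
        e, v = _escore([[2.0, 1.0], [1.0, 1.0]], [[-0.7, 0.3], [0.0, 0.0]])
        sx = build_sagex(e, v)
        with caplog.at_level(logging.WARNING):
            out = sagex_log_normalize(sx)
        assert out.barcodes == ["c0"]
        assert out.provenance["dropped_barcodes"] == ["c1"]
        assert "dropping" in caplog.text

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(3)
        e_vals = rng.uniform(0.1, 3, size=(3, 4))
        v_vals = rng.uniform(-1, 1, size=(3, 4))
        e, v = _escore(e_vals, v_vals)
        sx = build_sagex(e, v)
        out = sagex_log_normalize(sx, scale_factor=1e4).values.toarray()
        raw = sx.values.toarray()
        expected = np.log1p(raw / raw.sum(axis=1, keepdims=True) * 1e4)
        assert np.allclose(out, expected)

    def test_exclusivity_preserved(self):
        rng = np.random.default_rng(4)
        e_vals = rng.uniform(0.1, 3, size=(10, 6))
        v_vals = rng.uniform(-1, 1, size=(10, 6))
        e, v = _escore(e_vals, v_vals)
        out = sagex_log_normalize(build_sagex(e, v))
        out.validate()  # raises if the pairing constraint is broken


class TestDiagnostics:
    def _pair(self):
        rng = np.random.default_rng(5)
        e_vals = rng.uniform(0, 2, size=(30, 5))
        e_vals[:, 4] = 1.3  # constant feature
        v_vals = rng.uniform(-1, 1, size=(30, 5))
        e, v = _escore(e_vals, v_vals)
        return e, build_sagex(e, v)

    def test_constant_feature_variance_zero(self):
        e, sx = self._pair()
        feats = distribution_diagnostics(e, sx)["features"]
        row = feats[(feats.matrix == "gex") & (feats.feature == "g4")].iloc[0]
        assert row["variance"] == pytest.approx(0.0)

    def test_nonzero_vs_overall_mean(self):
        import scipy.sparse as sp
        from sansara.sagex import NormalizedExpression

        e = NormalizedExpression(
            e=sp.csr_matrix(np.array([[0.0], [0.0], [3.0]])),
            gene_ids=["g0"], barcodes=["a", "b", "c"],
        )
        _, sx = self._pair()
        feats = distribution_diagnostics(e, sx)["features"]
        row = feats[(feats.matrix == "gex")].iloc[0]
        assert row["mean"] == pytest.approx(1.0)
        assert row["nonzero_mean"] == pytest.approx(3.0)

    def test_moments_match_brute_force(self):
        e, sx = self._pair()
        feats = distribution_diagnostics(e, sx)["features"]
        dense = e.e.toarray()
        for j in range(dense.shape[1]):
            row = feats[(feats.matrix == "gex")].iloc[j]
            assert row["mean"] == pytest.approx(dense[:, j].mean())
            assert row["variance"] == pytest.approx(dense[:, j].var(ddof=1))

    def test_histogram_covers_all_values(self):
        e, sx = self._pair()
        hist = distribution_diagnostics(e, sx)["histogram"]
        n_gex = hist[hist.matrix == "gex"]["count"].sum()
        assert n_gex == e.e.shape[0] * e.e.shape[1]
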