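"""Moderated differential expression: transforms, fit, thresholds."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cernax import ExpressionMatrix, bh_adjust, call_de, fit_and_moderate, \
    maybe_log2, quantile_normalize, voom_transform
from cernax.diffexp import estimate_prior, posterior_variance

from oracles import moderated_t_reference


def _mat(arr, scale="log2", platform="microarray", features=None, samples=None):
    arr = np.asarray(arr, float)
    df = pd.DataFrame(arr,
                      index=features or [f"G{i}" for i in range(arr.shape[0])],
                      columns=samples or [f"S{i}" for i in range(arr.shape[1])])
    return ExpressionMatrix(df, scale=scale, platform=platform)


class TestMaybeLog2:
    def test_linear_value_transforms_as_log2_x_plus_1(self):
        out = maybe_log2(_mat([[3.0]], scale="linear"))
        assert out.values.iloc[0, 0] == pytest.approx(2.0)
        assert out.scale == "log2"

    def test_log2_input_passes_through_unchanged(self, small_matrix):
        out = maybe_log2(small_matrix)
        pd.testing.assert_frame_equal(out.values, small_matrix.values)

    def test_negative_linear_value_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            maybe_log2(_mat([[-1.0, 2.0]], scale="linear"))

    def test_counts_redirected_to_voom(self):
        with pytest.raises(ValueError, match="voom"):
            maybe_log2(_mat([[1, 2]], scale="counts", platform="rnaseq_counts"))


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        out = quantile_normalize(_mat([[1, 4], [2, 5], [3, 6]]))
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_identical_columns_are_a_fixed_point(self):
        m = _mat([[1, 1], [5, 5], [3, 3]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_columns_share_sorted_values_afterwards(self, small_matrix):
        out = quantile_normalize(small_matrix).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_idempotent(self, small_matrix):
        once = quantile_normalize(small_matrix)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values.to_numpy(),
                                   once.values.to_numpy(), atol=1e-12)

    def test_ties_receive_mean_of_spanned_quantiles(self):
        # column 0 has a tie at 1 spanning the two lowest quantiles
        out = quantile_normalize(_mat([[1, 10], [1, 20], [5, 30]]))
        col0 = np.sort(out.values.to_numpy()[:, 0])
        assert col0[0] == pytest.approx(col0[1])

    def test_single_sample_returned_unchanged(self, caplog):
        m = _mat([[1.0], [2.0]])
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)


class TestVoom:
    def test_logcpm_formula_at_zero_count(self):
        # library size 10^6 in sample 0; the zero-count gene's log-CPM
        # follows directly from log2((0+0.5)/(1e6+1)*1e6)
        counts = _mat([[0, 5], [1_000_000, 999_995]],
                      scale="counts", platform="rnaseq_counts")
        logcpm, _ = voom_transform(counts)
        assert logcpm.values.iloc[0, 0] == pytest.approx(
            math.log2(0.5 / 1_000_001 * 1e6))
        assert logcpm.values.iloc[0, 0] == pytest.approx(-1.0000014, abs=1e-6)

    def test_identical_genes_get_equal_weights(self):
        counts = _mat(np.full((5, 4), 100), scale="counts",
                      platform="rnaseq_counts")
        _, w = voom_transform(counts)
        assert w.to_numpy().std() == pytest.approx(0.0)

    def test_scale_equivariance_up_to_pseudocount(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 2000, size=(30, 6))
        a, _ = voom_transform(_mat(base, scale="counts", platform="rnaseq_counts"))
        b, _ = voom_transform(_mat(base * 2, scale="counts", platform="rnaseq_counts"))
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy(),
                                   atol=0.02)

    def test_all_zero_genes_excluded(self):
        counts = _mat([[0, 0], [5, 7], [3, 1]], scale="counts",
                      platform="rnaseq_counts")
        logcpm, w = voom_transform(counts)
        assert logcpm.n_features == 2
        assert w.shape == (2, 2)


class TestFitAndModerate:
    def test_unmoderated_limit_equals_two_sample_t(self, small_matrix, groups10):
        fit, _ = fit_and_moderate(small_matrix, groups10)
        # d0 = 0: posterior variance reduces to the sample variance, and the
        # statistic is the ordinary equal-variance two-sample t
        t0 = fit.coef / (np.sqrt(fit.sigma2) * fit.se_factor)
        arr = small_matrix.values.to_numpy()
        t_ref = stats.ttest_ind(arr[:, :5], arr[:, 5:], axis=1).statistic
        np.testing.assert_allclose(t0.to_numpy(), t_ref, atol=1e-10)

    def test_infinite_prior_df_collapses_posterior_to_prior(self):
        s2 = np.array([0.5, 1.0, 2.0])
        post = posterior_variance(s2, 4.0, math.inf, 1.23)
        np.testing.assert_allclose(post, 1.23)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_reference(self, seed):
        rng = np.random.default_rng(seed)
        n_feat = int(rng.integers(10, 51))
        n = int(rng.integers(6, 13))
        n_t = int(rng.integers(2, n - 1))
        X = rng.normal(0, rng.uniform(0.3, 2.0), size=(n_feat, n))
        tumor = np.zeros(n, bool)
        tumor[:n_t] = True
        mat = _mat(X)
        groups = pd.Series(np.where(tumor, "tumor", "normal"),
                           index=mat.sample_ids)
        fit, table = fit_and_moderate(mat, groups)
        t_ref, d0_ref, s0_ref = moderated_t_reference(X, tumor)
        np.testing.assert_allclose(table["t"].to_numpy(), t_ref, atol=1e-10)
        assert fit.d0 == pytest.approx(d0_ref, rel=1e-6)
        assert fit.s0_squared == pytest.approx(s0_ref, rel=1e-6)

    def test_statistic_monotone_in_coefficient_at_fixed_variance(self, rng):
        # identical residuals, different planted shifts
        resid = rng.normal(0, 1, size=8)
        rows = [resid + np.r_[np.full(4, delta), np.zeros(4)]
                for delta in (0.5, 1.0, 2.0, 4.0)]
        mat = _mat(np.array(rows))
        groups = pd.Series(["tumor"] * 4 + ["normal"] * 4, index=mat.sample_ids)
        _, table = fit_and_moderate(mat, groups)
        t = table["t"].to_numpy()
        assert np.all(np.diff(np.abs(t)) > 0)

    def test_zero_variance_features_get_p_of_one(self):
        X = np.vstack([np.r_[np.full(3, 5.0), np.full(3, 3.0)],
                       np.random.default_rng(1).normal(size=(6, 6))[0:5]])
        mat = _mat(X)
        groups = pd.Series(["tumor"] * 3 + ["normal"] * 3, index=mat.sample_ids)
        _, table = fit_and_moderate(mat, groups)
        assert table.loc[0, "p"] == 1.0
        assert table.loc[0, "log2fc"] == pytest.approx(2.0)

    def test_empty_group_rejected(self, small_matrix):
        groups = pd.Series(["tumor"] * 10, index=small_matrix.sample_ids)
        with pytest.raises(ValueError):
            fit_and_moderate(small_matrix, groups)

    def test_two_samples_without_weights_rejected(self):
        mat = _mat([[1.0, 2.0], [3.0, 4.0]])
        groups = pd.Series(["tumor", "normal"], index=mat.sample_ids)
        with pytest.raises(ValueError, match="residual degrees of freedom"):
            fit_and_moderate(mat, groups)


class TestBHAdjust:
    def test_hand_stepup_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_empty_list(self):
        assert len(bh_adjust([])) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=40))
    def test_q_dominates_p_and_capped_at_one(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-15)
        assert np.all(q <= 1.0)


class TestCallDE:
    def test_threshold_application(self):
        table = pd.DataFrame({
            "feature": ["a", "b", "c"],
            "log2fc": [1.2, 1.0, -3.0],
            "t": [5.0, 9.0, -2.0],
            "p": [0.001, 0.0001, 0.1],
            "q": [0.01, 0.001, 0.2],
        })
        up, down, out = call_de(table)
        assert up == ["a"]
        # a boundary gene at log2FC exactly 1.0 is never called, however
        # significant: the fold-change inequality is strict
        assert out.loc[out["feature"] == "b", "direction"].item() == "ns"
        # FDR failure alone is enough to exclude
        assert down == []

    def test_requires_q_column(self):
        with pytest.raises(ValueError, match="q column"):
            call_de(pd.DataFrame({"feature": ["a"], "log2fc": [2.0]}))


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_moderated_fit_matches_limma_reference(tmp_path, rng):
    """Dual-route check: the moderated t pipeline against Bioconductor limma
    on a small two-group matrix."""
    X = rng.normal(7, 1, size=(40, 8))
    X[:5, :4] += 2.0
    mat = _mat(X)
    groups = pd.Series(["tumor"] * 4 + ["normal"] * 4, index=mat.sample_ids)
    _, table = fit_and_moderate(mat, groups)

    mat_path = tmp_path / "m.tsv"
    mat.values.to_csv(mat_path, sep="\t")
    out_path = tmp_path / "limma.tsv"
    script = tmp_path / "fit.R"
    script.write_text(f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim("{mat_path}", row.names=1))
design <- cbind(normal=1, tumor_vs_normal=c(rep(1,4), rep(0,4)))
fit <- eBayes(lmFit(x, design))
write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]),
            "{out_path}", sep="\t", quote=FALSE)
""")
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(out_path, sep="\t", index_col=0)
    np.testing.assert_allclose(table["t"].to_numpy(), ref["t"].to_numpy(),
                               atol=1e-6)
    np.testing.assert_allclose(table["p"].to_numpy(), ref["p"].to_numpy(),
                               atol=1e-6)


def test_null_false_positive_rate_near_alpha(rng):
    """On null data the moderated-t p-values are roughly uniform: the
    fraction below 0.05 stays within binomial 3*SE of 0.05."""
    X = rng.normal(0, 1, size=(2000, 10))
    mat = _mat(X)
    groups = pd.Series(["tumor"] * 5 + ["normal"] * 5, index=mat.sample_ids)
    _, table = fit_and_moderate(mat, groups)
    rate = float((table["p"] < 0.05).mean())
    band = 3 * math.sqrt(0.05 * 0.95 / 2000)
    assert abs(rate - 0.05) < band
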