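"""Moderated t-test machinery: preprocessing, shrinkage, prior fit, BH."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from monomeg.diffexpr import (
    EBPrior,
    bh_adjust,
    estimate_prior,
    fit_comparison,
    preprocess,
)
from monomeg.matrix import DataError
from tests.conftest import balanced_stages, make_matrix


# ---------------------------------------------------------------- preprocess
def test_preprocess_log2_then_zscore():
    matrix = make_matrix([[1, 3, 7]], ["normal", "I", "II"], scale_state="raw_fpkm")
    out = preprocess(matrix, log_transform=True)
    np.testing.assert_allclose(out.values.to_numpy()[0], [-1, 0, 1], atol=1e-12)
    assert out.scale_state == "standardized"


def test_preprocess_drops_constant_genes_with_warning(caplog):
    matrix = make_matrix(
        [[1, 3, 7], [5, 5, 5]], ["normal", "I", "II"], scale_state="raw_fpkm"
    )
    with caplog.at_level("WARNING", logger="monomeg.diffexpr"):
        out = preprocess(matrix)
    assert list(out.gene_ids) == ["g0"]
    assert any("zero-variance" in r.message for r in caplog.records)


def test_preprocess_output_rows_standardized():
    rng = np.random.default_rng(0)
    matrix = make_matrix(
        rng.gamma(2.0, 5.0, size=(20, 12)), balanced_stages(3), scale_state="raw_fpkm"
    )
    out = preprocess(matrix)
    vals = out.values.to_numpy()
    np.testing.assert_allclose(vals.mean(axis=1), 0, atol=1e-8)
    np.testing.assert_allclose(vals.var(axis=1, ddof=1), 1, atol=1e-8)


def test_preprocess_rejects_negative_and_all_constant():
    with pytest.raises(DataError, match="negative"):
        preprocess(make_matrix([[1, -2, 3]], ["normal", "I", "II"], "raw_fpkm"))
    with pytest.raises(DataError, match="constant"):
        preprocess(make_matrix([[2, 2, 2]], ["normal", "I", "II"], "raw_fpkm"))


# ------------------------------------------------------------ fit_comparison
def test_unmoderated_equals_classical_pooled_t():
    """d0 = 0: the hand-computed pooled two-sample t for (1,2,3) vs (3,4,5)."""
    matrix = make_matrix(
        [[1, 2, 3, 3, 4, 5]], ["normal"] * 3 + ["I"] * 3, scale_state="standardized"
    )
    table = fit_comparison(matrix, "I", prior=EBPrior(d0=0.0, s0_sq=1.0)).table
    assert table["lfc"].iloc[0] == pytest.approx(2.0)
    assert table["t_mod"].iloc[0] == pytest.approx(2.449, abs=5e-4)
    expected = stats.ttest_ind([3, 4, 5], [1, 2, 3], equal_var=True)
    assert table["t_mod"].iloc[0] == pytest.approx(expected.statistic, rel=1e-12)
    assert table["p"].iloc[0] == pytest.approx(expected.pvalue, rel=1e-12)


def test_equal_means_give_null_statistics():
    matrix = make_matrix(
        [[1, 2, 3, 1, 2, 3]], ["normal"] * 3 + ["II"] * 3, scale_state="standardized"
    )
    table = fit_comparison(matrix, "II", prior=EBPrior(d0=0.0, s0_sq=1.0)).table
    assert table["lfc"].iloc[0] == 0
    assert table["t_mod"].iloc[0] == 0
    assert table["p"].iloc[0] == pytest.approx(1.0)


def test_infinite_prior_is_total_shrinkage():
    rng = np.random.default_rng(1)
    matrix = make_matrix(rng.normal(size=(30, 12)), balanced_stages(3))
    prior = EBPrior(d0=math.inf, s0_sq=0.5)
    table = fit_comparison(matrix, "III", prior=prior).table
    cols = matrix.stages.index
    x1 = matrix.values[cols[matrix.stages == "III"]].to_numpy()
    x0 = matrix.values[cols[matrix.stages == "normal"]].to_numpy()
    lfc = x1.mean(axis=1) - x0.mean(axis=1)
    expected_t = lfc / (np.sqrt(0.5) * np.sqrt(1 / 3 + 1 / 3))
    np.testing.assert_allclose(table["t_mod"], expected_t, rtol=1e-12)
    assert math.isinf(table["df_total"].iloc[0])
    assert np.isfinite(table["p"]).all()


def test_column_order_invariance():
    rng = np.random.default_rng(2)
    matrix = make_matrix(rng.normal(size=(25, 16)), balanced_stages(4))
    perm = rng.permutation(16)
    shuffled = make_matrix(
        matrix.values.to_numpy()[:, perm], list(np.array(matrix.stages)[perm])
    )
    t1 = fit_comparison(matrix, "I", prior="auto").table
    t2 = fit_comparison(shuffled, "I", prior="auto").table
    pd.testing.assert_frame_equal(t1, t2)


def test_too_small_group_errors_with_group_name():
    matrix = make_matrix(
        [[1.0, 2, 3, 4, 5]], ["normal"] * 4 + ["I"], scale_state="standardized"
    )
    with pytest.raises(DataError, match="'I'"):
        fit_comparison(matrix, "I", prior=EBPrior(0.0, 1.0))


def test_direction_calls_respect_lfc_sign_and_cutoff():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(200, 40))
    x[:50, 20:] += 2.0  # up in stage
    x[50:100, 20:] -= 2.0  # down in stage
    matrix = make_matrix(x, ["normal"] * 20 + ["I"] * 20)
    table = fit_comparison(matrix, "I", prior="auto", fdr_cutoff=0.01).table
    called = table[table["direction"] != "none"]
    assert ((called["direction"] == "up") == (called["lfc"] > 0)).all()
    assert (called["fdr"] < 0.01).all()
    assert (table["fdr"] >= table["p"] - 1e-15).all()


# ------------------------------------------------------------ estimate_prior
@pytest.mark.parametrize("seed", range(3))
def test_prior_recovery_from_hierarchical_law(seed):
    """sigma^2 ~ scaled-inv-chi2(d0=4, s0^2=2); s^2 ~ sigma^2 chi2_dg / dg."""
    rng = np.random.default_rng(seed)
    d0, s0_sq, d_g, n = 4.0, 2.0, 20.0, 5000
    sigma2 = s0_sq * d0 / rng.chisquare(d0, n)
    s2 = sigma2 * rng.chisquare(d_g, n) / d_g
    prior = estimate_prior(s2, d_g)
    assert abs(prior.d0 - d0) / d0 < 0.25
    assert abs(prior.s0_sq - s0_sq) / s0_sq < 0.15


def test_identical_variances_give_infinite_d0():
    prior = estimate_prior(np.full(50, 3.0), d_g=10.0)
    assert math.isinf(prior.d0)
    assert prior.s0_sq > 0


def test_large_d0_makes_shrinkage_total():
    """Near-constant s^2 at large d_g: posterior variances collapse to s0^2."""
    rng = np.random.default_rng(4)
    d_g = 2000.0
    s2 = 2.0 * rng.chisquare(d_g, 1000) / d_g
    prior = estimate_prior(s2, d_g)
    s2_post = (prior.d0 * prior.s0_sq + d_g * s2) / (prior.d0 + d_g)
    np.testing.assert_allclose(s2_post, prior.s0_sq, rtol=0.1)


def test_prior_estimation_needs_enough_genes():
    with pytest.raises(DataError, match="10"):
        estimate_prior(np.array([1.0, 2.0]), d_g=4.0)


def test_moderated_t_matches_limma_ebayes(tmp_path):
    """Independent oracle: limma's lmFit + eBayes on the same small matrix."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the limma cross-check")
    rng = np.random.default_rng(7)
    n1 = n0 = 5
    x = rng.normal(size=(60, n0 + n1)) * rng.gamma(2, 0.5, size=(60, 1))
    x[:10, n0:] += 1.0
    genes = [f"g{i}" for i in range(60)]
    frame = pd.DataFrame(x, index=genes)
    frame.to_csv(tmp_path / "m.tsv", sep="\t")
    script = textwrap.dedent(
        """
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("%s", row.names = 1))
        design <- cbind(Intercept = 1, Stage = rep(c(0, 1), each = 5))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t = fit$t[, "Stage"], p = fit$p.value[, "Stage"])
        out$d0 <- fit$df.prior
        out$s0sq <- fit$s2.prior
        write.table(out, "%s", sep = "\t", quote = FALSE)
        """
        % (tmp_path / "m.tsv", tmp_path / "limma.tsv")
    )
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")

    matrix = make_matrix(x, ["normal"] * n0 + ["I"] * n1)
    table = fit_comparison(matrix, "I", prior="auto")
    np.testing.assert_allclose(table.prior.d0, ref["d0"].iloc[0], rtol=1e-6)
    np.testing.assert_allclose(table.prior.s0_sq, ref["s0sq"].iloc[0], rtol=1e-6)
    np.testing.assert_allclose(table.table["t_mod"], ref["t"], rtol=1e-6)
    np.testing.assert_allclose(table.table["p"], ref["p"], rtol=1e-6)


# ---------------------------------------------------------------- bh_adjust
def test_bh_hand_enumerated_example():
    np.testing.assert_allclose(
        bh_adjust(np.array([0.005, 0.01, 0.03, 0.04])), [0.02, 0.02, 0.04, 0.04]
    )


def test_bh_trivial_cases():
    assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)
    np.testing.assert_allclose(bh_adjust(np.full(4, 0.02)), np.full(4, 0.02))


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    p = rng.uniform(size=500)
    expected = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(DataError):
        bh_adjust(np.array([0.5, 1.2]))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
)
def test_bh_properties(p_list):
    """Adjusted values dominate raw ones and are monotone in raw-p order."""
    p = np.array(p_list)
    adjusted = bh_adjust(p)
    assert (adjusted >= p - 1e-15).all()
    assert (adjusted <= 1.0).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(adjusted[order]) >= -1e-15).all()
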