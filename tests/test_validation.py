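"""Latent-mean stage tests: Welch/ANOVA oracles, verdicts, end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from monomeg.matrix import DataError, STAGES
from monomeg.monotone import MonotoneGeneSets
from monomeg.synthetic import SimulationConfig, generate
from monomeg.diffexpr import preprocess
from monomeg.vae import LatentSummary, VAEConfig
from monomeg.validation import test_latent_means, validate_gene_sets

test_latent_means.__test__ = False  # library function, not a test item


def make_summary(mu_by_stage: dict[str, list[float]], latent_dim: int = 1) -> LatentSummary:
    rows = []
    index = []
    for stage, values in mu_by_stage.items():
        for i, v in enumerate(values):
            row = {f"mu_{j}": (v if j == 0 else 0.0) for j in range(latent_dim)}
            row.update({f"logvar_{j}": 0.0 for j in range(latent_dim)})
            row["stage"] = stage
            rows.append(row)
            index.append(f"{stage}_{i}")
    return LatentSummary(table=pd.DataFrame(rows, index=index), latent_dim=latent_dim)


def _full_summary(shift_per_stage, base=None, n=3):
    base = base or [0.0, 0.05, -0.05]
    return make_summary(
        {s: [b + shift_per_stage[k] for b in base] for k, s in enumerate(STAGES)}
    )


def test_welch_hand_computed_example():
    """Mean difference 1.0, each group variance 0.01, n = 3 -> |t| = 12.247."""
    summary = make_summary(
        {
            "normal": [0, 0.1, -0.1],
            "I": [1, 1.1, 0.9],
            "II": [1, 1.1, 0.9],
            "III": [1, 1.1, 0.9],
        }
    )
    report = test_latent_means(summary)
    row = report.pairwise.set_index("pair").loc["normal_vs_I"]
    assert abs(row["t"]) == pytest.approx(12.247, abs=5e-4)
    assert row["p"] < 0.001
    # oracle: explicit Welch formula
    t_manual = (0.0 - 1.0) / np.sqrt(0.01 / 3 + 0.01 / 3)
    assert row["t"] == pytest.approx(t_manual, rel=1e-6)


def test_equal_groups_give_t_zero_p_one():
    summary = make_summary(
        {"normal": [0, 1, -1], "I": [1, -1, 0], "II": [0, 1, -1], "III": [1, -1, 0]}
    )
    report = test_latent_means(summary)
    row = report.pairwise.set_index("pair").loc["normal_vs_I"]
    assert row["t"] == pytest.approx(0.0)
    assert row["p"] == pytest.approx(1.0)


def test_anova_matches_scipy_oracle():
    rng = np.random.default_rng(0)
    groups = {s: list(rng.normal(k * 0.5, 1.0, size=10)) for k, s in enumerate(STAGES)}
    report = test_latent_means(make_summary(groups))
    expected = stats.f_oneway(*(np.array(groups[s]) for s in STAGES))
    assert report.anova_f == pytest.approx(expected.statistic, rel=1e-12)
    assert report.anova_p == pytest.approx(expected.pvalue, rel=1e-12)


@pytest.mark.parametrize(
    "means, verdict",
    [
        ((0.5, 0.2, 0.1, -0.3), "decreasing"),
        ((-0.5, -0.2, 0.1, 0.3), "increasing"),
        ((0.5, 0.2, 0.25, -0.3), "non_monotone"),
    ],
)
def test_verdict_from_strict_stage_ordering(means, verdict):
    report = test_latent_means(_full_summary(means))
    assert report.verdict == verdict


def test_verdict_antisymmetric_under_negation():
    summary = _full_summary((0.8, 0.4, 0.0, -0.4))
    negated = LatentSummary(
        table=summary.table.assign(mu_0=-summary.table["mu_0"]),
        latent_dim=1,
    )
    assert test_latent_means(summary).verdict == "decreasing"
    assert test_latent_means(negated).verdict == "increasing"


def test_missing_stage_is_named():
    summary = make_summary({"normal": [0, 1], "I": [0, 1], "II": [0, 1]})
    with pytest.raises(DataError, match="III"):
        test_latent_means(summary)


def test_multidimensional_latent_reduced_with_warning(caplog):
    summary = make_summary(
        {s: [0.1 * k, 0.1 * k + 0.2, 0.1 * k - 0.2] for k, s in enumerate(STAGES)},
        latent_dim=2,
    )
    with caplog.at_level("WARNING", logger="monomeg.validation"):
        report = test_latent_means(summary)
    assert any("first latent axis" in r.message for r in caplog.records)
    assert len(report.pairwise) == 3


def test_bh_flag_adjusts_pairwise_pvalues():
    rng = np.random.default_rng(1)
    groups = {s: list(rng.normal(0, 1, size=8)) for s in STAGES}
    raw = test_latent_means(make_summary(groups)).pairwise["p"]
    adjusted = test_latent_means(make_summary(groups), bh_correct_pairwise=True).pairwise["p"]
    assert (adjusted >= raw - 1e-15).all()


# ---------------------------------------------------- validate_gene_sets
@pytest.fixture(scope="module")
def planted_cohort():
    config = SimulationConfig(
        group_sizes=(40, 40, 40, 40),
        n_genes_per_class={"mono_inc": 50, "mono_dec": 50, "null": 200},
        effect_size=1.0,
        seed=17,
    )
    matrix, truth = generate(config)
    return preprocess(matrix), truth


def _sets(truth, decreasing=(), increasing=()):
    return MonotoneGeneSets(
        decreasing=set(decreasing), increasing=set(increasing), audit=pd.DataFrame()
    )


def test_pooled_validation_recovers_monotone_verdicts(planted_cohort):
    matrix, truth = planted_cohort
    sets = _sets(
        truth,
        decreasing=truth.genes_in_class("mono_dec"),
        increasing=truth.genes_in_class("mono_inc"),
    )
    reports = validate_gene_sets(matrix, sets, VAEConfig(input_dim=1, seed=0), mode="pooled")
    assert reports["decreasing"].verdict == "decreasing"
    assert reports["increasing"].verdict == "increasing"
    assert reports["decreasing"].anova_p < 0.01
    assert reports["increasing"].anova_p < 0.01
    assert reports["decreasing"].audit["mode"] == "pooled"


def test_swapped_sets_swap_verdicts(planted_cohort):
    matrix, truth = planted_cohort
    swapped = _sets(
        truth,
        decreasing=truth.genes_in_class("mono_inc"),
        increasing=truth.genes_in_class("mono_dec"),
    )
    reports = validate_gene_sets(matrix, swapped, VAEConfig(input_dim=1, seed=0))
    assert reports["decreasing"].verdict == "increasing"
    assert reports["increasing"].verdict == "decreasing"


def test_per_stage_mode_runs_and_records_four_seeds(planted_cohort):
    matrix, truth = planted_cohort
    sets = _sets(truth, decreasing=truth.genes_in_class("mono_dec"))
    reports = validate_gene_sets(
        matrix, sets, VAEConfig(input_dim=1, seed=3), mode="per_stage"
    )
    report = reports["decreasing"]
    assert not report.skipped
    assert set(report.audit["seeds"]) == set(STAGES)
    assert reports["increasing"].skipped


def test_empty_sets_are_skipped_not_errors(planted_cohort):
    matrix, truth = planted_cohort
    reports = validate_gene_sets(matrix, _sets(truth), VAEConfig(input_dim=1))
    assert reports["decreasing"].skipped and reports["increasing"].skipped


def test_null_genes_do_not_earn_significance(planted_cohort):
    """Feeding planted-null genes: the joint ANOVA p behaves like a null p."""
    matrix, truth = planted_cohort
    null_genes = list(truth.genes_in_class("null"))[:50]
    hits = 0
    n_runs = 8
    for seed in range(n_runs):
        reports = validate_gene_sets(
            matrix, _sets(truth, decreasing=null_genes),
            VAEConfig(input_dim=1, seed=seed),
        )
        if reports["decreasing"].anova_p < 0.05:
            hits += 1
    assert hits <= n_runs // 2
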