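"""Hypothesis tests on VAE latent means across ordered stages.

The null hypothesis of interest is mu_normal = mu_I = mu_II = mu_III for the
per-stage latent means. Each sample's posterior mean is treated as one
observation, so sample size and power are well defined; adjacent stages are
compared with Welch (unequal-variance) two-sample t-tests — independently
trained per-stage encoders give no variance-homogeneity guarantee — and the
joint null with one-way ANOVA. A gene set earns a monotone verdict only when
the four stage means are strictly ordered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from monomeg.matrix import STAGES, DataError, ExpressionMatrix
from monomeg.monotone import MonotoneGeneSets
from monomeg.diffexpr import bh_adjust
from monomeg.vae import LatentSummary, VAEConfig, build, encode, train

logger = logging.getLogger(__name__)

_PAIRS = (("normal", "I"), ("I", "II"), ("II", "III"))


@dataclass
class StageValidationReport:
    """Per-stage latent summaries, pairwise and joint tests, and a verdict.

    ``per_stage``: index stage, columns n / mean / var of per-sample latent
    means. ``pairwise``: one row per adjacent-stage Welch t-test with
    statistic, degrees of freedom and two-sided p (optionally BH-adjusted).
    ``verdict``: decreasing | increasing | non_monotone, from strict ordering
    of the recorded stage means. ``skipped`` marks a report requested for an
    empty gene set.
    """

    per_stage: pd.DataFrame
    pairwise: pd.DataFrame
    anova_f: float
    anova_p: float
    verdict: str
    rule: str = "strict ordering of per-stage means of per-sample latent mu"
    skipped: bool = False
    audit: dict | None = None

    def to_text(self) -> str:
        if self.skipped:
            return "skipped: empty gene set\n"
        lines = ["Per-stage latent means:"]
        for stage, row in self.per_stage.iterrows():
            lines.append(
                f"  {stage:>7}: n={int(row['n']):4d}  mean={row['mean']:+.4f}  var={row['var']:.4f}"
            )
        lines.append("Adjacent-stage Welch t-tests:")
        for _, row in self.pairwise.iterrows():
            lines.append(
                f"  {row['pair']:>13}: t={row['t']:+.3f}  df={row['df']:.1f}  p={row['p']:.4g}"
            )
        lines.append(f"Joint one-way ANOVA: F={self.anova_f:.3f}  p={self.anova_p:.4g}")
        lines.append(f"Verdict: {self.verdict}  ({self.rule})")
        return "\n".join(lines) + "\n"

    def to_tsv(self, path: str | Path) -> None:
        self.pairwise.assign(
            anova_f=self.anova_f, anova_p=self.anova_p, verdict=self.verdict
        ).to_csv(path, sep="\t", index=False)


def test_latent_means(
    summary: LatentSummary, bh_correct_pairwise: bool = False
) -> StageValidationReport:
    """Welch t-tests between adjacent stages plus joint one-way ANOVA.

    Multidimensional latents are reduced to their first axis with a warning.
    Raises :class:`DataError` if any stage is absent or has < 2 samples.
    """
    if summary.latent_dim > 1:
        logger.warning(
            "latent_dim = %d; stage tests use the first latent axis only",
            summary.latent_dim,
        )
    groups: dict[str, np.ndarray] = {}
    for stage in STAGES:
        mask = (summary.stages == stage).to_numpy()
        if not mask.any():
            raise DataError(f"stage {stage!r} absent from the latent summary")
        mu = summary.mu[mask, 0]
        if mu.size < 2:
            raise DataError(f"stage {stage!r} has {mu.size} sample(s); >= 2 required")
        groups[stage] = mu

    per_stage = pd.DataFrame(
        {
            "n": [groups[s].size for s in STAGES],
            "mean": [groups[s].mean() for s in STAGES],
            "var": [groups[s].var(ddof=1) for s in STAGES],
        },
        index=pd.Index(STAGES, name="stage"),
    )

    rows = []
    for a, b in _PAIRS:
        res = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append(
            {"pair": f"{a}_vs_{b}", "t": float(res.statistic), "df": float(res.df),
             "p": float(res.pvalue)}
        )
    pairwise = pd.DataFrame(rows)
    if bh_correct_pairwise:
        pairwise["p"] = bh_adjust(pairwise["p"].to_numpy())

    anova = stats.f_oneway(*(groups[s] for s in STAGES))
    means = per_stage["mean"].to_numpy()
    if np.all(np.diff(means) < 0):
        verdict = "decreasing"
    elif np.all(np.diff(means) > 0):
        verdict = "increasing"
    else:
        verdict = "non_monotone"
    return StageValidationReport(
        per_stage=per_stage,
        pairwise=pairwise,
        anova_f=float(anova.statistic),
        anova_p=float(anova.pvalue),
        verdict=verdict,
    )


def _derived_seed(base_seed: int, index: int) -> int:
    state = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(index,)).generate_state(1)
    return int(state[0] % (2**31))


def _fit_and_encode(
    matrix: ExpressionMatrix,
    gene_ids: list[str],
    config: VAEConfig,
    mode: str,
    seed_offset: int,
) -> tuple[LatentSummary, dict]:
    sub = matrix.subset_genes(gene_ids)
    audit: dict = {"mode": mode, "n_genes": len(gene_ids), "seeds": {}}
    if mode == "pooled":
        seed = _derived_seed(config.seed, seed_offset)
        cfg = replace(config, input_dim=sub.n_genes, seed=seed)
        model = train(build(cfg), sub)
        audit["seeds"]["pooled"] = seed
        audit["config"] = vars(cfg)
        return encode(model, sub, align_sign=True), audit
    if mode != "per_stage":
        raise ValueError(f"mode must be 'pooled' or 'per_stage', got {mode!r}")
    pieces = []
    for k, stage in enumerate(STAGES):
        stage_matrix = sub.subset_stage(stage)
        if stage_matrix.n_samples < 2:
            raise DataError(f"stage {stage!r} has < 2 samples; cannot train a per-stage model")
        seed = _derived_seed(config.seed, seed_offset * 8 + k + 1)
        cfg = replace(config, input_dim=sub.n_genes, seed=seed)
        model = train(build(cfg), stage_matrix)
        audit["seeds"][stage] = seed
        pieces.append(encode(model, stage_matrix, align_sign=True).table)
    audit["config"] = vars(replace(config, input_dim=sub.n_genes))
    table = pd.concat(pieces).loc[sub.sample_ids]
    return LatentSummary(table=table, latent_dim=config.latent_dim), audit


def validate_gene_sets(
    matrix: ExpressionMatrix,
    sets: MonotoneGeneSets,
    config: VAEConfig,
    mode: Literal["pooled", "per_stage"] = "pooled",
) -> dict[str, StageValidationReport]:
    """Train VAEs on each monotone gene set and test the latent stage means.

    In ``pooled`` mode one model is trained on all samples per direction; in
    ``per_stage`` mode four independent models are trained, one per stage,
    and every sample is encoded by its own stage's model (latent axes are
    sign-aligned to the mean expression of the gene set so the four latents
    share an orientation). Empty gene sets yield a report marked skipped.
    """
    if matrix.scale_state != "standardized":
        raise DataError("validate_gene_sets expects a standardized matrix")
    reports: dict[str, StageValidationReport] = {}
    for offset, (direction, gene_set) in enumerate(
        (("decreasing", sets.decreasing), ("increasing", sets.increasing))
    ):
        if not gene_set:
            reports[direction] = StageValidationReport(
                per_stage=pd.DataFrame(),
                pairwise=pd.DataFrame(),
                anova_f=float("nan"),
                anova_p=float("nan"),
                verdict="non_monotone",
                skipped=True,
            )
            continue
        gene_ids = sorted(gene_set)
        summary, audit = _fit_and_encode(matrix, gene_ids, config, mode, offset + 1)
        report = test_latent_means(summary)
        report.audit = audit
        reports[direction] = report
    return reports
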