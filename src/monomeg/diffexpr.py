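"""Empirical-Bayes moderated t-statistics with Benjamini-Hochberg FDR control.

Implements, from first principles, the hierarchical-variance model behind
moderated t-tests for two-group comparisons. Per gene g with pooled residual
variance ``s_g^2`` on ``d_g`` degrees of freedom, the gene variances are
modeled as draws from a scaled inverse-chi-square prior with hyperparameters
``(d0, s0^2)``. The posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces ``s_g^2`` in the t-statistic, which then follows a t distribution
with ``d0 + d_g`` degrees of freedom under the null. The hyperparameters are
estimated by matching the first two moments of ``log s_g^2`` through the
digamma/trigamma functions. With ``d0 = 0`` the statistic reduces to the
classical pooled two-sample t; with ``d0 = +inf`` shrinkage is total and every
gene is tested against ``s0^2``.

Multiple testing is addressed per comparison with the Benjamini-Hochberg
step-up adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from monomeg.matrix import STAGES, DataError, ExpressionMatrix

logger = logging.getLogger(__name__)

COMPARISONS = ("I_vs_normal", "II_vs_normal", "III_vs_normal")


@dataclass(frozen=True)
class EBPrior:
    """Variance-prior hyperparameters: degrees of freedom and scale.

    ``d0`` may be ``math.inf`` (total shrinkage). ``d0 = 0`` is accepted as
    the degenerate no-moderation case even though the prior is then improper.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or math.isnan(self.d0):
            raise ValueError(f"prior d0 must be >= 0, got {self.d0}")
        if self.s0_sq <= 0 and self.d0 > 0:
            raise ValueError(f"prior s0_sq must be positive, got {self.s0_sq}")


@dataclass
class DiffExprTable:
    """Per-gene statistics for one stage-vs-normal comparison.

    ``table`` columns: ``lfc`` (stage minus normal mean difference on the
    analysis scale), ``s2`` (pooled within-group variance), ``t_mod``,
    ``df_total``, ``p``, ``fdr``, ``direction`` in {up, down, none}.
    """

    comparison: str
    table: pd.DataFrame
    prior: EBPrior
    fdr_cutoff: float

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "comparison", self.comparison)
        out.to_csv(path, sep="\t", index_label="gene_id")


def preprocess(matrix: ExpressionMatrix, log_transform: bool = True) -> ExpressionMatrix:
    """Optionally log2(x+1)-transform, then z-score each gene across samples.

    Genes with zero variance carry no between-group information and are
    dropped with a warning. Raises :class:`DataError` on negative input or
    if nothing remains to analyze.
    """
    if matrix.scale_state != "raw_fpkm":
        raise DataError(f"preprocess expects raw_fpkm input, got {matrix.scale_state}")
    values = matrix.values.to_numpy(dtype=float)
    if (values < 0).any():
        raise DataError("negative expression values in raw FPKM matrix")
    if log_transform:
        values = np.log2(values + 1.0)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    constant = sds[:, 0] == 0
    if constant.all():
        raise DataError("all genes are constant; nothing to analyze")
    if constant.any():
        dropped = matrix.gene_ids[constant].tolist()
        logger.warning(
            "dropped %d zero-variance genes (first: %s)", len(dropped), dropped[:3]
        )
        values = values[~constant]
        means = means[~constant]
        sds = sds[~constant]
    standardized = (values - means) / sds
    return ExpressionMatrix(
        values=pd.DataFrame(
            standardized, index=matrix.gene_ids[~constant], columns=matrix.sample_ids
        ),
        stages=matrix.stages.copy(),
        scale_state="standardized",
    )


def estimate_prior(s2_values: np.ndarray, d_g: float) -> EBPrior:
    """Fit ``(d0, s0^2)`` from observed pooled variances by log-moment matching.

    Under the model, ``e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2)`` has
    mean ``log s0^2 - digamma(d0/2) - log(2/d0)`` and variance
    ``trigamma(d0/2) + trigamma(d_g/2)``; ``d0`` solves the trigamma equation
    and ``s0^2`` follows from the mean. If the observed spread of ``log s^2``
    does not exceed the sampling component ``trigamma(d_g/2)``, the prior is
    degenerate: ``d0 = +inf`` with ``s0^2`` from the mean equation.
    """
    s2 = np.asarray(s2_values, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 10:
        raise DataError(f"prior estimation needs >= 10 positive variances, got {s2.size}")
    if d_g <= 0:
        raise DataError(f"residual degrees of freedom must be positive, got {d_g}")
    z = np.log(s2)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = e.mean()
    excess = e.var(ddof=1) - special.polygamma(1, d_g / 2.0)
    if excess <= 0:
        logger.info("no excess spread in log s^2; prior degrees of freedom set to +inf")
        return EBPrior(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    # invert trigamma(d0/2) = excess; trigamma is decreasing so bracket and solve
    half_d0 = optimize.brentq(
        lambda x: special.polygamma(1, x) - excess, 1e-8, 1e8, xtol=1e-12, rtol=1e-12
    )
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return EBPrior(d0=d0, s0_sq=s0_sq)


def _moderated_stats(
    lfc: np.ndarray,
    s2: np.ndarray,
    d_g: float,
    n1: int,
    n2: int,
    prior: EBPrior,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Return (t_mod, df_total, two-sided p) given pooled variances."""
    se_factor = math.sqrt(1.0 / n1 + 1.0 / n2)
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d_g * s2) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = lfc / (np.sqrt(s2_post) * se_factor)
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    return t_mod, df_total, np.minimum(p, 1.0)


def fit_comparison(
    matrix: ExpressionMatrix,
    stage: str,
    prior: EBPrior | str = "auto",
    fdr_cutoff: float = 0.01,
) -> DiffExprTable:
    """Moderated t-test of one stage against normal, gene by gene.

    ``prior="auto"`` estimates the variance-prior hyperparameters from this
    comparison's pooled variances via :func:`estimate_prior`.
    """
    if stage not in ("I", "II", "III"):
        raise DataError(f"stage must be one of I, II, III; got {stage!r}")
    stage_cols = matrix.samples_in_stage(stage)
    normal_cols = matrix.samples_in_stage("normal")
    for name, cols in (("normal", normal_cols), (stage, stage_cols)):
        if len(cols) < 2:
            raise DataError(f"group {name!r} has {len(cols)} samples; >= 2 required")

    x1 = matrix.values[stage_cols].to_numpy(dtype=float)
    x0 = matrix.values[normal_cols].to_numpy(dtype=float)
    n1, n0 = x1.shape[1], x0.shape[1]
    d_g = float(n1 + n0 - 2)

    lfc = x1.mean(axis=1) - x0.mean(axis=1)
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss0 = ((x0 - x0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = (ss1 + ss0) / d_g

    if isinstance(prior, str):
        if prior != "auto":
            raise ValueError(f"prior must be an EBPrior or 'auto', got {prior!r}")
        prior = estimate_prior(s2, d_g)

    t_mod, df_total, p = _moderated_stats(lfc, s2, d_g, n1, n0, prior)
    fdr = bh_adjust(p)
    direction = np.where(
        fdr < fdr_cutoff, np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")), "none"
    )
    table = pd.DataFrame(
        {
            "lfc": lfc,
            "s2": s2,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "fdr": fdr,
            "direction": direction,
        },
        index=matrix.gene_ids,
    )
    return DiffExprTable(
        comparison=f"{stage}_vs_normal", table=table, prior=prior, fdr_cutoff=fdr_cutoff
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adjusted_(i) = min_{j >= i} m * p_(j) / j`` capped at 1, returned in
    the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted
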