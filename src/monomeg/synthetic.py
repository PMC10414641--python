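"""Seeded synthetic bulk-expression generator with planted change-pattern classes.

Emulates a four-group ordered cohort (normal, stage I, II, III) with
gene-wise heteroscedastic noise. Data are generated on the log2 scale as
group mean + Gaussian noise with a gene-specific variance drawn from a
scaled inverse-chi-square law (the conjugate prior behind empirical-Bayes
variance moderation), then mapped to a non-negative FPKM-like scale via
``2**x - 1`` floored at zero so the pipeline's ``log2(x + 1)`` preprocessing
inverts the mapping exactly.

Planted classes
---------------
With per-step shift ``delta = effect_size * sigma_g`` (each gene's own noise
standard deviation, so the planted signal-to-noise is uniform across genes)
and log-scale baseline ``m``:

==========  =================================
mono_inc    (m, m+d, m+2d, m+3d)
mono_dec    (m, m-d, m-2d, m-3d)
u_shape     (m+d, m, m, m+d)  — falls then rises
waved       (m, m+d, m, m+d)  — alternates
null        (m, m, m, m)
==========  =================================

The U-shaped and waved patterns are nuisance classes the monotone filter
must reject; they are fixed shapes since only their non-monotonicity matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from monomeg.matrix import STAGES, ExpressionMatrix


class ConfigError(ValueError):
    """Invalid simulation configuration."""


#: Canonical planted-class order; generation order is independent of dict order.
CLASSES: tuple[str, ...] = ("mono_inc", "mono_dec", "u_shape", "waved", "null")

#: Default gene counts per class (used by the pipeline-scale benchmark).
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "mono_inc": 50,
    "mono_dec": 100,
    "u_shape": 100,
    "waved": 100,
    "null": 4650,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    group_sizes default to the TCGA BRCA stage composition (105 normal,
    140 stage I, 480 stage II, 180 stage III). ``effect_size`` is the
    per-step mean shift in units of each gene's own noise standard
    deviation; ``noise_df`` and ``noise_scale`` are the degrees of freedom
    and scale of the inverse-chi-square law the gene variances are drawn
    from.
    """

    group_sizes: tuple[int, int, int, int] = (105, 140, 480, 180)
    n_genes_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    effect_size: float = 1.0
    noise_df: float = 4.0
    noise_scale: float = 1.0
    baseline_mean: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.group_sizes) != 4:
            raise ConfigError("group_sizes: exactly four group sizes required")
        for stage, n in zip(STAGES, self.group_sizes):
            if int(n) < 2:
                raise ConfigError(
                    f"group_sizes: group {stage!r} has {n} samples; "
                    "at least 2 required so each group's variance is estimable"
                )
        unknown = set(self.n_genes_per_class) - set(CLASSES)
        if unknown:
            raise ConfigError(f"n_genes_per_class: unknown classes {sorted(unknown)}")
        if any(int(n) < 0 for n in self.n_genes_per_class.values()):
            raise ConfigError("n_genes_per_class: counts must be non-negative")
        if self.total_genes < 1:
            raise ConfigError("n_genes_per_class: total gene count must be >= 1")
        if self.effect_size < 0:
            raise ConfigError("effect_size: must be non-negative")
        if self.noise_df <= 0:
            raise ConfigError("noise_df: must be positive")
        if self.noise_scale <= 0:
            raise ConfigError("noise_scale: must be positive")
        if int(self.seed) < 0:
            raise ConfigError("seed: must be non-negative")

    @property
    def total_genes(self) -> int:
        return sum(int(self.n_genes_per_class.get(c, 0)) for c in CLASSES)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort: one row per gene.

    ``table`` columns: ``pattern_class``, ``mean_normal``, ``mean_I``,
    ``mean_II``, ``mean_III`` (true log2-scale group means) and
    ``variance`` (true gene noise variance).
    """

    table: pd.DataFrame

    def genes_in_class(self, pattern_class: str) -> pd.Index:
        return self.table.index[self.table["pattern_class"] == pattern_class]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def _class_means(pattern_class: str, m: float, delta: float) -> np.ndarray:
    if pattern_class == "mono_inc":
        return m + delta * np.arange(4.0)
    if pattern_class == "mono_dec":
        return m - delta * np.arange(4.0)
    if pattern_class == "u_shape":
        return np.array([m + delta, m, m, m + delta])
    if pattern_class == "waved":
        return np.array([m, m + delta, m, m + delta])
    return np.full(4, float(m))


def generate(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a seeded FPKM-like cohort and its ground truth.

    Identical configuration (including seed) yields bit-identical output.
    Each gene draws from its own random stream, split deterministically by
    global gene index, so per-gene data do not depend on how many genes any
    other class requested.
    """
    config.validate()

    sample_ids: list[str] = []
    stage_of: dict[str, str] = {}
    for stage, n in zip(STAGES, config.group_sizes):
        for i in range(int(n)):
            sid = f"{stage}_{i:04d}"
            sample_ids.append(sid)
            stage_of[sid] = stage
    stage_index = np.concatenate(
        [np.full(int(n), k) for k, n in enumerate(config.group_sizes)]
    )

    gene_ids: list[str] = []
    classes: list[str] = []
    means = np.empty((config.total_genes, 4))
    variances = np.empty(config.total_genes)
    log2_values = np.empty((config.total_genes, len(sample_ids)))

    g = 0
    for pattern_class in CLASSES:
        n_class = int(config.n_genes_per_class.get(pattern_class, 0))
        for i in range(n_class):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(config.seed), spawn_key=(g,))
            )
            # sigma^2 ~ noise_df * noise_scale / chi2_{noise_df}
            sigma2 = config.noise_df * config.noise_scale / rng.chisquare(config.noise_df)
            delta = config.effect_size * np.sqrt(sigma2)
            mu = _class_means(pattern_class, config.baseline_mean, delta)
            noise = rng.normal(0.0, np.sqrt(sigma2), size=len(sample_ids))
            log2_values[g] = mu[stage_index.astype(int)] + noise
            gene_ids.append(f"{pattern_class}_{i:04d}")
            classes.append(pattern_class)
            means[g] = mu
            variances[g] = sigma2
            g += 1

    fpkm = np.maximum(np.exp2(log2_values) - 1.0, 0.0)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        stages=pd.Series(stage_of),
        scale_state="raw_fpkm",
    )
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {
                "pattern_class": classes,
                "mean_normal": means[:, 0],
                "mean_I": means[:, 1],
                "mean_II": means[:, 2],
                "mean_III": means[:, 3],
                "variance": variances,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    return matrix, truth
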