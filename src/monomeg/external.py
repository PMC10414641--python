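"""External-cohort validation: shared-gene VAE plus nearest-centroid staging.

An overall VAE is trained on the discovery cohort restricted to the genes it
shares with an external dataset (e.g. a microarray cohort quantified on a
different platform). Both cohorts are standardized within their own dataset
— cross-platform scale differences would otherwise dominate the latent
embedding — and every sample is encoded with the discovery-trained model.
External samples are then assigned the stage of the nearest per-stage latent
centroid and the misclassification rate is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from monomeg.matrix import STAGES, DataError, ExpressionMatrix
from monomeg.diffexpr import preprocess
from monomeg.vae import LatentSummary, TrainedVAE, VAEConfig, build, encode, train

logger = logging.getLogger(__name__)


@dataclass
class ClassificationReport:
    """Stage predictions for external samples plus the confusion matrix.

    ``assignments``: per-sample true and predicted stage. ``confusion``:
    4 x 4 (rows true, columns predicted, stage order normal/I/II/III).
    """

    assignments: pd.DataFrame
    confusion: pd.DataFrame
    n_misclassified: int
    error_rate: float
    n_common_genes: int

    def to_text(self) -> str:
        lines = [
            f"Common genes: {self.n_common_genes}",
            f"Misclassified: {self.n_misclassified} / {len(self.assignments)} "
            f"(error rate {100 * self.error_rate:.2f}%)",
            "Confusion matrix (rows true, columns predicted):",
            self.confusion.to_string(),
        ]
        return "\n".join(lines) + "\n"

    def confusion_to_tsv(self, path: str | Path) -> None:
        self.confusion.to_csv(path, sep="\t", index_label="true_stage")


def _restandardize(matrix: ExpressionMatrix, log_transform: bool) -> ExpressionMatrix:
    if matrix.scale_state == "raw_fpkm":
        return preprocess(matrix, log_transform=log_transform)
    values = matrix.values.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    keep = sds[:, 0] > 0
    standardized = (values[keep] - means[keep]) / sds[keep]
    return ExpressionMatrix(
        values=pd.DataFrame(
            standardized, index=matrix.gene_ids[keep], columns=matrix.sample_ids
        ),
        stages=matrix.stages.copy(),
        scale_state="standardized",
    )


def intersect_features(
    discovery: ExpressionMatrix,
    external: ExpressionMatrix,
    log_transform: bool = True,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both cohorts to their shared genes and standardize each within itself.

    Gene identifiers are matched case-insensitively (exact match after lower-
    casing); the returned matrices share an identical gene order. Genes that
    become constant within either cohort are dropped from both.
    """
    disc_lower = {g.lower(): g for g in discovery.gene_ids}
    ext_lower = {g.lower(): g for g in external.gene_ids}
    common = [k for k in disc_lower if k in ext_lower]
    if not common:
        raise DataError(
            f"no shared genes: discovery has {discovery.n_genes}, "
            f"external has {external.n_genes}"
        )
    disc = _restandardize(
        discovery.subset_genes([disc_lower[k] for k in common]), log_transform
    )
    ext = _restandardize(
        external.subset_genes([ext_lower[k] for k in common]), log_transform
    )
    # drop genes lost to zero variance in either cohort, preserving order
    disc_kept = {g.lower() for g in disc.gene_ids}
    ext_kept = {g.lower() for g in ext.gene_ids}
    surviving = [k for k in common if k in disc_kept and k in ext_kept]
    if not surviving:
        raise DataError("all shared genes are constant in one of the cohorts")
    disc = disc.subset_genes([disc_lower[k] for k in surviving])
    ext = ext.subset_genes([ext_lower[k] for k in surviving])
    return disc, ext


def fit_stage_centroids(latent: LatentSummary) -> dict[str, np.ndarray]:
    """Per-stage centroid = mean of per-sample posterior means within the stage."""
    centroids: dict[str, np.ndarray] = {}
    for stage in STAGES:
        mask = (latent.stages == stage).to_numpy()
        if not mask.any():
            raise DataError(f"stage {stage!r} absent; cannot fit its centroid")
        centroids[stage] = latent.mu[mask].mean(axis=0)
    return centroids


def classify(
    external_latent: LatentSummary, centroids: dict[str, np.ndarray], n_common_genes: int = 0
) -> ClassificationReport:
    """Assign each external sample the stage of its nearest latent centroid.

    Distances are Euclidean in latent space; exact ties are broken toward the
    less-advanced stage (earlier in normal < I < II < III) and logged.
    """
    centroid_matrix = np.stack([np.atleast_1d(centroids[s]) for s in STAGES])
    mu = external_latent.mu
    dists = np.linalg.norm(mu[:, None, :] - centroid_matrix[None, :, :], axis=2)
    predicted_idx = dists.argmin(axis=1)  # argmin takes the first = least-advanced on ties
    n_ties = int((np.sum(dists == dists.min(axis=1, keepdims=True), axis=1) > 1).sum())
    if n_ties:
        logger.info("%d sample(s) tied between centroids; broken toward the earlier stage", n_ties)
    predicted = np.array(STAGES)[predicted_idx]
    true = external_latent.stages.to_numpy()
    assignments = pd.DataFrame(
        {"true_stage": true, "predicted_stage": predicted},
        index=external_latent.table.index,
    )
    confusion = pd.DataFrame(
        0, index=pd.Index(STAGES, name="true"), columns=pd.Index(STAGES, name="predicted")
    )
    for t, p in zip(true, predicted):
        confusion.loc[t, p] += 1
    n_mis = int((true != predicted).sum())
    return ClassificationReport(
        assignments=assignments,
        confusion=confusion,
        n_misclassified=n_mis,
        error_rate=n_mis / len(true),
        n_common_genes=n_common_genes,
    )


def _logistic_classify(
    discovery_latent: LatentSummary, external_latent: LatentSummary, n_common_genes: int, seed: int
) -> ClassificationReport:
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(max_iter=1000, random_state=int(seed) % (2**31))
    clf.fit(discovery_latent.mu, discovery_latent.stages.to_numpy())
    predicted = clf.predict(external_latent.mu)
    true = external_latent.stages.to_numpy()
    assignments = pd.DataFrame(
        {"true_stage": true, "predicted_stage": predicted},
        index=external_latent.table.index,
    )
    confusion = pd.DataFrame(
        0, index=pd.Index(STAGES, name="true"), columns=pd.Index(STAGES, name="predicted")
    )
    for t, p in zip(true, predicted):
        confusion.loc[t, p] += 1
    n_mis = int((true != predicted).sum())
    return ClassificationReport(
        assignments=assignments,
        confusion=confusion,
        n_misclassified=n_mis,
        error_rate=n_mis / len(true),
        n_common_genes=n_common_genes,
    )


def run_external_validation(
    discovery: ExpressionMatrix,
    external: ExpressionMatrix,
    config: VAEConfig,
    log_transform: bool = True,
    classifier: str = "centroid",
) -> tuple[ClassificationReport, TrainedVAE]:
    """Full external check: intersect genes, train one overall VAE, classify.

    The overall model is trained on all discovery samples over the shared
    gene panel; both cohorts are encoded with it and external samples are
    staged by nearest centroid (or multinomial logistic regression on the
    latent features when ``classifier='logistic'``).
    """
    disc, ext = intersect_features(discovery, external, log_transform=log_transform)
    cfg = replace(config, input_dim=disc.n_genes)
    model = train(build(cfg), disc)
    # one shared model encodes both cohorts, so latent orientation cancels
    # out of centroid distances; no sign alignment is applied here
    disc_latent = encode(model, disc, align_sign=False)
    ext_latent = encode(model, ext, align_sign=False)
    if classifier == "logistic":
        report = _logistic_classify(disc_latent, ext_latent, disc.n_genes, cfg.seed)
    elif classifier == "centroid":
        centroids = fit_stage_centroids(disc_latent)
        report = classify(ext_latent, centroids, n_common_genes=disc.n_genes)
    else:
        raise ValueError(f"classifier must be 'centroid' or 'logistic', got {classifier!r}")
    return report, model
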