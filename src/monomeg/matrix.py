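"""Expression-matrix container and tab-delimited I/O.

The canonical in-memory object is a genes x samples :class:`pandas.DataFrame`
wrapped together with per-sample ordered stage labels and a scale-state tag
so downstream operations can assert what transformation has been applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered group labels: adjacent-normal tissue then pathologic stages I-III.
STAGES: tuple[str, ...] = ("normal", "I", "II", "III")

SCALE_STATES = ("raw_fpkm", "log2p1", "standardized")

# Metadata dialects seen in the wild mapped to canonical tokens. Stage IV is
# deliberately absent: the four-group design excludes it (see read_expression).
_STAGE_ALIASES = {
    "normal": "normal",
    "n": "normal",
    "0": "normal",
    "control": "normal",
    "para-carcinoma": "normal",
    "adjacent normal": "normal",
    "i": "I",
    "1": "I",
    "stage i": "I",
    "stage 1": "I",
    "ii": "II",
    "2": "II",
    "stage ii": "II",
    "stage 2": "II",
    "iii": "III",
    "3": "III",
    "stage iii": "III",
    "stage 3": "III",
}

_STAGE_IV_TOKENS = {"iv", "4", "stage iv", "stage 4"}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def normalize_stage_label(raw: str) -> str | None:
    """Map a free-text stage label to a canonical token.

    Returns ``None`` for stage-IV labels (excluded by design) and raises
    :class:`DataError` for labels that cannot be interpreted at all.
    """
    token = str(raw).strip().lower()
    if token in _STAGE_IV_TOKENS:
        return None
    if token in _STAGE_ALIASES:
        return _STAGE_ALIASES[token]
    raise DataError(f"unrecognized stage label: {raw!r}")


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with per-sample stage labels.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene identifiers, columns are sample
        identifiers.
    stages
        Series indexed like ``values.columns`` with entries from
        :data:`STAGES`.
    scale_state
        One of ``raw_fpkm`` (non-negative), ``log2p1`` or ``standardized``
        (each gene row mean 0, variance 1).
    """

    values: pd.DataFrame
    stages: pd.Series
    scale_state: str = "raw_fpkm"

    def __post_init__(self) -> None:
        if self.scale_state not in SCALE_STATES:
            raise DataError(f"unknown scale_state {self.scale_state!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene identifiers: {dupes[:5]}")
        self.stages = self.stages.reindex(self.values.columns)
        if self.stages.isna().any():
            missing = self.stages.index[self.stages.isna()].tolist()
            raise DataError(f"samples without a stage label: {missing[:5]}")
        bad = sorted(set(self.stages) - set(STAGES))
        if bad:
            raise DataError(f"stage labels outside {STAGES}: {bad}")
        if self.values.isna().any().any():
            raise DataError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_sizes(self) -> dict[str, int]:
        counts = self.stages.value_counts()
        return {s: int(counts.get(s, 0)) for s in STAGES}

    def samples_in_stage(self, stage: str) -> pd.Index:
        if stage not in STAGES:
            raise DataError(f"unknown stage {stage!r}")
        return self.stages.index[self.stages == stage]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = pd.Index(gene_ids)
        missing = gene_ids.difference(self.values.index)
        if len(missing):
            raise DataError(f"{len(missing)} requested genes absent from matrix")
        return replace(self, values=self.values.loc[gene_ids])

    def subset_stage(self, stage: str) -> "ExpressionMatrix":
        cols = self.samples_in_stage(stage)
        return replace(self, values=self.values[cols], stages=self.stages[cols])

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    def metadata_to_tsv(self, path: str | Path) -> None:
        meta = pd.DataFrame({"sample_id": self.stages.index, "stage": self.stages.values})
        meta.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Parse a tab-delimited genes x samples matrix plus a sample-metadata table.

    The metadata table needs columns ``sample_id`` and ``stage``. Samples
    missing from the metadata are dropped with a warning; stage-IV samples
    are excluded with a warning because the pipeline's design compares the
    four ordered groups normal/I/II/III only.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene identifiers in {path}: {dupes[:5]}")
    non_numeric = [c for c in values.columns if not np.issubdtype(values[c].dtype, np.number)]
    if non_numeric:
        raise DataError(f"non-numeric cells in columns {non_numeric[:5]} of {path}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "stage"):
        if col not in meta.columns:
            raise DataError(f"metadata {metadata_path} lacks required column {col!r}")
    meta = meta.set_index("sample_id")

    keep: list[str] = []
    stages: dict[str, str] = {}
    for sample in values.columns:
        if sample not in meta.index:
            logger.warning("sample %s has no metadata row; dropped", sample)
            continue
        canonical = normalize_stage_label(meta.loc[sample, "stage"])
        if canonical is None:
            logger.warning(
                "sample %s is stage IV and was excluded: the pipeline's "
                "four-group design covers normal/I/II/III only",
                sample,
            )
            continue
        keep.append(sample)
        stages[sample] = canonical
    if not keep:
        raise DataError("no samples with usable stage labels")
    values = values[keep].astype(float)
    return ExpressionMatrix(values=values, stages=pd.Series(stages), scale_state="raw_fpkm")
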