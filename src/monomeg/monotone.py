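"""Extraction of strictly monotone gene sets from three stage-vs-normal screens.

A gene is monotonically decreasing when it is a significant under-expressed
DEG in all three comparisons (I, II, III vs normal) and its log-fold-changes
are strictly ordered LFC_I > LFC_II > LFC_III; monotonically increasing is
the mirror image (all up, LFC_I < LFC_II < LFC_III). The intersection plus
strict ordering discards U-shaped and waved nuisance patterns. Ties violate
the strict inequalities and are excluded; the audit trail records every
candidate's values and the first criterion that excluded it so near-misses
are visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from monomeg.diffexpr import DiffExprTable
from monomeg.matrix import DataError


@dataclass
class MonotoneGeneSets:
    """Decreasing and increasing monotone gene sets plus a per-gene audit table.

    ``audit`` has one row per candidate gene with the three (lfc, fdr) pairs,
    the assigned ``pattern`` ({mono_dec, mono_inc, other, not_deg}) and a
    human-readable ``reason`` for exclusion (empty for selected genes).
    """

    decreasing: set[str]
    increasing: set[str]
    audit: pd.DataFrame

    def write(self, out_dir: str | Path, prefix: str = "monotone") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, genes in (("decreasing", self.decreasing), ("increasing", self.increasing)):
            (out_dir / f"{prefix}_{name}.txt").write_text(
                "\n".join(sorted(genes)) + ("\n" if genes else "")
            )
        self.audit.to_csv(out_dir / f"{prefix}_audit.tsv", sep="\t", index_label="gene_id")


def pattern_classify(
    lfc_triple, fdr_triple, cutoff: float
) -> tuple[str, str]:
    """Classify one gene's (LFC, FDR) triples; returns (pattern, reason).

    ``not_deg`` if any comparison misses the FDR cutoff or the LFC signs
    disagree across comparisons; ``mono_dec``/``mono_inc`` per the strict
    ordering predicates; ``other`` for consistently-signed DEGs whose
    ordering fails (U-shaped/waved-like profiles, including ties).
    """
    lfc = [float(v) for v in lfc_triple]
    fdr = [float(v) for v in fdr_triple]
    not_sig = [i for i, q in enumerate(fdr) if q >= cutoff]
    if not_sig:
        comps = ", ".join("I II III".split()[i] for i in not_sig)
        return "not_deg", f"fdr >= {cutoff} in comparison(s) {comps}"
    all_down = all(v < 0 for v in lfc)
    all_up = all(v > 0 for v in lfc)
    if not (all_down or all_up):
        return "not_deg", "lfc signs disagree across comparisons"
    if all_down:
        if lfc[0] > lfc[1] > lfc[2]:
            return "mono_dec", ""
        return "other", "strict ordering lfc_I > lfc_II > lfc_III fails"
    if lfc[0] < lfc[1] < lfc[2]:
        return "mono_inc", ""
    return "other", "strict ordering lfc_I < lfc_II < lfc_III fails"


def select_monotone(
    tables: tuple[DiffExprTable, DiffExprTable, DiffExprTable],
    fdr_cutoff: float = 0.01,
) -> MonotoneGeneSets:
    """Apply the intersection + strict-LFC-ordering restriction to three screens.

    ``tables`` must cover the comparisons I/II/III vs normal (any order) on a
    shared gene universe.
    """
    by_comp = {t.comparison: t for t in tables}
    expected = {"I_vs_normal", "II_vs_normal", "III_vs_normal"}
    if set(by_comp) != expected:
        raise DataError(f"need comparisons {sorted(expected)}, got {sorted(by_comp)}")
    t1, t2, t3 = (by_comp[c] for c in ("I_vs_normal", "II_vs_normal", "III_vs_normal"))

    universe = t1.gene_ids
    for t in (t2, t3):
        diff = universe.symmetric_difference(t.gene_ids)
        if len(diff):
            raise DataError(
                f"gene universes differ between comparisons ({len(diff)} mismatched ids)"
            )

    lfc = np.column_stack(
        [t.table["lfc"].reindex(universe).to_numpy() for t in (t1, t2, t3)]
    )
    fdr = np.column_stack(
        [t.table["fdr"].reindex(universe).to_numpy() for t in (t1, t2, t3)]
    )

    patterns: list[str] = []
    reasons: list[str] = []
    for g in range(len(universe)):
        pattern, reason = pattern_classify(lfc[g], fdr[g], fdr_cutoff)
        patterns.append(pattern)
        reasons.append(reason)

    patterns_arr = np.array(patterns)
    audit = pd.DataFrame(
        {
            "lfc_I": lfc[:, 0],
            "lfc_II": lfc[:, 1],
            "lfc_III": lfc[:, 2],
            "fdr_I": fdr[:, 0],
            "fdr_II": fdr[:, 1],
            "fdr_III": fdr[:, 2],
            "pattern": patterns_arr,
            "reason": reasons,
        },
        index=universe,
    )
    return MonotoneGeneSets(
        decreasing=set(universe[patterns_arr == "mono_dec"]),
        increasing=set(universe[patterns_arr == "mono_inc"]),
        audit=audit,
    )
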