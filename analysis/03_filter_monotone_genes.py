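#!/usr/bin/env python
"""Intersect the three DEG screens and keep strictly monotone LFC orderings.

Reads results/diffexpr/, applies the decreasing (LFC_I > LFC_II > LFC_III,
all significant and negative) and increasing restrictions, writes the gene
lists and audit table to results/monotone/, and scores them against the
planted truth.
"""

from pathlib import Path

import pandas as pd

from monomeg.diffexpr import DiffExprTable, EBPrior
from monomeg.monotone import select_monotone
from monomeg.synthetic import SyntheticTruth

IN = Path("results/diffexpr")
TRUTH = Path("results/cohort/truth.tsv")
OUT = Path("results/monotone")
FDR_CUTOFF = 0.01


def main() -> None:
    tables = []
    for comp in ("I_vs_normal", "II_vs_normal", "III_vs_normal"):
        frame = pd.read_csv(IN / f"diffexpr_{comp}.tsv", sep="\t", index_col=0)
        tables.append(DiffExprTable(comparison=comp, table=frame,
                                    prior=EBPrior(1.0, 1.0), fdr_cutoff=FDR_CUTOFF))
    sets = select_monotone(tuple(tables), fdr_cutoff=FDR_CUTOFF)
    sets.write(OUT)
    print(f"monotone decreasing: {len(sets.decreasing)} genes; "
          f"increasing: {len(sets.increasing)} genes")

    truth = SyntheticTruth(table=pd.read_csv(TRUTH, sep="\t", index_col=0))
    for direction, selected, cls in (
        ("decreasing", sets.decreasing, "mono_dec"),
        ("increasing", sets.increasing, "mono_inc"),
    ):
        planted = set(truth.genes_in_class(cls))
        sens = len(selected & planted) / len(planted)
        fp = len(selected - planted)
        print(f"  {direction}: sensitivity {sens:.3f} ({len(selected & planted)}/"
              f"{len(planted)} planted), {fp} false selections")
    nuisance = set(truth.genes_in_class("u_shape")) | set(truth.genes_in_class("waved"))
    leaked = (sets.decreasing | sets.increasing) & nuisance
    print(f"  U-shaped/waved patterns selected: {len(leaked)}")


if __name__ == "__main__":
    main()
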