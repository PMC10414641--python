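#!/usr/bin/env python
"""Screen each stage against normal with empirical-Bayes moderated t-tests.

Reads results/cohort/, applies log2(x+1) + per-gene standardization, fits
the variance prior per comparison, and writes the three statistics tables
plus the standardized matrix to results/diffexpr/.
"""

from pathlib import Path

from monomeg.diffexpr import fit_comparison, preprocess
from monomeg.matrix import read_expression

IN = Path("results/cohort")
OUT = Path("results/diffexpr")
FDR_CUTOFF = 0.01


def main() -> None:
    matrix = read_expression(IN / "expression.tsv", IN / "metadata.tsv")
    standardized = preprocess(matrix, log_transform=True)
    OUT.mkdir(parents=True, exist_ok=True)
    standardized.to_tsv(OUT / "standardized_matrix.tsv")
    for stage in ("I", "II", "III"):
        table = fit_comparison(standardized, stage, prior="auto", fdr_cutoff=FDR_CUTOFF)
        table.to_tsv(OUT / f"diffexpr_{table.comparison}.tsv")
        down = int((table.table["direction"] == "down").sum())
        up = int((table.table["direction"] == "up").sum())
        print(f"{table.comparison}: prior d0={table.prior.d0:.1f}, "
              f"s0^2={table.prior.s0_sq:.3f}; {down} down- and {up} up-regulated "
              f"DEGs at FDR < {FDR_CUTOFF}")


if __name__ == "__main__":
    main()
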