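#!/usr/bin/env python
"""Znet differential expression for the three pairwise comparisons.

For each substrate contrast: detection filter, Z/R ratio populations,
normalization, Znet merge and tier assignment. Writes one result TSV per
comparison under scratch/ (full per-protein tables) and a compact summary
of significant counts under results/.

Run after 01_simulate.py:  python analysis/03_differential.py
"""

from pathlib import Path

import pandas as pd

from ticnet import (
    Comparison,
    classify_tiers,
    compute_ratio_populations,
    filter_detected,
    merge_znet,
    nd_proteins,
    system_sn,
)
from ticnet.io import read_tic_table, write_result

COMPARISONS = [
    Comparison("GB", "R80"),
    Comparison("GB", "FFA"),
    Comparison("FFA", "R80"),
]
RESULTS = Path("results")
SCRATCH = Path("scratch/results")


def main() -> None:
    table = read_tic_table("scratch/data/tic.tsv")
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for comp in COMPARISONS:
        filtered = filter_detected(table, comp)
        pops = compute_ratio_populations(filtered, comp)
        result = classify_tiers(merge_znet(pops))
        result.nd_proteins = nd_proteins(table, comp)
        result.system_sn = system_sn(pops)
        write_result(result, SCRATCH / f"result_{comp.label}.tsv")
        sig = result.frame["significant"]
        up = int((sig & (result.frame["znet"] > 0)).sum())
        down = int((sig & (result.frame["znet"] < 0)).sum())
        rows.append({
            "comparison": comp.label,
            "n_compared": len(pops),
            "n_nd": len(result.nd_proteins),
            "system_sn": round(result.system_sn, 2),
            "up_outer10": up,
            "down_outer10": down,
        })
        print(f"{comp.label}: {len(pops)} compared, system S/N "
              f"{result.system_sn:.2f}, |Znet|>1.65: {up} up / {down} down")
    pd.DataFrame(rows).to_csv(RESULTS / "differential_summary.tsv", sep="\t",
                              index=False)
    print(f"wrote {RESULTS}/differential_summary.tsv")


if __name__ == "__main__":
    main()
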