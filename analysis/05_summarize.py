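#!/usr/bin/env python
"""Functional summaries: COG cross-tab and three-way overlap regions.

Counts significantly up/down proteins (|Znet| > 1.65) per COG class and
comparison, and partitions the significant proteins of the three contrasts
into the seven Venn regions. Writes results/cog_crosstab.tsv and
results/overlap_summary.tsv.

Run after 03_differential.py:  python analysis/05_summarize.py
"""

from pathlib import Path

import pandas as pd

from ticnet import Comparison, cog_crosstab, overlap_counts
from ticnet.diffstats import ComparisonResult
from ticnet.io import read_annotation

COMPARISONS = [
    Comparison("GB", "R80"),
    Comparison("GB", "FFA"),
    Comparison("FFA", "R80"),
]
RESULTS = Path("results")


def load_result(comp: Comparison) -> ComparisonResult:
    frame = pd.read_csv(
        f"scratch/results/result_{comp.label}.tsv",
        sep="\t", comment="#", index_col="protein_id",
    )
    return ComparisonResult(frame[frame["tier"] != "ND"], comp)


def main() -> None:
    results = [load_result(c) for c in COMPARISONS]
    ann = read_annotation("scratch/data/annotation.tsv")
    RESULTS.mkdir(exist_ok=True)

    tab = cog_crosstab(results, ann)
    tab.to_csv(RESULTS / "cog_crosstab.tsv", sep="\t")
    totals = tab.loc["Total"]
    for comp in COMPARISONS:
        print(f"{comp.label}: {totals[(comp.label, 'up')]} up / "
              f"{totals[(comp.label, 'down')]} down (COG-letter counts)")

    overlap = overlap_counts(results)
    overlap.to_csv(RESULTS / "overlap_summary.tsv", sep="\t")
    print(f"overlap: {overlap['n'].sum()} significant proteins across "
          f"{len(overlap)} regions; triple intersection "
          f"{overlap.loc['&'.join(c.label for c in COMPARISONS), 'n']}")
    print(f"wrote {RESULTS}/cog_crosstab.tsv and {RESULTS}/overlap_summary.tsv")


if __name__ == "__main__":
    main()
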