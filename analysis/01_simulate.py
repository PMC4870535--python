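#!/usr/bin/env python
"""Generate the synthetic study: three substrate conditions, two replicates.

Emulates a three-condition label-free proteomics experiment (conditions GB,
R80, FFA, two biological replicates each, ~1200 proteins with 6% dropout)
with known differential-expression truth, plus a synthetic annotation map.
Large tables go to scratch/data/ (regenerable); this script is the single
source of the inputs used by the later analysis steps.

Run from the repository root:  python analysis/01_simulate.py
"""

from pathlib import Path

from ticnet import generate_annotation, generate_multistate_dataset, paperlike_config
from ticnet import io as tio

SEED = 42
DATA = Path("scratch/data")


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    config = paperlike_config(seed=SEED)
    table, truth = generate_multistate_dataset(config, states=("GB", "R80", "FFA"))
    tio.write_tic_table(table, DATA / "tic.tsv")
    tio.write_truth(truth, DATA / "truth.tsv")
    ann = generate_annotation(table.protein_ids, seed=SEED)
    tio.write_annotation(ann, DATA / "annotation.tsv")

    n_de = int((truth["label"] == "de").sum())
    print(f"simulated {len(table)} proteins x {len(table.values.columns)} samples "
          f"({n_de} truly differential somewhere) -> {DATA}/tic.tsv")
    print(f"annotation map for {len(ann)} proteins -> {DATA}/annotation.tsv")


if __name__ == "__main__":
    main()
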