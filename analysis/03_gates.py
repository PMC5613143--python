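#!/usr/bin/env python
"""Cross-tabulate knockout dosage calls against maturation classes.

Reads the two per-gene tables written by 02_dosage.py and prints the
3x3 gate table with the up-row fractions. Because knockout targets are
planted only in the destabilized and unchanged maturation classes, the
up row should concentrate in 'unchanged' with a minority 'destabilized'
— the gate pattern the knockout analysis is designed to expose.
"""

from pathlib import Path

import pandas as pd

from matdosage.gates import gate_crosstab

OUT = Path(__file__).resolve().parents[1] / "results" / "demo"


def main() -> None:
    ko = pd.read_csv(OUT / "dosage_ko.tsv", sep="\t", index_col=0)["call"]
    classes = pd.read_csv(OUT / "dosage_maturation.tsv", sep="\t",
                          index_col=0)["maturation_class"]
    gt = gate_crosstab(ko, classes)
    gt.table.to_csv(OUT / "gates.tsv", sep="\t")
    print(gt.table.to_string())
    n_up = int(gt.row_margins()["up"])
    print(f"\nup row (n={n_up}):")
    for cls, frac in gt.up_row_fractions.items():
        print(f"  {cls}: {int(gt.table.loc['up', cls])}/{n_up} = {frac:.2f}")


if __name__ == "__main__":
    main()
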