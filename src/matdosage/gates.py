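"""Maturation classes and the knockout-by-maturation gate table.

Genes are classified by their behavior across oocyte maturation from
the GV-vs-MII control comparison: *stabilized* (relative dosage rises at
least fc_min-fold with significance), *destabilized* (falls), otherwise
*unchanged*. Cross-tabulating these classes against the knockout dosage
calls shows which maturation class the knockout-deregulated genes come
from; the up row additionally reports its class fractions (the
"168/201"-style split).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

KO_CALLS = ("up", "down", "unchanged")
MATURATION_CLASSES = ("stabilized", "destabilized", "unchanged")


def classify_maturation(
    gv_vs_mii: pd.DataFrame,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    p_comparison: str = "inclusive",
    use_adjusted: bool = False,
) -> pd.Series:
    """Per-gene maturation class from a GV-vs-MII (control) comparison.

    ``gv_vs_mii`` is a moderated-t table whose log2FC is MII minus GV.
    The maturation contrast uses an inclusive p threshold by default
    (p <= p_max), unlike the knockout contrast's strict default.
    """
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    if not 0 < p_max <= 1:
        raise ValueError("p_max must be in (0, 1]")
    if p_comparison not in ("strict", "inclusive"):
        raise ValueError("p_comparison must be 'strict' or 'inclusive'")
    pcol = "q" if use_adjusted else "p"
    pvals = gv_vs_mii[pcol].to_numpy()
    sig = pvals < p_max if p_comparison == "strict" else pvals <= p_max
    thr = math.log2(fc_min)
    fc = gv_vs_mii["log2FC"].to_numpy()
    cls = np.where(
        sig & (fc >= thr),
        "stabilized",
        np.where(sig & (fc <= -thr), "destabilized", "unchanged"),
    )
    return pd.Series(cls, index=gv_vs_mii.index, name="maturation_class")


@dataclass
class GateTable:
    """3x3 contingency of knockout call (rows) vs maturation class (columns)."""

    table: pd.DataFrame
    up_row_fractions: pd.Series

    @property
    def n_genes(self) -> int:
        return int(self.table.to_numpy().sum())

    def row_margins(self) -> pd.Series:
        return self.table.sum(axis=1)

    def column_margins(self) -> pd.Series:
        return self.table.sum(axis=0)


def gate_crosstab(ko_calls: pd.Series, maturation_classes: pd.Series) -> GateTable:
    """Cross-tabulate knockout dosage calls against maturation classes.

    Both inputs must cover the same gene universe; the up row's
    fractions over maturation classes are reported alongside (e.g. the
    share of knockout-upregulated genes that are maturation-unchanged).
    """
    if not ko_calls.index.sort_values().equals(
        maturation_classes.index.sort_values()
    ):
        only_ko = ko_calls.index.difference(maturation_classes.index)
        only_mat = maturation_classes.index.difference(ko_calls.index)
        raise ValueError(
            "gene universes differ between calls and classes; "
            f"only in calls: {list(only_ko[:5])}, "
            f"only in classes: {list(only_mat[:5])}"
        )
    maturation_classes = maturation_classes.reindex(ko_calls.index)
    table = pd.crosstab(ko_calls, maturation_classes)
    table = table.reindex(index=KO_CALLS, columns=MATURATION_CLASSES, fill_value=0)
    table.index.name = "ko_call"
    table.columns.name = "maturation_class"
    up = table.loc["up"]
    total_up = int(up.sum())
    fractions = up / total_up if total_up else up.astype(float) * np.nan
    return GateTable(table=table, up_row_fractions=fractions.rename("fraction_of_up"))
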