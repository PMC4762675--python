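"""Collapse fitted trajectory groups into four clinical phenotypes.

Groups are placed on a grid of intercept level (low / intermediate / high,
split at 60 and 70 ml/min/1.73m^2) and average annual % eGFR change
(positive / mild negative / fast negative, split at 0 and -3 %/yr), and the
grid cells map to:

    (high, positive)        -> HIPT   high intercept, positive trajectory
    (intermediate, mild)    -> IIMNT  intermediate intercept, mild negative
    (low, fast)             -> LIFNT  low intercept, fast negative
    (high, fast)            -> HIFNT  high intercept, fast negative

The cut points are not universal constants; the defaults are the round
numbers that separate the canonical seven-group solution into these four
phenotypes, and both are configurable.  A combination outside the four
named cells maps to the nearest rule (grid distance, ties preferring
IIMNT) with an explicit warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PhenotypeRule", "PhenotypeLabel", "assign_phenotype", "map_all_groups"]

PHENOTYPES = ("HIPT", "IIMNT", "LIFNT", "HIFNT")

# grid coordinates (intercept level, % change level) of the named cells;
# levels: intercept low=0, intermediate=1, high=2; change positive=0,
# mild negative=1, fast negative=2
_RULE_CELLS = {
    "IIMNT": (1, 1),
    "HIPT": (2, 0),
    "LIFNT": (0, 2),
    "HIFNT": (2, 2),
}
_TIE_ORDER = ("IIMNT", "HIPT", "LIFNT", "HIFNT")


@dataclass(frozen=True)
class PhenotypeRule:
    intercept_cuts: tuple = (60.0, 70.0)  # low | intermediate | high
    pct_change_cuts: tuple = (0.0, -3.0)  # positive | mild | fast

    def __post_init__(self) -> None:
        if not self.intercept_cuts[0] < self.intercept_cuts[1]:
            raise ValueError("intercept_cuts must be strictly increasing")
        if not self.pct_change_cuts[0] > self.pct_change_cuts[1]:
            raise ValueError("pct_change_cuts must be strictly decreasing")

    def intercept_level(self, intercept: float) -> int:
        lo, hi = self.intercept_cuts
        return 0 if intercept < lo else (1 if intercept < hi else 2)

    def change_level(self, pct_change: float) -> int:
        pos, fast = self.pct_change_cuts
        return 0 if pct_change > pos else (1 if pct_change > fast else 2)


@dataclass(frozen=True)
class PhenotypeLabel:
    group_id: int
    label: str
    exact: bool  # False when resolved by nearest-rule fallback


def assign_phenotype(
    intercept: float,
    annual_pct_change: float,
    rule: PhenotypeRule = PhenotypeRule(),
    group_id: int = 0,
) -> PhenotypeLabel:
    """Deterministic table lookup from (intercept, annual % change)."""
    if not (np.isfinite(intercept) and np.isfinite(annual_pct_change)):
        raise ValueError("intercept and annual % change must be finite")
    cell = (rule.intercept_level(intercept), rule.change_level(annual_pct_change))
    for label, rule_cell in _RULE_CELLS.items():
        if cell == rule_cell:
            return PhenotypeLabel(group_id, label, exact=True)
    dist = {
        label: abs(cell[0] - c[0]) + abs(cell[1] - c[1])
        for label, c in _RULE_CELLS.items()
    }
    best = min(_TIE_ORDER, key=lambda lb: (dist[lb], _TIE_ORDER.index(lb)))
    warnings.warn(
        f"(intercept={intercept:.2f}, pct_change={annual_pct_change:.2f}) falls "
        f"outside the four named phenotype cells; using nearest rule {best}",
        stacklevel=2,
    )
    return PhenotypeLabel(group_id, best, exact=False)


def map_all_groups(
    summaries: pd.DataFrame,
    memberships: pd.DataFrame,
    rule: PhenotypeRule = PhenotypeRule(),
):
    """Label every fitted group and propagate labels to patients.

    ``summaries`` is the per-group table from the trajectory stage (columns
    group, intercept, avg_annual_pct_change); ``memberships`` holds
    patient_id and hard-assigned group.  Returns (labels, patient table):
    per-group labels with their inputs, and per-patient phenotype rows whose
    phenotype shares sum to 1.
    """
    labels = []
    for row in summaries.itertuples():
        lab = assign_phenotype(
            row.intercept, row.avg_annual_pct_change, rule, group_id=int(row.group)
        )
        labels.append(
            {
                "group": lab.group_id,
                "label": lab.label,
                "intercept": row.intercept,
                "pct_change": row.avg_annual_pct_change,
                "exact_rule": lab.exact,
            }
        )
    label_df = pd.DataFrame(labels)
    mapping = label_df.set_index("group")["label"]
    patient = memberships[["patient_id", "group"]].copy()
    patient["phenotype"] = patient["group"].map(mapping)
    shares = patient["phenotype"].value_counts(normalize=True)
    assert abs(shares.sum() - 1.0) < 1e-9
    return label_df, patient
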