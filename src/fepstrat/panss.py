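"""PANSS instrument constants, the item-score container, and the RSWG remission rule.

The Positive and Negative Syndrome Scale (PANSS) rates 30 symptom items
(7 positive, 7 negative, 16 general psychopathology), each on a 1-7 severity
scale.  Symptomatic remission follows the Remission in Schizophrenia Working
Group (RSWG) consensus: a score of <= 3 simultaneously on the eight items
P1, P2, P3, N1, N4, N6, G5 and G9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

POSITIVE_ITEMS: tuple[str, ...] = tuple(f"P{i}" for i in range(1, 8))
NEGATIVE_ITEMS: tuple[str, ...] = tuple(f"N{i}" for i in range(1, 8))
GENERAL_ITEMS: tuple[str, ...] = tuple(f"G{i}" for i in range(1, 17))
ITEM_NAMES: tuple[str, ...] = POSITIVE_ITEMS + NEGATIVE_ITEMS + GENERAL_ITEMS

SUBSCALES: dict[str, tuple[str, ...]] = {
    "PPANSS": POSITIVE_ITEMS,
    "NPANSS": NEGATIVE_ITEMS,
    "GPANSS": GENERAL_ITEMS,
}

SCORE_MIN = 1
SCORE_MAX = 7


@dataclass(frozen=True)
class RemissionCriterion:
    """RSWG symptomatic-remission criterion: all listed items at or below `cutoff`."""

    items: tuple[str, ...] = ("P1", "P2", "P3", "N1", "N4", "N6", "G5", "G9")
    cutoff: int = 3

    def __post_init__(self) -> None:
        if len(self.items) != 8:
            raise ValueError(f"criterion requires exactly 8 items, got {len(self.items)}")


RSWG_CRITERION = RemissionCriterion()


def classify_remission(
    followup_items: pd.DataFrame,
    criterion: RemissionCriterion = RSWG_CRITERION,
) -> pd.Series:
    """Apply the remission criterion to follow-up item scores.

    Parameters
    ----------
    followup_items
        Patients x items table of follow-up PANSS scores; must contain every
        criterion item as a column, values in [1, 7].
    criterion
        The remission rule (items and cutoff).

    Returns
    -------
    Boolean Series indexed by patient: True = remitter.
    """
    missing = [it for it in criterion.items if it not in followup_items.columns]
    if missing:
        raise ValueError(f"missing criterion items: {missing}")
    sub = followup_items[list(criterion.items)]
    vals = sub.to_numpy()
    if np.isnan(vals.astype(float)).any():
        raise ValueError("criterion items contain missing values")
    if (vals < SCORE_MIN).any() or (vals > SCORE_MAX).any():
        raise ValueError("criterion item scores outside the 1-7 range")
    return pd.Series((vals <= criterion.cutoff).all(axis=1), index=followup_items.index, name="remission")


@dataclass
class ItemScoreMatrix:
    """Patients x PANSS-items score matrix (integer scores in [1, 7]).

    `values` is a DataFrame with one patient per row and one item per column.
    Arbitrary item subsets are allowed (toy problems, per-branch refits); the
    full instrument has the 30 columns of :data:`ITEM_NAMES`.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size:
            farr = arr.astype(float)
            if np.isnan(farr).any():
                raise ValueError("item scores contain missing values")
            if (farr < SCORE_MIN).any() or (farr > SCORE_MAX).any():
                raise ValueError("item scores outside the 1-7 range")
            if not np.allclose(farr, np.round(farr)):
                raise ValueError("item scores must be integers")

    @property
    def item_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.index

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subscale_totals(self) -> pd.DataFrame:
        """Per-patient PPANSS/NPANSS/GPANSS sums and the PANSS total (full instrument only)."""
        out = {}
        for name, items in SUBSCALES.items():
            present = [it for it in items if it in self.values.columns]
            out[name] = self.values[present].sum(axis=1)
        totals = pd.DataFrame(out)
        totals["PANSS_total"] = totals.sum(axis=1)
        return totals
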