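"""Serum analyte panel vocabulary and container.

The panel covers 43 interleukins, chemokines and inflammation biomarkers
measured by multiplexed immunoassay.  Each analyte has a lower limit of
detection (LLOD, blank signal plus 2 SD, supplied per analyte as an input);
values below it are censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Analytes that survive the detectability screen in a typical serum panel
# (concentrations comfortably above the LLOD in >= 90% of samples).
DETECTABLE_ANALYTES: tuple[str, ...] = (
    "CCL2", "CCL3", "CCL4", "CCL11", "CCL13", "CCL17", "CCL19", "CCL20",
    "CCL22", "CCL26", "CCL27", "CX3CL1", "CXCL10", "CXCL11", "CXCL12",
    "IL-6", "IL-7", "IL-8", "IL-10", "IL-12p40", "IL-15", "IL-16", "IL-17",
    "IL-18", "IL-21", "IL-23", "IL-27", "IFN-g", "TNF-a", "TNF-b", "VEGF",
    "sICAM-1", "sVCAM-1", "CRP", "SAA",
)

# Low-abundance cytokines that commonly fall below the detection limit.
LOW_ABUNDANCE_ANALYTES: tuple[str, ...] = (
    "IL-1a", "IL-1b", "IL-2", "IL-4", "IL-5", "IL-12p70", "IL-13", "GM-CSF",
)

ANALYTE_NAMES: tuple[str, ...] = DETECTABLE_ANALYTES + LOW_ABUNDANCE_ANALYTES


@dataclass
class AnalytePanel:
    """Patients x analytes raw concentrations with per-analyte LLOD.

    Attributes
    ----------
    concentrations
        Raw-scale (e.g. pg/mL) concentrations, one patient per row.
    llod
        Per-analyte lower limit of detection on the raw scale.
    below_llod
        Boolean mask, True where the measured value is below the analyte's
        LLOD (censored).  Derived from `concentrations` and `llod` when not
        supplied.
    """

    concentrations: pd.DataFrame
    llod: pd.Series
    below_llod: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        cols = list(self.concentrations.columns)
        missing = [a for a in cols if a not in self.llod.index]
        if missing:
            raise ValueError(f"llod missing for analytes: {missing}")
        self.llod = self.llod.loc[cols].astype(float)
        if self.below_llod is None:
            self.below_llod = self.concentrations.lt(self.llod, axis=1)
        else:
            self.below_llod = self.below_llod[cols].astype(bool)
            expected = self.concentrations.lt(self.llod, axis=1)
            if self.concentrations.size and not self.below_llod.equals(expected):
                raise ValueError("below_llod mask inconsistent with concentrations and llod")

    @property
    def analyte_names(self) -> list[str]:
        return list(self.concentrations.columns)

    @property
    def patient_ids(self) -> pd.Index:
        return self.concentrations.index

    def censored_fraction(self) -> pd.Series:
        """Fraction of samples below the LLOD, per analyte."""
        if len(self.concentrations) == 0:
            return pd.Series(0.0, index=self.concentrations.columns)
        return self.below_llod.mean(axis=0)


def suggest_analyte_name(name: str) -> str | None:
    """Closest canonical analyte name for a misspelled column, or None."""
    import difflib

    # common no-hyphen variants: IL15 -> IL-15, TNFa -> TNF-a
    compact = {a.replace("-", "").lower(): a for a in ANALYTE_NAMES}
    key = name.replace("-", "").replace("_", "").lower()
    if key in compact:
        return compact[key]
    close = difflib.get_close_matches(name, ANALYTE_NAMES, n=1, cutoff=0.6)
    return close[0] if close else None
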