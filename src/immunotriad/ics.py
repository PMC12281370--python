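"""Intracellular cytokine staining (ICS) positivity and Th1 polyfunctionality.

Flow-cytometric ICS measures, per CD4+ T cell, which of IFN-gamma, TNF-alpha
and IL-2 are produced after peptide stimulation.  The 7 non-null Boolean
cytokine combinations partition the cytokine-positive compartment; a patient's
Th1 immunotype is the highest-order combination that becomes positive after
vaccination: triple-positive (all three cytokines), double-positive, or
single-functional.

Frequencies are percentages of CD4+ T cells, already gated and
background-subtracted against the unstimulated condition unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "COMBOS",
    "CytokineCombo",
    "IcsPanel",
    "subtract_background",
    "ics_positive",
    "immunotype",
    "combo_composition",
    "absolute_count",
    "call_table",
]

#: the 7 non-null (IFNg, TNFa, IL-2) Boolean combinations, highest order first
COMBOS: tuple[tuple[bool, bool, bool], ...] = (
    (True, True, True),
    (True, True, False),
    (True, False, True),
    (False, True, True),
    (True, False, False),
    (False, True, False),
    (False, False, True),
)

#: frequency threshold (percent of CD4+ T cells) for a positive combination
MIN_FREQ_PCT = 0.05

IMMUNOTYPE_ORDER = ("none", "singleF", "polyF_double", "polyF_triple")


@dataclass(frozen=True)
class CytokineCombo:
    ifng: bool
    tnfa: bool
    il2: bool
    freq_pct: float

    def __post_init__(self) -> None:
        if not (self.ifng or self.tnfa or self.il2):
            raise ValueError("a cytokine combination must have at least one cytokine")
        if self.freq_pct < 0:
            raise ValueError("freq_pct must be non-negative")

    @property
    def order(self) -> int:
        """Number of cytokines co-produced (1, 2 or 3)."""
        return int(self.ifng) + int(self.tnfa) + int(self.il2)

    @property
    def key(self) -> tuple[bool, bool, bool]:
        return (self.ifng, self.tnfa, self.il2)


@dataclass(frozen=True)
class IcsPanel:
    """Per-patient combo frequencies at baseline and >=1 post timepoint.

    ``baseline`` and each entry of ``post`` map a combination key
    (ifng, tnfa, il2) to its background-subtracted frequency (percent of
    CD4+ T cells).  Missing combinations are treated as 0.
    """

    patient_id: str
    baseline: Mapping[tuple[bool, bool, bool], float]
    post: tuple[Mapping[tuple[bool, bool, bool], float], ...]
    cd4_count_per_mm3: float | None = None

    def __post_init__(self) -> None:
        if len(self.post) == 0:
            raise ValueError("IcsPanel requires at least one post-vaccination timepoint")
        for tp in (self.baseline, *self.post):
            for key, v in tp.items():
                if key not in COMBOS:
                    raise ValueError(f"unknown cytokine combination {key}")
                if v < 0:
                    raise ValueError("background-subtracted frequencies must be >= 0")


def subtract_background(stim_pct: float, unstim_pct: float) -> float:
    """Stimulated minus unstimulated-control frequency, floored at 0."""
    if stim_pct < 0 or unstim_pct < 0:
        raise ValueError("frequencies must be non-negative")
    return max(0.0, stim_pct - unstim_pct)


def ics_positive(post_pct: float, baseline_pct: float) -> bool:
    """Positivity rule for one combination.

    True iff the post-vaccination frequency is at least a 2-fold increase
    over baseline AND strictly exceeds 0.05% of CD4+ T cells.  A baseline of
    exactly zero satisfies the fold clause; the 0.05% floor still binds.
    """
    if post_pct < 0 or baseline_pct < 0:
        raise ValueError("frequencies must be non-negative")
    return post_pct >= 2.0 * baseline_pct and post_pct > MIN_FREQ_PCT


def immunotype(panel: IcsPanel) -> str:
    """Highest-order positive combination across post timepoints.

    Returns ``polyF_triple`` if the IFNg+TNFa+IL-2+ combination is positive
    at any post timepoint, else ``polyF_double`` if any two-cytokine
    combination is, else ``singleF`` if any single-cytokine combination is,
    else ``none``.
    """
    best = 0
    for tp in panel.post:
        for key in COMBOS:
            post_pct = float(tp.get(key, 0.0))
            base_pct = float(panel.baseline.get(key, 0.0))
            if ics_positive(post_pct, base_pct):
                best = max(best, sum(key))
    return IMMUNOTYPE_ORDER[best]


def combo_composition(freqs: Mapping[tuple[bool, bool, bool], float]) -> tuple[dict, float]:
    """Per-combination frequencies plus their total.

    The 7 combinations partition the cytokine-positive compartment, so the
    total equals the any-cytokine-positive frequency by construction.
    """
    comp = {key: float(freqs.get(key, 0.0)) for key in COMBOS}
    for v in comp.values():
        if v < 0:
            raise ValueError("frequencies must be non-negative")
    return comp, sum(comp.values())


def absolute_count(freq_pct: float, cd4_per_mm3: float | None) -> float:
    """Absolute cells per mm3 of blood from a percent-of-CD4 frequency.

    Returns ``freq_pct / 100 * cd4_per_mm3``; a missing CD4 count is an
    error (the count is undefined, not zero).
    """
    if cd4_per_mm3 is None:
        raise ValueError("absolute_count requires a CD4 count per mm3")
    if freq_pct < 0 or cd4_per_mm3 < 0:
        raise ValueError("inputs must be non-negative")
    return freq_pct / 100.0 * cd4_per_mm3


# ---------------------------------------------------------------------------
# table-level interface

def panels_from_table(table: pd.DataFrame, baseline_label: str = "baseline") -> list[IcsPanel]:
    """Build panels from a long table with columns
    ``patient_id, timepoint, condition, ifng, tnfa, il2, freq_pct``
    (+ optional ``cd4_count_per_mm3``); ``condition`` in
    {stimulated, unstimulated}.  Stimulated frequencies are background-
    subtracted against the matching unstimulated row before calling.
    """
    required = {"patient_id", "timepoint", "condition", "ifng", "tnfa", "il2", "freq_pct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ICS table missing columns: {sorted(missing)}")
    panels = []
    for pid, grp in table.groupby("patient_id", sort=False):
        per_tp: dict[str, dict] = {}
        for tp, tgrp in grp.groupby("timepoint", sort=False):
            freqs: dict[tuple[bool, bool, bool], float] = {}
            for key in COMBOS:
                sel = (
                    (tgrp["ifng"].astype(bool) == key[0])
                    & (tgrp["tnfa"].astype(bool) == key[1])
                    & (tgrp["il2"].astype(bool) == key[2])
                )
                stim = tgrp.loc[sel & (tgrp["condition"] == "stimulated"), "freq_pct"]
                unstim = tgrp.loc[sel & (tgrp["condition"] == "unstimulated"), "freq_pct"]
                s = float(stim.iloc[0]) if len(stim) else 0.0
                u = float(unstim.iloc[0]) if len(unstim) else 0.0
                freqs[key] = subtract_background(s, u)
            per_tp[str(tp)] = freqs
        if baseline_label not in per_tp:
            raise ValueError(f"patient {pid}: missing baseline ICS timepoint")
        post = tuple(v for k, v in per_tp.items() if k != baseline_label)
        cd4 = None
        if "cd4_count_per_mm3" in grp.columns:
            vals = grp["cd4_count_per_mm3"].dropna()
            if len(vals):
                cd4 = float(vals.iloc[0])
        panels.append(IcsPanel(str(pid), per_tp[baseline_label], post, cd4))
    return panels


def call_table(table: pd.DataFrame, baseline_label: str = "baseline") -> pd.DataFrame:
    """Assign each patient's Th1 immunotype from a long-format ICS table."""
    panels = panels_from_table(table, baseline_label=baseline_label)
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in panels],
            "immunotype": [immunotype(p) for p in panels],
        }
    )
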