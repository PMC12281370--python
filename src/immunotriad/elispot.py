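"""Ex vivo IFN-gamma ELISpot response calling.

An ELISpot well counts cytokine-secreting cells; an antigen-specific T-cell
response shows up as an excess of spots in peptide-stimulated wells over
irrelevant-peptide background wells.  The caller implements the two-clause
positivity rule used in vaccine immunomonitoring: the stimulated mean must be
at least twice the background mean, and the background-subtracted count must
exceed 10 spots (per 3e5 cells plated, by convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ElispotRecord",
    "ElispotCall",
    "specific_spots",
    "call_positive",
    "responder_rate",
    "intensity_class",
    "durable_response",
    "call_table",
]

#: default plating density (cells per well) for ex vivo assays
DEFAULT_CELLS_PER_WELL = 300_000

#: minimum background-subtracted spot count for a positive call (strict)
MIN_SPECIFIC_SPOTS = 10.0

#: required fold of the stimulated mean over the background mean
MIN_FOLD = 2.0


@dataclass(frozen=True)
class ElispotRecord:
    """Replicate spot counts for one patient/timepoint/stimulus.

    Parameters
    ----------
    patient_id, timepoint, stimulus
        Identifiers; ``stimulus`` is the peptide label (e.g. UCP2, UCP4, or a
        tumour-associated antigen for spreading panels).
    stimulated_spots
        Spot counts of the peptide-stimulated replicate wells.
    background_spots
        Spot counts of the irrelevant-peptide (negative control) wells.
    cells_per_well
        Cells plated per well; purely descriptive, counts are reported on
        this basis as-is.
    """

    patient_id: str
    timepoint: str
    stimulus: str
    stimulated_spots: Sequence[float]
    background_spots: Sequence[float]
    cells_per_well: int = DEFAULT_CELLS_PER_WELL

    def __post_init__(self) -> None:
        for name in ("stimulated_spots", "background_spots"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} must contain at least one replicate well")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass(frozen=True)
class ElispotCall:
    """Outcome of the positivity rule for one record.

    ``fold_over_background`` is ``nan`` when the background mean is zero
    (fold undefined); the fold clause is then satisfied by any non-zero
    stimulated signal.
    """

    patient_id: str
    timepoint: str
    stimulus: str
    specific_spots: float
    positive: bool
    fold_over_background: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if self.positive and not self.specific_spots > MIN_SPECIFIC_SPOTS:
            raise ValueError("positive call requires specific_spots > 10")


def specific_spots(record: ElispotRecord) -> float:
    """Background-subtracted spot count, floored at zero.

    Returns ``max(0, mean(stimulated) - mean(background))`` on the per-well
    cell basis of the record.
    """
    stim = float(np.mean(np.asarray(record.stimulated_spots, dtype=float)))
    bg = float(np.mean(np.asarray(record.background_spots, dtype=float)))
    return max(0.0, stim - bg)


def call_positive(record: ElispotRecord) -> ElispotCall:
    """Apply the two-clause positivity rule.

    Positive iff ``mean(stimulated) >= 2 * mean(background)`` and the
    specific (background-subtracted) count is strictly greater than 10.
    A background mean of exactly zero satisfies the fold clause whenever the
    stimulated mean is non-zero.
    """
    stim = float(np.mean(np.asarray(record.stimulated_spots, dtype=float)))
    bg = float(np.mean(np.asarray(record.background_spots, dtype=float)))
    spec = max(0.0, stim - bg)
    if bg == 0.0:
        fold_ok = stim > 0.0
        fold = math.nan
    else:
        fold = stim / bg
        fold_ok = stim >= MIN_FOLD * bg
    positive = fold_ok and spec > MIN_SPECIFIC_SPOTS
    return ElispotCall(
        patient_id=record.patient_id,
        timepoint=record.timepoint,
        stimulus=record.stimulus,
        specific_spots=spec,
        positive=positive,
        fold_over_background=fold,
    )


def responder_rate(calls: Iterable[bool]) -> tuple[float, int]:
    """Percent responders among evaluable patients.

    Returns ``(exact_percent, rounded_percent)``: the exact value
    ``100 * positives / evaluable`` and its nearest-integer rounding used for
    reporting.
    """
    flags = [bool(c) for c in calls]
    if not flags:
        raise ValueError("responder_rate requires at least one patient")
    exact = 100.0 * sum(flags) / len(flags)
    return exact, int(round(exact))


def intensity_class(spots: float, cohort_median: float) -> str:
    """Classify a responder as ``"low"`` or ``"high"`` against the cohort
    median of specific spots for that peptide; ties go to ``"high"``."""
    return "high" if spots >= cohort_median else "low"


def durable_response(boost_calls: Sequence[ElispotCall | bool]) -> bool:
    """True iff the response is positive at >=1 boost-phase timepoint."""
    if len(boost_calls) == 0:
        raise ValueError("durable_response requires at least one boost timepoint")
    return any(c.positive if isinstance(c, ElispotCall) else bool(c) for c in boost_calls)


# ---------------------------------------------------------------------------
# table-level interface

def _records_from_table(table: pd.DataFrame) -> list[ElispotRecord]:
    required = {"patient_id", "timepoint", "stimulus", "arm", "spots"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ELISpot table missing columns: {sorted(missing)}")
    records = []
    keys = ["patient_id", "timepoint", "stimulus"]
    for (pid, tp, stim), grp in table.groupby(keys, sort=False):
        stim_wells = grp.loc[grp["arm"] == "stimulated", "spots"].tolist()
        bg_wells = grp.loc[grp["arm"] == "background", "spots"].tolist()
        if not stim_wells or not bg_wells:
            raise ValueError(
                f"patient {pid} / {tp} / {stim}: both stimulated and background "
                "wells are required"
            )
        cells = int(grp["cells_per_well"].iloc[0]) if "cells_per_well" in grp else DEFAULT_CELLS_PER_WELL
        records.append(
            ElispotRecord(str(pid), str(tp), str(stim), stim_wells, bg_wells, cells)
        )
    return records


def call_table(table: pd.DataFrame) -> pd.DataFrame:
    """Call every patient/timepoint/stimulus cell of a long-format well table.

    Expects columns ``patient_id, timepoint, stimulus, arm, spots`` with
    ``arm`` in {stimulated, background, positive_control}; positive-control
    wells are recorded but not used by the rule.
    """
    calls = [call_positive(r) for r in _records_from_table(table)]
    return pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in calls],
            "timepoint": [c.timepoint for c in calls],
            "stimulus": [c.stimulus for c in calls],
            "specific_spots": [c.specific_spots for c in calls],
            "fold_over_background": [c.fold_over_background for c in calls],
            "positive": [c.positive for c in calls],
        }
    )
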