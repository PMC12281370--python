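"""Epitope-spreading calls from pre/post IVS-ELISpot antigen panels.

Epitope spreading is the appearance, after vaccination, of T-cell reactivity
against tumour antigens that were not in the vaccine (intermolecular) or
against other epitopes of the vaccinated antigen (intramolecular).  PBMCs are
expanded in vitro against a panel of class II tumour-associated-antigen
epitopes and class I hTERT peptides, then read out by IFN-gamma ELISpot
(counts per 1e5 cells); the per-antigen caller reuses the ELISpot positivity
rule.  Only de novo responses count: an antigen already positive at baseline
is pre-existing reactivity, not spreading, even if it expands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .elispot import ElispotCall, call_table as _elispot_call_table

__all__ = [
    "AntigenResult",
    "SpreadingCall",
    "antigen_spread",
    "patient_spreading",
    "call_table",
    "DEFAULT_PANEL",
]

#: default antigen panel with class tags (intermolecular = non-vaccine TAA
#: class II epitopes; intramolecular = class I epitopes of the vaccinated
#: antigen hTERT)
DEFAULT_PANEL: dict[str, str] = {
    "NY-ESO-1": "classII_TAA",
    "KK-LC-1": "classII_TAA",
    "Mesothelin_366-380": "classII_TAA",
    "Mesothelin_523-537": "classII_TAA",
    "KRAS_G12V": "classII_TAA",
    "hTERT_classI": "classI_hTERT",
}


@dataclass(frozen=True)
class AntigenResult:
    antigen: str
    antigen_class: str  # classII_TAA | classI_hTERT
    status: str  # de_novo | preexisting | none


@dataclass(frozen=True)
class SpreadingCall:
    patient_id: str
    positive: bool
    breadth: int  # number of de novo antigens
    intramolecular: bool
    intermolecular: bool
    antigens: tuple[AntigenResult, ...]


def antigen_spread(pre: ElispotCall | bool | None, post: ElispotCall | bool) -> str:
    """Classify one antigen: ``de_novo`` iff pre-vaccination negative and
    post-vaccination positive; ``preexisting`` iff pre positive (whatever the
    post call); ``none`` otherwise.  A missing pre call is treated as
    potentially pre-existing, so the antigen cannot be called de novo."""
    if post is None:
        raise ValueError("post-vaccination call is required")
    post_pos = post.positive if isinstance(post, ElispotCall) else bool(post)
    if pre is None:
        return "none"
    pre_pos = pre.positive if isinstance(pre, ElispotCall) else bool(pre)
    if pre_pos:
        return "preexisting"
    return "de_novo" if post_pos else "none"


def patient_spreading(
    patient_id: str,
    panel: Mapping[str, tuple[ElispotCall | bool | None, ElispotCall | bool]],
    antigen_classes: Mapping[str, str] | None = None,
) -> SpreadingCall:
    """Patient-level spreading call over an antigen panel.

    ``panel`` maps antigen label -> (pre call, post call).  Positive iff at
    least one antigen is de novo; breadth counts de novo antigens; each de
    novo antigen is tagged intramolecular (class I hTERT) or intermolecular
    (class II TAA).  Antigens are treated independently.
    """
    if not panel:
        raise ValueError("patient_spreading requires a non-empty antigen panel")
    classes = dict(DEFAULT_PANEL)
    if antigen_classes:
        classes.update(antigen_classes)
    results = []
    for antigen, (pre, post) in panel.items():
        status = antigen_spread(pre, post)
        results.append(AntigenResult(antigen, classes.get(antigen, "classII_TAA"), status))
    de_novo = [r for r in results if r.status == "de_novo"]
    return SpreadingCall(
        patient_id=patient_id,
        positive=len(de_novo) > 0,
        breadth=len(de_novo),
        intramolecular=any(r.antigen_class == "classI_hTERT" for r in de_novo),
        intermolecular=any(r.antigen_class == "classII_TAA" for r in de_novo),
        antigens=tuple(results),
    )


def call_table(table: pd.DataFrame) -> pd.DataFrame:
    """Call spreading from a long IVS-ELISpot well table.

    Same schema as the ELISpot table plus a ``phase`` column in {pre, post};
    ``stimulus`` holds the antigen label.  Returns one row per patient with
    positivity, breadth and intra/intermolecular tags.
    """
    if "phase" not in table.columns:
        raise ValueError("spreading table requires a 'phase' column (pre/post)")
    calls = []
    for phase in ("pre", "post"):
        sub = table[table["phase"] == phase].drop(columns=["phase"])
        if len(sub):
            c = _elispot_call_table(sub)
            c["phase"] = phase
            calls.append(c)
    calls_df = pd.concat(calls, ignore_index=True) if calls else pd.DataFrame()
    rows = []
    for pid, grp in calls_df.groupby("patient_id", sort=False):
        panel: dict[str, tuple[bool | None, bool]] = {}
        for antigen, agrp in grp.groupby("stimulus", sort=False):
            pre = agrp.loc[agrp["phase"] == "pre", "positive"]
            post = agrp.loc[agrp["phase"] == "post", "positive"]
            if not len(post):
                continue
            panel[str(antigen)] = (
                bool(pre.iloc[0]) if len(pre) else None,
                bool(post.iloc[0]),
            )
        if not panel:
            continue
        call = patient_spreading(str(pid), panel)
        rows.append(
            {
                "patient_id": call.patient_id,
                "spreading_positive": call.positive,
                "breadth": call.breadth,
                "intramolecular": call.intramolecular,
                "intermolecular": call.intermolecular,
            }
        )
    return pd.DataFrame(rows)
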