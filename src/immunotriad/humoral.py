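"""Anti-peptide IgG ELISA: standard-curve fitting, titer estimation, calling.

Plasma is assayed at two dilutions against peptide-coated and
ovalbumin-coated (background) wells.  A purified IgG1 serial dilution
(0.31-20 ng/mL) provides the standard curve; sample concentrations are read
off a low-degree polynomial fitted to that curve, then multiplied back by the
plasma dilution factor.  Positivity requires a 2-fold excess of the peptide
OD over the ovalbumin OD; patients already seropositive at baseline must in
addition show a 2-fold rise in titer or OD after vaccination.  Titers above
1,000 ng/mL are reported as high-titer responses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .elispot import responder_rate as _rate

__all__ = [
    "StandardCurve",
    "AbResult",
    "fit_standard_curve",
    "ab_call",
    "ab_response_rate",
    "call_table",
]

HIGH_TITER_NG_ML = 1000.0
DEFAULT_DEGREE = 2


@dataclass(frozen=True)
class StandardCurve:
    """Polynomial calibration mapping optical density to ng/mL.

    ``coeffs`` are highest-degree-first (numpy.polyval order).  Prediction is
    restricted to the OD range spanned by the calibration points; ODs outside
    it are flagged, never silently extrapolated.
    """

    points: tuple[tuple[float, float], ...]  # (conc ng/mL, OD), conc increasing
    coeffs: tuple[float, ...]
    od_range: tuple[float, float]
    residual: float

    def predict(self, od: float) -> tuple[float, str]:
        """Concentration (ng/mL) for an OD, with a range flag.

        Returns ``(conc, flag)`` with flag in {"ok", "below_range",
        "above_range"}; out-of-range ODs yield ``nan``.
        """
        lo, hi = self.od_range
        if od < lo:
            return math.nan, "below_range"
        if od > hi:
            return math.nan, "above_range"
        return float(np.polyval(self.coeffs, od)), "ok"


def fit_standard_curve(
    points: Sequence[tuple[float, float]], degree: int = DEFAULT_DEGREE
) -> StandardCurve:
    """Least-squares polynomial fit of concentration on OD.

    ``points`` are (known concentration ng/mL, OD) pairs with strictly
    increasing concentrations; a non-monotone OD series is rejected (the
    inverse mapping would be ambiguous).
    """
    pts = [(float(c), float(o)) for c, o in points]
    if len(pts) < degree + 1:
        raise ValueError(f"need at least {degree + 1} calibration points for degree {degree}")
    conc = np.array([p[0] for p in pts])
    od = np.array([p[1] for p in pts])
    if np.any(np.diff(conc) <= 0):
        raise ValueError("calibration concentrations must be strictly increasing")
    if np.any(od < 0):
        raise ValueError("optical densities must be non-negative")
    if np.any(np.diff(od) <= 0):
        warnings.warn("non-monotone OD series: inverse calibration is ambiguous")
        raise ValueError("calibration ODs must be strictly increasing with concentration")
    coeffs = np.polyfit(od, conc, degree)
    residual = float(np.sqrt(np.mean((np.polyval(coeffs, od) - conc) ** 2)))
    return StandardCurve(
        points=tuple(pts),
        coeffs=tuple(float(c) for c in coeffs),
        od_range=(float(od.min()), float(od.max())),
        residual=residual,
    )


@dataclass(frozen=True)
class AbResult:
    patient_id: str
    timepoint: str
    specific_od: float
    titer_ng_ml: float  # nan when out of calibration range / no curve
    titer_flag: str  # ok / below_range / above_range / no_curve
    positive: bool
    high_titer: bool

    def __post_init__(self) -> None:
        if self.high_titer and not self.positive:
            raise ValueError("high_titer implies positive")


def _titer(specific_od: float, curve: StandardCurve | None, dilution: float) -> tuple[float, str]:
    if curve is None:
        return math.nan, "no_curve"
    conc, flag = curve.predict(specific_od)
    if flag != "ok":
        return math.nan, flag
    return conc * dilution, flag


def ab_call(
    od_ucp: float,
    od_ova: float,
    *,
    baseline: AbResult | None = None,
    curve: StandardCurve | None = None,
    dilution: float = 125.0,
    patient_id: str = "",
    timepoint: str = "",
) -> AbResult:
    """Call one plasma sample.

    Positive iff ``od_ucp >= 2 * od_ova``; when the patient was already
    positive at ``baseline``, positivity additionally requires a >=2-fold
    increase of titer or specific OD over baseline.  ``dilution`` is the
    reciprocal plasma dilution multiplied back into the reported ng/mL.
    """
    if od_ucp < 0 or od_ova < 0:
        raise ValueError("optical densities must be non-negative")
    specific = max(0.0, od_ucp - od_ova)
    titer, flag = _titer(specific, curve, dilution)
    positive = od_ucp >= 2.0 * od_ova
    if positive and baseline is not None and baseline.positive:
        od_rise = baseline.specific_od > 0 and specific >= 2.0 * baseline.specific_od
        titer_rise = (
            math.isfinite(titer)
            and math.isfinite(baseline.titer_ng_ml)
            and baseline.titer_ng_ml > 0
            and titer >= 2.0 * baseline.titer_ng_ml
        )
        if baseline.specific_od == 0 and not math.isfinite(baseline.titer_ng_ml):
            pass  # degenerate baseline: treat as de novo
        else:
            positive = od_rise or titer_rise
    high = positive and math.isfinite(titer) and titer > HIGH_TITER_NG_ML
    return AbResult(patient_id, timepoint, specific, titer, flag, positive, high)


def ab_response_rate(calls: Iterable[bool]) -> tuple[float, int]:
    """Percent antibody responders; same contract as elispot.responder_rate."""
    return _rate(calls)


# ---------------------------------------------------------------------------
# table-level interface

def call_table(
    table: pd.DataFrame,
    standards: pd.DataFrame,
    *,
    baseline_label: str = "baseline",
    degree: int = DEFAULT_DEGREE,
) -> pd.DataFrame:
    """Call every patient/timepoint of a long ELISA table.

    ``table`` columns: patient_id, timepoint, coat in {UCP, OVA}, dilution
    (reciprocal, e.g. 125 or 1000), od.  ``standards`` columns: conc_ng_ml,
    od.  When both dilutions give an in-range specific OD the less-diluted
    well (smaller reciprocal) wins.
    """
    curve = fit_standard_curve(
        list(zip(standards["conc_ng_ml"], standards["od"])), degree=degree
    )
    rows = []
    for pid, grp in table.groupby("patient_id", sort=False):
        baseline_res: AbResult | None = None
        tps = list(dict.fromkeys(grp["timepoint"]))
        if baseline_label in tps:  # baseline must be called first
            tps.remove(baseline_label)
            tps.insert(0, baseline_label)
        for tp in tps:
            tgrp = grp[grp["timepoint"] == tp]
            best: AbResult | None = None
            for dil in sorted(tgrp["dilution"].unique()):
                ucp = tgrp.loc[(tgrp["coat"] == "UCP") & (tgrp["dilution"] == dil), "od"]
                ova = tgrp.loc[(tgrp["coat"] == "OVA") & (tgrp["dilution"] == dil), "od"]
                if not len(ucp) or not len(ova):
                    continue
                res = ab_call(
                    float(ucp.mean()),
                    float(ova.mean()),
                    baseline=baseline_res if tp != baseline_label else None,
                    curve=curve,
                    dilution=float(dil),
                    patient_id=str(pid),
                    timepoint=str(tp),
                )
                if best is None or (best.titer_flag != "ok" and res.titer_flag == "ok"):
                    best = res
            if best is None:
                continue
            if tp == baseline_label:
                baseline_res = best
            rows.append(best)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "timepoint": [r.timepoint for r in rows],
            "specific_od": [r.specific_od for r in rows],
            "titer_ng_ml": [r.titer_ng_ml for r in rows],
            "titer_flag": [r.titer_flag for r in rows],
            "positive": [r.positive for r in rows],
            "high_titer": [r.high_titer for r in rows],
        }
    )
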