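"""Patient-level integration, immune-triad classification and survival.

The immune triad is the conjunction, in one patient, of three
vaccine-induced responses: polyfunctional triple-positive Th1 cells
(IFN-gamma + TNF-alpha + IL-2), a specific IgG antibody response, and
epitope spreading.  This module joins the per-assay calls into one row per
patient, classifies the triad, builds unsupervised immune groups
(z-scored PCA + k-means), and associates groups with overall survival via
the Kaplan-Meier product-limit estimator and the two-group log-rank test;
baseline covariates are compared with Mann-Whitney / Fisher / chi-square.

All p-values are exploratory: no multiple-testing correction is applied.

The ``ImmuneCorrelates`` model / ``ImmuneCorrelatesResults`` pair wraps the
whole pipeline: build the model from assay tables, ``fit()`` it, and read
rates, triad counts, KM medians and the log-rank comparison off the results.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import elispot as _elispot
from . import humoral as _humoral
from . import ics as _ics
from . import spreading as _spreading

__all__ = [
    "SurvivalCurve",
    "triad_status",
    "km_estimate",
    "logrank",
    "immune_group_clustering",
    "group_compare",
    "join_calls",
    "ImmuneCorrelates",
    "ImmuneCorrelatesResults",
]


def triad_status(
    immunotype: str | None, ab_positive: bool | None, spreading_positive: bool | None
) -> bool:
    """Conjunction of the three triad components.

    Any missing component makes the status undetermined and raises; callers
    doing cohort-level work exclude such patients (complete-case) and log it.
    """
    if immunotype is None or ab_positive is None or spreading_positive is None:
        raise ValueError("triad undetermined: a component call is missing")
    return immunotype == "polyF_triple" and bool(ab_positive) and bool(spreading_positive)


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier curve summary for one patient group."""

    label: str
    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_months: float  # inf when S(t) never reaches 0.5
    median_ci: tuple[float, float]
    rate_12m: float
    n: int
    n_events: int


def km_estimate(
    times: Sequence[float], events: Sequence[bool | int], label: str = "", horizon: float = 12.0
) -> SurvivalCurve:
    """Product-limit survival estimate for one group.

    The median is the smallest time where the estimated survival drops to
    <= 0.5 (infinity when never reached); ``rate_12m`` is the estimated
    survival probability at the 12-month horizon (or ``horizon``).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if t.size == 0:
        raise ValueError("km_estimate requires at least one record")
    if np.any(t < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e, label=label or "group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ci = median_survival_times(kmf.confidence_interval_)
    ci_vals = tuple(float(x) for x in np.asarray(ci).ravel()[:2]) if ci is not None else (math.nan, math.nan)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    return SurvivalCurve(
        label=label or "group",
        timeline=timeline,
        survival=surv,
        at_risk=at_risk,
        median_months=float(kmf.median_survival_time_),
        median_ci=ci_vals,
        rate_12m=float(kmf.predict(horizon)),
        n=int(t.size),
        n_events=int(e.sum()),
    )


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[bool | int],
    times_b: Sequence[float],
    events_b: Sequence[bool | int],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, two-tailed p).

    With zero events in both groups combined the statistic is 0 and p is 1.
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a).astype(int), np.asarray(events_b).astype(int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def immune_group_clustering(
    features: pd.DataFrame, k: int = 4, seed: int = 0, n_components: int = 3
):
    """Unsupervised immune groups: z-scored PCA projection plus k-means.

    ``features`` is a per-patient numeric table (index = patient).  Constant
    columns are dropped with a warning; rows with missing values are
    excluded (complete-case).  Returns ``(projection, labels)`` where
    ``projection`` is a DataFrame of principal components and ``labels`` a
    Series of cluster labels, both indexed by the retained patients.
    """
    if len(features) < 2:
        raise ValueError("clustering requires at least two patients")
    x = features.dropna()
    keep = [c for c in x.columns if x[c].nunique() > 1]
    dropped = set(x.columns) - set(keep)
    if dropped:
        warnings.warn(f"dropping constant feature columns: {sorted(dropped)}")
    if not keep:
        raise ValueError("no non-constant feature columns")
    x = x[keep]
    z = (x - x.mean()) / x.std(ddof=0)
    n_comp = min(n_components, z.shape[1], len(z))
    pca = PCA(n_components=n_comp, random_state=seed)
    proj = pca.fit_transform(z.to_numpy())
    km = KMeans(n_clusters=min(k, len(z)), random_state=seed, n_init=10)
    labels = km.fit_predict(proj)
    projection = pd.DataFrame(
        proj, index=x.index, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    return projection, pd.Series(labels, index=x.index, name="cluster")


def group_compare(a, b, kind: str = "continuous") -> tuple[float, float]:
    """Two-group comparison: Mann-Whitney U for continuous values,
    Fisher exact / chi-square for categorical counts.

    For ``kind="categorical"`` pass 2x2 counts ``a=(pos_a, n_a)``,
    ``b=(pos_b, n_b)``; Fisher's exact test is used whenever any expected
    cell count is below 5, chi-square otherwise.
    """
    if kind == "continuous":
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.size == 0 or b.size == 0:
            raise ValueError("both groups must be non-empty")
        # exact permutation null for small tie-free samples, normal
        # approximation otherwise
        tie_free = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
        method = "exact" if (tie_free and a.size <= 25 and b.size <= 25) else "asymptotic"
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(u), float(p)
    if kind == "categorical":
        (pos_a, n_a), (pos_b, n_b) = a, b
        table = np.array([[pos_a, n_a - pos_a], [pos_b, n_b - pos_b]])
        if np.any(table < 0):
            raise ValueError("counts must satisfy 0 <= positives <= total")
        expected = stats.contingency.expected_freq(table) if table.sum() else table
        if np.any(expected < 5):
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            return float(odds), float(p)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# joining the per-assay call tables

def join_calls(
    elispot_calls: pd.DataFrame,
    immunotypes: pd.DataFrame,
    ab_calls: pd.DataFrame,
    spreading_calls: pd.DataFrame,
    survival: pd.DataFrame,
    baseline_label: str = "baseline",
) -> pd.DataFrame:
    """One row per patient joining assay calls, triad status and survival.

    A patient responds to a peptide when positive at any post-vaccination
    timepoint; the pooled flag requires a response to at least one peptide.
    The antibody flag is positivity at any post-vaccination timepoint.
    Patients missing any triad component carry a missing triad status.
    """
    post = elispot_calls[elispot_calls["timepoint"] != baseline_label]
    resp = (
        post.groupby(["patient_id", "stimulus"])["positive"].any().unstack(fill_value=False)
    )
    resp.columns = [f"responder_{c}" for c in resp.columns]
    spots = (
        post.groupby("patient_id")["specific_spots"].max().rename("max_specific_spots")
    )
    ab_post = ab_calls[ab_calls["timepoint"] != baseline_label]
    ab = ab_post.groupby("patient_id").agg(
        ab_positive=("positive", "any"), ab_high_titer=("high_titer", "any"),
        titer_ng_ml=("titer_ng_ml", "max"),
    )
    out = (
        resp.join(spots, how="outer")
        .join(immunotypes.set_index("patient_id"), how="outer")
        .join(ab, how="outer")
        .join(spreading_calls.set_index("patient_id"), how="outer")
        .join(survival.set_index("patient_id"), how="outer")
        .reset_index(names="patient_id")
    )
    responder_cols = [c for c in out.columns if c.startswith("responder_")]
    out["responder_any"] = out[responder_cols].fillna(False).any(axis=1)

    def _triad(row):
        if (
            pd.isna(row.get("immunotype"))
            or pd.isna(row.get("ab_positive"))
            or pd.isna(row.get("spreading_positive"))
        ):
            return pd.NA
        return triad_status(row["immunotype"], row["ab_positive"], row["spreading_positive"])

    out["triad"] = out.apply(_triad, axis=1)
    return out


# ---------------------------------------------------------------------------
# model / results

class ImmuneCorrelates:
    """Immune-correlates model over the raw assay tables of one cohort.

    Parameters mirror the delimited-text schemas of the assay modules;
    ``fit()`` runs every caller, joins the calls, classifies the triad and
    estimates group survival, returning an :class:`ImmuneCorrelatesResults`.
    """

    def __init__(
        self,
        elispot: pd.DataFrame,
        ics: pd.DataFrame,
        elisa: pd.DataFrame,
        standards: pd.DataFrame,
        spreading: pd.DataFrame | None,
        survival: pd.DataFrame,
        baseline_label: str = "baseline",
    ):
        self.elispot = elispot
        self.ics = ics
        self.elisa = elisa
        self.standards = standards
        self.spreading = spreading
        self.survival = survival
        self.baseline_label = baseline_label

    @classmethod
    def from_tables(cls, tables, **kwargs) -> "ImmuneCorrelates":
        """Build from a :class:`~immunotriad.synth.CohortTables`-like bundle
        (anything with elispot/ics/elisa/standards/survival attributes)."""
        spreading = getattr(tables, "spreading", None)
        return cls(
            tables.elispot, tables.ics, tables.elisa, tables.standards,
            spreading, tables.survival, **kwargs,
        )

    def fit(self, horizon: float = 12.0) -> "ImmuneCorrelatesResults":
        elispot_calls = _elispot.call_table(self.elispot)
        immunotypes = _ics.call_table(self.ics, baseline_label=self.baseline_label)
        ab_calls = _humoral.call_table(
            self.elisa, self.standards, baseline_label=self.baseline_label
        )
        if self.spreading is not None and len(self.spreading):
            spreading_calls = _spreading.call_table(self.spreading)
        else:
            # no spreading panel supplied: approximate the spreading latent
            # state as undetermined for every patient
            spreading_calls = pd.DataFrame(columns=["patient_id", "spreading_positive", "breadth"])
        patient_table = join_calls(
            elispot_calls, immunotypes, ab_calls, spreading_calls,
            self.survival, baseline_label=self.baseline_label,
        )
        return ImmuneCorrelatesResults(self, patient_table, elispot_calls, horizon=horizon)


class ImmuneCorrelatesResults:
    """Fitted immune-correlates results: per-patient calls, rates, survival."""

    def __init__(self, model: ImmuneCorrelates, patient_table: pd.DataFrame,
                 elispot_calls: pd.DataFrame, horizon: float = 12.0):
        self.model = model
        self.patient_table = patient_table
        self.elispot_calls = elispot_calls
        self.horizon = horizon
        self.km_by_triad: dict[str, SurvivalCurve] = {}
        self.logrank_triad: tuple[float, float] | None = None
        self._estimate_survival()

    # -- rates -----------------------------------------------------------
    def responder_rate(self, peptide: str | None = None) -> tuple[float, int]:
        """Percent ELISpot responders (pooled over peptides when None)."""
        col = "responder_any" if peptide is None else f"responder_{peptide}"
        flags = self.patient_table[col].fillna(False).astype(bool)
        return _elispot.responder_rate(flags)

    def ab_response_rate(self) -> tuple[float, int]:
        flags = self.patient_table["ab_positive"].dropna().astype(bool)
        return _humoral.ab_response_rate(flags)

    def triad_count(self) -> int:
        return int(self.patient_table["triad"].fillna(False).astype(bool).sum())

    # -- survival --------------------------------------------------------
    def _estimate_survival(self) -> None:
        tab = self.patient_table.dropna(subset=["os_months", "event"])
        tab = tab[tab["triad"].notna()]
        if not len(tab):
            return
        groups = {
            "triad": tab[tab["triad"].astype(bool)],
            "no_triad": tab[~tab["triad"].astype(bool)],
        }
        for label, sub in groups.items():
            if len(sub):
                self.km_by_triad[label] = km_estimate(
                    sub["os_months"], sub["event"], label=label, horizon=self.horizon
                )
        if all(len(g) for g in groups.values()):
            self.logrank_triad = logrank(
                groups["triad"]["os_months"], groups["triad"]["event"],
                groups["no_triad"]["os_months"], groups["no_triad"]["event"],
            )

    def km_by(self, column: str) -> dict[str, SurvivalCurve]:
        """Kaplan-Meier curves stratified by any boolean/categorical column."""
        tab = self.patient_table.dropna(subset=["os_months", "event", column])
        return {
            str(val): km_estimate(sub["os_months"], sub["event"], label=str(val),
                                  horizon=self.horizon)
            for val, sub in tab.groupby(column)
        }

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        lines = ["Immune-correlates summary", "=" * 25]
        n = len(self.patient_table)
        lines.append(f"patients: {n}")
        for col in sorted(c for c in self.patient_table.columns if c.startswith("responder_")):
            exact, rounded = _elispot.responder_rate(
                self.patient_table[col].fillna(False).astype(bool)
            )
            lines.append(f"{col}: {rounded}% ({exact:.1f}% exact)")
        if self.patient_table["ab_positive"].notna().any():
            exact, rounded = self.ab_response_rate()
            lines.append(f"antibody response: {rounded}% ({exact:.1f}% exact)")
        itypes = self.patient_table["immunotype"].value_counts(dropna=True)
        lines.append("immunotypes: " + ", ".join(f"{k}={v}" for k, v in itypes.items()))
        lines.append(f"immune triad: {self.triad_count()} patients")
        for label, curve in self.km_by_triad.items():
            med = "not reached" if math.isinf(curve.median_months) else f"{curve.median_months:.1f} mo"
            lines.append(
                f"OS [{label}] n={curve.n}, events={curve.n_events}, median {med}, "
                f"{self.horizon:.0f}-mo rate {curve.rate_12m:.2f}"
            )
        if self.logrank_triad is not None:
            chi2, p = self.logrank_triad
            lines.append(f"log-rank triad vs rest: chi2={chi2:.2f}, p={p:.3g} (exploratory)")
        return "\n".join(lines)
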