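"""Patient harmonic-mean best-rank (PHBR) HLA-DR presentation score.

For each vaccine peptide a predictor assigns every HLA-DRB1 allele a best
rank BR (any positive score where lower means better presentation, e.g. a
percentile rank).  A patient's PHBR for a peptide is the harmonic mean of
the BRs of their two DRB1 alleles:

    PHBR = 2 / (1/BR_1 + 1/BR_2)

Homozygous genotypes use the same BR twice and return that BR.  A lower
PHBR means the patient's HLA-DR alleles are more likely to present the
peptide.  The predictor itself is never invoked here: BRs arrive as a table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats

__all__ = ["HlaBestRanks", "phbr", "cohort_phbr"]


@dataclass(frozen=True)
class HlaBestRanks:
    """A patient's two HLA-DRB1 alleles with per-peptide best ranks."""

    patient_id: str
    alleles: tuple[str, str]
    br: Mapping[str, tuple[float, float]]  # peptide -> (BR allele 1, BR allele 2)

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError("exactly two HLA-DRB1 allele slots are required")
        for peptide, (a, b) in self.br.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"best ranks must be positive ({peptide})")


def phbr(br_1: float, br_2: float) -> float:
    """Harmonic mean of the two allele best ranks."""
    if br_1 <= 0 or br_2 <= 0:
        raise ValueError("best ranks must be positive")
    return 2.0 / (1.0 / br_1 + 1.0 / br_2)


def cohort_phbr(table: pd.DataFrame, peptides: tuple[str, str] | None = None):
    """Per-patient PHBR scores plus a two-peptide distribution comparison.

    ``table`` columns: patient_id, allele_1, allele_2, peptide, best_rank
    with one row per patient/peptide/allele slot — i.e. two rows (one per
    allele) per patient and peptide.  Patients with missing BRs for a
    peptide are listed in the returned summary, never imputed.

    Returns ``(scores, summary)``: a DataFrame (patient_id, peptide, phbr)
    and a dict with the Mann-Whitney statistic and p-value comparing the two
    peptides' score distributions (populated when exactly two peptides are
    scored).
    """
    required = {"patient_id", "allele_1", "allele_2", "peptide", "best_rank"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"best-rank table missing columns: {sorted(missing)}")
    rows = []
    incomplete = []
    for (pid, pep), grp in table.groupby(["patient_id", "peptide"], sort=False):
        brs = grp["best_rank"].astype(float).tolist()
        if len(brs) < 2:
            incomplete.append((str(pid), str(pep)))
            continue
        rows.append({"patient_id": str(pid), "peptide": str(pep), "phbr": phbr(brs[0], brs[1])})
    scores = pd.DataFrame(rows, columns=["patient_id", "peptide", "phbr"])
    summary: dict = {"missing": incomplete}
    peps = list(peptides) if peptides else sorted(scores["peptide"].unique()) if len(scores) else []
    if len(peps) == 2:
        a = scores.loc[scores["peptide"] == peps[0], "phbr"]
        b = scores.loc[scores["peptide"] == peps[1], "phbr"]
        if len(a) and len(b):
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            summary.update(
                {
                    "peptides": tuple(peps),
                    "median_phbr": {peps[0]: float(a.median()), peps[1]: float(b.median())},
                    "mannwhitney_u": float(u),
                    "p_value": float(p),
                }
            )
    return scores, summary


def spearman_with_response(scores: pd.DataFrame, magnitudes: pd.DataFrame):
    """Spearman correlation of PHBR with response magnitude (descriptive).

    ``magnitudes`` columns: patient_id, peptide, specific_spots.  Returns
    (rho, p) over the inner join of the two tables.
    """
    merged = scores.merge(magnitudes, on=["patient_id", "peptide"])
    if len(merged) < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = stats.spearmanr(merged["phbr"], merged["specific_spots"])
    return float(rho), float(p)
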