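"""Seeded synthetic-cohort generator.

Generates a vaccine-trial cohort with the statistical structure the
downstream analysis assumes, so every stage of the pipeline can be exercised
without patient data:

* ELISpot well counts: Poisson per replicate well, background wells at the
  background rate and responder stimulated wells at background + effect.
* ICS: seven-way Boolean cytokine-combination frequencies drawn from a
  Dirichlet over the positive combinations (plus an implicit negative mass),
  so the partition identity holds by construction.
* ELISA: a quadratic OD/concentration standard curve and two plasma
  dilutions per patient, with log-normal titers for antibody responders.
* HLA-DRB1 best ranks: log-normal per-allele predictor ranks, one peptide
  systematically better presented than the other.
* TCR repertoires: Zipf/power-law ranked clone frequencies, multinomial
  counts, random CDR3 sequences.
* Survival: exponential times with an immunotype-group-dependent monthly
  hazard; independent uniform censoring over follow-up.

One global seed fans out to per-table substreams, so tables are independent
yet byte-identical across runs with the same (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SynthConfig", "CohortTables", "generate_cohort", "simulate_survival"]

AA = "ACDEFGHIKLMNPQRSTVWY"
V_GENES = [f"TRBV{i}" for i in (2, 4, 5, 6, 7, 9, 11, 12, 15, 19, 20, 27, 28, 29, 30)]

_COMBOS = (
    (1, 1, 1),
    (1, 1, 0),
    (1, 0, 1),
    (0, 1, 1),
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
)

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults mirror the trial's cohort statistics.

    60 patients, two vaccine peptides, a priming phase followed by boosts;
    responder rates, effect sizes (median specific spots), antibody and
    spreading rates and group hazards are set to the cohort's printed
    values.  All rates are probabilities in [0, 1]; hazards are per month.
    """

    n_patients: int = 60
    peptides: tuple[str, ...] = ("UCP2", "UCP4")
    timepoints: tuple[str, ...] = ("baseline", "priming", "boost_1", "boost_2")
    responder_rate_per_peptide: dict = field(
        default_factory=lambda: {"UCP2": 0.68, "UCP4": 0.57}
    )
    bg_spot_rate: float = 5.0
    effect_spots: dict = field(default_factory=lambda: {"UCP2": 84.0, "UCP4": 63.0})
    ics_combo_concentration: tuple[float, ...] = (4.0, 1.0, 0.5, 2.0, 0.5, 2.0, 0.5)
    ab_rate: float = 0.88  # P(IgG response | vaccine responder)
    ab_leak_rate: float = 0.06  # P(IgG response | non-responder)
    titer_lognormal_params: tuple[float, float] = (7.2, 0.8)  # ln ng/mL scale
    spreading_rate_given_response: float = 0.37
    repertoire_zipf_exponent: float = 1.1
    n_clonotypes: int = 400
    survival_hazard_by_group: dict = field(
        default_factory=lambda: {"triad": _LN2 / 19.0, "other": _LN2 / 8.3}
    )
    censor_rate: float = 0.2
    follow_up_months: float = 36.0
    n_wells: int = 3
    cells_per_well: int = 300_000
    seed: int = 0

    def validate(self) -> None:
        def _prob(name: str, value: float) -> None:
            if not (math.isfinite(value) and 0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {value}")

        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for pep in self.peptides:
            _prob(f"responder_rate_per_peptide[{pep}]", self.responder_rate_per_peptide[pep])
        _prob("ab_rate", self.ab_rate)
        _prob("ab_leak_rate", self.ab_leak_rate)
        _prob("spreading_rate_given_response", self.spreading_rate_given_response)
        _prob("censor_rate", self.censor_rate)
        if not (math.isfinite(self.bg_spot_rate) and self.bg_spot_rate >= 0):
            raise ValueError(f"bg_spot_rate must be finite and >= 0, got {self.bg_spot_rate}")
        for pep, eff in self.effect_spots.items():
            if not (math.isfinite(eff) and eff >= 0):
                raise ValueError(f"effect_spots[{pep}] must be finite and >= 0, got {eff}")
        if len(self.ics_combo_concentration) != 7 or any(
            not (math.isfinite(c) and c > 0) for c in self.ics_combo_concentration
        ):
            raise ValueError("ics_combo_concentration must be 7 positive concentrations")
        for grp, lam in self.survival_hazard_by_group.items():
            if not (math.isfinite(lam) and lam > 0):
                raise ValueError(f"survival_hazard_by_group[{grp}] must be > 0, got {lam}")
        if self.repertoire_zipf_exponent <= 0:
            raise ValueError("repertoire_zipf_exponent must be positive")
        if self.n_clonotypes < 1:
            raise ValueError("n_clonotypes must be >= 1")

    @classmethod
    def from_json(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("peptides", "timepoints", "ics_combo_concentration", "titer_lognormal_params"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2, default=list)


@dataclass
class CohortTables:
    """The generated table bundle, one DataFrame per assay."""

    elispot: pd.DataFrame
    ics: pd.DataFrame
    elisa: pd.DataFrame
    standards: pd.DataFrame
    spreading: pd.DataFrame  # IVS antigen-panel wells (pre/post phases)
    hla: pd.DataFrame
    repertoire: pd.DataFrame
    survival: pd.DataFrame
    patients: pd.DataFrame  # latent per-patient truth (responder flags, group)

    TABLE_NAMES = (
        "elispot", "ics", "elisa", "standards", "spreading", "hla",
        "repertoire", "survival", "patients",
    )

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self.TABLE_NAMES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def read(cls, in_dir) -> "CohortTables":
        src = Path(in_dir)
        return cls(**{name: pd.read_csv(src / f"{name}.csv") for name in cls.TABLE_NAMES})


# true OD(conc) used to simulate the plate reader; mildly saturating quadratic,
# strictly increasing over the 0.31-20 ng/mL standard range; zero blank so the
# background-subtracted specific OD sits on the same scale as the standards
_CURVE_A, _CURVE_B, _CURVE_C = 0.0, 0.11, -0.0012


def _od_from_conc(conc: float) -> float:
    return _CURVE_A + _CURVE_B * conc + _CURVE_C * conc * conc


def _standards_table() -> pd.DataFrame:
    concs = [0.31, 0.63, 1.25, 2.5, 5.0, 10.0, 20.0]
    return pd.DataFrame(
        {"conc_ng_ml": concs, "od": [round(_od_from_conc(c), 4) for c in concs]}
    )


def simulate_survival(
    n: int, hazard_per_month: float, censor_rate: float, rng: np.random.Generator,
    follow_up_months: float = 36.0,
) -> pd.DataFrame:
    """Exponential survival times with independent uniform censoring.

    Each subject's death time is Exponential(hazard); with probability
    ``censor_rate`` the record is censored at a Uniform(0, follow_up) time
    (taking the earlier of the two).
    """
    if hazard_per_month <= 0:
        raise ValueError("hazard_per_month must be positive")
    t_event = rng.exponential(1.0 / hazard_per_month, size=n)
    censored = rng.random(n) < censor_rate
    t_cens = rng.uniform(0.0, follow_up_months, size=n)
    time = np.where(censored, np.minimum(t_event, t_cens), t_event)
    event = np.where(censored & (t_cens < t_event), 0, 1)
    return pd.DataFrame({"os_months": time, "event": event.astype(int)})


def _gen_elispot(cfg: SynthConfig, rng: np.random.Generator, responders: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, pr in responders.iterrows():
        pid = pr["patient_id"]
        for pep in cfg.peptides:
            is_resp = bool(pr[f"responder_{pep}"])
            for tp in cfg.timepoints:
                # vaccine-induced responses only appear after priming
                signal = is_resp and tp != "baseline"
                lam_stim = cfg.bg_spot_rate + (cfg.effect_spots[pep] if signal else 0.0)
                for arm, lam in (("stimulated", lam_stim), ("background", cfg.bg_spot_rate)):
                    spots = rng.poisson(lam, size=cfg.n_wells)
                    for w, s in enumerate(spots):
                        rows.append(
                            (pid, tp, pep, w, arm, int(s), cfg.cells_per_well)
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "timepoint", "stimulus", "well_index", "arm", "spots",
            "cells_per_well",
        ],
    )


def _gen_ics(cfg: SynthConfig, rng: np.random.Generator, patients: pd.DataFrame) -> pd.DataFrame:
    rows = []
    conc = np.asarray(cfg.ics_combo_concentration, dtype=float)
    for _, pr in patients.iterrows():
        pid = pr["patient_id"]
        itype = pr["true_immunotype"]
        cd4 = float(rng.normal(719.0, 150.0))
        cd4 = max(cd4, 100.0)
        for tp in ("baseline", "priming"):
            # unstimulated background: small uniform noise per combo
            unstim = rng.uniform(0.0, 0.02, size=7)
            if tp == "baseline" or itype == "none":
                stim = unstim + rng.uniform(0.0, 0.02, size=7)
            else:
                total = float(rng.lognormal(math.log(0.35), 0.4))
                weights = conc.copy()
                # steer the Dirichlet toward the patient's latent immunotype
                if itype == "polyF_triple":
                    weights[0] += 20.0
                elif itype == "polyF_double":
                    weights[0] = 0.05
                    weights[3] += 20.0  # TNFa+IL-2 double, the predominant one
                else:  # singleF
                    weights[0] = 0.05
                    weights[1:4] = 0.05
                    weights[5] += 20.0  # TNFa single
                split = rng.dirichlet(weights)
                stim = unstim + total * split
            for combo, s, u in zip(_COMBOS, stim, unstim):
                for cond, v in (("stimulated", s), ("unstimulated", u)):
                    rows.append(
                        (pid, tp, cond, combo[0], combo[1], combo[2], round(float(v), 5), round(cd4, 1))
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "timepoint", "condition", "ifng", "tnfa", "il2",
            "freq_pct", "cd4_count_per_mm3",
        ],
    )


def _gen_elisa(cfg: SynthConfig, rng: np.random.Generator, patients: pd.DataFrame) -> pd.DataFrame:
    rows = []
    mu, sigma = cfg.titer_lognormal_params
    for _, pr in patients.iterrows():
        pid = pr["patient_id"]
        ab_pos = bool(pr["true_ab_positive"])
        titer_post = float(rng.lognormal(mu, sigma)) if ab_pos else float(rng.uniform(0.0, 10.0))
        for tp, titer in (("baseline", float(rng.uniform(0.0, 10.0))), ("priming", titer_post)):
            for dil in (125.0, 1000.0):
                conc_in_well = titer / dil
                od_ova = float(rng.uniform(0.02, 0.06))
                od_sig = _od_from_conc(conc_in_well) - _od_from_conc(0.0)
                od_ucp = od_ova + max(0.0, od_sig * (1.0 + rng.normal(0.0, 0.03)))
                rows.append((pid, tp, "UCP", dil, round(od_ucp, 4)))
                rows.append((pid, tp, "OVA", dil, round(od_ova, 4)))
    return pd.DataFrame(rows, columns=["patient_id", "timepoint", "coat", "dilution", "od"])


_SPREADING_ANTIGENS = (
    "NY-ESO-1", "KK-LC-1", "Mesothelin_366-380", "Mesothelin_523-537",
    "KRAS_G12V", "hTERT_classI",
)


def _gen_spreading(cfg: SynthConfig, rng: np.random.Generator, patients: pd.DataFrame) -> pd.DataFrame:
    """IVS antigen-panel wells at 1e5 cells/well, pre and post vaccination.

    Spreading-positive patients acquire de novo reactivity against 1-3
    randomly chosen panel antigens; a small fraction of antigens carry
    pre-existing reactivity (positive already at baseline) regardless, which
    the caller must exclude.
    """
    rows = []
    bg = 3.0
    effect = 40.0  # per 1e5 cells after 6-day expansion
    preexisting_rate = 0.05
    for _, pr in patients.iterrows():
        pid = pr["patient_id"]
        # pre-existing reactivity is decided first; de novo antigens are drawn
        # among the remaining ones so the latent spreading label always has a
        # recoverable de novo signal in the generated wells
        preexisting_set = {
            a for a in range(len(_SPREADING_ANTIGENS)) if rng.random() < preexisting_rate
        }
        candidates = [a for a in range(len(_SPREADING_ANTIGENS)) if a not in preexisting_set]
        n_spread = min(int(rng.integers(1, 4)), len(candidates)) if pr["true_spreading"] else 0
        de_novo = set(rng.choice(candidates, size=n_spread, replace=False).tolist())
        for a, antigen in enumerate(_SPREADING_ANTIGENS):
            preexisting = a in preexisting_set
            for phase in ("pre", "post"):
                signal = preexisting or (phase == "post" and a in de_novo)
                lam_stim = bg + (effect if signal else 0.0)
                for arm, lam in (("stimulated", lam_stim), ("background", bg)):
                    spots = rng.poisson(lam, size=cfg.n_wells)
                    for w, s in enumerate(spots):
                        rows.append((pid, "ivs", antigen, phase, w, arm, int(s), 100_000))
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "timepoint", "stimulus", "phase", "well_index", "arm",
            "spots", "cells_per_well",
        ],
    )


_DRB1_POOL = [
    "DRB1*01:01", "DRB1*03:01", "DRB1*04:01", "DRB1*07:01", "DRB1*11:01",
    "DRB1*13:01", "DRB1*15:01", "DRB1*08:01", "DRB1*12:01", "DRB1*14:01",
]


def _gen_hla(cfg: SynthConfig, rng: np.random.Generator, patients: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, pr in patients.iterrows():
        pid = pr["patient_id"]
        alleles = rng.choice(_DRB1_POOL, size=2, replace=True)
        for pep in cfg.peptides:
            # one peptide binds HLA-DR systematically better than the other
            scale = 1.0 if pep == cfg.peptides[0] else 2.0
            for allele in alleles:
                br = float(rng.lognormal(math.log(2.0 * scale), 0.6))
                rows.append((pid, alleles[0], alleles[1], pep, round(br, 4)))
    return pd.DataFrame(
        rows, columns=["patient_id", "allele_1", "allele_2", "peptide", "best_rank"]
    )


def _random_cdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(10, 18))
    middle = "".join(rng.choice(list(AA), size=length - 2))
    return "C" + middle + "F"


def _gen_repertoire(cfg: SynthConfig, rng: np.random.Generator, patients: pd.DataFrame) -> pd.DataFrame:
    rows = []
    total_reads = 20_000
    ranks = np.arange(1, cfg.n_clonotypes + 1, dtype=float)
    weights = ranks ** (-cfg.repertoire_zipf_exponent)
    probs = weights / weights.sum()
    for _, pr in patients.iterrows():
        pid = pr["patient_id"]
        counts = rng.multinomial(total_reads, probs)
        keep = counts > 0
        seen = set()
        for c in np.flatnonzero(keep):
            cdr3 = _random_cdr3(rng)
            v = str(rng.choice(V_GENES))
            while (cdr3, v) in seen:
                cdr3 = _random_cdr3(rng)
            seen.add((cdr3, v))
            rows.append((f"{pid}_UCP_specific", cdr3, v, int(counts[c])))
    return pd.DataFrame(rows, columns=["sample_id", "junction_aa", "v_call", "duplicate_count"])


def _gen_patients(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        # comonotone coupling: one uniform drives all peptides, so per-peptide
        # marginals are preserved while responses nest (the pooled responder
        # rate equals the largest per-peptide rate, as observed in the cohort)
        u = rng.random()
        resp = {
            pep: bool(u < cfg.responder_rate_per_peptide[pep]) for pep in cfg.peptides
        }
        any_resp = any(resp.values())
        if any_resp:
            # latent Th1 immunotype mirrors the observed patient repartition:
            # triple+ expanded in about half, the rest split single/double
            itype = str(rng.choice(
                ["polyF_triple", "polyF_double", "singleF"], p=[0.53, 0.21, 0.26]
            ))
        else:
            itype = "none"
        ab = rng.random() < (cfg.ab_rate if any_resp else cfg.ab_leak_rate)
        spread = any_resp and (rng.random() < cfg.spreading_rate_given_response)
        triad = (itype == "polyF_triple") and ab and spread
        rows.append(
            {
                "patient_id": pid,
                **{f"responder_{p}": resp[p] for p in cfg.peptides},
                "responder_any": any_resp,
                "true_immunotype": itype,
                "true_ab_positive": ab,
                "true_spreading": spread,
                "group": "triad" if triad else "other",
            }
        )
    return pd.DataFrame(rows)


def _gen_survival(cfg: SynthConfig, rng: np.random.Generator, patients: pd.DataFrame) -> pd.DataFrame:
    frames = []
    for grp, sub in patients.groupby("group", sort=True):
        lam = cfg.survival_hazard_by_group.get(grp, cfg.survival_hazard_by_group["other"])
        surv = simulate_survival(
            len(sub), lam, cfg.censor_rate, rng, follow_up_months=cfg.follow_up_months
        )
        surv.insert(0, "patient_id", sub["patient_id"].tolist())
        frames.append(surv)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values("patient_id", ignore_index=True)


def generate_cohort(config: SynthConfig | None = None, seed: int | None = None) -> CohortTables:
    """Generate the full synthetic table bundle.

    ``seed`` overrides ``config.seed``.  The seed fans out through
    ``numpy.random.SeedSequence.spawn`` to one substream per table.
    """
    cfg = config or SynthConfig()
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    streams = [np.random.default_rng(s) for s in root.spawn(8)]
    patients = _gen_patients(cfg, streams[0])
    return CohortTables(
        elispot=_gen_elispot(cfg, streams[1], patients),
        ics=_gen_ics(cfg, streams[2], patients),
        elisa=_gen_elisa(cfg, streams[3], patients),
        standards=_standards_table(),
        spreading=_gen_spreading(cfg, streams[4], patients),
        hla=_gen_hla(cfg, streams[5], patients),
        repertoire=_gen_repertoire(cfg, streams[6], patients),
        survival=_gen_survival(cfg, streams[7], patients),
        patients=patients,
    )
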