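# Methods

## Scope and model

`immunotriad` is a deterministic calling-and-association pipeline, not a
parametric model fit: each assay has a published positivity rule, the rules
are conjoined into patient-level immunotypes and the immune-triad flag, and
groups are compared with standard nonparametric survival and rank
statistics. The only fitted objects are the ELISA calibration polynomial,
the Kaplan–Meier product-limit estimator, and the PCA/k-means immune
grouping. The `ImmuneCorrelates`/`ImmuneCorrelatesResults` pair packages
the pipeline in a model-and-results shape so the whole analysis is one
`fit()` away from the raw tables.

## Calling rules and their edge conventions

The rules are stated with their deliberate boundary choices; each is
configurable only where noted.

**ELISpot.** Specific spots = `max(0, mean(stimulated) − mean(background))`
per 3·10⁵ cells. Negative differences are floored at zero (non-physical).
Positive iff `mean(stimulated) ≥ 2 · mean(background)` and specific spots
strictly `> 10`. The fold clause is read on the stimulated mean, not on the
subtracted value; with a background mean of exactly 0 the fold clause is
satisfied by any non-zero stimulated signal (avoids a division by zero
while preserving the intent of the rule). Low/high responder intensity
splits at the per-peptide cohort median of specific spots among
responders; a tie is classed *high* (deterministic, inclusive). Durability
over the boost phase is defined as positivity at ≥ 1 boost timepoint — the
most permissive reading of a response "still detected" — and pooled
immunogenicity as positivity to ≥ 1 peptide at ≥ 1 post-vaccination
timepoint.

**ICS.** Frequencies are percentages of CD4⁺ T cells, background-subtracted
against the unstimulated condition with a floor at zero. A cytokine
combination is positive iff post ≥ 2 × baseline **and** post > 0.05 %;
baseline 0 satisfies the fold clause (the 0.05 % floor still binds). The
patient immunotype is the highest-order positive combination across post
timepoints (triple ≻ double ≻ single ≻ none); the hierarchy makes the
classes mutually exclusive with triple⁺ as the headline subset. Th2/Th17/
Th9/Treg cytokines, when provided, run through the same rule but never
enter the Th1 immunotype. Note a unit inconsistency in the source cohort
description: triple⁺ cells "exceeding 0.2 % of circulating CD4⁺ T cells"
is equated there with 100 cells/mm³, yet 0.2 % of a typical ~719 CD4/mm³
is ≈ 1.4 cells/mm³. `absolute_count` computes strictly
`freq/100 × CD4 count` and the discrepancy is flagged here rather than
resolved by guessing the intended denominator.

**ELISA.** The standard curve regresses concentration on OD with a
degree-2 polynomial (lowest degree that captures ELISA curvature on a
7-point IgG1 series from 0.31 to 20 ng/mL; degree configurable).
Prediction is restricted to the calibrated OD range — out-of-range ODs are
flagged, never extrapolated. Reported titers multiply the well
concentration back by the plasma dilution (1/125 or 1/1000); when both
dilutions are in range the less-diluted well wins. Positivity is
`OD_peptide ≥ 2 × OD_ovalbumin`; a patient already seropositive at
baseline must additionally show a ≥ 2-fold rise of titer or specific OD.
High titer is strictly > 1,000 ng/mL. Note: the source cohort prints an
antibody response rate of "59 % (31/50)"; 31/50 = 62 %, and the rate
function reports the computed 62 % — the printed rounding is not
reproduced by construction. Similarly "15/41 (36.5 %)" computes to
36.59 %.

**Epitope spreading.** Per-antigen calls reuse the ELISpot rule on
per-10⁵-cell IVS counts. An antigen is *de novo* iff negative
pre-vaccination and positive post; any pre-positive antigen is
*pre-existing* regardless of its post call and never counts as spreading.
Antigens are treated independently (a pre-existing response to antigen A
does not block de novo calling on antigen B). A missing baseline makes an
antigen ineligible for de novo (conservative). Breadth is the count of de
novo antigens; class I hTERT hits are tagged intramolecular, class II TAA
hits intermolecular.

**PHBR.** `PHBR = 2/(1/BR₁ + 1/BR₂)` over the two HLA-DRB1 allele best
ranks; homozygotes return their single BR. Any positive lower-is-better
score works as BR — the module never invokes a binding predictor, keeping
the pipeline predictor-version-independent. Only DRB1 is scored.

**Repertoire.** Clonotype identity is (CDR3 amino-acid sequence, V gene);
duplicate rows merge with counts summed in first-appearance order, which
also fixes all tie-breaks. Clonality is defined as 1 for a monoclonal
repertoire (Pielou undefined at n = 1; a single clone is maximally
clonal). Homeostasis bins use the conventional frequency edges
(0, 10⁻⁴] small, (10⁻⁴, 10⁻³] medium, (10⁻³, 10⁻²] large, (10⁻², 1]
hyperexpanded; configurable). Overlap reports the shared-key count as the
primary statistic with Jaccard alongside.

**Outcome.** Triad = polyF triple⁺ Th1 ∧ IgG response ∧ epitope spreading;
patients missing any component are excluded complete-case (matching the
varying per-assay denominators of real cohorts) and counted as
undetermined. Kaplan–Meier medians are the smallest time with S(t) ≤ 0.5
(infinite when never reached); the log-rank is the standard 1-df two-group
chi-square. Mann–Whitney uses the exact permutation null for tie-free
samples up to 25 per arm, the normal approximation otherwise; 2×2 tables
use Fisher's exact test when any expected cell is below 5, chi-square
otherwise. k-means defaults to k = 4 on z-scored features (z-scoring
prevents titer-scale dominance); the PCA/k-means feature set uses
continuous values where available (specific spots) and binary flags
otherwise (triple⁺, antibody, spreading). No multiple-testing correction
is applied anywhere; every p-value is labelled exploratory.

## Synthetic-cohort generator

The generator emulates the study conditions the analysis was designed for:
60 patients, two vaccine peptides, a priming phase plus boosts, and the
full assay battery. Defaults (all `SynthConfig` fields):

- **Responder structure.** Marginal responder rates 0.68 (UCP2) and 0.57
  (UCP4). One uniform draw per patient drives both peptides (comonotone
  coupling), so responses nest and the pooled rate equals the larger
  marginal (0.68) — matching the observed cohort where overall
  immunogenicity equals the UCP2 rate.
- **ELISpot.** Counts are Poisson per replicate well (3 wells): background
  wells at rate 5 spots/well, responder stimulated wells at background +
  effect with effects 84 (UCP2) and 63 (UCP4) — the per-peptide cohort
  median specific counts; only medians, not variances, are published, so
  Poisson is adopted as the standard count-assay noise model.
- **ICS.** Responder post-vaccination combination frequencies are a total
  cytokine-positive mass (log-normal around 0.35 %) split by a Dirichlet
  over the 7 combinations, tilted toward the patient's latent immunotype
  (triple/double/single with probabilities 0.53/0.21/0.26 among
  responders, the published patient repartition); the double tilt favours
  TNF-α⁺IL-2⁺ and the single tilt TNF-α⁺, the predominant observed
  subsets. The Dirichlet construction guarantees the combination-partition
  identity by design.
- **Antibody.** P(IgG response | vaccine responder) = 0.88 and 0.06
  otherwise, derived from the published 30/31 vs 4/19 concurrent-response
  split; the implied marginal (≈ 62 %) matches the published 31/50.
  Responder titers are log-normal(μ = 7.2, σ = 0.8 on the ln-ng/mL scale),
  putting ≈ 60 % of responders above 1,000 ng/mL (published: 61 %).
  Plate ODs come from a fixed mildly saturating quadratic with 3 %
  multiplicative noise, read at both plasma dilutions.
- **Spreading.** P(spreading | vaccine responder) = 0.37 (published
  15/41), zero otherwise — spreading is exclusive to responders by
  construction, as observed. Spreaders acquire 1–3 de novo antigens drawn
  among panel antigens without pre-existing reactivity (5 % of antigens
  carry pre-existing responses that the caller must exclude).
- **HLA/PHBR.** Best ranks are log-normal with the UCP2 scale half the
  UCP4 scale, reproducing the better HLA-DR presentation of UCP2.
- **Repertoire.** 400 clonotypes with Zipf-ranked probabilities (exponent
  1.1), multinomial counts over 20,000 reads, random CDR3s — an
  oligoclonal, hyperexpanded-tail structure.
- **Survival.** Exponential months with group hazards ln 2/19 (triad) and
  ln 2/8.3 (others) — the published group medians; uniform censoring over
  36 months applied to a 0.2 fraction. Exponential + uniform censoring is
  the simplest model with analytic parameter-recovery tests.

One global seed fans out through `SeedSequence.spawn` to one substream per
table: tables are mutually independent and byte-identical across runs with
the same (config, seed).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: inter-patient assay-scale heterogeneity and
plate effects, over-dispersion beyond Poisson/log-normal noise, correlated
longitudinal drift of responses, HLA linkage structure, shared (public)
TCR clonotypes across patients, non-exponential (e.g. delayed-separation)
survival, and informative censoring. The generator validates the pipeline
logic and its statistical calibration, not biological effect sizes.

## Numerical choices

- All "two-fold" clauses are ≥, all ">10 spots" / ">0.05 %" /
  ">1,000 ng/mL" clauses strict, following the literal rule statements.
- D50 and top-k tracking break frequency ties by stable input order.
- KM medians use the product-limit convention S(t) ≤ 0.5; `inf` encodes
  "not reached". A two-group log-rank with zero events returns statistic 0,
  p 1.
- Degenerate inputs raise with the offending field named (empty replicate
  lists, non-positive best ranks, non-monotone standards, missing CD4
  counts, missing baseline panels); nothing is silently imputed.

## Problem sizes used in the checks

The acceptance-style checks run at sizes chosen to keep Monte-Carlo error
well inside the stated tolerances on a single CPU: exponential-median
recovery at n = 1,000 (15 % tolerance vs ≈ 5 % sampling error), log-rank
type-I calibration over 1,000 replicates of 200 subjects per arm
(±0.02 band vs ≈ 0.007 binomial SE), diversity oracles over 1,000 random
repertoires, and the survival-target simulation at n = 2,000.

## Known limitations

- The pipeline calls responses; it does not model assay measurement error
  propagation into the calls (no uncertainty on a positivity call).
- Cox proportional-hazards modelling and reverse-KM follow-up are out of
  scope here (the survival surface is KM + log-rank).
- Published cohort-level survival medians are properties of the patients,
  not of the method; they are recoverable here only by simulating arms
  with the corresponding hazards.
- PHA positive-control wells are recorded but not used to invalidate
  samples (no published rule for control failure).
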