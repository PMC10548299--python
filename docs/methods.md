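# Methods notes

## Donor potential and measures

Donor potential for an OPO-year is the count of death records satisfying all
three CALC conditions: inpatient death, primary cause of death consistent
with organ donation, and age ≤ 75 (the boundary is inclusive). Deaths are
attributed to the OPO serving the county where the death occurred; donors to
the OPO of the hospital county. Both inherit the ADI quintile of the county
of residence, falling back to the death (or hospital) county when residence
is missing — the fallback exists because a small share of death certificates
lack a residence county.

Three measures are computed per OPO-year as percentages of donor potential
*D*: donors, organs transplanted, and kidneys transplanted. The donation
measure is a true proportion (each donor is one potential death, O ≤ D). The
transplant measures are counts per potential — several organs per donor — so
they can exceed 100% and are treated as count-type (Poisson-scale) quantities
for interval estimation.

## Indirect standardization

For adjustment variant *v* with stratum set S(v) — `raw` (one stratum),
`age` (six bins), `adi` (five quintiles), `age_adi` (30 cells) — national
stratum rates are pooled over OPOs within a year, r_s = Σ O_s / Σ D_s.
An OPO's expected count is E = Σ_s D_s r_s, and

adjusted rate = 100 · (O / E) · R_nat, with R_nat = Σ O / Σ D.

Algebraic consequences used as correctness oracles:

* **Conservation**: Σ_OPO E = Σ_OPO O per measure-year when the reference
  rates come from the same cohort.
* **Proportional-mix identity**: an OPO whose stratum mix is proportional to
  the national mix has E = D·R_nat and adjusted = crude.
* **Collapse identity**: if r_s is constant across strata, adjusted = crude
  for *every* OPO, so all four tier variants coincide and reclassification is
  exactly zero.

Events are attributed to strata via the donor's own age and ADI quintile,
which is why donor events carry an age column. Strata occupied by an OPO but
with zero national potential contribute nothing to E and are flagged. E = 0
with O > 0 is an error; E = 0 with O = 0 yields rate 0 with a flag.

Default age bins are 0–14, 15–24, 25–39, 40–54, 55–64, 65–75 (inclusive
upper bound fixed by the CALC definition; interior cuts configurable).

## One-sided 95% upper confidence limits

The donation UCL defaults to the exact one-sided Clopper–Pearson bound, the
95th percentile of Beta(O+1, D−O), which satisfies the tail condition
P[X ≤ O | p = UCL] = 0.05 for O < D and equals 100% at O = D. Wilson and Wald
one-sided bounds are available for sensitivity analysis. Because transplant
counts are not proportions, their bound is the exact one-sided Poisson
(gamma) bound, Gamma(O+1) 95th percentile divided by D — a documented
deviation from naively reusing the binomial machinery on a quantity that can
exceed its denominator. Adjusted UCLs pass the crude bound through the same
O/E scaling as the point rate, so they reduce to the crude UCL whenever
E = D·R_nat.

## Thresholds and tiers

Thresholds for year y are the median and 75th percentile of the *point rates*
(not UCLs) across OPOs in year y−1, computed per (measure, variant). The
percentile rule defaults to the averaged-inverted-CDF definition (the average
of the two straddling order statistics when p·n is integral; SAS's default
definition) — with four rates 10, 20, 30, 40 this gives thresholds 25 and 35.
The rule is configurable and recorded in output metadata because tier flips
can hinge on it. Comparisons use ≥ (meeting a threshold suffices), so
boundary OPOs benefit. OPOs with undefined rates (D = 0) are excluded from
threshold computation and flagged rather than defaulted into tier 3.

The tier is the worse of the donation and transplant groups. Variant
pairings, including the HIOP kidney-only override, are tabulated in
`tiering.py`; the HIOP OPO is configured by code, never hard-wired.

## Reclassification statistics

Movement categories are counted against the *same-year* CALC tier; "into a
lower tier" means a numerically smaller (better) tier. A 3 → 1 move counts in
both "out of tier 3" and "into tier 1". Cumulative change is the share of
OPOs differing from their CALC tier in at least one evaluation year; the
comparison refuses to silently intersect mismatched OPO sets.

The rate-shift test is a Wilcoxon signed-rank on paired (CALC, adjusted)
rates: zero differences are dropped, tied absolute differences get midranks,
and the exact conditional null distribution is computed by a
generating-function convolution over doubled midranks for n ≤ 25 (two-sided
p = 2·min(P≤, P≥), capped at 1); larger n uses the normal approximation with
continuity and tie correction. Percentages are carried at full precision and
display-rounded to one decimal (two decimals below 1%).

Spearman correlations use midranks with the two-sided t-approximation
p-value; an exact permutation p is provided for n ≤ 10 as a small-sample
oracle. County ADI quintiles use ceil(5·rank/n) on ordinal ranks with tied
values forced into the lowest applicable quintile, keeping the assignment
monotone and permutation-invariant; OPO-level quintiles rank the OPOs'
population-weighted median ADI with the same rule. The weighted median is
the lower-median convention (smallest value whose cumulative weight reaches
half the total), so tests can assert it exactly.

## Synthetic cohort generator

The generator emulates the *structure* the analysis consumes, at a scale a
desktop run can afford, not the real national registries:

* **Counties**: dealt evenly to OPOs in seeded random order (sizes differ by
  at most one county), so every OPO serves a workable population, mirroring
  how DSAs partition counties. ADI = OPO-level center (sd `opo_adi_sd`,
  default 10) plus county noise (sd `adi_spread`, default 12), clipped to
  [1, 100]; populations are lognormal (default mean 40 000, σ = 0.8, floor
  500).
* **Deaths**: Poisson county-year counts at an annual crude death rate of
  1.15% with an old-skewed age profile (46% of deaths over 75). CALC
  eligibility is drawn per record with probability `calc_fraction` (default
  0.062 for deaths aged ≤ 75, i.e. ≈ 3.3% of all deaths) and materialized as
  the inpatient/cause flag pair the filter reads; ineligible records never
  carry both flags with age ≤ 75, so the filter — not a rate — defines
  potential. Residence equals the death county except with probability
  `p_cross_dsa` (default 0.04) when it is drawn from another OPO's county,
  and is missing with probability `p_missing_residence` (default 0.002).
* **Donors**: each CALC death becomes a donor with probability
  `donation_propensity(age bin, ADI quintile) × opo_effect`; organ yields are
  1 + Poisson(mean − 1) (default mean 3.0) with kidneys Binomial within
  organs (default mean 1.5), so kidneys ≤ organs by construction.

One integer seed drives everything through per-table `SeedSequence` child
streams; identical configs reproduce identical tables record-for-record.

Stratum-level donation propensities are free scenario parameters, not
estimates of the real system. Scenarios:

* **null** — the exact-collapse configuration: propensity 1 in every
  stratum, unit OPO effects, and fixed integer organ/kidney yields (3 and 1).
  Every stratum rate is then exactly constant, the collapse identity holds to
  machine precision, and reclassification is exactly 0% for every seed. This
  is deliberate: with Bernoulli draws at any cohort size, sampling noise in
  stratum rates and the margins of near-threshold OPOs shrink at the same
  1/√n rate, so occasional tier flips would never vanish; the null scenario
  is therefore a degenerate consistency stress test of the standardization
  and tiering algebra, not a realistic cohort.
* **adi_confounded** — propensity (0.24, 0.20, 0.15, 0.10, 0.06) across ADI
  quintiles 1–5, unit OPO effects, larger between-OPO ADI spread
  (`opo_adi_sd` = 14): apparent OPO differences are pure population
  confounding that ADI adjustment should remove and age adjustment should
  not.
* **quality_varying** — flat propensity 0.15 with lognormal OPO effects
  (σ = 0.25): genuine quality differences that adjustment should preserve.

What the generator does **not** emulate: ICD-coded cause detail, hospital
identifiers, within-county deprivation heterogeneity, year-to-year crosswalk
changes, secular mortality trends, or the county comorbidity surfaces
(obesity, diabetes, CKD, cancer, CLD) — those are accepted as optional input
columns only. Passing tests therefore demonstrate the correctness and
internal consistency of the metric machinery on cohorts with known
structure; they do not certify national-registry estimates.

## Problem sizes

Default scenario sizes were chosen so a full 20-seed sweep of the 58-OPO,
four-year pipeline completes in about a minute on one CPU while keeping
per-OPO donor potential near 65 per year (≈ 10 donors): 232 counties of mean
population 38 000 (≈ 100 000 deaths and ≈ 3 500 CALC deaths per year) for the
stochastic scenarios, and 116 counties of mean population 15 000 for the
null consistency sweep. These are scaled-down study conditions; rates and
reclassification percentages are computed identically at any scale.

## Known limitations

* The exact one-sided CI formula used operationally by CMS is not public in
  detail; the Clopper–Pearson default (with Wilson/Wald alternatives and the
  Poisson-scale bound for count measures) is this package's declared choice.
* Whether the operational age adjustment of transplant rates uses exactly
  this indirect-standardization algebra is likewise a declared assumption.
* The threshold percentile definition is not standardized across software;
  the SAS-compatible default is recorded in output metadata.
* County ADI is static across years; waiver counties and appeal processes
  are out of scope.
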