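# Methods

## Problem setting

Cancer registries built principally from hospitalization discharge abstracts
undercount patients whose disease is diagnosed and managed entirely in
outpatient settings — disproportionately younger and more socioeconomically
privileged patients. `crcclaims` implements claims-based case-ascertainment
algorithms for incident colorectal cancer (CRC) over linked administrative
health data — physician fee-for-service billing claims and hospital
admissions keyed by an anonymized person identifier — together with the
registry-concordance analysis and the descriptive epidemiology used to
evaluate such algorithms.

## Case-finding algorithms

Three algorithms are available, all producing at most one incident case per
person (the first qualifying event wins; no recurrence detection):

* **A1 — inpatient.** Any hospital admission with a CRC diagnostic code in
  any diagnostic position. Diagnosis date = admission date of the earliest
  qualifying admission.
* **A2 — outpatient two-claim rule.** Two CRC-coded billing claims on
  distinct service dates `d1 < d2` with
  `min_separation_days ≤ d2 − d1 ≤ max_window_days` (defaults 30 and 730,
  both bounds inclusive). Diagnosis date = the smallest `d1` participating
  in any qualifying pair. The separation floor filters isolated "rule-out"
  codes recorded while a work-up is still in progress; the window keeps the
  two signals within a two-year episode.
* **A3 — union.** A person qualifying under A1 and/or A2, dated at whichever
  signal comes first.

**Treatment confirmation** scans all of a person's billing act codes and
hospital intervention codes for CRC-directed treatment (surgery,
chemotherapy/radiotherapy, other) anywhere in the study period — before or
after the assigned diagnosis date, since treatment billing can precede the
diagnostic coding episode. Restricting to treatment-confirmed cases is a
monotone filter that raises positive predictive value at the cost of
dropping genuinely untreated (e.g. palliative or refusing) cases.

Design choices where the convention was genuinely open:

* *Two-year window as 730 days, inclusive bounds.* Day arithmetic is
  reproducible across calendars; calendar-month conventions are not.
* *Duplicate same-date claims collapse to one date* and can never satisfy
  the separation rule on their own — a guard against duplicate billing lines.
* *Any diagnostic position* of an admission qualifies; principal-diagnosis
  restriction is not imposed.
* *The two billing claims need only distinct dates*, not distinct physicians
  or claim lines.
* *No prevalence washout by default.* An optional `lookback_days` argument
  drops cases assigned within that many days of period start, off unless
  requested.
* *Site ties* (colon and rectum codes on the same earliest evidence) resolve
  to colon and are logged; with realistic coding this affects well under 1%
  of cases.

## Code sets

Diagnostic codes match by normalized prefix (dots stripped, upper-cased):
ICD-9 `153` (colon), `1540`/`1541` (rectosigmoid junction, rectum); ICD-10
`C18` (colon), `C19`/`C20` (rectum). Anal-canal codes (ICD-9 154.2+, ICD-10
C21) are excluded. `C19` and `154.0` map to rectum, a common registry
convention. Nested prefixes within one ICD version are rejected at load time
to prevent double counting, and each treatment code may belong to exactly
one therapeutic group. Treatment/billing-act codes are jurisdiction-specific
and carry no hierarchy, so they match exactly; the packaged treatment codes
are an explicit placeholder taxonomy used by the simulator and tests — real
deployments supply their own list via a YAML config.

## Concordance analysis

The registry is the reference. Matching is **by person identifier only** —
no date or site agreement required — because registry diagnosis dates are
assigned by different rules than claims dates and differ systematically.
Each person is *concordant* (both sources), *newly captured* (algorithm
only) or *registry-only* (registry only); treated status for registry-only
persons comes from running treatment confirmation over their events. The
summary table's percent-difference column is computed on **treated totals**
(`100·(n_alg − n_reg)/n_reg`), the comparison that isolates
treatment-corroborated case-finding from rule-out noise. All internal
arithmetic is unrounded; presentation rounds half-up to one decimal at write
time only.

## Epidemiologic statistics

* **Proportions** use the Wald interval `p̂ ± z·sqrt(p̂(1−p̂)/n)` with
  `z = 1.959964` at 95%, truncated to [0, 1]. On the concordant-surgery
  worked example (9,896/11,476) the closed form gives an upper bound of
  86.9% where a published rendering of the same cell prints 86.8; the
  package reports the computed value and documents rather than reconciles
  the one-unit-last-decimal difference (the source's exact CI method and
  rounding pipeline are unstated).
* **Two-proportion comparisons** use the pooled-variance z-test, two-sided;
  `z²` equals the 2×2 Pearson chi-square without continuity correction, and
  the test suite cross-checks against `scipy.stats.chi2_contingency`.
* **Relative difference** is `100·(p1 − p2)/p1`, undefined (NA) at `p1 = 0`.
* **Direct age standardization**: `Σ_g (cases_g/pop_g)·w_g·100000` with
  weights `w_g` from a fixed reference population. The result is a convex
  combination of stratum rates; a reference proportional to the study
  population recovers the crude rate. Default age grouping is 5-year bands
  20–24 … 85+; the packaged reference population is a **synthetic stand-in**
  with a plausible mid-2000s urban adult age structure — analyses of real
  data should supply the jurisdiction's census table.
* **Rate series**: cases bin by calendar year of the assigned diagnosis
  date; calendar years only partially covered by the (fiscal,
  April-to-March) study period are dropped, so the default ten-fiscal-year
  window yields 2001–2009. Mid-year (July 1) cohort counts are the
  denominators.
* **Characteristics table**: rows are total, sex, age bands {<50, 50–69,
  70+}, deprivation quintiles Q1–Q5 (Pampalon material deprivation, Q1 most
  privileged) and site; treatment proportions use the row-by-group subgroup
  as denominator, so "concordant, female, surgery" is the share of
  concordant treated women who received surgery.

## Synthetic cohort generator

The simulator produces the linkage structure above with known ground truth.
What it emulates, and the defaults chosen as the study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_persons` | 200,000 | large enough for stable rate and concordance estimates on one CPU |
| study period | 2000-04-01 – 2010-03-31, age 20+ | ten fiscal years of adult coverage |
| age mix | 5-year bands, mid-2000s urban adult shape | matches the packaged reference population |
| incidence | 1.5 → 350 per 100,000/year across bands | steeply age-graded, typical North-American CRC surveillance values for the 2000s |
| site split | colon 0.67 / rectum 0.33 | standard CRC site distribution |
| `p_hospitalized` | 0.80 | most but not all incident CRC reaches hospital |
| registry capture | 0.98 hospitalized / 0.05 outpatient-only | encodes a hospitalization-driven registry |
| capture multipliers | 0.90 under-50, 0.95 for Q1–Q2 | mild differential undercount of younger and privileged cases |
| treatment | surgery 0.80, chemo/radio 0.60 (independent) | ~8% of cases carry no treatment code |
| CRC claims per case | 1 + Poisson(3) over a 180-day horizon | diagnostic episode after onset |
| rule-out noise | 0.5% of non-cases emit CRC codes; 10% of those form a qualifying pair | isolated claims the two-claim rule must ignore, plus a small residual false-positive channel |
| background claims | Poisson(2) non-CRC claims per person | linkage realism |

Mechanics: incidence is drawn as per person-year Bernoulli trials at the
person's current age band, so the configured age-specific rates are exact
annual risks and are recoverable by `rate_series`. Onset dates are uniform
within each year-slice, with a guard keeping the 180-day claim horizon
inside the period (so tests are free of edge censoring; set
`edge_censoring=True` to disable). All randomness flows from one seed
through named substreams (`persons`, `cases`, `registry`, …), so adding a
parameter never perturbs unrelated draws and a fixed seed is byte-identical.

What the simulator does **not** reproduce — and hence what passing tests do
not show about real data: coding errors and version drift, migration in and
out of coverage, mortality (death dates are left empty by default),
day-surgery ambiguity between the billing and admission files, stage and
recurrence, and any calibration of the capture probabilities to a real
registry (no quantitative capture probabilities are published; defaults
reproduce the qualitative mechanism, not exact counts).

## Numerical and degenerate-input conventions

Rounding is decimal half-up, applied only at presentation. Percent
differences and untreated shares with zero denominators are NA, never 0.
A standardization stratum with cases but zero population is an error; an
empty stratum (0/0) contributes zero. Events before birth or after death
are rejected during reading (post-death with a warning); period and age
filtering is idempotent. Output ordering is deterministic (by person
identifier) and invariant to input row order.

## Problem sizes

The test suite and the reproduction script run the full pipeline —
simulate, three algorithms, concordance, rates, reports — at 200,000
persons (roughly 1,900 incident cases over ten years), which completes in
well under a minute per run; worked-arithmetic checks are instantaneous.
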