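# Methods

## Problem and model

In a regionalized trauma system, a seriously injured patient who first
reaches the emergency department (ED) of a nontrauma or level III/IV center
should be *re-triaged* — emergently transferred — to a level I/II trauma
center. This package analyzes administrative discharge data to classify each
re-triage as **optimal** (receiving center holds a level I or II designation
that year) or **suboptimal** (receiving center is itself nontrauma or level
III/IV), and to quantify, model, and hypothetically repair the geography of
suboptimality.

The data model mirrors statewide ED/inpatient discharge datasets: records
carry a pseudonymous record-linkage number (RLN), date-only stamps, coded
dispositions and covariates, and a precomputed injury-severity score (RISS)
field. RISS derivation from ICD codes is out of scope; RISS is consumed as
an input column.

## Linkage and cohort definition

Exact duplicate rows (same RLN, facility, record kind, admission and
discharge date) are collapsed before linkage. A re-triage pair is a sending
ED encounter and a receiving encounter at a *different* facility under the
same RLN with

    gap_days = receiving admission date − sending ED discharge date ∈ {0, 1}.

The 1-day window is inclusive of same-day transfers because date-only
stamps cannot separate a late-night departure from an early-morning
arrival; candidates at gap ≥ 2 days are nonemergent interfacility transfers
and are excluded. When several receiving encounters qualify, the earliest
admission wins, ties broken by lexicographic facility id.

The inclusion/exclusion cascade is applied to every deduplicated ED
encounter in a fixed, published order with first-match attribution:

1. missing RLN; 2. age outside 18–89; 3. no injury diagnosis (null RISS);
4. RISS ≤ 15 (inclusion requires RISS > 15, strictly); 5. burn injury;
6. sending facility holds a level I/II designation that year (direct field
triage); 7. sending facility not a low-level short-term acute hospital;
8. sending disposition expired / left against medical advice /
rehabilitation-with-planned-readmission; 9. interfacility transfer (gap
≥ 2); 10. elective receiving admission; 11. receiving facility not
short-term acute (rehab/psychiatric/long-term).

The source protocol does not publish its rule order; the order above is a
package choice. Per-rule removal counts depend on it; the final cohort does
not. The cascade partitions ED encounters exactly into {cohort pair,
under-triaged-not-transferred, excluded-with-reason}, and the ledger's
removals plus survivors reconcile to the deduplicated input count — both
are enforced by tests and by a post-run consistency check.

Trauma levels are annual; both the sending and receiving designation are
resolved at the sending discharge year so that labeling is a pure function
of (receiving level, year).

## Rates and hierarchy

Suboptimal counts and rates are aggregated at state, RTCC (regional trauma
coordinating committee), LEMSA, and sending-center level, per year and
pooled, with each unit's share of statewide suboptimal re-triages. Units
with zero re-triages are omitted rather than reported as rate 0 — an
undefined rate must not masquerade as a perfect one. Rates are reported to
one decimal in percent. Center summaries use as denominator the number of
sending-eligible (low-level, short-term acute) centers operating that year;
the ≥ 40 %-suboptimal stratum uses centers with at least one re-triage and
an inclusive threshold.

## Hospital-course outcomes

Receiving-center dispositions collapse into HOME / DIED / SHORT_TERM_ACUTE /
POST_ACUTE through a configurable mapping with documented defaults. Length
of stay is discharge minus admission in whole days. Readmission within 10,
30, 60 days is any later inpatient encounter under the same RLN at any
short-term acute facility with an admission 1..W days after the receiving
discharge: day 0 is a transfer, not a readmission, and day W counts
(boundaries are a package choice; the source text states none). Patients
who die before discharge carry null flags and leave the denominators.
Contrasts between suboptimal and optimal strata use Pearson chi-square
without continuity correction and crude 2×2 odds ratios with Woolf
log-normal intervals; any zero cell triggers the Haldane–Anscombe 0.5
correction with a flag.

## Mixed-effects model

Suboptimality is modeled with a binomial GLMM (logit link): fixed effects
for age band (18–24 reference), sex (male), race (White), ethnicity
(non-Hispanic), insurance (self-pay), mechanism (all transport), body
region (torso), RISS band (16–25), and sending-center RTCC (Central);
crossed Gaussian random intercepts for sending center and year. Year enters
as a grouping factor, not a trend (a linear-trend fixed effect is available
behind `ModelSpec.year_trend`). Crossed rather than nested effects because
centers persist across years.

Estimation is the Laplace approximation to the marginal likelihood, the
same approach lme4's `glmer` uses at default accuracy:

- inner loop: Newton iteration on the penalized log-likelihood of the joint
  coefficient vector (β, u), with sparse design algebra and step halving;
- outer loop: Nelder-Mead over the two log standard deviations of the
  Laplace profile `h(β*, u*) − ½ log det(H_uu · D)`, with log σ clipped to
  [−6, 3].

Wald intervals come from the (β, u)-block inverse of the joint Hessian at
the optimum, exponentiated to odds ratios. As σ → 0 the fit collapses to
ordinary logistic regression (verified to 1e-5 against a statsmodels GLM);
the fit is also cross-checked against `glmer` on simulated data (max
coefficient difference ~0.01, standard errors to 5e-4, σ's to three
decimals). The joint-posterior-mode fitter in statsmodels was rejected
because its objective is unbounded as σ → 0, which biases fixed effects in
weak-clustering data.

Complete separation in a dummy column raises a warning naming the
covariate; a constant outcome or a single-level grouping factor is an
error.

## Transfer network

Labeled events aggregate into a directed graph: one edge per ordered
(sending, receiving) pair in the selected year, edge weight = that pair's
share of the year's re-triages (weights sum to 1), category OPTIMAL /
SUBOPT_TO_NONTRAUMA / SUBOPT_TO_III_IV. Normalization is per selected year.
Layouts are geographic (lon/lat) or Fruchterman–Reingold with a fixed
iteration count (500) and seed, so layouts are reproducible. Exports:
GraphML, GeoJSON, and a static plot where width encodes volume and color
the category.

## Destination optimization

For each suboptimal event the candidate set is the level I/II short-term
acute centers operating that year. The transport rule: ground is assumed
fastest below 50 miles, air at or ≥ 50 miles (the boundary goes to air).
Air time is great-circle miles / 120 mph — a deliberately conservative
fixed speed with no dispatch or ground-leg delays, which cannot be
estimated from data lacking transport type. Ground time comes from a
pluggable drive-time provider; the built-in fallback is great-circle miles
× circuity 1.3 / 40 mph (both config-exposed). Selection: if any candidate
lies within 50 great-circle miles, the shortest ground time among those;
otherwise the shortest air time over all candidates; ties break by facility
id; an empty candidate set yields `resolvable=False` as a data outcome. The
50-mile screen uses the provider's road distance when it exposes one, else
great-circle distance (the default). Great-circle distance uses the
haversine formula with Earth radius 3958.8 miles.

## Synthetic data: what it emulates, and what it does not

The generator draws a hospital directory (configurable counts per level per
region, coordinates inside per-region bounding boxes mimicking dense-urban
vs sparse-rural geography, annual designations with optional mid-horizon
level changes, LEMSA/RTCC membership) and a patient population. Default
study conditions: 10 years (2009–2018); 80 % of seriously injured patients
present first to a low-level center; 20.6 % of those are re-triaged within
the window; per-region baseline suboptimality {North 0.22, Bay Area 0.375,
Central 0.104, South-East 0.202, South-West 0.688}; 25 % of ED records
missing RLNs; 5 % duplicate rows. Suboptimality is assigned on the logit
scale: region baseline + configurable covariate log-odds + Gaussian random
intercepts for center and year. Covariate marginals default to a plausible
elderly, fall-dominated transfer population (~59 % male, majority ≥ 65)
but carry no claim of demographic fidelity — the joint distribution of real
covariates is unknown, so passing tests demonstrate pipeline correctness
and estimator calibration, not epidemiological realism. Edge-case rates
inject records firing every exclusion rule. Everything is driven by one
seeded generator; identical configs give byte-identical outputs.

Dates are date-only; ED stays are same-day; duplicates are exact row
copies; missing RLN is a true null, never an empty string. The generator
does not simulate ICD code strings, prehospital vitals, seasonality, or
transport logistics.

## Problem sizes and numerical choices

Unit tests run at 4,000–5,000 patients; partition/recovery and GLMM
recovery checks at 20,000 patients, 100 centers, 10 years, with 20
simulation seeds for recovery/coverage (the reproduction script uses 5
seeds for the same quantities). Newton tolerance 1e-9 (1e-11 for the final
polish), Nelder-Mead xatol 1e-3. Rate shares are checked to 1e-9; the
zero-cell odds-ratio path and degenerate chi-square tables raise or flag
rather than silently correcting.

## Known limitations

- The cascade's per-rule counts are order-dependent by design; comparisons
  across implementations require the same published order.
- Readmission ORs are crude (unadjusted) 2×2 ratios.
- The fallback drive-time model ignores road networks entirely; it is a
  circuity-scaled great-circle estimate, adequate for rule exercising and
  screening, not for operational routing.
- With date-only stamps, a same-day ED discharge/receiving admission at
  gap 0 cannot be distinguished from rapid interfacility churn; the window
  rule is the best available proxy.
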