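# Methods

## Model

Linkage compares candidate record pairs on an ordered identifier set,
by default {date of birth, sex, postcode}.  Agreement is binary per
identifier (exact string match after trimming and case-folding); a missing
value on either side — or both — scores as disagreement.  There is no
partial or phonetic agreement level.  A pair's evidence is its agreement
pattern φ, one of 2^k possibilities; pairs agreeing on nothing, or on sex
alone, are treated as certain non-matches and removed before estimation
(`prefilter_pairs`), since chance agreement on a two-category field carries
no information.

m- and u-probabilities are estimated by supervised counting from pairs with
a gold-standard match label: `m_k` is the fraction of matched pairs
agreeing on identifier k, `u_k` the same among non-matches; the joint
variant counts whole patterns instead.  Every estimated probability is
clamped to `[1/(2N), 1 − 1/(2N)]` (N the relevant denominator) so that all
log-ratios stay finite; pattern-level tables are renormalised to sum to one
after clamping, which preserves ratios between observed cells.  Unobserved
patterns therefore carry a floor mass of roughly `1/(2N)` rather than zero:
a deliberate choice that keeps joint weights defined for every pattern, at
the cost of mildly optimistic weights for match-only patterns whose
non-match probability is below the floor.

u-probabilities are conditioned on whatever pair set the caller supplies.
The CLI applies the prefilter by default, so u denominators refer to the
*retained* comparison space; post-filter conditioning induces negative
dependence between identifiers among non-matches, which is one reason the
joint and traditional weight scales differ even when errors are generated
independently (their rank orders still agree; see the property tests).

### Weight variants

* **traditional** — full Fellegi–Sunter sum with agreement and
  disagreement terms, log base 2 throughout.
* **joint** — `W = log2(m_φ / u_φ)` from the pattern-level table.
* **attribute** — traditional-form weights from per-stratum m/u tables
  keyed by (age cohort, sex, ethnic group); 3×2×6 = 36 possible strata.
* **organisation** — the same, keyed by hospital.

Stratified variants use per-identifier (independence) estimation only:
pattern-level tables within strata would rest on cell counts too small to
be stable.  A stratum whose match count falls below `min_stratum_matches`
(default 100 for attribute strata, 500 for hospitals, both configurable)
falls back to the global table, as does any stratum unseen at fit time.

### Threshold calibration

Pairs are rank-ordered by weight and the cut-off is the smallest observed
weight c such that, among pairs with weight ≥ c, the fraction of
non-matches (false-match rate among accepted) is at most the target,
default 1%.  Ties at the cut-off are accepted together; the search runs
over observed weights only, making the result deterministic.  If no weight
qualifies, the cut-off is +∞ and nothing is accepted.  One global cut-off
serves all strata; per-stratum calibration would be a natural extension but
is not provided.

### Identifier-error model

Error records are matched pairs stacked over identifiers
(`error = 1 − agreement bit`), so error-rate point estimates coincide with
`1 − m_k` up to clamping.  Risk is modelled by logistic regression on age
cohort, sex and ethnic group (reference levels: infants 0–1, male, White)
plus an identifier fixed effect in the pooled fit.  With
`include_random_effect` a hospital random intercept is added and the
marginal likelihood is maximised directly: observations are collapsed to
binomial counts per (hospital, covariate pattern), each cluster's integral
is recentred at its posterior mode (Newton iterations) and rescaled by the
local curvature, then evaluated with a 15-node Gauss–Hermite rule —
adaptive quadrature, which remains accurate for the large, informative
clusters where fixed-node quadrature fails.  Convergence tolerance is
1e-11 on the scaled objective; standard errors come from the
finite-difference observed information.  Non-convergence and separation are
flagged on the result object, never raised.  A test cross-checks the fit
against `lme4::glmer` (nAGQ = 15) on a small fixture.

Funnel limits for hospital comparison use the normal approximation on the
proportion scale, `rate ± z·sqrt(rate(1−rate)/n)` with z = 1.959964 (95%)
and 3.090232 (99.8%, the two-sided control-chart convention), truncated to
[0, 1]; an exact-binomial option is available.

## Synthetic data generator

The generator emulates a gold-standard-validated extract of admission
records.  Individuals draw attributes from a configurable mix (defaults:
three equal age cohorts; equal sexes; ethnic groups White 0.70, Asian 0.10,
Black 0.06, Missing 0.06, Mixed 0.04, Other 0.04 — a plausible English
hospital casemix) and a uniformly assigned hospital.  A fraction
(default 0.088) is readmitted and contributes one true-match pair.

Identifier error is modelled on the log-odds scale:
`logit P(error) = baseline_k + attribute effects + hospital intercept`,
with hospital intercepts N(0, sd²).  Defaults:

| parameter | default | basis |
|---|---|---|
| marginal error rates | dob 0.0011, sex 0.0011, postcode 0.53 | observed rates in the reference extract |
| female vs male odds | 0.84 | reported attribute effect |
| 5–6y, 18–19y vs infant odds | 0.39, 0.37 | reported attribute effects |
| ethnic-group odds (vs White) | Missing 1.5, Mixed 1.1, Asian 0.89, Black 1.1, Other 0.95 | Asian as reported; others set to the described qualitative ordering (Missing highest, Asian lowest) |
| hospital sd (log-odds) | 0.5 | a modest organisational spread consistent with visible funnel scatter |
| hospitals | 388 | reference extract |

The *baseline* intercepts are calibrated (Brent root-finding, integrating
over the attribute mix and the hospital distribution by quadrature) so that
the population-marginal error rate equals the configured value exactly;
the attribute effects then redistribute that marginal across strata — e.g.
infant postcode error ≈ 0.70 versus ≈ 0.45 in the older cohorts at the
defaults.

Matched pairs receive agreement bits directly from pair-level Bernoulli
draws at these probabilities, so configured rates are pair-level
disagreement rates.  Non-match pairs are cross-paired within age-cohort
blocks (default volume 0.75 pairs per individual, representing a moderately
blocked candidate space) and agree on an identifier only when the two
individuals' actual values coincide (birthdays uniform over 365 days,
postcodes uniform over 1,500 values, sex from the mix) *and* neither side
is corrupted.  Non-match pairs carry the attributes and hospital of their
first record.  All randomness flows through a single `numpy` Generator;
identical seeds give byte-identical output.

### Unique-identifier scenarios

The unique identifier (an NHS-number analogue) enters only as a tri-state
flag on each pair.  Scenarios corrupt matched pairs: A and B are i.i.d. at
30% and 0.5%; C keeps a 30% marginal but doubles the *probability* (not
odds) of corruption when any other identifier disagrees, solving
`r·P(clean) + 2r·P(error) = 0.30` exactly; D distributes the 30% across
ethnic groups proportionally to a profile, by default the generator's own
ethnic-group error effects.  Non-matches never agree on the unique id.

### The study loop

Weight models are fitted once from a large training extract (340,000
individuals ≈ 30,000 matched pairs, with a deeper 3,000,000-pair non-match
sample to stabilise per-stratum u estimates), then each replicate draws a
fresh study population, overlays the scenario, and links in two stages:
deterministic accept on unique-id agreement, then probabilistic
classification of the remainder under each weight variant with the cut-off
recalibrated per replicate.  Accepted pairs (true and false) are edges in a
record graph; the readmission estimate is the fraction of connected
components holding ≥ 2 records, so missed matches both shrink the numerator
and inflate the denominator, and false matches merge strangers.  Percent
bias compares the mean estimate to the mean realised prevalence, which is
recomputed per replicate rather than fixed at 8.8%.

Reported study sizes: 20,000 individuals per replicate, 100 replicates per
scenario in the acceptance suite (20 in the example script), 50 hospitals in
the study configuration so that per-hospital training strata clear the
500-match fallback threshold.  Per-replicate Monte-Carlo error on the
estimated rate is ≈ 0.2 percentage points, so 100 replicates pin method
means to ≈ 0.02 points — ample for the ordering comparisons.

## What the generator does and does not show

Passing tests demonstrate internal consistency: planted rates and effects
are recovered, weights match counting oracles, calibrated thresholds meet
their guarantee, and stratified weights reduce readmission-rate bias
whenever identifier error varies by attributes or organisation and
unique-id error is substantial.  The generator does *not* reproduce a real
extract's joint pattern frequencies: identifier errors are conditionally
independent given stratum and hospital (real data show mild dob–sex
dependence), postcode values have no geography or household clustering,
identifiers do not change over time, and both records of a readmitted
individual share one hospital.  Consequently the *sizes* of the bias
reductions here are smaller than those reported for the private reference
data — stratification there captured an 83%-vs-40% postcode missingness
split, sharper than the default effects produce — while the directions are
the same.  Scenario B (0.5% random unique-id error) yields near-zero bias
under the two-stage design, because almost every match is linked
deterministically; published results for that scenario appear to reflect a
different use of the unique identifier, which the source does not specify.

## Degenerate inputs and numerical conventions

Estimation requires at least one match and one non-match and raises
otherwise; dependence tests return flagged results for empty 2×2 margins or
an identifier tested against itself; scenario C raises when the implied
dependent rate exceeds 1; funnel limits require a rate strictly inside
(0, 1).  Weights are log base 2 everywhere.  Probabilities are serialised
at full precision in JSON and rounded only in human-readable tables
(weights to 1 decimal place, probabilities to 4).
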