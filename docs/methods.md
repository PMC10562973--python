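# Methods

This note documents the models, conventions and numerical choices behind
`iqcapture`, and what its synthetic data can and cannot show.

## Branching questionnaire model

A questionnaire is an ordered item list plus branch rules
(`trigger item` × `trigger options` → `revealed items`). Items with no
incoming branch are *top-level* and always visible; everything else is
revealed transitively. The reveal graph must be a DAG (validated); arbitrary
finite depth is supported, though the packaged preadmission instrument uses
at most two levels (e.g. drinking → beverage types → beer quantities). A
multi-choice answer triggers a branch when **any** selected option is a
trigger option, consistent with the interview-stub behaviour where each
selected restriction opens its own text box.

`enumerate_answer_paths` computes the exact min/max visible-set size by
searching over the distinct *branch-activation signatures* of every trigger
item rather than over raw answers: for a single-choice item, each option
maps to the set of branch rules it fires; for a multi-choice item the
signatures are unions over nonempty selections. A complete response must
answer every visible item, and multi-choice answers are nonempty by type —
so the empty selection is not a legal path, and "no-op" answers exist only
where the instrument offers an explicitly non-triggering option ("No
restrictions", "None of the above"). This is exact for any DAG and agrees
with brute-force assignment enumeration (property-tested on random
definitions).

Free-text items are supported by the model but absent from the packaged
instrument: small-screen entry is a poor fit for detailed prose, which is
exactly what the interview-stub mechanism hands to the nurse instead.

## Fixtures

The packaged questionnaire (15 top-level questions on ADLs, weight change,
dietary restrictions, drinking and smoking; path bounds 15–53), profile
template (77 sections over Gordon's 11 functional health patterns) and
quotation ruleset (20 quoted sections in 5 patterns; none in sleep/rest,
self-perception/self-concept, role/relationship, sexuality/reproduction,
coping/stress tolerance, values/beliefs) are *structurally faithful
skeletons*: the published architecture and all printed exemplars are
reproduced exactly, but the full item and section wording of the deployed
instrument is not public, so the remaining content is plausible filler
authored for this package. Structural counts computed on these fixtures are
therefore exact; per-item wording is not authoritative.

## Quotation engine

Rules are applied in ruleset order; at most one non-stub rule may target a
field (validated), so order affects only the reporting of skipped rules.
Conventions:

* **Terminology conversion** never guesses: an option absent from the map
  leaves the field for manual entry and records the rule as skipped,
  mirroring the workflow in which the nurse reviews and corrects quoted
  data. For multi-choice sources each selected option is mapped
  independently; unmapped selections are reported.
* **Aggregation** uses an ordered case list (first match wins) on the source
  answers; the optional comment instantiates a template with the
  contributing answers and is emitted only when every referenced answer
  exists.
* **Calculations**: pure alcohol in grams = volume × cans × 0.8 ×
  alcohol-fraction (0.8 g/mL ethanol density factor; fraction is
  per-beverage configuration, 0.05 for beer — the only beverage with a
  printed constant, and the only one in the packaged ruleset); units =
  grams / 20 (the Japanese standard drink). Smoking duration is quit − start
  age for ex-smokers and current − start for current smokers (the current
  age comes from the case record via an `apply_ruleset` argument, not from
  the questionnaire). Presentation: grams rounded half-up to an integer,
  units to one decimal; underlying arithmetic is exact. Implausible numeric
  combinations (quit age before start age) skip the rule with a reason
  instead of failing the whole document — data entry problems are the
  nurse's call, not the engine's.
* **Interview stubs** are empty text-entry values flagged `stub=True` with
  questionnaire provenance; they count as *unfilled* in the registered-item
  metrics, since the nurse has yet to type the content.

Application is deterministic and idempotent; every produced value carries
`questionnaire` provenance, and no untargeted field is ever touched.

## Two-zone relay

Tokens are 128-bit hex strings (uniqueness enforced by the store); URL and
QR payload are the same string and embed only the token. The outside-zone
record type has *no patient field at all* — the privacy guarantee is
structural, not a filtering step — and the fuzz tests assert that a full
serialization of the outside store never contains any issued patient
identifier under randomized operation sequences. Transfer is strictly
one-way (outside → inside): payloads are copied inward, re-keyed to patient
identity via the inside URL table, and deleted outside; outside tokens with
no inside binding are quarantined with an audit entry rather than imported.
Resubmission overwrites the previous payload until registration, which
freezes it (the inside table is authoritative for that state). Responses are
serialized as XML (`iqcapture-response-1` schema) with typed numeric values;
round-tripping is lossless for all generator-produced responses. Token
expiry is supported as configuration but has no default. No real network or
firewall is modelled; the direction contract lives in the API surface.

## Synthetic cohort

The generator emulates a ~2425-case scheduled-admission cohort split into
questionnaire use / no-use groups. Defaults: use fraction 1326/2425;
internal-medicine ward fraction 0.46 (use) / 0.25 (no-use); independent-ADL
(bedriddenness rank J) fraction 0.84 / 0.74, with dependent cases spread
over ranks A/B/C at 0.5/0.3/0.2 (the within-dependent split is not
reported; chosen once as a plausible skew toward milder dependence); ward
and ADL sampled independently within group (their joint distribution is not
reported). Per-case documentation volumes are normal draws around
single-choice median 56 (both groups) and multi-choice 16/15, and
negative-binomial character counts centred on medians 237/208 via a
Wilson-Hilferty median↔mean approximation.

Input times are lognormal per stratum, specified as (median, sigma):
right-skewed and positive, consistent with a mean well above the median.
Defaults are medians 9.4 (use) and 10.1 (no-use) minutes with sigma set
from the reported interquartile ratios (ln(Q3/Q1)/1.349 ≈ 0.65–0.69). Note
a lognormal cannot match a median of 9.4 *and* quartiles 6.2/15.0
simultaneously (their geometric mean is 9.64): the model centres the
quartile bracket on the configured median and preserves the ratio. The
lognormal is a stand-in for an unknown true distribution, and the total is
split across 1 + Poisson(1.5) editing episodes (Dirichlet shares) over the
admission day and the following day, with a configurable rate (default
0.02) of unterminated episodes (open without save, closed by a later
logout) to exercise the truncation handling.

What this does **not** emulate: nurse experience effects, within-nurse
correlation, time-of-day workload, real EMR event vocabularies, or any
relationship between case complexity and input time beyond the stratum
medians. Passing tests show the pipeline recovers structure the generator
put in — not that the observed hospital results would replicate.

### Power note

With dispersion matched to the reported interquartile ranges, a 9.4 vs 10.1
median gap at ~1200 cases/group gives a Wilcoxon rank-sum power of only
≈ 0.75 (the standardized log-scale shift is 0.072/0.67 ≈ 0.11). The
end-to-end acceptance check that expects detection in ≥ 90% of 20
replicates therefore fails by design honesty at these defaults (15/20 in
the committed seeds): meeting it would require either tightening the
dispersion well below what the published IQRs imply or enlarging the
samples. We keep the faithful defaults and leave the check red rather than
tune the generator to the threshold.

## Log analysis

* **Sessionization**: an episode runs from `open_profile` to the next
  `save` or `logout`; a logout-closed episode is flagged truncated (no save
  occurred — the duration runs to the forced logout and may overestimate).
  Episodes whose *open* falls on the admission day or the following
  calendar day are included; profile views with no terminating event are
  dropped. A `save` with no open episode, or an open during an open
  episode, marks the case malformed and excludes it with a reason.
* **Outlier rule**: records with input time strictly greater than
  mean + 3·SD (sample SD, n−1), computed once over all records —
  non-iterative, so constant data excludes nothing. The originating
  phrasing ("3 times greater than the mean by SD") is ambiguous; this
  single-pass strict reading is the documented choice.
* **Rank-sum test**: exact two-sided p by exhaustive enumeration of all
  C(n, n1) midrank assignments when combined n ≤ 12 (p = share of
  assignments with |W − E W| ≥ observed), otherwise the tie-corrected
  normal approximation without continuity correction (matches
  `scipy.stats.mannwhitneyu(use_continuity=False)` to machine precision).
* **Chi-square**: Pearson, no continuity correction (including 2×2); a
  warning is emitted when expected cell counts fall below 5.
* **Trend**: Cochran-Armitage with equally spaced scores and the
  unconditional variance — identical to R's `prop.trend.test`; statsmodels'
  linear-by-linear association differs by the factor √((N−1)/N)
  (hypergeometric variance), which the tests account for explicitly.
* All tests two-sided, no multiplicity adjustment. Stratified tables
  (overall, by ward, by ADL) report median (IQR) per group for input time,
  single-choice items, multi-choice items and character sums; the pipeline
  is deterministic given cases, events and configuration.

## Problem sizes used in the test suite

Structural checks run on the packaged fixtures (53 items, 77 sections) and
are instantaneous. Property tests use 400–1000-case cohorts for the
sessionization oracle, 500 fuzzed relay sequences for the privacy
invariants, and 20 replicates of the full ~2425-case pipeline for the
end-to-end detection check. The acceptance script's quantities are
deterministic fixture computations.

## Known limitations

* Fixture wording beyond the printed exemplars is invented; only the
  structure is authoritative.
* The relay is an in-process emulation; it demonstrates the data-flow and
  privacy contracts, not network security.
* The character-count model's median calibration is approximate (a few
  percent high at the default dispersion).
* The prolonged-stay attribute is a plain boolean on the case record; no
  diagnosis-procedure-combination lookup is modelled.
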