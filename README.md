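# iqcapture

Tools for capturing patient self-reports on electronic devices and turning
them into hospital nursing documentation — plus the analysis machinery to
measure what that does to nurses' documentation time.

Nursing admission assessments are largely assembled from what the patient
reports: activities of daily living (ADL), assistive devices, diet, drinking
and smoking habits. Conventionally a patient fills in a paper questionnaire,
a nurse interviews them, and then transcribes everything into the electronic
medical record (EMR). `iqcapture` implements the electronic alternative as a
reusable toolkit, for clinical-informatics researchers and nursing-system
developers:

* **Branching questionnaire engine** (`iqcapture.questionnaire`) — a
  preadmission instrument whose items change with the answers: 15 top-level
  questions, with detail items revealed by branch rules so a complete answer
  path covers between 15 and 53 items. Exhaustive branch-graph traversal
  computes those bounds exactly.
* **Patient profile model** (`iqcapture.profile`) — the 77-section inpatient
  assessment document organised by Gordon's 11 functional health patterns,
  with per-field provenance (quoted from the questionnaire vs typed by a
  nurse) and the registered-item metrics (single-choice items, multi-choice
  items, characters of free text) used in evaluation.
* **Intelligent quotation** (`iqcapture.quotation`) — the rule engine that
  maps answers into profile fields: direct quotes, terminology conversion
  ("I can do it myself" → "Independent"), aggregation of several answers
  into one value with a generated comment, clinical calculations, and
  interview stubs (empty text boxes opened per selected option for the
  nurse's focused interview). Drinking habits are converted to pure alcohol
  per day, *grams = volume × cans × 0.8 × fraction* (0.8 = ethanol density
  factor, fraction 0.05 for beer), and to Japanese standard-drink units
  (1 unit = 20 g); smoking duration is derived from start/quit ages.
* **Two-zone capture relay** (`iqcapture.relay`) — session issuance with
  128-bit tokens and QR/URL payloads that contain no patient identifier; an
  outside-zone store that never holds patient identity; one-way transfer
  with purge of outside payloads; and XML registration into an EMR template
  store after a completeness check.
* **Synthetic cohort generator** (`iqcapture.cohort`) — admission cases in
  questionnaire *use* / *no-use* groups with ward, ADL (bedriddenness rank J
  = independent), and documentation-volume structure, plus per-case EMR
  operation logs (open/save/logout events) whose episode durations sum to a
  per-stratum lognormal input time.
* **Log analysis** (`iqcapture.analysis`) — sessionization of operation logs
  into per-case input time over the admission day and the following day,
  single-pass mean + 3·SD outlier exclusion, and use vs no-use comparisons
  (overall, by ward, by ADL) with the Wilcoxon rank-sum test, Pearson
  chi-square, and the Cochran-Armitage trend test.

## Worked example

Enumerate the packaged instrument's answer-path bounds, simulate a cohort at
study scale and analyse it:

```bash
$ iqcapture paths
min items: 15
max items: 53

$ iqcapture simulate --n-cases 2425 --seed 7 --out-dir sim/
wrote 2425 cases and 13928 events to sim

$ iqcapture analyze --cases sim/cases.csv --events sim/events.csv --out report/
sessionized 2425 cases (0 malformed, 38 outliers excluded)
== overall ==
           variable                 use              no_use              test statistic  p_value
         input_time      9.3 (6.2-14.1)      9.7 (6.4-15.0) Wilcoxon rank-sum 1496778.0   0.0433
single_choice_items    56.0 (50.0-61.0)    55.0 (50.0-61.0) Wilcoxon rank-sum 1540224.0    0.571
 multi_choice_items    15.0 (12.0-19.0)    14.0 (11.0-18.0) Wilcoxon rank-sum 1610408.5 1.98e-06
         characters 241.5 (157.0-343.8) 207.0 (144.0-298.0) Wilcoxon rank-sum 1625563.0 1.61e-08
...
```

Read: the simulated questionnaire-use group documents a similar number of
single-choice items but more multi-choice items and characters, and still
has a shorter profile input time (medians 9.3 vs 9.7 minutes here, rank-sum
p = .04) — the configured generator contrast, recovered by the analysis
pipeline.

Capture flow from the shell (token issuance → outside submission → one-way
transfer → EMR registration):

```bash
iqcapture issue --store store/ --patient PAT-001 --mode outside
iqcapture submit --store store/ --token <token> --response response.xml
iqcapture transfer --store store/
iqcapture register --store store/ --token <token>
```

The library surface mirrors these commands (`issue_session`,
`submit_response`, `transfer_and_purge`, `register_to_emr`,
`apply_ruleset`, `stratified_analysis`, ...); see `docs/methods.md` for the
underlying models and conventions.

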