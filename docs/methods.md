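# Methods

## Problem and data model

The package estimates when an adverse drug event (ADE) begins and how long it
lasts, per patient, from heterogeneous clinical text. The inputs are (a)
timestamped free-text records of six document types — physician progress
notes, nursing records, discharge summaries, radiology reports, radioisotope
reports, pharmacist progress notes — and (b) structured medication orders of
two types (injection, medicine). All quantities are whole days; intra-day
time is discarded at ingest. The on-disk format is one JSON object per line,
chosen because the text fields contain line breaks and JSONL escapes them
losslessly, where CSV would need bespoke quoting.

## Extraction and factuality

Records are split into passages at line breaks; a passage longer than the
character budget (default 500) is split at sentence-final punctuation and,
last resort, at the budget boundary. The budget is in characters, not
tokens, so the package does not depend on any particular tokenizer; it
honours the fixed-window constraint of transformer taggers as a contract.

The built-in tagger does a longest-match, left-to-right, non-overlapping
scan for lexicon surface forms. Factuality is decided per passage: any
negation cue in the passage ⇒ *negative*; otherwise any risk/explanation cue
⇒ *suspected*; otherwise *positive*. Negation outranks risk cues — a
deterministic tie-break, configured in `TaggerConfig`. The factuality scope
is the passage (one line) because clinical notes put one statement per line;
no sentence segmentation inside lines is attempted. Offsets are 0-based,
half-open, in whole-record coordinates, and extraction never mutates text
(canonicalization happens later, on copies), so `text[start:end] == surface`
is an enforced invariant — also for mentions imported from an external NER
model through the JSONL adapter, which rejects spans outside the record or
disagreeing surfaces.

The tagger is deliberately simple; known failure modes of NER-based ADE
extraction (missed onomatopoeic expressions such as びりびり, risk-counselling
statements misread as events by cue-blind models) are reproduced by the
*generator* as configurable mention classes rather than patched in the
tagger, so their downstream effect on detection curves can be studied.

## Normalization

Surface forms are mapped to normalized terms by minimum Levenshtein distance
against a surface→normalized dictionary. The distance is the classic
unit-cost edit distance on Unicode code points (not grapheme clusters — the
dictionary is plain text and code points keep the primitive simple and
testable against the recursive definition). Before any distance is computed,
both sides are canonicalized: NFKC (which unifies full-width/half-width
variants), whitespace trimming, and lower-casing of ASCII segments only —
Japanese has no case, and folding non-Latin scripts would silently change
every distance.

Ties at the minimal distance are broken by (1) largest alignment overlap with
the query, measured as longest-common-subsequence length; (2) shorter
dictionary surface; (3) lexicographic order. The overlap criterion is the
substantive one: a four-character query sharing a two-character stem with one
candidate (異常変化 → 感覚異常) should beat an unrelated candidate at the
same raw distance (しびれ, also at distance 4). Length and lexicographic
order only guarantee platform-independent determinism. No distance threshold
is applied by default — the minimum always matches — but `max_distance`
exists because a threshold is the natural knob for trading the documented
false positives (e.g. 集積低下 → 痛覚低下 at distance 2) against misses.
With `max_distance=0` normalization degenerates to exact lookup.

The bundled dictionary (`data/fixture_dictionary.tsv`) is a synthetic,
desk-scale fixture of peripheral-neuropathy surface forms plus distractor
symptoms; real studies supply their own TSV (surface TAB normalized, UTF-8,
no header). A surface mapping to two different normalized forms is a load
error, not a silent overwrite.

## Cohort and timelines

Cohort selection is by exclusive exposure: ≥1 order matching the arm-A drug
names and none matching arm B ⇒ arm A (symmetrically for B); both ⇒ excluded
(a second neurotoxic drug started mid-follow-up would confound onset and
duration); neither ⇒ out of scope. The four sets partition the patient
universe by construction. Drug matching is exact on canonicalized names
against an explicit list — substring matching is avoided because it invites
silent false exposure (パクリタキセル注射液 is not an order for パクリタキセル
under this rule; list both names if both occur).

Day 0 is the first matching dose date itself, so a same-day mention has
day-index 0 and duration arithmetic stays exact. Onset is the minimum event
day over *all* document types, last detection the maximum, duration their
difference (0 for a single detection). Mentions dated before first dose
cannot be attributed to the drug; they are dropped from the timeline but
counted (`n_pre_dose_dropped`) for audit rather than guessed at. Patients
with no detection are censored at last contact — the latest record of any
document type. Restricting the document set can only remove events, so onset
is monotone non-decreasing and last detection non-increasing under document-set
restriction; this is the mechanism behind multitype documents outperforming
any single type, and it is asserted as a property test.

## Incidence analysis

Time-to-onset is estimated with the Kaplan-Meier product-limit estimator
(lifelines), ties handled by the standard simultaneous-event formula;
cumulative incidence is 1 − Ŝ(t), evaluated on the integer day grid — the
finest grid whole-day data support. Confidence intervals are Greenwood
variance with the log(−log) transform, which keeps the band inside [0, 1];
the method is a package choice since daily clinical reports rarely state one.

Curve comparison offers: the detection gap (reference − system incidence, in
percentage points, negative when the system over-detects); the detection
ratio (system ÷ reference at a fixed day, undefined at zero reference); the
Pearson correlation of two daily series over days 0..D; and OLS of the
all-documents daily series on the per-document daily series, with intercept
and conventional OLS standard errors. In that regression the all-documents
series is the *response* — the per-document curves explain the combined
curve — and constant or collinear predictor series are dropped with a logged
warning before fitting. Daily series are serially correlated, so the
correlation p-value and the OLS standard errors are descriptive, not
honest tests; they are reported because they are the field's conventional
summary for this comparison.

## Synthetic-corpus generator

The generator emulates the *structure* of a multitype hospital corpus, not
its language: the realism bar for templates is "exercises the tagger's cue
logic". Per patient it draws an arm (drug A / drug B / both / neither, default
fractions 0.045 / 0.049 / 0.0035 / 0.9025 — a small exposed fraction of a
large universe), a first-dose date, a follow-up length (uniform 90–1100
days), and a latent disease course: with probability 1 − 0.058 an onset day
from Weibull(shape 0.44, scale 27.6 days), then a resolution day after an
exponential duration with median 92 days. These defaults were derived once
from the headline figures of taxane-induced peripheral neuropathy — median
onset near 12 days among developers, ≈61% cumulative incidence at 30 days,
≈6% never developing, median detected duration near 92 days — and are not
tuning knobs.

Each document type writes records on its own cadence (nursing every 3 days,
physician 7, pharmacist 21, discharge 60, radiology 90, radioisotope 300)
with its own per-encounter recording probability and a Poisson charting
delay (mean 1 day). While symptomatic, encounter opportunities are anchored
at the onset day, so with recording probability 1 and zero delay the first
symptomatic record falls exactly on the true onset — the configuration under
which the pipeline must recover every onset exactly, which the test suite
asserts at n = 200. Planted mention classes: affirmative (dictionary surface
or a variant at known edit distance 1), negated, risk-explanation (the
early-overdetection bait for cue-blind taggers), and onomatopoeic surfaces
absent from the lexicon (structural false negatives); `degrade()` injects
higher miss/false-positive rates into a config without touching anything
else. Ground truth records every planted mention with its record index and
exact character span, and identical seed + config yields byte-identical
output.

What passing tests on this generator do **not** show: robustness to real
clinical Japanese (morphology, misspellings, free word order), to NER models
with other error profiles, to dose interruptions or competing risks, or to
documentation habits that differ from the stationary cadence/probability
model. They do show that the aggregation, survival estimation and evaluation
machinery is exact where exactness is provable and consistent where only
distributional checks are possible.

## Numerical and scale choices

Test and script problem sizes are chosen to make the checks sharp at desk
scale: exhaustive edit-distance enumeration runs over all string pairs of
length ≤ 3 on a 4-symbol alphabet and length ≤ 4 on a binary alphabet against
the plain recursive oracle (longer random pairs against a memoised oracle and
an independent C implementation); end-to-end recovery uses 200 patients;
monotonicity sweeps 20 seeded cohorts of 30; the acceptance script simulates
a 1200-patient universe (~100 exposed patients), evaluates incidence at day
30, and correlates system vs truth curves up to day 101. KM-vs-truth
agreement is asserted within pointwise binomial 95% bands on a horizon with
no censoring, where the estimator reduces to the empirical CDF.

## Known limitations

- The built-in tagger is a lexicon matcher; it neither generalizes beyond
  its lexicon nor resolves scope the way a trained factuality classifier
  does. External NER output is first-class input through the adapter.
- Onset is *first documented mention*, not clinical onset: late charting of
  a past symptom biases onset late; truncated follow-up biases duration low.
  Both biases are properties of the definition, not bugs.
- No competing-risks estimator, no covariate adjustment, no dose/cycle
  modelling, no CTCAE grading.
- Compound spans ("痛み・しびれ") are normalized as extracted; no re-segmentation
  is attempted, so such spans may match poorly — mirrored, not fixed.
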