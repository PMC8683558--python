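# Methods

## Data model and counting unit

The package operates on spontaneous safety reports. A *report* is one
submission to the database: demographics, a set of drugs (verbatim names,
with role codes PS/SS/C/I), a set of MedDRA preferred terms (PTs) and a set
of outcome codes (DE death, LT life-threatening, HO hospitalization, DS
disability, CA congenital anomaly, RI required intervention, OT other
serious). A *case* may appear as several report versions as corrections are
submitted.

All statistics count **reports**, never drug–event pairs: after
deduplication each report contributes at most one to any contingency-table
cell. This choice reproduces the regimen-level tables the package validates
against, whose margins are report counts.

### Deduplication

FAERS convention: for each case id only the highest case version is kept
(ties broken by latest receipt date, then report id). Within a report,
repeated drug rows and repeated PT rows collapse to sets; case/spacing
variants of one drug (e.g. `OPDIVO` vs `Opdivo `) merge at vocabulary
normalization, where variants map to one canonical id and duplicates are
dropped. Deduplication is idempotent and pure (input frames untouched).

### Assembly exclusions

Reports lacking any drug name or any reaction are excluded and counted
(`meta["excluded_no_drug"]`, `meta["excluded_no_reaction"]`) — a report
without a drug or an event cannot enter any 2×2 cell. Ages are converted to
years from their unit codes (YR, DEC, MON, WK, DY, HR); unknown units or
negative results become missing rather than guesses.

## Statistics

For a target group vs comparator with cells a, b, c, d (margins
N_Drug = a+b, N_Event = a+c, N_Total, expected E = N_Drug·N_Event/N_Total):

* **ROR (classical)**: ad/bc; CI = exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)) with
  the exact normal quantile z ≈ 1.959964 at α = 0.95. Any zero cell switches
  to the Haldane–Anscombe +0.5 correction on all four cells and sets a flag;
  nonzero tables are never altered.
* **Shrunken O/E ratio**: (a+0.5)/(E+0.5), exposed as `ror_shrunken` — an
  additively smoothed relative-reporting estimator equal to 1 when observed
  matches expected (including the empty table). It is *not* an odds ratio
  and is provided as a secondary estimator; the reportable ROR columns use
  the classical estimator, which is what reproduces the published values.
* **IC**: log₂ of the shrunken O/E ratio, with credibility bounds
  IC₀₂₅ = IC − 3.3(a+0.5)^−½ − 2.0(a+0.5)^−³ᐟ²,
  IC₉₇₅ = IC + 2.4(a+0.5)^−½ − 0.5(a+0.5)^−³ᐟ² —
  the standard closed-form approximation to the BCPNN posterior interval.
  The combination classical-ROR + shrunken-IC is the one that reproduces the
  published regimen table to its printed precision (IC₉₇₅ excepted: the
  recomputed upper bound differs from print by ~0.01–0.05 on some rows, so
  it is reported but not treated as a validated surface).
* **Signal rule**: eligible iff a ≥ `min_reports` (default 3); signal iff
  eligible and (ROR₀₂₅ > 1 or IC₀₂₅ > 0). Threshold ties are **not**
  signals ("exceeding" is strict).
* **Comparative ROR**: the same classical estimator between two disjoint
  regimen groups. No IC is reported there because neither group is the
  whole-database background that the O/E expectation assumes.

Monotonicity caveat: the ROR is strictly increasing in a (b, c, d fixed)
everywhere; the shrunken IC is strictly increasing in the pharmacovigilance
regime (a small relative to the database) but not globally — as a grows
comparable to the margins the O/E ratio renormalizes. Property tests assert
the regime that matters.

No multiple-comparison adjustment is applied anywhere, deliberately: the
analysis is signal *detection*, and the validated reference tables apply
none either.

## Regimen classification

A report's regimen is a pure function of its normalized drug set: the ICIs
it lists (anti-PD-1: nivolumab, pembrolizumab, cemiplimab; anti-PD-L1:
atezolizumab, avelumab, durvalumab; anti-CTLA-4: ipilimumab, tremelimumab),
monotherapy (exactly one) vs polytherapy (more than one), and chemotherapy
co-listing (any drug of class `chemotherapy`). Four combinations carry named
labels (poly1 = pembrolizumab+ipilimumab+nivolumab, poly2 =
ipilimumab+nivolumab, poly3 = pembrolizumab+ipilimumab, poly4 =
durvalumab+tremelimumab); other multi-ICI sets are `other` and still count
in aggregate polytherapy-vs-monotherapy comparisons. "ICIs alone" means no
listed chemotherapy-class drug; co-listed non-chemotherapy anticancer drugs
do not remove a report from the "alone" arm. Therapy dates are not used:
co-listing on one report is taken as combination exposure, since report-level
data carry no reliable overlap windows.

Design choices that were genuinely open:

* **Age dichotomy** defaults to 65 (the cutoff used by the reference
  baseline tabulation) and is a parameter, since <60/≥60 is also common.
* **Drug roles**: PS, SS and C are all included by default — combination
  regimens are frequently reported with the partner drug as concomitant —
  with `restrict_to_suspect` to keep PS/SS only.
* **Top-k event ranking** (per-PT tables) is computed within ICI reports by
  default (`rank_events_within="ici"`), switchable to whole-database.
* **Pooled comparisons**: anti-PD-1/PD-L1 pools the six PD-1/PD-L1
  monotherapies against anti-CTLA-4 monotherapy; poly-vs-mono pools all
  polytherapy (named or not) against all monotherapy.
* **Most-serious outcome**: the baseline table tabulates each report once
  under its most serious outcome (severity order DE > LT > DS > HO > CA >
  RI > OT) so stratum percentages sum to 100; the *death* count is
  unaffected because death outranks everything. Fatality tables count DE in
  any position.
* **Fatality direction**: death proportions are reported for both
  chemotherapy panels side by side; the package asserts no direction of the
  with-vs-without-chemotherapy difference.

## Dictionaries

Drug and event dictionaries are plain text and user-replaceable. The bundled
renal PT list contains the common renal/urinary-disorder PTs (acute kidney
injury, renal failure, nephritis, …); it stands in for "all PTs under the
renal and urinary SOC", which cannot be bundled because the MedDRA hierarchy
is licensed. The bundled chemotherapy list covers common cytotoxics with
frequent brand names. Exact replication of any specific published study
therefore requires substituting that study's own PT and chemotherapy lists;
the statistics are dictionary-agnostic.

Name lookup is case- and whitespace-insensitive and total: unmapped names
become `other:<NAME>` rather than being dropped, so normalization never
loses a drug row.

## Synthetic data generator

The generator emulates the FAERS quarterly schema (DEMO/DRUG/REAC/OUTC,
`$`-delimited) with a fully known data-generating process:

* **Drugs**: independent Bernoulli use per drug (default catalogue: 8 ICIs,
  12 cytotoxics, 30 background drugs, probabilities echoing relative
  real-world reporting volume), then combination co-prescription rules
  (e.g. ipilimumab added to 25% of nivolumab reports) and chemotherapy
  co-listing for ICI reports (default rate 0.30). Reports that drew no drug
  receive one background drug — real reports always list one.
* **Events**: independent Bernoulli per (report, PT) at a baseline rate,
  multiplied by θ for reports containing a planted drug or combination
  (capped at 1; truncations are counted). Under this mechanism the planted
  θ *is* the true reporting-rate ratio, and for the rare events used it is
  within ~2% of the true odds ratio the ROR estimates. Reports that drew no
  event receive one **background (non-renal)** event, so the study-event
  rates stay exactly at their configured values; ground-truth counts record
  the raw Bernoulli draws, before these minimum-one fills.
* **Duplicates**: a configurable fraction of cases (exact count,
  `round(rate·n)`) is re-submitted with case version 2 and identical
  content — precisely what deduplication must remove.
* **Missingness**: exact counts of reports with blanked drug names (and
  optionally no reactions); brand-name substitution and an `XQ`-suffix
  misspelling channel exercise normalization and its `other:*` fallback.
* **Outcomes and demographics**: death probability per report (base rate
  0.08, overridable per (drug-set, PT)); independent other outcome codes;
  sex/age/year/country from configurable marginals.

Everything is deterministic given the seed; equal config+seed yields
byte-identical files.

What the generator does **not** model — and what passing tests therefore do
not establish about real data: correlated drug co-prescription beyond the
configured pairs, event–event competition within a report, time trends in
reporting (Weber effect), country- or reporter-specific reporting cultures,
real name-variant typo distributions, and non-random missingness. Tests
against the generator validate the *machinery* (counting, dedup, estimator
calibration, signal recovery), not epidemiological conclusions.

## Validation problem sizes

The suite validates calibration and recovery at sizes chosen to keep a full
run to a few minutes: CI coverage over 2000 simulated studies (true ratio 2,
event baseline 0.005, 10k target / 100k comparator reports; observed
coverage ~95%); end-to-end planted-signal recovery over 100 replicates of
200 000 reports with a θ = 3 ipilimumab+nivolumab → acute-kidney-injury
association (expected a ≈ 40; a trimmed drug/event catalogue keeps replicate
cost low while preserving those conditions), alongside five θ = 1 pairs per
replicate for the null flag rate. Published-cell reproduction runs from the
bundled fixture, so no large simulation is needed for it.

## Degenerate inputs and numerical notes

* Empty 2×2 table: expected = 0, shrunken O/E = 1, IC = 0 exactly.
* Zero cells: continuity-corrected ROR with flag (see above); `ror_shrunken`
  and IC need no correction by construction.
* `alpha` outside (0,1), negative cells, unknown filter keys, overlapping
  target/comparator groups, missing files and missing mandatory columns all
  raise immediately with the offending name in the message.
* Ranking ties in top-k events break alphabetically; dedup ties break by
  receipt date then report id — all orderings are deterministic, and
  `run_all` output files are byte-identical for identical (inputs, config,
  seed).
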