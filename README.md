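# renalpv

Pharmacovigilance signal detection for **renal adverse events under
immune-checkpoint-inhibitor (ICI) regimens**, built for FAERS-style
spontaneous-report databases.

Spontaneous reporting systems such as the FDA Adverse Event Reporting System
(FAERS) collect millions of post-marketing safety reports, each listing the
drugs a patient received and the adverse events (MedDRA preferred terms, PTs)
that were reported. Because there is no denominator of exposed patients,
safety questions are asked *disproportionally*: is a renal event reported
more often with a given ICI regimen than with everything else in the
database? This package implements that analysis end to end — quarterly-file
ingestion and deduplication, drug-name normalization, regimen classification
(anti-PD-1 / anti-PD-L1 / anti-CTLA-4 monotherapy and combinations, with or
without co-listed chemotherapy), the disproportionality statistics, study
tables and fatality-outcome summaries — together with a synthetic FAERS-schema
generator so every stage is testable with known ground truth.

It is aimed at drug-safety researchers and biostatisticians who want a
reproducible, scripted version of this kind of study rather than a one-off
SAS/R analysis.

## The statistics

Every estimate derives from a 2×2 table of *report counts*:

|                | event *E* | no event |
|----------------|-----------|----------|
| target regimen | a         | b        |
| comparator     | c         | d        |

with N_Drug = a+b, N_Event = a+c, N_Total = a+b+c+d and expected count
E[a] = N_Drug·N_Event / N_Total.

* **Reporting odds ratio** — ROR = ad/bc with the Woolf (log-normal) interval
  exp(ln ROR ± z₀.₉₇₅·√(1/a + 1/b + 1/c + 1/d)); a zero cell triggers the
  Haldane–Anscombe +0.5 correction (flagged, never silent).
* **Information component** — IC = log₂((a + 0.5)/(E[a] + 0.5)), the shrunken
  observed-to-expected ratio on the log₂ scale, with closed-form credibility
  bounds IC₀₂₅ = IC − 3.3(a+0.5)^−½ − 2(a+0.5)^−³ᐟ² (Norén-style BCPNN
  approximation).
* **Signal rule** — a drug–event pair with at least 3 reports is a signal
  when ROR₀₂₅ > 1 **or** IC₀₂₅ > 0 (both strict).
* **Comparative ROR** — the same odds ratio computed between two regimen
  groups (e.g. combination vs monotherapy) instead of regimen vs database.

Counting is report-level: one deduplicated report contributes at most one to
any cell.

## Worked example

Statistics from pre-aggregated regimen-level cells (the bundled
`table2_fixture` carries published regimen-vs-database report counts):

```python
from renalpv import ror_classical, ic, estimate_signal
from renalpv.synthetic_data import table2_fixture

t = table2_fixture()["Atezolizumab"]     # a=337 b=5861 c=1108529 d=29488088
r, i, e = ror_classical(t), ic(t), estimate_signal(t)
```

prints, formatted:

```
ROR  = 1.53 (95% CI 1.37-1.71)
IC   = 0.58 (95% CrI 0.40 to 0.72)
signal = True (>=3 reports and ROR025>1 or IC025>0)
```

Atezolizumab monotherapy reports renal events 1.53 times the odds of the rest
of the database, and both interval lower bounds clear their thresholds, so the
pair is flagged. The pooled chemotherapy contrast

```python
r = ror_classical(table2_fixture()["ICI+chemo vs ICI alone"])
# ROR = 1.30 (1.17-1.45)
```

says renal events are reported ~30% more often when chemotherapy is co-listed
with an ICI than with ICIs alone.

From the shell, against a (here synthetic) quarter on disk:

```console
$ pv simulate --seed 3 --out demo --n-reports 50000
wrote 4 tables to demo (52500 report rows, 50000 unique cases)
$ pv signal --drug nivolumab --data demo
{
  "drug": "nivolumab",
  "a": 37, "b": 1456, "c": 1281, "d": 44726,
  "ror": 0.887, "ror_025": 0.637, "ror_975": 1.235,
  "ic": -0.161, "ic_025": -0.709, "ic_975": 0.229,
  "eligible": true, "signal": false
}
```

(37 of 1493 nivolumab reports mention a renal PT; no excess over background,
as expected for data generated with no planted association.)

A full study — baseline table, regimen signal table, per-PT ROR₀₂₅ matrix,
fatality proportions, manifest — runs from a YAML config:

```console
$ pv run --config study.yaml
```

## Layout

| module | role |
|---|---|
| `renalpv.faers_io` | read/write `$`-delimited quarterly tables, assemble reports, deduplicate case versions |
| `renalpv.vocabulary` | drug-name → canonical drug/class mapping; renal PT dictionary |
| `renalpv.cohort` | regimen assignment (mono/poly, named combos, ± chemo) and subgroup filters |
| `renalpv.disproportionality` | contingency tables, ROR/IC, signal rule, comparative ROR |
| `renalpv.pipeline` | study orchestration, output tables, manifest; `AnalysisConfig` |
| `renalpv.synthetic_data` | FAERS-schema simulator with planted ground truth; published-cell fixtures |

The bundled dictionaries (`src/renalpv/data/`) are editable text files; see
`docs/methods.md` for the model, parameter defaults and known limitations.
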