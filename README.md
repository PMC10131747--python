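# tnstager

Rule-based TN staging of free-text chest-CT radiology reports under the
TNM classification, 8th edition.

Staging a patient with lung cancer requires the tumor (T) and nodal (N)
categories, but the radiology report that carries the evidence is usually
free text. `tnstager` is a clinical-NLP pipeline that reads such a report and
assigns the T substage (T1a–T4, from tumor size, presence findings and
invaded structures), the N substage (N0–N3, from pathological lymph nodes,
their station, their side and the tumor side) and the combined TN label,
together with a rule-by-rule explanation trace pointing at the exact text
spans that fired.

Because real staging reports cannot be redistributed, the package also ships
a synthetic report generator that renders gold-labelled sectioned reports
from templates (with controllable noise: typos, hedged findings, missing
stations, omitted headings) and an evaluation harness (accuracy, confusion
matrices, support-weighted precision/recall/F1, under/over-staging tallies,
error-taxonomy tabulation).

## The model

The pipeline is a classic rule-based information-extraction stack:

1. **Preprocessing** — offset-preserving text cleaning (decimal commas,
   dimension glyphs `×`/`*` → `x`, whitespace), sectionizing by subheadings
   (clinical details, modality, report, body part, impression), sentence
   splitting protected against decimals and abbreviations, number tagging.
2. **Extraction** — regular-expression concept lexicons for the primary
   tumor, lymph nodes, the 14 IASLC nodal stations (with R/L side capture),
   laterality, invaded structures (each tagged with the T level it implies)
   and presence findings; a measurement extractor that normalizes
   expressions like `12x44x29 mm` or `3.5 cm` to millimetres and binds them
   to the nearest tumor/node mention.
3. **Context** — a ConText-style algorithm linking negation, uncertainty and
   *pathological* trigger terms to in-scope targets (directional scope,
   token window, terminators). A node is pathological through any of three
   routes: an intrinsically pathological surface form ("lymphadenopathy",
   "enlarged lymph node"), a short axis ≥ 10 mm, or a detached pathological
   modifier.
4. **Staging** — the TNM-8 decision rules. T = max(size band, implied level
   of asserted involvements) on the scale T1a < T1b < T1c < (T2) < T2a <
   T2b < T3 < T4, with size bands (cm, left-open/right-closed)
   `≤1 | 1–2 | 2–3 | 3–4 | 4–5 | 5–7 | >7`; undivided T2 appears only when a
   T2-level finding fires without any size. N per pathological node:
   supraclavicular (station 1) → N3; subcarinal (7) → N2 regardless of side;
   other mediastinal (2–9) → N2 ipsilateral / N3 contralateral;
   hilar–intrapulmonary (10–14) → N1 ipsilateral / N3 contralateral;
   bilateral → N3; report level = max. Missing evidence degrades to
   explicit TX/NX labels, never to a guess.

All synonyms, station patterns, modifier triggers, size cut points and
thresholds live in two YAML files (`lexicon_en.yaml`, `rules_tnm8.yaml`), so
another language or institution is a configuration swap.

## Worked example

```python
from tnstager import classify_tn

report = """Report: There is a 35 mm tumor in the right upper lobe.
Enlarged lymph nodes at station 4R.
Impression: Pulmonary malignancy in the right lung as described above."""

stage = classify_tn(report)
print(stage.tn_label)
print(stage.summary.tumor_size_mm, stage.summary.tumor_side)
for entry in stage.trace:
    print(f"{entry.rule}: {entry.detail}")
```

prints

```
T2aN2
35.0 right
t_size_band: tumor size 35 mm -> T2a
n_station_rule: station 4 relation ipsilateral -> N2
```

The 35 mm size falls in the 3–4 cm band (T2a); the enlarged node at station
4R is an ipsilateral mediastinal node for a right-sided tumor, hence N2.

The same flow from the shell, on a generated corpus:

```
$ tnstage generate --n 5 --seed 11
wrote 5 reports to corpus.jsonl (gold: gold.csv)
$ tnstage stage corpus.jsonl --out-dir staged
report_id                tn_label
synthetic-0000           T2bN0
synthetic-0001           T1bN0
synthetic-0002           T2N3
synthetic-0003           T4N3
synthetic-0004           T2N2
staged 5 report(s), 0 unreadable
$ tnstage eval --predictions staged --gold gold.csv --out-dir evaluation
n=5  accuracy T=1.000 N=1.000 TN=1.000  weighted F1(TN)=1.000
```

Each per-report JSON in `staged/` carries the structured findings summary
and the trace spans; `evaluation/` receives `metrics.json` and the T/N/TN
confusion matrices as CSV.

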