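# Methods

This note records how the pipeline works, which knobs matter, what the
synthetic corpus does and does not emulate, and where the design was
genuinely open.

## Pipeline model and assumptions

The pipeline assumes one primary tumor per report (restaging and
two-primary cases are out of scope) and a report written as declarative
sentences, optionally under the conventional subheadings. All downstream
character spans refer to the *cleaned* text — one coordinate system across
modules — with a cleaned→raw offset map retained for display. Cleaning is
idempotent and deliberately minimal: decimal commas become dots only
between digits (enumeration commas untouched), dimension glyphs become a
canonical `x` only in digit context, whitespace runs collapse.

Headings are recognized only at line starts and only when followed by a
colon, so the word "report" mid-sentence never opens a section. Absence of
headings is not an error: the whole text becomes a single `unknown`
section, and by default every section is searched for staging concepts
(`excluded_sections` lets a deployment drop referral text such as
clinical details, since whether such text should contribute to staging is a
site policy, not a property of the algorithm).

Sentence splitting is rule-based (punctuation + hard line breaks), with
splits suppressed inside decimals and after a configurable abbreviation
list. A statistical sentence model would add a heavy dependency for no
benefit on radiology prose, where the failure modes are exactly the
protected cases.

## Extraction and context

Concept matching is pure lexicon regex; on overlapping candidates the
longest match wins, ties to the leftmost. Compound surfaces such as
"pathological lymph node" fold the adjective into the mention as an
intrinsic attribute, which is what makes "no pathological lymph nodes"
come out as a *negated pathological* node — present in the findings list,
contributing nothing positive to the stage.

Measurements are normalized to millimetres; `cm` is multiplied by 10. A
lone number requires an explicit unit (so "station 4" is never a size);
dimension-joined runs (`12x44`) count as measurements even unitless,
millimetres being the multi-axis convention. Each measurement binds to the
nearest tumor/node mention in its sentence (ties to the preceding
mention); unbound measurements are kept as orphans but do not stage.

Context linking follows the ConText family: a trigger term scopes in its
lexicon-given direction up to `scope_window_tokens` (default 8, in the
range ConText-style systems use) or a terminator (`but`, `however`, …).
By default a modifier links only to its nearest in-direction target —
multi-node sentences are the known hardest case for scope algorithms, and
nearest-target linking is the conservative choice; `modifier_broadcast`
switches to link-all for ablation.

A node mention is pathological via any of three routes: intrinsic surface
form, bound short axis ≥ `node_short_axis_threshold_mm`, or an in-scope
pathological modifier. The threshold default is 10 mm short axis, the
standard radiological enlargement criterion; the short axis of a
multi-axis node measurement is its minimum dimension and the tumor size
for T staging its maximum (`node_axis`/`tumor_axis`), both the TNM-8
convention. Hedged positives ("possibly enlarged node") are excluded from
staging by default (`uncertain_positive_counts: false`): treating
uncertainty conservatively is the safer clinical default, and the flag
exposes the opposite semantics.

## Staging rules

Size bands are left-open/right-closed in millimetres: exactly 30 mm is
T1c (T1 caps at ≤3 cm), 30.1 mm is T2a. The cut points live once in the
rules file, shared by the engine and its tests. The label scale carries an
undivided `T2` between T1c and T2a: it is emitted only when a T2-level
involvement or presence finding fires with no measured size, because a
stated size always refines T2 into T2a/T2b. That yields exactly 8
reachable T labels (T1a, T1b, T1c, T2, T2a, T2b, T3, T4) plus TX.

N staging maps each pathological, non-negated node through the IASLC
station groups (1 supraclavicular; 2–9 mediastinal with 7 subcarinal and
midline; 10–14 hilar/intrapulmonary) against the tumor side, and takes the
maximum. A node whose evidence cannot place it — a lateral node with
unknown tumor side, an ipsilateral node with unknown station, a
side-dependent station with no side — contributes an *indeterminate*
stage: the report becomes NX unless another node already determines N3
(contralateral, bilateral and supraclavicular nodes dominate regardless of
the missing evidence). An explicit, inspectable NX was preferred over any
guessing rule. A separate module holds a literal, enumerated transcription
of the TNM-8 T/N tables with no code shared with the engine; it is the
oracle for the generator's gold labels and for the exhaustive equivalence
tests.

Every classification carries a trace of fired rules with the text spans
that triggered them; the flags on each asserted mention are reproducible
from its linked modifier list alone. TX/NX are real outputs, counted as
errors by the evaluator but never raised as exceptions.

## Synthetic corpus

The generator emulates the layout of sectioned chest-CT staging reports:
one tumor sentence (size in the target band and/or an involvement phrase
forcing the target level), node sentences realizing the target N through
the three pathological-mention patterns (compound adjective /
lymphadenopathy, enlarged size, detached modifier), negated node
statements for N0, and neutral distractors. The default class distribution
over the 32 TN labels is proportional to a 95-report staging cohort's
training counts (zero-mass classes stay absent); a fixed seed makes the
corpus bit-exact. Noise injectors mirror the error taxonomy of dictated
reports: character typos, hedged extra findings, several nodes in one
sentence, omitted headings, node mentions missing their station,
inconsistent tumor location. Uncertainty noise only ever *adds* hedged
higher-stage findings, so gold labels remain derivable from the recipe by
the oracle tables.

What passing tests show, and what they do not: perfect recovery on the
zero-noise corpus is a grammar-coverage contract — every rule path is
exercised and the engine inverts its own grammar — not a claim about
clinical text, whose lexical variety, implicit phrasing and dictation
errors the templates deliberately do not model. The shipped English
lexicon is likewise a synthetic reconstruction from TNM-8 vocabulary and
common radiology phrasing, not a harvested synonym list.

## Evaluation

Accuracy and confusion matrices are computed per stage and for the
combined label (X labels as extra rows/columns); precision/recall/F1 are
one-vs-rest per label, then weighted by gold support, computed both for TN
and per stage since either reading of "combined" is defensible.
Under/over-staging is counted on the ordinal scales with X excluded;
undivided T2 ranks just below T2a. Error-category attribution is a manual
annotation format (CSV with the seven-category taxonomy: data selection,
context missing/complexity, concept missing/ambiguity/complexity,
reporter) that the tool tabulates — automated root-cause analysis is out
of scope.

## Problem sizes and numerical choices

The exhaustive engine-vs-oracle checks cover all sizes 1–120 mm (plus the
no-size case) crossed with structure subsets up to size 3, and all 14
stations × 3 side relations × pathological flag. Corpus-level tests use
192 reports (matching the reference cohort size), and the chi-square check
of the label histogram uses the configured multinomial as its reference.
Metric agreement with the independent hand computation is required to
1e-12. All randomness in the package flows from explicit seeds; the
staging path itself is seed-free and byte-deterministic.

## Known limitations

Implicit phrasing is out of rule reach by design: a T4 "multiple lobes"
description without an explicit other-lobe-nodule phrase, gravity-dependent
atelectasis wrongly credited to the tumor, or a station implied purely by
anatomy will be missed or mis-scoped. Dependency-parse-based modifier
linking (the natural fix for multi-node sentences) is not implemented.
M stage, PET tracer uptake, restaging reports and non-English lexicons are
outside the package's scope, though the configuration surface is designed
for the latter.
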