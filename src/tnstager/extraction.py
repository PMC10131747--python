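"""Concept and measurement extraction.

Concepts (tumor, lymph node, nodal station, laterality, invaded structure,
presence finding, pathological term) are matched with the regular-expression
lexicon, one pattern set per concept; overlaps are resolved longest-match
first, ties leftmost.  Measurements are extracted from tagged numbers and
normalized to millimetres, grouping dimension-joined runs (``12x44x29 mm``)
into a single multi-axis measurement.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

from .config import Lexicon
from .types import ConceptMention, Measurement, Sentence, Span


def _overlaps(a: Span, b: Span) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def resolve_overlaps(candidates: list) -> list:
    """Longest-match-wins, ties leftmost, over items carrying a .span."""
    kept: list = []
    for cand in sorted(candidates, key=lambda c: (-(c.span[1] - c.span[0]), c.span[0])):
        if not any(_overlaps(cand.span, k.span) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.span[0])
    return kept


def match_concepts(sentence: Sentence, lexicon: Lexicon) -> list[ConceptMention]:
    """All non-overlapping concept mentions in a sentence, ordered by span."""
    text = sentence.text
    base = sentence.span[0]
    cands: list[ConceptMention] = []

    def add(kind: str, m: re.Match, **attrs) -> None:
        cands.append(
            ConceptMention(kind, (base + m.start(), base + m.end()), m.group(), attrs)
        )

    c = lexicon.compiled
    for pat in c["tumor"]:
        for m in pat.finditer(text):
            add("tumor", m)
    for pat, entry in c["lymph_node"]:
        for m in pat.finditer(text):
            add("lymph_node", m, pathological=entry.pathological)
    for pat in c["lymphadenopathy"]:
        for m in pat.finditer(text):
            # inherently pathological surface form
            add("lymphadenopathy", m, pathological=True)
    for pat, sid in c["stations"]:
        for m in pat.finditer(text):
            side = None
            raw_side = m.groupdict().get("side")
            if raw_side and raw_side.upper() in ("R", "L"):
                side = "right" if raw_side.upper() == "R" else "left"
            add("station", m, station_id=sid, side=side)
    for pat, value in c["laterality"]:
        for m in pat.finditer(text):
            add("laterality", m, value=value)
    for pat, sid, implies_t in c["structures"]:
        for m in pat.finditer(text):
            add("structure", m, structure_id=sid, implies_t=implies_t)
    for pat, pid, implies_t in c["presence_findings"]:
        for m in pat.finditer(text):
            add("presence_finding", m, presence_id=pid, implies_t=implies_t)
    for pat in c["pathological_terms"]:
        for m in pat.finditer(text):
            add("pathological_term", m)

    return resolve_overlaps(cands)


_MEASURE = re.compile(
    r"(?P<dims>\d+(?:\.\d+)?(?:\s*x\s*\d+(?:\.\d+)?)*)"
    r"(?:\s*(?P<unit>millimet(?:re|er)s?|centimet(?:re|er)s?|mm|cm)\b)?",
    re.IGNORECASE,
)
_CM_UNITS = ("cm", "centimetre", "centimetres", "centimeter", "centimeters")


def extract_measurements(sentence: Sentence) -> list[Measurement]:
    """Normalized size measurements (millimetres) found in a sentence.

    A lone number needs an explicit length unit; dimension-joined runs count
    as measurements even without one (millimetres assumed, the convention in
    multi-axis CT measurements).  Centimetres are converted (x10).  Runs with
    more than three components are not sizes (e.g. dates) and are ignored.
    """
    out: list[Measurement] = []
    base = sentence.span[0]
    for m in _MEASURE.finditer(sentence.text):
        dims_s = re.split(r"\s*x\s*", m.group("dims"), flags=re.IGNORECASE)
        unit = (m.group("unit") or "").lower()
        if not unit and len(dims_s) < 2:
            continue
        if not 1 <= len(dims_s) <= 3:
            continue
        factor = 10.0 if unit in _CM_UNITS else 1.0
        dims = tuple(float(d) * factor for d in dims_s)
        if any(d <= 0 for d in dims):
            continue
        out.append(Measurement((base + m.start(), base + m.end()), dims, m.group("unit") or ""))
    return out


_BINDABLE = ("tumor", "lymph_node", "lymphadenopathy")


def _distance(a: Span, b: Span) -> int:
    if _overlaps(a, b):
        return 0
    return b[0] - a[1] if a[1] <= b[0] else a[0] - b[1]


def bind_measurements(
    mentions: Sequence[ConceptMention],
    measurements: Sequence[Measurement],
    sentence: Sentence,
) -> list[tuple[ConceptMention, Measurement]]:
    """Bind each measurement to the nearest tumor/node mention in the
    sentence (character distance, ties to the preceding mention); unbindable
    measurements are left out and treated as orphan sizes downstream."""
    targets = [c for c in mentions if c.concept_kind in _BINDABLE]
    bindings: list[tuple[ConceptMention, Measurement]] = []
    for meas in measurements:
        best: Optional[ConceptMention] = None
        best_key: Optional[tuple] = None
        for t in targets:
            precedes = t.span[0] <= meas.span[0]
            key = (_distance(t.span, meas.span), 0 if precedes else 1, t.span[0])
            if best_key is None or key < best_key:
                best, best_key = t, key
        if best is not None:
            bindings.append((best, meas))
    return bindings


def orphan_measurements(
    bindings: Sequence[tuple[ConceptMention, Measurement]],
    measurements: Sequence[Measurement],
) -> list[Measurement]:
    bound = {id(m) for _, m in bindings}
    return [m for m in measurements if id(m) not in bound]
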