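"""ConText-style modifier detection and target linking.

Trigger terms for negation, uncertainty and the staging-specific
``pathological`` category scope over target concepts in their lexicon-given
direction, up to a token window or a scope terminator (``but`` and friends).
A lymph-node mention counts as pathological through any of three routes: an
intrinsically pathological surface form ("lymphadenopathy", "enlarged lymph
node"), a bound measurement with short axis at or above the enlargement
threshold, or an in-scope pathological modifier.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

from .config import Lexicon, Rules
from .extraction import resolve_overlaps
from .types import (
    AssertedMention,
    ConceptMention,
    ContextModifier,
    Measurement,
    Sentence,
    Span,
)

TARGET_KINDS = ("tumor", "lymph_node", "lymphadenopathy", "structure", "presence_finding")
NODE_KINDS = ("lymph_node", "lymphadenopathy")

_TOKEN = re.compile(r"\S+")


def detect_modifiers(sentence: Sentence, lexicon: Lexicon) -> list[ContextModifier]:
    """All context-modifier matches in a sentence (longest wins on overlap,
    ties leftmost), ordered by span."""
    base = sentence.span[0]
    cands: list[ContextModifier] = []
    for pat, entry in lexicon.compiled["context_modifiers"]:
        for m in pat.finditer(sentence.text):
            cands.append(
                ContextModifier(
                    entry.category, (base + m.start(), base + m.end()), m.group(), entry.direction
                )
            )
    return resolve_overlaps(cands)


def _token_spans(sentence: Sentence) -> list[Span]:
    base = sentence.span[0]
    return [(base + m.start(), base + m.end()) for m in _TOKEN.finditer(sentence.text)]


def _scope_interval(
    modifier: ContextModifier,
    direction: str,
    tokens: list[Span],
    token_texts: list[str],
    window: int,
    terminators: set[str],
) -> Optional[Span]:
    """Character interval a modifier's scope covers in one direction."""
    if direction == "forward":
        idxs = [i for i, t in enumerate(tokens) if t[0] >= modifier.span[1]]
        end = modifier.span[1]
        taken = 0
        for i in idxs:
            if token_texts[i] in terminators:
                break
            end = tokens[i][1]
            taken += 1
            if taken >= window:
                break
        return (modifier.span[1], end) if end > modifier.span[1] else None
    else:
        idxs = [i for i, t in enumerate(tokens) if t[1] <= modifier.span[0]]
        start = modifier.span[0]
        taken = 0
        for i in reversed(idxs):
            if token_texts[i] in terminators:
                break
            start = tokens[i][0]
            taken += 1
            if taken >= window:
                break
        return (start, modifier.span[0]) if start < modifier.span[0] else None


def _overlap(a: Span, b: Span) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _distance(a: Span, b: Span) -> int:
    if _overlap(a, b):
        return 0
    return b[0] - a[1] if a[1] <= b[0] else a[0] - b[1]


def link_modifiers(
    mentions: Sequence[ConceptMention],
    modifiers: Sequence[ContextModifier],
    sentence: Sentence,
    rules: Rules,
    bindings: Sequence[tuple[ConceptMention, Measurement]] = (),
) -> list[AssertedMention]:
    """Resolve each target mention's asserted/negated/uncertain/pathological
    status from the in-scope modifiers.

    By default a modifier links only to the nearest target in its direction
    (multi-node sentences are the known hard case); setting
    ``rules.modifier_broadcast`` links it to every in-scope target.
    """
    tokens = _token_spans(sentence)
    token_texts = [
        sentence.text[s - sentence.span[0] : e - sentence.span[0]].strip(".,;:").lower()
        for s, e in tokens
    ]
    terminators = {t.lower() for t in rules.scope_terminators}

    targets = [c for c in mentions if c.concept_kind in TARGET_KINDS]
    size_of: dict[int, Measurement] = {}
    for concept, meas in bindings:
        size_of.setdefault(id(concept), meas)

    linked: dict[int, list[ContextModifier]] = {id(t): [] for t in targets}
    for mod in modifiers:
        directions = (
            ("forward", "backward") if mod.direction == "bidirectional" else (mod.direction,)
        )
        in_scope: list[ConceptMention] = []
        for direction in directions:
            interval = _scope_interval(
                mod, direction, tokens, token_texts, rules.scope_window_tokens, terminators
            )
            if interval is None:
                continue
            in_scope.extend(
                t for t in targets if _overlap(t.span, interval) or _overlap(t.span, mod.span)
            )
        if not in_scope:
            # a target whose span contains the modifier is still in reach
            in_scope = [t for t in targets if _overlap(t.span, mod.span)]
        if not in_scope:
            continue
        if rules.modifier_broadcast:
            chosen = in_scope
        else:
            chosen = [min(in_scope, key=lambda t: (_distance(t.span, mod.span), t.span[0]))]
        for t in chosen:
            linked[id(t)].append(mod)

    asserted: list[AssertedMention] = []
    for t in targets:
        mods = linked[id(t)]
        negated = any(m.category == "negation" for m in mods)
        uncertain = any(m.category == "uncertainty" for m in mods)
        size = size_of.get(id(t))
        pathological = False
        if t.concept_kind in NODE_KINDS:
            intrinsic = bool(t.attributes.get("pathological"))
            by_size = (
                size is not None and size.min_dim_mm >= rules.node_short_axis_threshold_mm
            )
            by_modifier = any(m.category == "pathological" for m in mods)
            pathological = intrinsic or by_size or by_modifier
        asserted.append(
            AssertedMention(
                mention=t,
                negated=negated,
                uncertain=uncertain,
                pathological=pathological,
                size=size,
                modifiers=mods,
            )
        )
    return asserted
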