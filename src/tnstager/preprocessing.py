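"""Report preprocessing: text cleaning, sectionizing, sentence splitting and
number tagging.

The cleaner is offset-preserving: every cleaned character knows which raw
character produced it, so downstream spans (always expressed in cleaned-text
coordinates) can be mapped back to the original report.  Cleaning is
idempotent.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional

from .config import Lexicon, PipelineConfig
from .types import (
    EmptyReportError,
    NumberToken,
    RawReport,
    Section,
    SectionedReport,
    Sentence,
)

_DIMENSION_GLYPHS = {"×", "✕", "*"}  # multiplication sign, variants, asterisk


def clean_text(raw: str) -> tuple[str, list[int]]:
    """Normalize a raw report string.

    Rules: CR/LF unification; runs of spaces/tabs collapse to one space; runs
    of blank lines collapse to one newline (trailing spaces dropped); decimal
    commas become dots only between digits; dimension glyphs (x-like symbols
    and ``*``) become a canonical ``x`` between digits.  Returns the cleaned
    text plus ``offset_map`` with ``offset_map[i]`` the raw index of the
    character behind ``cleaned[i]``.
    """
    if not raw or not raw.strip():
        raise EmptyReportError("report is empty after whitespace stripping")

    # pass 1: character substitutions that keep 1:1 raw indices
    chars: list[tuple[str, int]] = []
    n = len(raw)
    i = 0
    while i < n:
        ch = raw[i]
        if ch == "\r":
            chars.append(("\n", i))
            if i + 1 < n and raw[i + 1] == "\n":
                i += 2
                continue
            i += 1
            continue
        prev = chars[-1][0] if chars else ""
        nxt = raw[i + 1] if i + 1 < n else ""
        if ch == "×" or ch == "✕":
            chars.append(("x", i))
        elif ch == "*" and prev.isdigit() and (nxt.isdigit() or nxt in " \t"):
            chars.append(("x", i))
        elif ch == "," and prev.isdigit() and nxt.isdigit():
            chars.append((".", i))
        else:
            chars.append((ch, i))
        i += 1

    # pass 2: whitespace normalization with offset bookkeeping
    out: list[str] = []
    offsets: list[int] = []
    j = 0
    m = len(chars)
    # skip leading whitespace
    while j < m and chars[j][0].isspace():
        j += 1
    while j < m:
        ch, raw_idx = chars[j]
        if ch.isspace():
            k = j
            has_newline = False
            while k < m and chars[k][0].isspace():
                has_newline = has_newline or chars[k][0] == "\n"
                k += 1
            if k < m:  # drop trailing whitespace entirely
                out.append("\n" if has_newline else " ")
                offsets.append(raw_idx)
            j = k
        else:
            out.append(ch)
            offsets.append(raw_idx)
            j += 1
    cleaned = "".join(out)
    if not cleaned:
        raise EmptyReportError("report is empty after whitespace stripping")
    return cleaned, offsets


def sectionize(cleaned: str, lexicon: Lexicon) -> list[Section]:
    """Split cleaned text into sections at subheading matches.

    A heading is recognized only at a line start and only when followed by a
    colon (so the word "report" mid-sentence is never a heading).  Each
    heading opens a section extending to the next heading or end of text;
    text before the first heading — or all text when no heading is present —
    becomes an ``unknown`` section.
    """
    heading_patterns = lexicon.compiled["headings"]
    hits: list[tuple[int, int, int, str]] = []  # (heading_start, body_start, _, label)
    for line_start in _line_starts(cleaned):
        best: Optional[tuple[int, int, str]] = None
        for pat, label in heading_patterns:
            m = pat.match(cleaned, line_start)
            if not m:
                continue
            end = m.end()
            while end < len(cleaned) and cleaned[end] == " ":
                end += 1
            if end < len(cleaned) and cleaned[end] == ":":
                end += 1
                if best is None or end > best[1]:
                    best = (m.start(), end, label)
        if best:
            hits.append((best[0], best[1], line_start, best[2]))

    sections: list[Section] = []
    if not hits or hits[0][0] > 0:
        body_end = hits[0][0] if hits else len(cleaned)
        text = cleaned[:body_end]
        if text.strip():
            sections.append(Section("unknown", (0, body_end), text, (0, body_end)))
        elif hits:
            # leading whitespace-only prefix: fold it into the first heading's
            # full_span so full spans still tile the text
            hits[0] = (0, hits[0][1], hits[0][2], hits[0][3])
    for idx, (h_start, body_start, _, label) in enumerate(hits):
        body_end = hits[idx + 1][0] if idx + 1 < len(hits) else len(cleaned)
        sections.append(
            Section(
                name=label,
                span=(body_start, body_end),
                text=cleaned[body_start:body_end],
                full_span=(h_start, body_end),
                heading_surface=cleaned[h_start:body_start],
            )
        )
    return sections


def _line_starts(text: str) -> Iterable[int]:
    yield 0
    for i, ch in enumerate(text):
        if ch == "\n" and i + 1 < len(text):
            yield i + 1


_SENT_END = re.compile(r"[.?!]+")


def split_sentences(section: Section, abbreviations: Iterable[str] = ()) -> list[Sentence]:
    """Split a section body into sentences.

    Boundaries are sentence-final punctuation followed by whitespace/end of
    text, plus hard line breaks.  Splits are suppressed inside decimals
    (``1.2 cm``) and after configured abbreviations; enumeration periods like
    ``station 4R.`` only end a sentence when genuinely sentence-final, which
    the whitespace requirement already guarantees.
    """
    abbrev = {a.lower().rstrip(".") for a in abbreviations}
    text = section.text
    base = section.span[0]
    boundaries: list[int] = []
    for m in _SENT_END.finditer(text):
        end = m.end()
        if end < len(text) and not text[end].isspace():
            continue  # internal dot (decimal handled here too: "1.2")
        word = re.search(r"(\w+)$", text[: m.start()])
        if word and word.group(1).lower() in abbrev:
            continue
        if word and len(word.group(1)) == 1 and word.group(1).isupper() and word.group(1).isalpha():
            continue  # initials like "J."
        boundaries.append(end)
    boundaries.extend(i + 1 for i, ch in enumerate(text) if ch == "\n")
    boundaries = sorted(set(boundaries) | {len(text)})

    sentences: list[Sentence] = []
    start = 0
    for b in boundaries:
        chunk = text[start:b]
        lstrip = len(chunk) - len(chunk.lstrip())
        rstrip = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            s0, s1 = start + lstrip, b - rstrip
            sentences.append(
                Sentence(section.name, (base + s0, base + s1), text[s0:s1])
            )
        start = b
    return sentences


_NUMBER = re.compile(r"\d+(?:\.\d+)?")


def tag_numbers(sentence: Sentence) -> Sentence:
    """Tag every maximal digit run (with optional decimal point) in place;
    dimension-joined runs like ``12x44x29`` yield one token per component."""
    base = sentence.span[0]
    sentence.number_tokens = [
        NumberToken((base + m.start(), base + m.end()), m.group(), float(m.group()))
        for m in _NUMBER.finditer(sentence.text)
    ]
    return sentence


def preprocess(report: RawReport, config: PipelineConfig) -> SectionedReport:
    """Full preprocessing: clean, sectionize, split and number-tag."""
    cleaned, offset_map = clean_text(report.text)
    sections = sectionize(cleaned, config.lexicon)
    sentences: list[Sentence] = []
    for section in sections:
        for sent in split_sentences(section, config.lexicon.abbreviations):
            sentences.append(tag_numbers(sent))
    return SectionedReport(report.report_id, cleaned, sections, sentences, offset_map)
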