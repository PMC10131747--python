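"""Core in-memory objects shared across the staging pipeline.

All character spans are 0-based half-open intervals ``(start, end)`` into the
*cleaned* report text (one coordinate system across modules); raw-text offsets
are recoverable through :attr:`SectionedReport.offset_map`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

Span = tuple[int, int]

SECTION_NAMES = (
    "clinical_details",
    "modality",
    "report",
    "body_part",
    "impression",
    "unknown",
)

CONCEPT_KINDS = (
    "tumor",
    "lymph_node",
    "lymphadenopathy",
    "station",
    "laterality",
    "structure",
    "pathological_term",
    "presence_finding",
)

MODIFIER_CATEGORIES = ("negation", "uncertainty", "pathological")

T_LABELS = ("T1a", "T1b", "T1c", "T2", "T2a", "T2b", "T3", "T4")
N_LABELS = ("N0", "N1", "N2", "N3")

#: Ordinal rank used wherever two T labels are compared.  The undivided T2
#: (non-size criteria only) sits between T1c and the size-refined T2a.
T_RANK = {"T1a": 1.0, "T1b": 2.0, "T1c": 3.0, "T2": 3.5, "T2a": 4.0, "T2b": 5.0, "T3": 6.0, "T4": 7.0}
N_RANK = {"N0": 0, "N1": 1, "N2": 2, "N3": 3}


class EmptyReportError(ValueError):
    """Raised when a report contains no text after whitespace stripping."""


@dataclass(frozen=True)
class RawReport:
    report_id: str
    text: str


@dataclass(frozen=True)
class NumberToken:
    span: Span
    surface: str
    value: float


@dataclass(frozen=True)
class Section:
    """A named report section.

    ``span`` covers the section body; ``full_span`` additionally covers the
    heading and its separator, so consecutive ``full_span`` intervals tile the
    cleaned text exactly.
    """

    name: str
    span: Span
    text: str
    full_span: Span
    heading_surface: str = ""


@dataclass
class Sentence:
    section_name: str
    span: Span
    text: str
    number_tokens: list[NumberToken] = field(default_factory=list)


@dataclass
class SectionedReport:
    report_id: str
    cleaned_text: str
    sections: list[Section]
    sentences: list[Sentence]
    #: offset_map[i] = index into the raw text of the character that produced
    #: cleaned_text[i].
    offset_map: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class ConceptMention:
    concept_kind: str
    span: Span
    surface: str
    attributes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.concept_kind not in CONCEPT_KINDS:
            raise ValueError(f"unknown concept kind {self.concept_kind!r}")


@dataclass(frozen=True)
class Measurement:
    span: Span
    dimensions_mm: tuple[float, ...]
    unit_surface: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.dimensions_mm) <= 3:
            raise ValueError("a measurement carries 1-3 dimensions")
        if any(d <= 0 for d in self.dimensions_mm):
            raise ValueError("dimensions must be positive")

    @property
    def max_dim_mm(self) -> float:
        return max(self.dimensions_mm)

    @property
    def min_dim_mm(self) -> float:
        return min(self.dimensions_mm)


@dataclass(frozen=True)
class ContextModifier:
    category: str
    span: Span
    surface: str
    direction: str  # forward | backward | bidirectional

    def __post_init__(self) -> None:
        if self.category not in MODIFIER_CATEGORIES:
            raise ValueError(f"unknown modifier category {self.category!r}")
        if self.direction not in ("forward", "backward", "bidirectional"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class AssertedMention:
    """A concept mention with its contextual status resolved.

    The flags are fully determined by ``modifiers`` plus mention-intrinsic
    attributes (and, for the pathological flag on nodes, the bound short
    axis), which keeps every decision reconstructible for explanation.
    """

    mention: ConceptMention
    negated: bool = False
    uncertain: bool = False
    pathological: bool = False
    size: Optional[Measurement] = None
    modifiers: list[ContextModifier] = field(default_factory=list)


@dataclass
class NodeFinding:
    station_id: Optional[int]  # 1..14 or None when unknown
    side: str  # left | right | bilateral | ipsilateral | contralateral | unknown
    pathological: bool
    short_axis_mm: Optional[float] = None
    negated: bool = False
    uncertain: bool = False
    span: Optional[Span] = None


@dataclass
class Involvement:
    structure_id: str
    implies_t: str  # T2 | T3 | T4
    span: Optional[Span] = None


@dataclass
class FindingsSummary:
    """Structured intermediate consumed by the rule engine: tumor size, side
    and invaded structures plus every asserted lymph-node finding."""

    tumor_size_mm: Optional[float] = None
    tumor_side: Optional[str] = None  # left | right
    tumor_span: Optional[Span] = None
    involvements: list[Involvement] = field(default_factory=list)
    presence_findings: list[Involvement] = field(default_factory=list)
    nodes: list[NodeFinding] = field(default_factory=list)
    orphan_sizes: list[Measurement] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TraceEntry:
    rule: str
    detail: str
    spans: tuple[Span, ...] = ()


@dataclass
class TNStage:
    t_label: str
    n_label: str
    trace: list[TraceEntry] = field(default_factory=list)
    summary: Optional[FindingsSummary] = None

    @property
    def tn_label(self) -> str:
        return self.t_label + self.n_label
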