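"""The TNM-8 rule engine: reduce asserted mentions to a findings summary and
classify T, N and the combined TN stage, with an explanation trace.

T is the maximum of the size band (left-open/right-closed cut points from the
rules config) and the level implied by asserted involvements or presence
findings; an undivided ``T2`` is emitted only when a T2-level finding fires
with no tumor size at all (a size always refines to T2a/T2b).  N follows the
station map: supraclavicular is N3 regardless of side, subcarinal N2
regardless, other mediastinal stations N2 ipsilateral / N3 contralateral,
hilar and intrapulmonary stations N1 ipsilateral / N3 contralateral,
bilateral N3.  Missing information degrades to the explicit TX/NX labels —
never an exception.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .config import PipelineConfig, Rules, load_config
from .context import NODE_KINDS, detect_modifiers, link_modifiers
from .extraction import bind_measurements, extract_measurements, match_concepts, orphan_measurements
from .preprocessing import preprocess
from .types import (
    AssertedMention,
    ConceptMention,
    EmptyReportError,
    FindingsSummary,
    Involvement,
    NodeFinding,
    RawReport,
    SectionedReport,
    Sentence,
    Span,
    TNStage,
    TraceEntry,
    N_RANK,
    T_RANK,
)


def _nearest(anchor: Span, candidates: Sequence[ConceptMention]) -> Optional[ConceptMention]:
    def dist(c: ConceptMention) -> tuple:
        if c.span[0] < anchor[1] and anchor[0] < c.span[1]:
            d = 0
        elif c.span[1] <= anchor[0]:
            d = anchor[0] - c.span[1]
        else:
            d = c.span[0] - anchor[1]
        return (d, c.span[0])

    return min(candidates, key=dist) if candidates else None


def _counts_positive(am: AssertedMention, rules: Rules) -> bool:
    """Whether an asserted mention may contribute positive staging evidence."""
    if am.negated:
        return False
    if am.uncertain and not rules.uncertain_positive_counts:
        return False
    return True


def summarize(
    sentence_results: Sequence[tuple[Sentence, list[ConceptMention], list[AssertedMention]]],
    rules: Rules,
) -> FindingsSummary:
    """Aggregate per-sentence asserted mentions into a findings summary.

    Tumor size is the maximum over measurements bound to countable tumor
    mentions; the tumor side is the laterality mention nearest a tumor
    mention, first asserted side winning (later conflicts are recorded, not
    resolved).  Node side resolution: explicit R/L station suffix, then a
    laterality word in the sentence, then unknown.
    """
    summary = FindingsSummary()
    axis = max if rules.tumor_axis == "max" else min

    for sentence, mentions, asserted in sentence_results:
        if sentence.section_name in rules.excluded_sections:
            continue
        lateralities = [m for m in mentions if m.concept_kind == "laterality"]
        stations = [m for m in mentions if m.concept_kind == "station"]

        for am in asserted:
            kind = am.mention.concept_kind
            if kind == "tumor":
                if not _counts_positive(am, rules):
                    continue
                if summary.tumor_span is None:
                    summary.tumor_span = am.mention.span
                if am.size is not None:
                    size = axis(am.size.dimensions_mm)
                    if summary.tumor_size_mm is None or size > summary.tumor_size_mm:
                        summary.tumor_size_mm = size
                lat = _nearest(
                    am.mention.span,
                    [m for m in lateralities if m.attributes["value"] in ("left", "right")],
                )
                if lat is not None:
                    side = lat.attributes["value"]
                    if summary.tumor_side is None:
                        summary.tumor_side = side
                    elif summary.tumor_side != side:
                        summary.notes.append(
                            f"inconsistent tumor location: {summary.tumor_side} vs {side}"
                        )
            elif kind in ("structure", "presence_finding"):
                if not _counts_positive(am, rules):
                    continue
                ident = am.mention.attributes.get("structure_id") or am.mention.attributes.get(
                    "presence_id"
                )
                inv = Involvement(ident, am.mention.attributes["implies_t"], am.mention.span)
                if kind == "structure":
                    summary.involvements.append(inv)
                else:
                    summary.presence_findings.append(inv)
            elif kind in NODE_KINDS:
                station_mention = _nearest(am.mention.span, stations)
                station_id = station_mention.attributes["station_id"] if station_mention else None
                side = "unknown"
                if station_mention and station_mention.attributes.get("side"):
                    side = station_mention.attributes["side"]
                else:
                    lat = _nearest(am.mention.span, lateralities)
                    if lat is not None:
                        side = lat.attributes["value"]
                summary.nodes.append(
                    NodeFinding(
                        station_id=station_id,
                        side=side,
                        pathological=am.pathological,
                        short_axis_mm=(
                            min(am.size.dimensions_mm) if am.size is not None else None
                        ),
                        negated=am.negated,
                        uncertain=am.uncertain,
                        span=am.mention.span,
                    )
                )
    return summary


# ---- T classification ------------------------------------------------------

_UNDIVIDED_FLOOR = {"T2": "T2a", "T3": "T3", "T4": "T4"}


def classify_t(summary: FindingsSummary, rules: Rules) -> tuple[str, list[TraceEntry]]:
    trace: list[TraceEntry] = []
    findings = summary.involvements + summary.presence_findings

    size_label: Optional[str] = None
    if summary.tumor_size_mm is not None:
        size = summary.tumor_size_mm
        for band in rules.t_size_bands:
            if size <= band.upper:
                size_label = band.label
                break
        trace.append(
            TraceEntry(
                "t_size_band",
                f"tumor size {size:g} mm -> {size_label}",
                (summary.tumor_span,) if summary.tumor_span else (),
            )
        )

    has_size = size_label is not None
    label = size_label
    for inv in findings:
        # a stated size always refines T2 to T2a/T2b; without one, T2-level
        # findings yield the undivided T2
        implied = _UNDIVIDED_FLOOR[inv.implies_t] if has_size else inv.implies_t
        if label is None or T_RANK[implied] > T_RANK[label]:
            label = implied
            trace.append(
                TraceEntry(
                    "t_involvement",
                    f"{inv.structure_id} implies {inv.implies_t} -> {label}",
                    (inv.span,) if inv.span else (),
                )
            )

    if label is None:
        return "TX", [TraceEntry("t_unknown", "no tumor size and no involvement found")]
    return label, trace


# ---- N classification ------------------------------------------------------


def _relation(node: NodeFinding, tumor_side: Optional[str]) -> Optional[str]:
    """Side relation of a node to the tumor; None when undeterminable."""
    if node.side in ("ipsilateral", "contralateral", "bilateral"):
        return node.side
    if node.side in ("left", "right"):
        if tumor_side is None:
            return None
        return "ipsilateral" if node.side == tumor_side else "contralateral"
    return None  # unknown side


def classify_n(summary: FindingsSummary, rules: Rules) -> tuple[str, list[TraceEntry]]:
    trace: list[TraceEntry] = []
    supraclavicular = set(rules.station_groups.get("supraclavicular", [1]))
    midline = set(rules.station_groups.get("midline", [7]))
    mediastinal = set(rules.station_groups.get("mediastinal", range(2, 10)))
    hilar = set(rules.station_groups.get("hilar_intrapulmonary", range(10, 15)))

    active = [
        n
        for n in summary.nodes
        if n.pathological
        and not n.negated
        and (rules.uncertain_positive_counts or not n.uncertain)
    ]
    if not active:
        detail = "no pathological lymph nodes asserted"
        spans = tuple(n.span for n in summary.nodes if n.span)
        trace.append(TraceEntry("n_no_pathological_nodes", detail, spans))
        return "N0", trace

    best = "N0"
    indeterminate = False
    for node in active:
        rel = _relation(node, summary.tumor_side)
        contrib: Optional[str] = None
        if node.station_id in supraclavicular:
            contrib = "N3"
        elif rel == "bilateral":
            contrib = "N3"
        elif node.station_id in midline:
            contrib = "N2"
        elif rel == "contralateral":
            contrib = "N3"
        elif node.station_id in mediastinal and rel == "ipsilateral":
            contrib = "N2"
        elif node.station_id in hilar and rel == "ipsilateral":
            contrib = "N1"

        spans = (node.span,) if node.span else ()
        if contrib is None:
            indeterminate = True
            why = (
                "tumor side unknown"
                if node.side in ("left", "right") or (node.side == "unknown" and node.station_id)
                else "node station/side unresolved"
            )
            if summary.tumor_side is None and node.side in ("left", "right"):
                why = "pathological lateral node but tumor side unknown"
            trace.append(
                TraceEntry(
                    "n_indeterminate",
                    f"station {node.station_id or '?'} side {node.side}: {why}",
                    spans,
                )
            )
        else:
            trace.append(
                TraceEntry(
                    "n_station_rule",
                    f"station {node.station_id or '?'} relation {rel or 'n/a'} -> {contrib}",
                    spans,
                )
            )
            if N_RANK[contrib] > N_RANK[best]:
                best = contrib

    if indeterminate and best != "N3":
        trace.append(
            TraceEntry(
                "n_unresolved",
                "an unplaceable pathological node caps confidence below a definite stage",
            )
        )
        return "NX", trace
    return best, trace


# ---- full pipeline ---------------------------------------------------------


def process_report(
    report: RawReport, config: PipelineConfig
) -> tuple[SectionedReport, list[tuple[Sentence, list[ConceptMention], list[AssertedMention]]], FindingsSummary]:
    sectioned = preprocess(report, config)
    results = []
    all_orphans = []
    for sentence in sectioned.sentences:
        mentions = match_concepts(sentence, config.lexicon)
        measurements = extract_measurements(sentence)
        bindings = bind_measurements(mentions, measurements, sentence)
        modifiers = detect_modifiers(sentence, config.lexicon)
        asserted = link_modifiers(mentions, modifiers, sentence, config.rules, bindings)
        all_orphans.extend(orphan_measurements(bindings, measurements))
        results.append((sentence, mentions, asserted))
    summary = summarize(results, config.rules)
    summary.orphan_sizes = all_orphans
    return sectioned, results, summary


def classify_tn(
    text: str, config: Optional[PipelineConfig] = None, report_id: str = "report"
) -> TNStage:
    """Run the full pipeline on one report text and return the TN stage with
    its explanation trace.  Deterministic for fixed text and config; missing
    or empty input yields TX/NX labels rather than an exception."""
    if config is None:
        config = load_config()
    try:
        _, results, summary = process_report(RawReport(report_id, text), config)
    except EmptyReportError:
        return TNStage("TX", "NX", [], FindingsSummary())
    t_label, t_trace = classify_t(summary, config.rules)
    n_label, n_trace = classify_n(summary, config.rules)
    return TNStage(t_label, n_label, t_trace + n_trace, summary)


def stage_to_dict(report_id: str, stage: TNStage) -> dict:
    """JSON-serializable structured output for one report."""
    s = stage.summary or FindingsSummary()
    return {
        "report_id": report_id,
        "t_label": stage.t_label,
        "n_label": stage.n_label,
        "tn_label": stage.tn_label,
        "findings": {
            "tumor_size_mm": s.tumor_size_mm,
            "tumor_side": s.tumor_side,
            "involvements": [i.structure_id for i in s.involvements],
            "presence_findings": [i.structure_id for i in s.presence_findings],
            "nodes": [
                {
                    "station_id": n.station_id,
                    "side": n.side,
                    "pathological": n.pathological,
                    "short_axis_mm": n.short_axis_mm,
                    "negated": n.negated,
                    "uncertain": n.uncertain,
                }
                for n in s.nodes
            ],
            "notes": s.notes,
        },
        "trace": [
            {"rule": t.rule, "detail": t.detail, "spans": [list(sp) for sp in t.spans]}
            for t in stage.trace
        ],
    }
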