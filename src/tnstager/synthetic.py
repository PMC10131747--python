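"""Gold-labelled synthetic chest-CT staging reports.

The generator renders sectioned English reports from sentence templates: one
primary tumor description (size and/or an invaded structure forcing the
target T) and a node description set whose oracle N equals the target, plus
negated distractors and optional noise (typos, hedged extra findings,
incomplete node mentions, heading omission) mirroring the error sources seen
in real dictated reports.  Gold labels come from the literal TNM-8 tables in
:mod:`tnstager.tnm_tables`, computed from the sampled recipe — never from
the staging pipeline under test.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field, field_validator

from .config import default_resource_path
from .tnm_tables import STRUCTURE_T_TABLE, T_SIZE_TABLE, oracle_n, oracle_t
from .types import N_LABELS, T_LABELS


class GenerationError(ValueError):
    pass


#: Combined TN-class counts of the reference training cohort (N=95) used as
#: the default label distribution; classes with zero count get zero mass.
TRAINING_LABEL_COUNTS: dict[str, int] = {
    "T1aN0": 0, "T1aN1": 0, "T1aN2": 1, "T1aN3": 0,
    "T1bN0": 7, "T1bN1": 2, "T1bN2": 1, "T1bN3": 0,
    "T1cN0": 7, "T1cN1": 0, "T1cN2": 2, "T1cN3": 3,
    "T2N0": 0, "T2N1": 0, "T2N2": 4, "T2N3": 1,
    "T2aN0": 4, "T2aN1": 2, "T2aN2": 2, "T2aN3": 3,
    "T2bN0": 4, "T2bN1": 0, "T2bN2": 4, "T2bN3": 3,
    "T3N0": 5, "T3N1": 1, "T3N2": 6, "T3N3": 4,
    "T4N0": 7, "T4N1": 0, "T4N2": 13, "T4N3": 9,
}

ALL_TN_CLASSES = tuple(f"{t}{n}" for t in T_LABELS for n in N_LABELS)


def default_label_distribution() -> dict[str, float]:
    total = sum(TRAINING_LABEL_COUNTS.values())
    return {k: v / total for k, v in TRAINING_LABEL_COUNTS.items() if v > 0}


def split_tn(label: str) -> tuple[str, str]:
    i = label.index("N")
    t, n = label[:i], label[i:]
    if t not in T_LABELS or n not in N_LABELS:
        raise GenerationError(f"unknown TN class {label!r}")
    return t, n


class GeneratorConfig(BaseModel):
    n_reports: int = 192
    label_distribution: dict[str, float] = Field(default_factory=default_label_distribution)
    typo_rate: float = 0.0
    negation_distractor_rate: float = 0.0
    multi_node_rate: float = 0.0
    uncertainty_rate: float = 0.0
    heading_omission_rate: float = 0.0
    incomplete_node_rate: float = 0.0
    inconsistent_location_rate: float = 0.0
    seed: int = 0
    template_path: Optional[str] = None

    @field_validator("label_distribution")
    @classmethod
    def _check_dist(cls, v: dict[str, float]) -> dict[str, float]:
        for label in v:
            split_tn(label)
        mass = sum(p for p in v.values() if p > 0)
        if abs(mass - 1.0) > 1e-9:
            raise ValueError(f"label distribution mass is {mass}, expected 1")
        if any(p < 0 for p in v.values()):
            raise ValueError("label probabilities must be non-negative")
        return v


@dataclass
class GoldReport:
    report_id: str
    text: str
    gold_t: str
    gold_n: str
    recipe: dict = field(default_factory=dict)

    @property
    def gold_tn(self) -> str:
        return self.gold_t + self.gold_n


def _load_templates(path: Optional[Union[str, Path]]) -> dict:
    path = path or default_resource_path("templates_en.yaml")
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


# size bands, as sampling ranges of whole millimetres
_SIZE_RANGES = {
    lab: (int(lo) + 1, int(hi if hi != float("inf") else 120.0)) for lo, hi, lab in T_SIZE_TABLE
}
_STRUCTS_BY_LEVEL: dict[str, list[str]] = {}
for _sid, _lvl in STRUCTURE_T_TABLE.items():
    _STRUCTS_BY_LEVEL.setdefault(_lvl, []).append(_sid)

_OPPOSITE = {"left": "right", "right": "left"}


def _render_size(size_mm: int, rng: random.Random) -> str:
    style = rng.random()
    if style < 0.4:
        return f"{size_mm} mm"
    if style < 0.7:
        cm = size_mm / 10
        return f"{cm:g} cm"
    minor = max(2, int(size_mm * rng.uniform(0.5, 0.9)))
    return f"{size_mm}x{minor} mm"


def _render_station(station: int, side_letter: Optional[str], rng: random.Random) -> str:
    suffix = side_letter or ""
    return rng.choice([f"station {station}{suffix}", f"level {station}{suffix}"])


def _apply_typo(sentence: str, rng: random.Random) -> str:
    words = sentence.split(" ")
    idxs = [i for i, w in enumerate(words) if len(w.strip(".,")) >= 5 and w.isalpha()]
    if not idxs:
        idxs = [i for i, w in enumerate(words) if len(w) >= 5]
    if not idxs:
        return sentence
    i = rng.choice(idxs)
    w = words[i]
    j = rng.randrange(1, len(w.rstrip(".,")) - 1)
    words[i] = w[:j] + w[j + 1] + w[j] + w[j + 2 :]
    return " ".join(words)


#: Stations whose numeric lexicon pattern accepts an R/L suffix; the rest
#: (midline or A/P-sided stations) get their side as a laterality word.
_SUFFIX_STATIONS = {1, 2, 4, 8, 9, 10, 11, 12, 13, 14}


def _sample_node(
    target_n: str, tumor_side: str, rng: random.Random
) -> tuple[int, str, Optional[str]]:
    """(station, relation, rendered side letter or None) realizing target_n."""
    if target_n == "N1":
        station = rng.randrange(10, 15)
        return station, "ipsilateral", tumor_side[0].upper()
    if target_n == "N2":
        station = rng.choice([2, 3, 4, 5, 6, 7, 8, 9])
        letter = (
            tumor_side[0].upper() if station in _SUFFIX_STATIONS and station != 7 else None
        )
        return station, "ipsilateral", letter
    if target_n == "N3":
        mode = rng.random()
        if mode < 0.34:
            return 1, "ipsilateral", None  # supraclavicular: N3 regardless
        if mode < 0.67:
            station = rng.choice([2, 3, 4, 8, 9, 10, 11, 12, 13, 14])
            letter = (
                _OPPOSITE[tumor_side][0].upper() if station in _SUFFIX_STATIONS else None
            )
            return station, "contralateral", letter
        station = rng.choice([2, 4, 7, 10, 11])
        return station, "bilateral", None
    raise GenerationError(f"cannot sample a node for {target_n}")


def generate_report(
    target_t: str,
    target_n: str,
    config: GeneratorConfig,
    rng: random.Random,
    templates: Optional[dict] = None,
    report_id: str = "synthetic-0",
) -> GoldReport:
    """One synthetic report whose oracle labels equal the targets.

    The sampled recipe (template ids, size, structures, stations, sides,
    noise flags) is recorded verbatim as the label's provenance.
    """
    if target_t not in T_LABELS:
        raise GenerationError(f"unreachable T label {target_t!r}")
    if target_n not in N_LABELS:
        raise GenerationError(f"unreachable N label {target_n!r}")
    tpl = templates if templates is not None else _load_templates(config.template_path)
    recipe: dict = {"target_t": target_t, "target_n": target_n, "noise": []}

    tumor_side = rng.choice(["left", "right"])
    recipe["tumor_side"] = tumor_side
    lobe = rng.choice(tpl["lobes"])
    tumor_word = rng.choice(tpl["tumor_words"])

    # --- T realisation ------------------------------------------------------
    structures: list[str] = []
    size_mm: Optional[int] = None
    if target_t == "T2":
        # undivided T2: a T2-level finding with no size stated
        structures = [rng.choice(_STRUCTS_BY_LEVEL["T2"])]
    else:
        lo, hi = _SIZE_RANGES[target_t]
        if target_t in ("T3", "T4") and rng.random() < 0.4:
            # involvement-forced stage with a smaller tumor
            structures = [rng.choice(_STRUCTS_BY_LEVEL[target_t])]
            sub_lo, _ = _SIZE_RANGES["T1a"]
            size_mm = rng.randrange(sub_lo, hi + 1)
        else:
            size_mm = rng.randrange(lo, hi + 1)
            if rng.random() < 0.3:
                # optional co-finding that must not outrank the size band
                allowed = [
                    lvl
                    for lvl in ("T2", "T3", "T4")
                    if oracle_t(size_mm, [_STRUCTS_BY_LEVEL[lvl][0]]) == target_t
                ]
                if allowed:
                    structures = [rng.choice(_STRUCTS_BY_LEVEL[rng.choice(allowed)])]
    recipe["size_mm"] = size_mm
    recipe["structures"] = list(structures)

    involvement = ""
    if structures:
        involvement = rng.choice(tpl["involvement_phrases"][structures[0]])
    if size_mm is not None:
        tumor_sentence = rng.choice(tpl["tumor_sized"]).format(
            size=_render_size(size_mm, rng),
            tumor_word=tumor_word,
            side=tumor_side,
            lobe=lobe,
            involvement=involvement,
        )
    else:
        tumor_sentence = rng.choice(tpl["tumor_unsized"]).format(
            tumor_word=tumor_word, side=tumor_side, lobe=lobe, involvement=involvement
        )

    # --- N realisation ------------------------------------------------------
    node_sentences: list[str] = []
    nodes: list[dict] = []
    if target_n == "N0":
        node_sentences.append(rng.choice(tpl["node_negated"]))
        recipe["negated_node_sentence"] = node_sentences[-1]
    else:
        station, relation, letter = _sample_node(target_n, tumor_side, rng)
        node = {"station": station, "relation": relation, "pattern": rng.choice([1, 2, 3])}
        nodes.append(node)
        node_sentences.append(
            _render_node_sentence(node, letter, tumor_side, tpl, config, rng, recipe)
        )
        if rng.random() < config.multi_node_rate:
            # a second node in the same sentence, never outranking the target
            extra_station, extra_rel, extra_letter = _sample_node(
                target_n, tumor_side, rng
            )
            extra = {"station": extra_station, "relation": extra_rel, "pattern": 2}
            nodes.append(extra)
            extra_sentence = _render_node_sentence(
                extra, extra_letter, tumor_side, tpl, config, rng, recipe
            )
            node_sentences[-1] = (
                node_sentences[-1].rstrip(".") + ", and " + _decapitalize(extra_sentence)
            )
            recipe["noise"].append("multi_node")
    recipe["nodes"] = nodes

    # --- assemble -----------------------------------------------------------
    report_lines = [tumor_sentence] + node_sentences
    if rng.random() < config.negation_distractor_rate:
        report_lines.append(rng.choice(tpl["distractors"]))
        recipe["noise"].append("negation_distractor")
    if rng.random() < config.uncertainty_rate and target_n != "N3":
        # hedged extra finding at a higher-stage location; excluded from the
        # gold label (conservative uncertainty handling is the study default)
        st = rng.choice([1, 4])
        report_lines.append(
            rng.choice(tpl["node_uncertain"]).format(
                station=_render_station(st, None, rng)
            )
        )
        recipe["noise"].append("uncertainty")
    rng.shuffle(report_lines)

    if rng.random() < config.inconsistent_location_rate:
        impression = rng.choice(tpl["impression"]).format(side=_OPPOSITE[tumor_side])
        recipe["noise"].append("inconsistent_location")
    else:
        impression = rng.choice(tpl["impression"]).format(side=tumor_side)

    sections = [
        ("Clinical details", rng.choice(tpl["section_text"]["clinical_details"])),
        ("Modality", rng.choice(tpl["section_text"]["modality"])),
        ("Body part", rng.choice(tpl["section_text"]["body_part"])),
        ("Report", " ".join(report_lines)),
        ("Impression", impression),
    ]
    if rng.random() < config.heading_omission_rate:
        text = "\n".join(body for _, body in sections)
        recipe["noise"].append("heading_omission")
    else:
        text = "\n".join(f"{head}: {body}" for head, body in sections)

    if rng.random() < config.typo_rate:
        text = _apply_typo(text, rng)
        recipe["noise"].append("typo")

    gold_t = oracle_t(size_mm, structures)
    gold_n = oracle_n([(n["station"], n["relation"]) for n in nodes])
    if (gold_t, gold_n) != (target_t, target_n):
        raise GenerationError(
            f"recipe realizes {gold_t}{gold_n}, not the target {target_t}{target_n}"
        )
    return GoldReport(report_id, text, gold_t, gold_n, recipe)


def _decapitalize(s: str) -> str:
    words = s.split(" ", 1)
    first = words[0]
    if first.lower() in ("there", "the", "a", "an", "at"):
        first = first.lower()
    return " ".join([first] + words[1:])


def _render_node_sentence(
    node: dict,
    letter: Optional[str],
    tumor_side: str,
    tpl: dict,
    config: GeneratorConfig,
    rng: random.Random,
    recipe: dict,
) -> str:
    relation = node["relation"]
    station = node["station"]
    if relation == "bilateral":
        station_text = f"{_render_station(station, None, rng)} bilaterally"
    elif relation == "contralateral" and (letter is None or rng.random() < 0.5):
        station_text = f"the contralateral {_render_station(station, None, rng)}"
    elif relation == "ipsilateral" and letter is None and station not in (1, 7):
        station_text = f"the ipsilateral {_render_station(station, None, rng)}"
    else:
        station_text = _render_station(station, letter, rng)

    if rng.random() < config.incomplete_node_rate:
        station_text = ""
        recipe["noise"].append("incomplete_node")

    pattern = node["pattern"]
    if pattern == 2:
        short = rng.randrange(11, 26)
        long_axis = short + rng.randrange(2, 15)
        nsize = rng.choice([f"{short} mm", f"{long_axis}x{short} mm"])
        node["short_axis_mm"] = short
        sentence = rng.choice(tpl["node_sized"]).format(station=station_text, nsize=nsize)
    elif pattern == 1:
        sentence = rng.choice(tpl["node_compound"]).format(station=station_text)
    else:
        sentence = rng.choice(tpl["node_modifier"]).format(station=station_text)
    if not station_text:
        sentence = sentence.replace(" at  ", " ").replace(" at .", ".").replace("at ,", ",")
        sentence = " ".join(sentence.split()).replace(" .", ".")
    return sentence


def generate_corpus(config: GeneratorConfig) -> list[GoldReport]:
    """Draw ``n_reports`` reports from the configured TN-class distribution;
    bit-exact for a fixed seed."""
    rng = random.Random(config.seed)
    templates = _load_templates(config.template_path)
    labels = sorted(config.label_distribution)
    weights = [config.label_distribution[lab] for lab in labels]
    reports: list[GoldReport] = []
    for i in range(config.n_reports):
        label = rng.choices(labels, weights=weights, k=1)[0]
        t, n = split_tn(label)
        reports.append(
            generate_report(t, n, config, rng, templates, report_id=f"synthetic-{i:04d}")
        )
    return reports


def write_corpus_jsonl(reports: list[GoldReport], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(json.dumps({"report_id": r.report_id, "text": r.text}) + "\n")


def write_gold_csv(reports: list[GoldReport], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["report_id", "t", "n"])
        for r in reports:
            writer.writerow([r.report_id, r.gold_t, r.gold_n])


#: Map from generator noise kinds to the error-taxonomy categories used by
#: the evaluation harness.
NOISE_CATEGORY = {
    "typo": "reporter",
    "incomplete_node": "reporter",
    "inconsistent_location": "reporter",
    "heading_omission": "data_selection",
    "uncertainty": "context_missing",
    "multi_node": "context_complexity",
    "negation_distractor": "context_complexity",
}
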