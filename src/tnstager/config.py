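"""Configuration loading and validation.

The whole lexicon (headings, concept synonyms, context modifiers) lives in one
YAML file and the rule parameters (size cut points, thresholds, scope
settings) in another, so porting the pipeline to a different language or
institution is a configuration swap rather than a code change.  Files are
schema-validated with pydantic and every regex is compiled at load time;  a
malformed pattern raises :class:`ConfigurationError` naming the pattern.
"""

from __future__ import annotations

import math
import re
from importlib import resources
from pathlib import Path
from typing import Any, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class ConfigurationError(ValueError):
    pass


def _compile(pattern: str, where: str) -> re.Pattern:
    """Compile a lexicon pattern case-insensitively inside word boundaries."""
    try:
        return re.compile(rf"\b(?:{pattern})\b", re.IGNORECASE)
    except re.error as exc:
        raise ConfigurationError(f"malformed pattern {pattern!r} in {where}: {exc}") from exc


class LexiconEntry(BaseModel):
    """A single concept pattern, optionally carrying preset attributes."""

    model_config = ConfigDict(frozen=True)

    pattern: str
    pathological: bool = False


class StructureEntry(BaseModel):
    implies_t: str
    patterns: list[str]

    @field_validator("implies_t")
    @classmethod
    def _check_level(cls, v: str) -> str:
        if v not in ("T2", "T3", "T4"):
            raise ValueError(f"implies_t must be T2/T3/T4, got {v!r}")
        return v


class ModifierEntry(BaseModel):
    category: str
    pattern: str
    direction: str = "forward"

    @field_validator("category")
    @classmethod
    def _check_category(cls, v: str) -> str:
        if v not in ("negation", "uncertainty", "pathological"):
            raise ValueError(f"unknown modifier category {v!r}")
        return v

    @field_validator("direction")
    @classmethod
    def _check_direction(cls, v: str) -> str:
        if v not in ("forward", "backward", "bidirectional"):
            raise ValueError(f"unknown direction {v!r}")
        return v


class Lexicon(BaseModel):
    """Validated lexicon with all patterns pre-compiled."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    def __init__(self, **data: Any) -> None:
        try:
            super().__init__(**data)
        except Exception as exc:  # surface pattern-compilation problems as config errors
            if "malformed pattern" in str(exc):
                raise ConfigurationError(str(exc)) from exc
            raise

    headings: dict[str, str]
    abbreviations: list[str] = Field(default_factory=list)
    tumor: list[str]
    lymph_node: list[LexiconEntry]
    lymphadenopathy: list[str]
    stations: dict[int, list[str]]
    laterality: dict[str, list[str]]
    structures: dict[str, StructureEntry]
    presence_findings: dict[str, StructureEntry]
    pathological_terms: list[str]
    context_modifiers: list[ModifierEntry]

    # compiled artefacts, populated by model_post_init
    compiled: dict[str, Any] = Field(default_factory=dict, exclude=True, repr=False)

    @field_validator("stations")
    @classmethod
    def _check_stations(cls, v: dict[int, list[str]]) -> dict[int, list[str]]:
        bad = [s for s in v if not 1 <= s <= 14]
        if bad:
            raise ValueError(f"station ids must be 1..14, got {bad}")
        return v

    @field_validator("laterality")
    @classmethod
    def _check_laterality(cls, v: dict[str, list[str]]) -> dict[str, list[str]]:
        allowed = {"left", "right", "ipsilateral", "contralateral", "bilateral"}
        bad = set(v) - allowed
        if bad:
            raise ValueError(f"unknown laterality values {sorted(bad)}")
        return v

    def model_post_init(self, __context: Any) -> None:
        c: dict[str, Any] = {}
        c["headings"] = [(_compile(p, "headings"), label) for p, label in self.headings.items()]
        c["tumor"] = [_compile(p, "tumor") for p in self.tumor]
        c["lymph_node"] = [(_compile(e.pattern, "lymph_node"), e) for e in self.lymph_node]
        c["lymphadenopathy"] = [_compile(p, "lymphadenopathy") for p in self.lymphadenopathy]
        c["stations"] = [
            (_compile(p, f"stations[{sid}]"), sid) for sid, pats in self.stations.items() for p in pats
        ]
        c["laterality"] = [
            (_compile(p, f"laterality[{val}]"), val) for val, pats in self.laterality.items() for p in pats
        ]
        c["structures"] = [
            (_compile(p, f"structures[{sid}]"), sid, entry.implies_t)
            for sid, entry in self.structures.items()
            for p in entry.patterns
        ]
        c["presence_findings"] = [
            (_compile(p, f"presence_findings[{pid}]"), pid, entry.implies_t)
            for pid, entry in self.presence_findings.items()
            for p in entry.patterns
        ]
        c["pathological_terms"] = [_compile(p, "pathological_terms") for p in self.pathological_terms]
        c["context_modifiers"] = [
            (_compile(m.pattern, f"context_modifiers[{m.category}]"), m) for m in self.context_modifiers
        ]
        self.compiled.update(c)

    @property
    def structure_t_map(self) -> dict[str, str]:
        out = {sid: e.implies_t for sid, e in self.structures.items()}
        out.update({pid: e.implies_t for pid, e in self.presence_findings.items()})
        return out


class SizeBand(BaseModel):
    label: str
    max_mm: Optional[float] = None  # None = open-ended top band

    @property
    def upper(self) -> float:
        return math.inf if self.max_mm is None else self.max_mm


class Rules(BaseModel):
    """Rule-engine parameters (TNM-8 defaults shipped in rules_tnm8.yaml)."""

    t_size_bands: list[SizeBand]
    node_short_axis_threshold_mm: float = 10.0
    tumor_axis: str = "max"
    node_axis: str = "min"
    uncertain_positive_counts: bool = False
    scope_window_tokens: int = 8
    scope_terminators: list[str] = Field(default_factory=lambda: ["but", "however", "although"])
    modifier_broadcast: bool = False
    excluded_sections: list[str] = Field(default_factory=list)
    station_groups: dict[str, list[int]] = Field(default_factory=dict)

    @field_validator("t_size_bands")
    @classmethod
    def _check_bands(cls, v: list[SizeBand]) -> list[SizeBand]:
        uppers = [b.upper for b in v]
        if sorted(uppers) != uppers or len(set(uppers)) != len(uppers):
            raise ValueError("size bands must have strictly increasing upper bounds")
        if not v or v[-1].max_mm is not None:
            raise ValueError("last size band must be open-ended (max_mm: null)")
        return v


class PipelineConfig(BaseModel):
    lexicon: Lexicon
    rules: Rules


def _read_yaml(path: Union[str, Path]) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a YAML mapping at top level")
    return data


def default_resource_path(name: str) -> Path:
    return Path(str(resources.files("tnstager") / "resources" / name))


def load_lexicon(path: Optional[Union[str, Path]] = None) -> Lexicon:
    path = path or default_resource_path("lexicon_en.yaml")
    return Lexicon(**_read_yaml(path))


def load_rules(path: Optional[Union[str, Path]] = None) -> Rules:
    path = path or default_resource_path("rules_tnm8.yaml")
    return Rules(**_read_yaml(path))


def load_config(
    lexicon_path: Optional[Union[str, Path]] = None,
    rules_path: Optional[Union[str, Path]] = None,
    **rule_overrides: Any,
) -> PipelineConfig:
    """Load lexicon + rules (shipped English/TNM-8 defaults when paths are
    omitted); keyword overrides patch individual rule parameters."""
    rules = load_rules(rules_path)
    if rule_overrides:
        rules = rules.model_copy(update=rule_overrides)
    return PipelineConfig(lexicon=load_lexicon(lexicon_path), rules=rules)
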