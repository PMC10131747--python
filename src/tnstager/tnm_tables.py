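"""Literal transcription of the TNM-8 pulmonary T/N decision tables.

This module is the package's independent staging oracle: a direct, enumerated
lookup of the 8th-edition tables with no shared code or configuration with
the rule engine in :mod:`tnstager.staging`.  The synthetic-corpus generator
derives its gold labels here (never from the pipeline under test), and the
test suite checks the rule engine against these tables exhaustively.
"""

from __future__ import annotations

from typing import Iterable, Optional

# ---- T: size bands in mm, left-open / right-closed -------------------------

T_SIZE_TABLE: tuple[tuple[float, float, str], ...] = (
    (0.0, 10.0, "T1a"),
    (10.0, 20.0, "T1b"),
    (20.0, 30.0, "T1c"),
    (30.0, 40.0, "T2a"),
    (40.0, 50.0, "T2b"),
    (50.0, 70.0, "T3"),
    (70.0, float("inf"), "T4"),
)

# ---- T: level implied by each invaded structure / presence finding ---------

STRUCTURE_T_TABLE: dict[str, str] = {
    "visceral_pleura": "T2",
    "main_bronchus": "T2",
    "atelectasis": "T2",
    "obstructive_pneumonitis": "T2",
    "chest_wall": "T3",
    "parietal_pericardium": "T3",
    "phrenic_nerve": "T3",
    "same_lobe_nodule": "T3",
    "mediastinum": "T4",
    "diaphragm": "T4",
    "heart": "T4",
    "great_vessels": "T4",
    "carina": "T4",
    "trachea": "T4",
    "esophagus": "T4",
    "vertebra": "T4",
    "recurrent_laryngeal_nerve": "T4",
    "other_lobe_nodule": "T4",
}

_T_ORDER = {"T1a": 1.0, "T1b": 2.0, "T1c": 3.0, "T2": 3.5, "T2a": 4.0, "T2b": 5.0, "T3": 6.0, "T4": 7.0}
_UNDIVIDED_FLOOR = {"T2": "T2a", "T3": "T3", "T4": "T4"}  # floor once a size exists


def oracle_t(size_mm: Optional[float], structures: Iterable[str] = ()) -> str:
    """T substage for a tumor of ``size_mm`` (None = no size found) with the
    given invaded structures/presence findings (ids of STRUCTURE_T_TABLE)."""
    levels = [STRUCTURE_T_TABLE[s] for s in structures]
    if size_mm is None:
        if not levels:
            return "TX"
        return max(levels, key=_T_ORDER.__getitem__)
    label = next(lab for lo, hi, lab in T_SIZE_TABLE if lo < size_mm <= hi)
    for lvl in levels:
        floor = _UNDIVIDED_FLOOR[lvl]
        if _T_ORDER[floor] > _T_ORDER[label]:
            label = floor
    return label


# ---- N: fully enumerated (station, side relation) -> contribution ----------
#
# Station 1 (supraclavicular): N3 regardless of side.
# Bilateral involvement: N3 at any station below the supraclavicular row.
# Station 7 (subcarinal, midline): N2 for ipsi- and contralateral alike.
# Stations 2-6, 8-9 (mediastinal): ipsilateral N2, contralateral N3.
# Stations 10-14 (hilar/intrapulmonary): ipsilateral N1, contralateral N3.

N_TABLE: dict[tuple[int, str], str] = {
    (1, "ipsilateral"): "N3", (1, "contralateral"): "N3", (1, "bilateral"): "N3",
    (2, "ipsilateral"): "N2", (2, "contralateral"): "N3", (2, "bilateral"): "N3",
    (3, "ipsilateral"): "N2", (3, "contralateral"): "N3", (3, "bilateral"): "N3",
    (4, "ipsilateral"): "N2", (4, "contralateral"): "N3", (4, "bilateral"): "N3",
    (5, "ipsilateral"): "N2", (5, "contralateral"): "N3", (5, "bilateral"): "N3",
    (6, "ipsilateral"): "N2", (6, "contralateral"): "N3", (6, "bilateral"): "N3",
    (7, "ipsilateral"): "N2", (7, "contralateral"): "N2", (7, "bilateral"): "N3",
    (8, "ipsilateral"): "N2", (8, "contralateral"): "N3", (8, "bilateral"): "N3",
    (9, "ipsilateral"): "N2", (9, "contralateral"): "N3", (9, "bilateral"): "N3",
    (10, "ipsilateral"): "N1", (10, "contralateral"): "N3", (10, "bilateral"): "N3",
    (11, "ipsilateral"): "N1", (11, "contralateral"): "N3", (11, "bilateral"): "N3",
    (12, "ipsilateral"): "N1", (12, "contralateral"): "N3", (12, "bilateral"): "N3",
    (13, "ipsilateral"): "N1", (13, "contralateral"): "N3", (13, "bilateral"): "N3",
    (14, "ipsilateral"): "N1", (14, "contralateral"): "N3", (14, "bilateral"): "N3",
}

_N_ORDER = {"N0": 0, "N1": 1, "N2": 2, "N3": 3}


def oracle_n(nodes: Iterable[tuple[int, str]]) -> str:
    """N substage given pathological nodes as (station 1..14, side relation)
    pairs; no pathological nodes means N0."""
    label = "N0"
    for station, relation in nodes:
        contrib = N_TABLE[(station, relation)]
        if _N_ORDER[contrib] > _N_ORDER[label]:
            label = contrib
    return label


def oracle_tn(
    size_mm: Optional[float],
    structures: Iterable[str],
    nodes: Iterable[tuple[int, str]],
) -> tuple[str, str]:
    return oracle_t(size_mm, structures), oracle_n(nodes)
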