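"""Scoring of predicted against gold TN stages.

Accuracies and confusion matrices are computed per stage (T, N) and for the
combined TN label; precision/recall/F1 are one-vs-rest per label and then
support-weighted (weights proportional to the number of true instances of
each label), so labels absent from the gold set contribute nothing.  TX/NX
predictions count as plain errors and appear as dedicated rows/columns;
under/over-staging is tallied on the ordinal stage scales with X labels
excluded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .types import N_LABELS, N_RANK, T_LABELS, T_RANK

ERROR_CATEGORIES = (
    "data_selection",
    "context_missing",
    "context_complexity",
    "concept_missing",
    "concept_ambiguity",
    "concept_complexity",
    "reporter",
)


class EvaluationError(ValueError):
    pass


StagePair = tuple[str, str]  # (t_label, n_label)


@dataclass
class EvaluationResult:
    n_reports: int
    accuracy_t: float
    accuracy_n: float
    accuracy_tn: float
    confusion_t: pd.DataFrame
    confusion_n: pd.DataFrame
    confusion_tn: pd.DataFrame
    weighted: dict[str, dict[str, float]]  # per scale: precision/recall/f1
    deltas: dict[str, int]  # t_understaged/t_overstaged/n_understaged/n_overstaged
    x_predictions: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_reports": self.n_reports,
            "accuracy_t": self.accuracy_t,
            "accuracy_n": self.accuracy_n,
            "accuracy_tn": self.accuracy_tn,
            "weighted": self.weighted,
            "deltas": self.deltas,
            "x_predictions": self.x_predictions,
        }


def _check_keys(predictions: Mapping[str, StagePair], gold: Mapping[str, StagePair]) -> None:
    missing = sorted(set(gold) - set(predictions))
    extra = sorted(set(predictions) - set(gold))
    if missing or extra:
        raise EvaluationError(
            f"prediction/gold key mismatch: missing={missing[:10]} extra={extra[:10]}"
        )


def _confusion(gold: Sequence[str], pred: Sequence[str], order: Sequence[str]) -> pd.DataFrame:
    labels = [lab for lab in order if lab in set(gold) | set(pred)]
    labels += sorted((set(gold) | set(pred)) - set(labels))
    mat = confusion_matrix(gold, pred, labels=labels)
    return pd.DataFrame(mat, index=pd.Index(labels, name="gold"), columns=pd.Index(labels, name="pred"))


def _weighted_prf(gold: Sequence[str], pred: Sequence[str]) -> dict[str, float]:
    p, r, f, _ = precision_recall_fscore_support(
        gold, pred, average="weighted", zero_division=0
    )
    return {"precision": float(p), "recall": float(r), "f1": float(f)}


def stage_ordering_deltas(
    predictions: Mapping[str, StagePair], gold: Mapping[str, StagePair]
) -> dict[str, int]:
    """Counts of under/over-staged predictions on the ordinal T and N scales;
    X labels are excluded from the tallies (tracked separately in score())."""
    deltas = {"t_understaged": 0, "t_overstaged": 0, "n_understaged": 0, "n_overstaged": 0}
    for rid, (gt, gn) in gold.items():
        pt, pn = predictions[rid]
        if pt in T_RANK and gt in T_RANK:
            if T_RANK[pt] < T_RANK[gt]:
                deltas["t_understaged"] += 1
            elif T_RANK[pt] > T_RANK[gt]:
                deltas["t_overstaged"] += 1
        if pn in N_RANK and gn in N_RANK:
            if N_RANK[pn] < N_RANK[gn]:
                deltas["n_understaged"] += 1
            elif N_RANK[pn] > N_RANK[gn]:
                deltas["n_overstaged"] += 1
    return deltas


def score(
    predictions: Mapping[str, StagePair], gold: Mapping[str, StagePair]
) -> EvaluationResult:
    """Score predictions against gold labels keyed by report id."""
    _check_keys(predictions, gold)
    ids = sorted(gold)
    gt = [gold[i][0] for i in ids]
    gn = [gold[i][1] for i in ids]
    gtn = [t + n for t, n in zip(gt, gn)]
    pt = [predictions[i][0] for i in ids]
    pn = [predictions[i][1] for i in ids]
    ptn = [t + n for t, n in zip(pt, pn)]

    tn_order = [f"{t}{n}" for t in T_LABELS for n in N_LABELS]
    weighted = {
        "tn": _weighted_prf(gtn, ptn),
        "t": _weighted_prf(gt, pt),
        "n": _weighted_prf(gn, pn),
    }
    return EvaluationResult(
        n_reports=len(ids),
        accuracy_t=float(np.mean([a == b for a, b in zip(gt, pt)])) if ids else 0.0,
        accuracy_n=float(np.mean([a == b for a, b in zip(gn, pn)])) if ids else 0.0,
        accuracy_tn=float(np.mean([a == b for a, b in zip(gtn, ptn)])) if ids else 0.0,
        confusion_t=_confusion(gt, pt, list(T_LABELS) + ["TX"]),
        confusion_n=_confusion(gn, pn, list(N_LABELS) + ["NX"]),
        confusion_tn=_confusion(gtn, ptn, tn_order),
        weighted=weighted,
        deltas=stage_ordering_deltas(predictions, gold),
        x_predictions={
            "t": sum(1 for x in pt if x == "TX"),
            "n": sum(1 for x in pn if x == "NX"),
        },
    )


# ---- file ingestion --------------------------------------------------------


def read_gold_csv(path: Union[str, Path]) -> dict[str, StagePair]:
    """Gold labels from CSV (report_id, t, n); duplicate ids are invalid."""
    out: dict[str, StagePair] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            rid = row["report_id"]
            if rid in out:
                raise EvaluationError(f"duplicate report_id {rid!r} in gold file")
            out[rid] = (row["t"], row["n"])
    return out


@dataclass(frozen=True)
class ErrorRecord:
    """One manually annotated misclassification (error-taxonomy CSV row)."""

    report_id: str
    stage: str  # T | N
    category: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.stage not in ("T", "N"):
            raise EvaluationError(f"stage must be T or N, got {self.stage!r}")
        if self.category not in ERROR_CATEGORIES:
            raise EvaluationError(
                f"unknown error category {self.category!r}; expected one of {ERROR_CATEGORIES}"
            )


def read_error_records(path: Union[str, Path]) -> list[ErrorRecord]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return [
            ErrorRecord(r["report_id"], r["stage"], r["category"], r.get("note", ""))
            for r in csv.DictReader(fh)
        ]


def tabulate_errors(records: Sequence[ErrorRecord]) -> pd.DataFrame:
    """Error counts by taxonomy category (rows) and stage affected (cols)."""
    table = pd.DataFrame(
        0, index=pd.Index(ERROR_CATEGORIES, name="category"), columns=["T", "N"]
    )
    for rec in records:
        table.loc[rec.category, rec.stage] += 1
    table["total"] = table.sum(axis=1)
    return table
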