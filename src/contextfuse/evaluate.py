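"""Scoring pipeline output against ground truth.

The confusion matrix covers the fifteen high-level context classes in a fixed
legend order (Amusement … VeryHighRiskHealthState) with one extra predicted
column for ``Unidentified``.  Rows are truth classes, columns predictions, so
row sums equal per-class truth counts.  Precision / recall / F use the standard
definitions, with undefined scores reported as ``None`` rather than zero; a
looser historical variant (correct count over the number of defined classes,
and correct count over the dataset size) is reported alongside as
``paper_precision`` / ``paper_recall``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .model import UNIDENTIFIED, HLCInstance

# Legend order for the 15 HLC classes (A..O).
CLASS_ORDER = (
    "Amusement",
    "Commuting",
    "Exercising",
    "Gardening",
    "Carbohydrates",
    "Fats",
    "HouseWork",
    "Inactivity",
    "OfficeWork",
    "Protein",
    "Sleeping",
    "HighRiskHealthState",
    "ModerateHealthState",
    "NormalHealthState",
    "VeryHighRiskHealthState",
)


def confusion(
    predicted: Sequence[str], truth: Sequence[str], classes: Sequence[str] = CLASS_ORDER
) -> pd.DataFrame:
    """Count matrix from aligned prediction/truth label lists: rows are truth
    classes, columns the same classes plus ``Unidentified``."""
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    cols = list(classes) + [UNIDENTIFIED]
    mat = pd.DataFrame(0, index=list(classes), columns=cols, dtype=int)
    for p, t in zip(predicted, truth):
        if t not in mat.index:
            raise ValueError(f"unknown truth class {t!r}")
        if p not in mat.columns:
            raise ValueError(f"unknown predicted class {p!r}")
        mat.loc[t, p] += 1
    return mat


def precision_recall_f(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-class precision/recall/F plus macro averages (ignoring undefined
    entries).  A class never predicted has undefined precision (``None``); a
    class absent from the truth has undefined recall."""
    classes = list(matrix.index)
    rows = []
    for cls in classes:
        tp = int(matrix.loc[cls, cls])
        fp = int(matrix[cls].sum()) - tp
        fn = int(matrix.loc[cls].sum()) - tp
        precision = tp / (tp + fp) if tp + fp else None
        recall = tp / (tp + fn) if tp + fn else None
        if precision is None or recall is None or precision + recall == 0:
            f_measure = None
        else:
            f_measure = 2 * precision * recall / (precision + recall)
        rows.append(
            {"class": cls, "precision": precision, "recall": recall, "f_measure": f_measure}
        )
    frame = pd.DataFrame(rows).set_index("class")
    macro = frame.mean(skipna=True)
    frame.loc["macro"] = macro
    return frame


def paper_style_scores(matrix: pd.DataFrame) -> Dict[str, float]:
    """The looser textual definitions: correct inferences over the number of
    defined classes, and correct inferences over the dataset size."""
    correct = sum(int(matrix.loc[c, c]) for c in matrix.index)
    total = int(matrix.to_numpy().sum())
    return {
        "paper_precision": correct / len(matrix.index),
        "paper_recall": correct / total if total else float("nan"),
    }


@dataclass
class EvaluationReport:
    """Confusion matrix, scores and stream accounting for one pipeline run."""

    matrix: pd.DataFrame
    scores: pd.DataFrame
    accuracy: float
    misclassified_fraction: float
    unidentified_fraction: float
    unidentified_reasons: Dict[str, Dict[str, int]]
    recognized: int
    communicated: int
    missing_candidates: int = 0
    paper_precision: float = float("nan")
    paper_recall: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "accuracy": self.accuracy,
            "misclassified_fraction": self.misclassified_fraction,
            "unidentified_fraction": self.unidentified_fraction,
            "recognized": self.recognized,
            "communicated": self.communicated,
            "missing_candidates": self.missing_candidates,
            "paper_precision": self.paper_precision,
            "paper_recall": self.paper_recall,
        }
        return pd.DataFrame({"value": rows})


def align(
    instances: Sequence[HLCInstance], truth: Sequence[dict]
) -> Tuple[List[str], List[str], int]:
    """Pair pipeline instances with truth annotations by user, domain and
    interval overlap (greedy in time order — exact on clean streams).

    Returns ``(predicted_labels, truth_labels, missing)`` where ``missing``
    counts truth contexts for which no candidate instance was instantiated at
    all (e.g. the triggering low-level record was dropped).
    """
    by_key: Dict[tuple, List[HLCInstance]] = {}
    for inst in sorted(instances, key=lambda i: i.start):
        by_key.setdefault((inst.user_id, inst.domain), []).append(inst)
    used = set()
    predicted, truths = [], []
    missing = 0
    for item in sorted(truth, key=lambda t: (t["user_id"], t["start"], t["domain"])):
        candidates = by_key.get((item["user_id"], item["domain"]), [])
        best = None
        for inst in candidates:
            if id(inst) in used:
                continue
            if inst.start < item["end"] + 1 and inst.end + 1 > item["start"]:
                best = inst
                break
        if best is None:
            missing += 1
            continue
        used.add(id(best))
        predicted.append(best.inferred_class or UNIDENTIFIED)
        truths.append(item["cls"])
    return predicted, truths, missing


def unidentified_report(instances: Sequence[HLCInstance]) -> Dict[str, Dict[str, int]]:
    """Per-domain counts of unidentified candidates, partitioned by the reason
    code recorded at classification time."""
    out: Dict[str, Dict[str, int]] = {}
    for inst in instances:
        if inst.inferred_class != UNIDENTIFIED:
            continue
        reason = inst.unidentified_reason or "unknown"
        dom = out.setdefault(inst.domain, {})
        dom[reason] = dom.get(reason, 0) + 1
    return out


def evaluate_run(
    instances: Sequence[HLCInstance],
    truth: Sequence[dict],
    communicated: int = 0,
) -> EvaluationReport:
    """Full scoring of one classified stream against its ground truth."""
    predicted, truths, missing = align(instances, truth)
    matrix = confusion(predicted, truths)
    total = int(matrix.to_numpy().sum())
    correct = sum(int(matrix.loc[c, c]) for c in matrix.index)
    unid = int(matrix[UNIDENTIFIED].sum())
    scores = precision_recall_f(matrix)
    paper = paper_style_scores(matrix)
    recognized = sum(
        1 for i in instances if i.inferred_class not in (None, UNIDENTIFIED)
    )
    return EvaluationReport(
        matrix=matrix,
        scores=scores,
        accuracy=correct / total if total else float("nan"),
        misclassified_fraction=(total - correct - unid) / total if total else float("nan"),
        unidentified_fraction=unid / total if total else float("nan"),
        unidentified_reasons=unidentified_report(instances),
        recognized=recognized,
        communicated=communicated,
        missing_candidates=missing,
        paper_precision=paper["paper_precision"],
        paper_recall=paper["paper_recall"],
    )
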