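"""End-to-end composition: label → synchronize → classify → behavioral rules.

The pipeline is a pure function of (records, config, evaluation time): reruns
on identical input produce identical output.  Stage counts are collected so a
run can be audited (how many records in, groups formed, candidates emitted,
classified, notified, behaviors derived).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .evaluate import EvaluationReport, evaluate_run
from .horizontal import BehavioralContext, FactBase, run_all_rules
from .labeler import ClinicalLabeler
from .model import ContextConfig, HLCInstance, LLCRecord, validate_llc
from .sync import SyncWindow, instantiate_all, synchronize
from .vertical import classify_stream

log = logging.getLogger("contextfuse")


@dataclass
class PipelineResult:
    llcs: List[LLCRecord]
    instances: List[HLCInstance]
    notifications: List[HLCInstance]
    behaviors: List[BehavioralContext]
    unconsumed: List[LLCRecord]
    stage_counts: Dict[str, int] = field(default_factory=dict)
    report: Optional[EvaluationReport] = None


def run_pipeline(
    records: Sequence[LLCRecord],
    config: ContextConfig,
    at: Optional[float] = None,
    truth: Optional[Sequence[dict]] = None,
) -> PipelineResult:
    """Run the full fusion pipeline over a raw or labeled multi-user log.

    ``at`` is the behavioral evaluation time (default: the end of the stream);
    ``truth`` — ground-truth HLC annotations — adds an evaluation report.
    """
    labeler = ClinicalLabeler(config)
    labeled = labeler.label_stream(records)

    invalid = 0
    clean: List[LLCRecord] = []
    for rec in labeled:
        violations = validate_llc(rec, config.vocabulary)
        if violations:
            invalid += 1
            log.warning("dropping invalid record %s: %s", rec, violations)
        else:
            clean.append(rec)

    window = SyncWindow(length=config.engine.window_seconds)
    by_user: Dict[str, List[LLCRecord]] = {}
    for rec in clean:
        by_user.setdefault(rec.user_id, []).append(rec)

    instances: List[HLCInstance] = []
    unconsumed: List[LLCRecord] = []
    n_groups = 0
    for user in sorted(by_user):
        user_records = sorted(by_user[user], key=lambda r: (r.start, r.category, r.label or ""))
        groups = synchronize(user_records, window, user_id=user)
        n_groups += len(groups)
        insts, leftover = instantiate_all(groups, config.engine)
        instances.extend(insts)
        unconsumed.extend(leftover)

    instances.sort(key=lambda i: (i.user_id, i.start, i.domain))
    classified, notifications = classify_stream(instances, config)

    facts = FactBase(hlcs=classified, llcs=clean)
    if at is None:
        at = max((r.end for r in clean), default=0.0)
    behaviors = run_all_rules(facts, at, config)

    report = None
    if truth is not None:
        report = evaluate_run(classified, truth, communicated=len(notifications))

    counts = {
        "records_in": len(records),
        "records_invalid": invalid,
        "groups": n_groups,
        "candidates": len(instances),
        "classified": len(classified),
        "notifications": len(notifications),
        "behaviors": len(behaviors),
        "unconsumed": len(unconsumed),
    }
    for stage, value in counts.items():
        log.info("stage %s: %d", stage, value)
    return PipelineResult(
        llcs=clean,
        instances=classified,
        notifications=notifications,
        behaviors=behaviors,
        unconsumed=unconsumed,
        stage_counts=counts,
        report=report,
    )
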