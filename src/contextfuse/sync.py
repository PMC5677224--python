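"""Temporal synchronization of low-level contexts into candidate HLCs.

Concurrent records of one user are grouped by transitive closure of a pairwise
window criterion: two records belong together when their intervals overlap or
their start times lie within the synchronization window (default 15 s — point
events such as clinical readings have zero-length intervals and rely on the
start-proximity arm).  Each group is then offered to the three domain
instantiators, which emit unclassified HLC instances when the group carries the
domain's mandatory low-level contexts:

* physical activity — an Activity record (location/emotion attached if present);
* nutrition — a Food record together with an ``Eating`` Activity record;
* clinical — at least one labeled blood glucose or blood pressure record
  (gap sentinels excluded; water intake is carried as metadata only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

from .model import (
    UNSPECIFIED_BG,
    UNSPECIFIED_BP,
    EngineParams,
    HLCInstance,
    LLCRecord,
)


@dataclass(frozen=True)
class SyncWindow:
    """Concurrency window; ``proximity_or_overlap`` groups on either interval
    overlap or start-time proximity (the default and only shipped policy)."""

    length: float = 15.0
    policy: str = "proximity_or_overlap"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("window length must be positive")


def related(a: LLCRecord, b: LLCRecord, window: SyncWindow) -> bool:
    """Pairwise window criterion (symmetric)."""
    first, second = (a, b) if a.start <= b.start else (b, a)
    if second.start - first.start <= window.length:
        return True
    # half-open interval overlap; zero-length second falls inside first
    return second.start < first.end


def synchronize(
    records: Sequence[LLCRecord],
    window: Optional[SyncWindow] = None,
    user_id: Optional[str] = None,
) -> List[List[LLCRecord]]:
    """Group a single user's time-ordered records into concurrency groups
    (transitive closure of :func:`related` within the window).

    Raises ``ValueError`` on unsorted input or records from several users.
    """
    window = window or SyncWindow()
    records = list(records)
    if not records:
        return []
    users = {r.user_id for r in records}
    if user_id is not None:
        users.add(user_id)
    if len(users) > 1:
        raise ValueError(f"records span multiple users: {sorted(users)}")
    for prev, cur in zip(records, records[1:]):
        if cur.start < prev.start:
            raise ValueError("records must be sorted by start time")

    # Sorted by start, so a record relates to some group member iff it is
    # start-proximate to the latest start or begins before the furthest end.
    groups: List[List[LLCRecord]] = []
    last_start = max_end = None
    for rec in records:
        if groups and (
            rec.start - last_start <= window.length or rec.start < max_end
        ):
            groups[-1].append(rec)
            last_start = rec.start
            max_end = max(max_end, rec.end)
        else:
            groups.append([rec])
            last_start, max_end = rec.start, rec.end
    return groups


def _span(records: Sequence[LLCRecord]) -> tuple:
    return min(r.start for r in records), max(r.end for r in records)


def _pick_per_category(group: Sequence[LLCRecord], categories) -> dict:
    """One record per requested category.  Duplicates resolve to the record
    with the longest overlap with the group span (ties: earliest start, which
    also makes the choice independent of input permutation at equal overlap)."""
    lo, hi = _span(group)
    chosen: dict = {}
    for cat in categories:
        candidates = [r for r in group if r.category == cat]
        if not candidates:
            continue
        chosen[cat] = max(
            candidates,
            key=lambda r: (min(r.end, hi) - max(r.start, lo), -r.start, r.label or ""),
        )
    return chosen


def _labeled(rec: Optional[LLCRecord]) -> bool:
    return rec is not None and rec.label not in (None, UNSPECIFIED_BG, UNSPECIFIED_BP)


def instantiate_pa(group: Sequence[LLCRecord]) -> Optional[HLCInstance]:
    """Physical-activity candidate: requires an Activity record; attaches
    location and emotion when concurrently present."""
    picked = _pick_per_category(group, ("Activity", "Location", "Emotion"))
    act = picked.get("Activity")
    if act is None:
        return None
    assertions = {"hasActivity": act.label}
    sources = [act]
    for prop, cat in (("hasLocation", "Location"), ("hasEmotion", "Emotion")):
        rec = picked.get(cat)
        if rec is not None:
            assertions[prop] = rec.label
            sources.append(rec)
    start, end = _span(sources)
    return HLCInstance(
        user_id=act.user_id, domain="PA", assertions=assertions,
        start=start, end=end, source_llcs=sources,
    )


def instantiate_n(group: Sequence[LLCRecord]) -> Optional[HLCInstance]:
    """Nutrition candidate: requires a Food record and an ``Eating`` activity."""
    picked = _pick_per_category(group, ("Activity", "Location", "Emotion", "Food"))
    act, food = picked.get("Activity"), picked.get("Food")
    if food is None or act is None or act.label != "Eating":
        return None
    assertions = {"hasActivity": act.label, "hasFood": food.label}
    sources = [act, food]
    for prop, cat in (("hasLocation", "Location"), ("hasEmotion", "Emotion")):
        rec = picked.get(cat)
        if rec is not None:
            assertions[prop] = rec.label
            sources.append(rec)
    start, end = _span(sources)
    return HLCInstance(
        user_id=food.user_id, domain="N", assertions=assertions,
        start=start, end=end, source_llcs=sources,
    )


def instantiate_c(
    group: Sequence[LLCRecord], water_is_trigger: bool = False
) -> Optional[HLCInstance]:
    """Clinical candidate: requires at least one labeled blood glucose or blood
    pressure record (sentinel-labeled readings are excluded; water intake is
    metadata and, by default, never triggers an instance on its own)."""
    picked = _pick_per_category(group, ("BloodGlucose", "BloodPressure", "WaterIntake"))
    bg = picked.get("BloodGlucose")
    bp = picked.get("BloodPressure")
    water = picked.get("WaterIntake")
    assertions = {}
    sources = []
    if _labeled(bg):
        assertions["hasBloodGlucose"] = bg.label
        sources.append(bg)
    if _labeled(bp):
        assertions["hasBloodPressure"] = bp.label
        sources.append(bp)
    if not sources and not (water_is_trigger and _labeled(water)):
        return None
    if not sources:  # water-triggered instance carries no clinical assertion
        sources.append(water)
    start, end = _span(sources)
    return HLCInstance(
        user_id=sources[0].user_id, domain="C", assertions=assertions,
        start=start, end=end, source_llcs=sources,
    )


def instantiate_all(
    groups: Iterable[Sequence[LLCRecord]], engine: Optional[EngineParams] = None
) -> tuple:
    """Run all three instantiators over every group.

    Returns ``(instances, unconsumed)`` where ``unconsumed`` lists input
    records referenced by no emitted instance — nothing is silently dropped.
    """
    engine = engine or EngineParams()
    instances: List[HLCInstance] = []
    unconsumed: List[LLCRecord] = []
    for group in groups:
        emitted = [
            inst
            for inst in (
                instantiate_pa(group),
                instantiate_n(group),
                instantiate_c(group, water_is_trigger=engine.water_is_clinical_trigger),
            )
            if inst is not None
        ]
        instances.extend(emitted)
        consumed = {id(r) for inst in emitted for r in inst.source_llcs}
        unconsumed.extend(r for r in group if id(r) not in consumed)
    return instances, unconsumed
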