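"""Horizontal fusion: conjunctive temporal rules over the classified history.

Each behavioral rule is evaluated in four phases over a rolling evaluation
window (default seven days) ending at the evaluation time:

1. **match** — the ordered antecedent atoms are joined nested-loop style:
   pattern atoms (``user``, ``is_context_of``, ``activity_of`` and property
   filters) extend candidate bindings, builtins (``duration``, ``day_of``,
   comparisons) bind derived values or screen rows;
2. **group** — rows are grouped per user plus any declared ``group_by``
   variables (e.g. the calendar day);
3. **aggregate + filter** — set-style aggregations (``sum``, ``count``,
   ``count_distinct``) bind per-group values which the filter comparisons
   screen;
4. **select** — surviving groups project the consequent into a
   :class:`BehavioralContext`.

The phase split mirrors the collection-then-aggregation semantics of
SQWRL-style queries; the engine is intentionally limited to the builtin set
the packaged six rules need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

from .model import (
    UNIDENTIFIED,
    BehaviorRule,
    ContextConfig,
    EngineParams,
    HLCInstance,
    LLCRecord,
)

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0


class RuleError(ValueError):
    """Unknown atom/builtin or an unbound consequent variable at run time."""


def duration(start: float, end: float, unit: str) -> float:
    """Elapsed time between two instants, in ``Hours`` or ``Days``."""
    if end < start:
        raise ValueError("end before start")
    if unit == "Hours":
        return (end - start) / SECONDS_PER_HOUR
    if unit == "Days":
        return (end - start) / SECONDS_PER_DAY
    raise RuleError(f"unknown duration unit {unit!r}")


@dataclass(frozen=True)
class BehavioralContext:
    """One behavioral label for one user over one evaluation window."""

    user_id: str
    label: str
    rule_id: int
    window_start: float
    window_end: float
    values: tuple  # sorted (name, value) pairs from the consequent

    def value(self, name: str):
        return dict(self.values).get(name)

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "label": self.label,
            "rule_id": self.rule_id,
            "window_start": self.window_start,
            "window_end": self.window_end,
            **{k: v for k, v in self.values},
        }


@dataclass
class FactBase:
    """Per-user indexed fact store: classified HLC instances plus the labeled
    low-level history they came from."""

    hlcs: List[HLCInstance] = field(default_factory=list)
    llcs: List[LLCRecord] = field(default_factory=list)

    def users(self) -> List[str]:
        return sorted(
            {h.user_id for h in self.hlcs} | {r.user_id for r in self.llcs}
        )

    def hlcs_of(self, user: str, lo: float, hi: float) -> List[HLCInstance]:
        return [
            h
            for h in self.hlcs
            if h.user_id == user
            and lo <= h.start <= hi
            and h.inferred_class not in (None, UNIDENTIFIED)
        ]

    def activities_of(self, user: str, lo: float, hi: float) -> List[LLCRecord]:
        return [
            r
            for r in self.llcs
            if r.user_id == user and r.category == "Activity" and lo <= r.start <= hi
        ]


def _day_of(t: float, engine: EngineParams) -> int:
    return int((t + engine.tz_offset_hours * SECONDS_PER_HOUR) // SECONDS_PER_DAY)


def _resolve(arg, row: dict):
    if isinstance(arg, str) and arg.startswith("?"):
        if arg not in row:
            raise RuleError(f"variable {arg} unbound")
        return row[arg]
    return arg


_COMPARATORS = {
    "less_than": lambda a, b: a < b,
    "greater_than": lambda a, b: a > b,
    "equal": lambda a, b: a == b,
}


def _match_rows(
    rule: BehaviorRule, facts: FactBase, lo: float, hi: float, engine: EngineParams
) -> List[dict]:
    rows: List[dict] = [{}]
    for name, args in rule.match:
        new_rows: List[dict] = []
        if name == "user":
            (var,) = args
            for row in rows:
                for user in facts.users():
                    new_rows.append({**row, var: user})
        elif name == "is_context_of":
            uvar, cvar = args
            for row in rows:
                for hlc in facts.hlcs_of(_resolve(uvar, row), lo, hi):
                    new_rows.append({**row, cvar: hlc})
        elif name == "activity_of":
            uvar, avar = args
            for row in rows:
                for rec in facts.activities_of(_resolve(uvar, row), lo, hi):
                    new_rows.append({**row, avar: rec})
        elif name == "class_equal":
            cvar, term = args
            new_rows = [r for r in rows if _resolve(cvar, r).inferred_class == term]
        elif name in ("has_activity", "has_location", "has_emotion", "has_food"):
            cvar, term = args
            prop = "has" + name.split("_")[1].capitalize()
            new_rows = [
                r for r in rows if _resolve(cvar, r).assertions.get(prop) == term
            ]
        elif name == "label_equal":
            avar, term = args
            new_rows = [r for r in rows if _resolve(avar, r).label == term]
        elif name == "start_time":
            xvar, tvar = args
            new_rows = [{**r, tvar: _resolve(xvar, r).start} for r in rows]
        elif name == "end_time":
            xvar, tvar = args
            new_rows = [{**r, tvar: _resolve(xvar, r).end} for r in rows]
        elif name == "duration":
            hvar, svar, evar, unit = args
            new_rows = [
                {**r, hvar: duration(_resolve(svar, r), _resolve(evar, r), unit)}
                for r in rows
            ]
        elif name == "day_of":
            dvar, tvar = args
            new_rows = [{**r, dvar: _day_of(_resolve(tvar, r), engine)} for r in rows]
        elif name in _COMPARATORS:
            a, b = args
            cmp = _COMPARATORS[name]
            new_rows = [r for r in rows if cmp(_resolve(a, r), _resolve(b, r))]
        else:
            raise RuleError(f"unknown atom {name!r} in rule {rule.id}")
        rows = new_rows
        if not rows:
            break
    return rows


def _distinct(values) -> int:
    seen = set()
    for v in values:
        try:
            seen.add(v)
        except TypeError:
            seen.add(id(v))
    return len(seen)


def evaluate_rule(
    rule: BehaviorRule,
    facts: FactBase,
    at: float,
    engine: Optional[EngineParams] = None,
) -> List[BehavioralContext]:
    """Evaluate one rule at time ``at`` over the rolling window ending there."""
    engine = engine or EngineParams()
    lo, hi = at - engine.week_seconds, at
    rows = _match_rows(rule, facts, lo, hi, engine)

    uvar = rule.match[0][1][0] if rule.match else "?u"
    groups: Dict[tuple, List[dict]] = {}
    for row in rows:
        key = tuple(row[v] for v in (uvar, *rule.group_by))
        groups.setdefault(key, []).append(row)

    results: List[BehavioralContext] = []
    for key, grows in sorted(groups.items(), key=lambda kv: repr(kv[0])):
        bindings: dict = dict(zip((uvar, *rule.group_by), key))
        for name, args in rule.aggregate:
            out_var, in_var = args
            if name == "sum":
                bindings[out_var] = sum(r[in_var] for r in grows)
            elif name == "count":
                bindings[out_var] = _distinct(r[in_var] for r in grows)
            elif name == "count_distinct":
                bindings[out_var] = _distinct(r[in_var] for r in grows)
            else:
                raise RuleError(f"unknown aggregation {name!r} in rule {rule.id}")
        keep = True
        for name, args in rule.filter:
            a, b = args
            if name not in _COMPARATORS:
                raise RuleError(f"unknown builtin {name!r} in rule {rule.id}")
            if not _COMPARATORS[name](_resolve(a, bindings), _resolve(b, bindings)):
                keep = False
                break
        if not keep:
            continue
        values = []
        for var in rule.select:
            if var == uvar:
                continue
            if var not in bindings:
                raise RuleError(f"consequent variable {var} not group-bound in rule {rule.id}")
            values.append((var.lstrip("?"), bindings[var]))
        for var in rule.group_by:  # report the grouping key (e.g. the day)
            if var not in rule.select:
                values.append((var.lstrip("?"), bindings[var]))
        results.append(
            BehavioralContext(
                user_id=bindings[uvar],
                label=rule.name,
                rule_id=rule.id,
                window_start=lo,
                window_end=hi,
                values=tuple(sorted(values)),
            )
        )
    return results


def run_all_rules(
    facts: FactBase, at: float, config: ContextConfig
) -> List[BehavioralContext]:
    """Evaluate every packaged rule; deterministic ordering by (rule id,
    user id, bound values).  Users may legitimately satisfy several rules."""
    out: List[BehavioralContext] = []
    for rule in config.rules:
        out.extend(evaluate_rule(rule, facts, at, config.engine))
    out.sort(key=lambda b: (b.rule_id, b.user_id, b.values))
    return out
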