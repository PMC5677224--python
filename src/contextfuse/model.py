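"""Core record types, controlled vocabularies and configuration loading.

The context model separates the terminological side (vocabularies, class
definitions, behavioral rules — all loaded from a declarative YAML file) from
the assertional side (timestamped low-level context records flowing through the
pipeline).  Everything downstream — labeling, synchronization, classification,
rule evaluation — consumes the :class:`ContextConfig` produced here.

Timestamps are epoch seconds; intervals are half-open ``[start, end)`` in UTC,
with a configurable offset for calendar-day grouping.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, TextIO, Union

import yaml

# Sentinels for raw clinical readings falling outside every printed band.
UNSPECIFIED_BG = "UnspecifiedBG"
UNSPECIFIED_BP = "UnspecifiedBP"
# Sentinel class for candidate HLCs matching no class definition.
UNIDENTIFIED = "Unidentified"

CATEGORIES = (
    "Activity",
    "Location",
    "Emotion",
    "Food",
    "BloodGlucose",
    "BloodPressure",
    "WaterIntake",
)

DOMAINS = ("PA", "N", "C")

# Object properties an HLC instance may assert, and the LLC category each draws
# its values from.
PROPERTY_CATEGORY = {
    "hasActivity": "Activity",
    "hasLocation": "Location",
    "hasEmotion": "Emotion",
    "hasFood": "Food",
    "hasBloodGlucose": "BloodGlucose",
    "hasBloodPressure": "BloodPressure",
}


class ConfigError(ValueError):
    """Raised when the configuration file is unparsable or violates an invariant."""


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LLCRecord:
    """One timestamped low-level context observation for a user.

    ``label`` may be absent for raw clinical readings before labeling;
    ``raw_value`` carries mg/dL for blood glucose, a (systolic, diastolic)
    mmHg pair for blood pressure and accumulated mL/day for water intake.
    """

    user_id: str
    category: str
    start: float
    end: float
    label: Optional[str] = None
    raw_value: Optional[Union[float, tuple]] = None

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)

    def to_dict(self) -> dict:
        d = {
            "user_id": self.user_id,
            "category": self.category,
            "start": self.start,
            "end": self.end,
        }
        if self.label is not None:
            d["label"] = self.label
        if self.raw_value is not None:
            if self.category == "BloodPressure":
                d["systolic"], d["diastolic"] = self.raw_value
            else:
                d["value"] = self.raw_value
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "LLCRecord":
        raw = None
        if d.get("systolic") not in (None, ""):
            raw = (float(d["systolic"]), float(d["diastolic"]))
        elif d.get("value") not in (None, ""):
            raw = float(d["value"])
        label = d.get("label") or None
        return cls(
            user_id=str(d["user_id"]),
            category=str(d["category"]),
            start=float(d["start"]),
            end=float(d["end"]),
            label=label,
            raw_value=raw,
        )


@dataclass
class HLCInstance:
    """A candidate (or classified) high-level context.

    ``assertions`` maps object properties to single LLC labels; ``interval`` is
    the union span of the contributing low-level records; ``inferred_class`` is
    filled by classification (``Unidentified`` when no definition matches, with
    ``unidentified_reason`` saying which mandatory property was missing).
    """

    user_id: str
    domain: str
    assertions: dict
    start: float
    end: float
    source_llcs: list = field(default_factory=list)
    inferred_class: Optional[str] = None
    unidentified_reason: Optional[str] = None

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)

    def to_dict(self) -> dict:
        d = {
            "user_id": self.user_id,
            "domain": self.domain,
            "assertions": dict(self.assertions),
            "start": self.start,
            "end": self.end,
            "source_llcs": [r.to_dict() for r in self.source_llcs],
        }
        if self.inferred_class is not None:
            d["inferred_class"] = self.inferred_class
        if self.unidentified_reason is not None:
            d["unidentified_reason"] = self.unidentified_reason
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "HLCInstance":
        return cls(
            user_id=str(d["user_id"]),
            domain=str(d["domain"]),
            assertions=dict(d.get("assertions", {})),
            start=float(d["start"]),
            end=float(d["end"]),
            source_llcs=[LLCRecord.from_dict(r) for r in d.get("source_llcs", [])],
            inferred_class=d.get("inferred_class"),
            unidentified_reason=d.get("unidentified_reason"),
        )


@dataclass(frozen=True)
class RangeRule:
    """One clinical labeling band with optionally open/closed bounds."""

    label: str
    lower: Optional[float] = None
    lower_closed: bool = False
    upper: Optional[float] = None
    upper_closed: bool = False

    def contains(self, value: float) -> bool:
        if self.lower is not None:
            if value < self.lower or (value == self.lower and not self.lower_closed):
                return False
        if self.upper is not None:
            if value > self.upper or (value == self.upper and not self.upper_closed):
                return False
        return True


@dataclass(frozen=True)
class ClassDefinition:
    """One HLC class as existential + universal restrictions over properties.

    ``existential`` maps property → (witness label frozenset, mandatory flag).
    Every mandatory witness set must be hit by the asserted value; if any
    non-mandatory witness sets are declared, at least one of them must be hit.
    ``universal`` maps property → allowed label frozenset, enforced under
    closure: every asserted value of a constrained property must be allowed.
    """

    name: str
    domain: str
    existential: Mapping[str, tuple] = field(default_factory=dict)
    universal: Mapping[str, frozenset] = field(default_factory=dict)
    disjoint_with: frozenset = frozenset()


@dataclass(frozen=True)
class BehaviorRule:
    """One conjunctive temporal rule: match atoms, grouping, aggregation,
    group filters and the projected consequent."""

    id: int
    name: str
    match: tuple
    group_by: tuple
    aggregate: tuple
    filter: tuple
    select: tuple


@dataclass(frozen=True)
class EngineParams:
    window_seconds: float = 15.0
    week_seconds: float = 604800.0
    tz_offset_hours: float = 0.0
    water_is_clinical_trigger: bool = False


@dataclass(frozen=True)
class ContextVocabulary:
    """Controlled vocabularies for the seven LLC categories and the HLC classes."""

    activity_labels: frozenset
    location_labels: frozenset
    emotion_labels: frozenset
    food_items: frozenset
    food_groups: Mapping[str, str]          # item -> group
    group_members: Mapping[str, frozenset]  # group -> items
    bg_labels: frozenset
    bp_labels: frozenset
    water_labels: frozenset
    hlc_classes: Mapping[str, tuple]        # domain -> ordered class names
    food_nutrient: Mapping[str, str]        # item -> N-HLC class

    def labels_for(self, category: str) -> frozenset:
        return {
            "Activity": self.activity_labels,
            "Location": self.location_labels,
            "Emotion": self.emotion_labels,
            "Food": self.food_items,
            "BloodGlucose": self.bg_labels,
            "BloodPressure": self.bp_labels,
            "WaterIntake": self.water_labels,
        }[category]

    def all_hlc_classes(self) -> tuple:
        return tuple(c for dom in DOMAINS for c in self.hlc_classes[dom])


@dataclass(frozen=True)
class ContextConfig:
    """Everything load_config produces: the full terminological model."""

    vocabulary: ContextVocabulary
    class_definitions: tuple
    rules: tuple
    engine: EngineParams
    labeler: Mapping
    raw: Mapping = field(default_factory=dict, compare=False)

    def definitions_for(self, domain: str) -> tuple:
        return tuple(d for d in self.class_definitions if d.domain == domain)


# ---------------------------------------------------------------------------
# Configuration loading
# ---------------------------------------------------------------------------


def default_config_path() -> Path:
    return Path(resources.files("contextfuse").joinpath("data/default_config.yaml"))


def _err(key: str, msg: str) -> ConfigError:
    return ConfigError(f"config[{key}]: {msg}")


def _nutrient_sets(raw: Mapping) -> dict:
    groups = raw["vocabulary"]["food_groups"]
    nut = raw["nutrients"]
    fats = set(nut["fats_items"])
    sets = {"Fats": fats, "Carbohydrates": set(), "Protein": set()}
    for group, items in groups.items():
        target = nut["group_nutrient"].get(group)
        if target is None:
            raise _err("nutrients.group_nutrient", f"no nutrient for group {group!r}")
        for item in items:
            cls = nut.get("item_overrides", {}).get(item, target)
            if item in fats:
                cls = "Fats"
            sets[cls].add(item)
    return sets


_TOKEN_MAP = {"$fats": "Fats", "$carbohydrates": "Carbohydrates", "$protein": "Protein"}


def _expand_values(values, nutrient_sets) -> frozenset:
    if isinstance(values, str):
        if values in _TOKEN_MAP:
            return frozenset(nutrient_sets[_TOKEN_MAP[values]])
        raise ConfigError(f"unknown value-set token {values!r}")
    return frozenset(values)


def load_config(path: Optional[Union[str, Path]] = None) -> ContextConfig:
    """Load and validate a configuration file (the packaged default when
    ``path`` is None).  Raises :class:`ConfigError` naming the offending key on
    any invariant violation."""
    cfg_path = Path(path) if path is not None else default_config_path()
    try:
        raw = yaml.safe_load(cfg_path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise ConfigError(f"cannot parse {cfg_path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{cfg_path} does not contain a mapping")
    return build_config(raw)


def build_config(raw: Mapping) -> ContextConfig:
    voc = raw.get("vocabulary")
    if voc is None:
        raise _err("vocabulary", "missing section")

    # food groups: total, disjoint assignment of items to groups
    food_groups_raw = voc["food_groups"]
    item_group: dict = {}
    for group, items in food_groups_raw.items():
        for item in items:
            if item in item_group:
                raise _err(
                    "vocabulary.food_groups",
                    f"food item {item!r} assigned to both {item_group[item]!r} and {group!r}",
                )
            item_group[item] = group
    food_items = frozenset(item_group)

    nutrient_sets = _nutrient_sets(raw)
    food_nutrient = {
        item: cls for cls, items in nutrient_sets.items() for item in items
    }
    if set(food_nutrient) != set(food_items):
        missing = set(food_items) ^ set(food_nutrient)
        raise _err("nutrients", f"nutrient mapping does not cover items: {sorted(missing)}")

    hlc = raw["hlc_classes"]
    for dom in DOMAINS:
        if dom not in hlc:
            raise _err("hlc_classes", f"missing domain {dom}")
    domain_sets = {dom: set(hlc[dom]) for dom in DOMAINS}
    for a in DOMAINS:
        for b in DOMAINS:
            if a < b and domain_sets[a] & domain_sets[b]:
                raise _err("hlc_classes", f"domains {a} and {b} share classes")

    vocabulary = ContextVocabulary(
        activity_labels=frozenset(voc["activities"]),
        location_labels=frozenset(voc["locations"]),
        emotion_labels=frozenset(voc["emotions"]),
        food_items=food_items,
        food_groups=dict(item_group),
        group_members={g: frozenset(items) for g, items in food_groups_raw.items()},
        bg_labels=frozenset(voc["bg_labels"]),
        bp_labels=frozenset(voc["bp_labels"]),
        water_labels=frozenset(voc["water_labels"]),
        hlc_classes={dom: tuple(hlc[dom]) for dom in DOMAINS},
        food_nutrient=food_nutrient,
    )

    definitions = _load_definitions(raw, vocabulary, nutrient_sets)
    rules = _load_rules(raw)
    engine_raw = raw.get("engine", {})
    engine = EngineParams(
        window_seconds=float(engine_raw.get("window_seconds", 15)),
        week_seconds=float(engine_raw.get("week_seconds", 604800)),
        tz_offset_hours=float(engine_raw.get("tz_offset_hours", 0)),
        water_is_clinical_trigger=bool(engine_raw.get("water_is_clinical_trigger", False)),
    )

    return ContextConfig(
        vocabulary=vocabulary,
        class_definitions=definitions,
        rules=rules,
        engine=engine,
        labeler=raw["labeler"],
        raw=dict(raw),
    )


def _load_definitions(raw, vocabulary, nutrient_sets) -> tuple:
    by_domain: dict = {dom: [] for dom in DOMAINS}
    defs = []
    entries = raw.get("class_definitions", [])
    names = [e["name"] for e in entries]
    for entry in entries:
        name, domain = entry["name"], entry["domain"]
        if domain not in DOMAINS:
            raise _err("class_definitions", f"{name}: unknown domain {domain!r}")
        if name not in vocabulary.hlc_classes[domain]:
            raise _err("class_definitions", f"{name} not among {domain} HLC classes")
        existential = {}
        for prop, spec in (entry.get("existential") or {}).items():
            if prop not in PROPERTY_CATEGORY:
                raise _err("class_definitions", f"{name}: unknown property {prop!r}")
            values = _expand_values(spec["values"], nutrient_sets)
            if not values:
                raise _err("class_definitions", f"{name}.{prop}: empty witness set")
            existential[prop] = (values, bool(spec.get("mandatory", True)))
        universal = {}
        for prop, values in (entry.get("universal") or {}).items():
            if prop not in PROPERTY_CATEGORY:
                raise _err("class_definitions", f"{name}: unknown property {prop!r}")
            universal[prop] = _expand_values(values, nutrient_sets)
        # vocabulary membership of every referenced term
        for prop, vals in list(universal.items()) + [
            (p, v) for p, (v, _) in existential.items()
        ]:
            allowed = vocabulary.labels_for(PROPERTY_CATEGORY[prop])
            unknown = vals - allowed
            if unknown:
                raise _err(
                    "class_definitions",
                    f"{name}.{prop}: terms not in vocabulary: {sorted(unknown)}",
                )
        # witness sets must sit inside the universal allowed sets
        for prop, (vals, _) in existential.items():
            if prop in universal and not vals <= universal[prop]:
                raise _err(
                    "class_definitions",
                    f"{name}.{prop}: existential witnesses outside universal set",
                )
        siblings = frozenset(
            entry.get("disjoint_with")
            or [n for n, e in zip(names, entries) if e["domain"] == domain and n != name]
        )
        d = ClassDefinition(
            name=name,
            domain=domain,
            existential=existential,
            universal=universal,
            disjoint_with=siblings,
        )
        by_domain[domain].append(d)
        defs.append(d)
    return tuple(defs)


_ATOM_RE = re.compile(r"^\s*(\w+)\s*\((.*)\)\s*$")


def parse_atom(text: str) -> tuple:
    """Parse ``name(arg, arg, ...)`` into (name, args).  Variables keep their
    leading ``?``; numeric literals become floats; anything else is a term."""
    m = _ATOM_RE.match(text)
    if not m:
        raise ConfigError(f"malformed atom {text!r}")
    name, argtext = m.group(1), m.group(2)
    args = []
    for part in argtext.split(","):
        part = part.strip()
        if not part:
            continue
        if part.startswith("?"):
            args.append(part)
        else:
            try:
                args.append(float(part))
            except ValueError:
                args.append(part)
    return name, tuple(args)


def _load_rules(raw) -> tuple:
    rules = []
    for entry in raw.get("rules", []):
        rule = BehaviorRule(
            id=int(entry["id"]),
            name=str(entry["name"]),
            match=tuple(parse_atom(a) for a in entry.get("match", [])),
            group_by=tuple(entry.get("group_by", [])),
            aggregate=tuple(parse_atom(a) for a in entry.get("aggregate", [])),
            filter=tuple(parse_atom(a) for a in entry.get("filter", [])),
            select=tuple(entry.get("select", [])),
        )
        bound = set()
        for name, args in rule.match:
            bound |= {a for a in args if isinstance(a, str) and a.startswith("?")}
        for name, args in rule.aggregate:
            bound.add(args[0])
        for var in rule.select:
            if var not in bound:
                raise _err("rules", f"rule {rule.id}: consequent variable {var} unbound")
        rules.append(rule)
    return tuple(sorted(rules, key=lambda r: r.id))


def canonical_config(raw: Mapping) -> str:
    """Canonical serialized form of a raw config tree (sorted keys, stable
    formatting).  load → canonicalize is idempotent."""
    return yaml.safe_dump(
        json.loads(json.dumps(raw)), sort_keys=True, default_flow_style=False
    )


# ---------------------------------------------------------------------------
# Record validation
# ---------------------------------------------------------------------------


def validate_llc(record: LLCRecord, vocab: ContextVocabulary) -> list:
    """Return every violated record invariant (empty list when clean)."""
    violations = []
    if record.category not in CATEGORIES:
        violations.append(f"unknown category {record.category!r}")
        return violations
    if record.end < record.start:
        violations.append("negative duration (end before start)")
    clinical = record.category in ("BloodGlucose", "BloodPressure", "WaterIntake")
    if record.label is not None:
        allowed = vocab.labels_for(record.category)
        sentinel = record.label in (UNSPECIFIED_BG, UNSPECIFIED_BP)
        if record.label not in allowed and not (clinical and sentinel):
            noun = "food" if record.category == "Food" else record.category.lower()
            violations.append(f"unknown {noun} label {record.label!r}")
    if clinical and record.label is None and record.raw_value is None:
        violations.append(f"{record.category} record carries neither raw value nor label")
    if not clinical and record.label is None:
        violations.append(f"{record.category} record has no label")
    if record.category == "BloodPressure" and record.raw_value is not None:
        if not isinstance(record.raw_value, (tuple, list)) or len(record.raw_value) != 2:
            violations.append("blood pressure raw value must be a (systolic, diastolic) pair")
    return violations


# ---------------------------------------------------------------------------
# Log readers / writers
# ---------------------------------------------------------------------------

_LOG_FIELDS = ("user_id", "category", "label", "value", "systolic", "diastolic", "start", "end")


def read_llc_log(source: Union[str, Path, TextIO]) -> list:
    """Read an LLC log: JSON-lines, or delimited text (tab/comma) with a
    header ``user_id  category  label  value  systolic  diastolic  start  end``."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    if lines[0].lstrip().startswith("{"):
        return [LLCRecord.from_dict(json.loads(ln)) for ln in lines]
    delim = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(delim)]
    records = []
    for ln in lines[1:]:
        row = dict(zip(header, (c.strip() for c in ln.split(delim))))
        records.append(LLCRecord.from_dict(row))
    return records


def write_llc_log(records: Iterable[LLCRecord], sink: Union[str, Path, TextIO]) -> None:
    _write_jsonl((r.to_dict() for r in records), sink)


def read_hlc_log(source: Union[str, Path, TextIO]) -> list:
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    return [HLCInstance.from_dict(json.loads(ln)) for ln in text.splitlines() if ln.strip()]


def write_hlc_log(instances: Iterable[HLCInstance], sink: Union[str, Path, TextIO]) -> None:
    _write_jsonl((i.to_dict() for i in instances), sink)


def _write_jsonl(dicts: Iterator[dict], sink) -> None:
    if hasattr(sink, "write"):
        for d in dicts:
            sink.write(json.dumps(d, sort_keys=True) + "\n")
    else:
        with open(sink, "w") as fh:
            for d in dicts:
                fh.write(json.dumps(d, sort_keys=True) + "\n")


def strip_labels(records: Sequence[LLCRecord]) -> list:
    """Drop labels from clinical records (keep raw values), for round-trip tests."""
    out = []
    for r in records:
        if r.category in ("BloodGlucose", "BloodPressure", "WaterIntake") and r.raw_value is not None:
            out.append(replace(r, label=None))
        else:
            out.append(r)
    return out
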