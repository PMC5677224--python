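"""Vertical fusion: verification and classification of candidate HLCs.

A candidate instance is matched against the class definitions of its domain.
Matching applies the closure convention: because an instance's assertions are
taken as its complete value set, a universal ("only") restriction is checked
directly against the asserted values, and an existential ("some") restriction
is witnessed exactly when the asserted value lies in the witness set.  This
reproduces the effective behavior of a description-logic reasoner fed
per-instance closure axioms, without running one.

Class definitions within a domain are pairwise disjoint, so at most one class
may match; two matches signal a broken definition set and raise
:class:`AmbiguousClassification`.  No match yields the ``Unidentified``
sentinel together with a reason code naming the mandatory property whose
absence blocked classification (or ``assertion_mismatch`` when all mandatory
properties were present but carried out-of-set values).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import (
    PROPERTY_CATEGORY,
    UNIDENTIFIED,
    ClassDefinition,
    ContextConfig,
    ContextVocabulary,
    HLCInstance,
)

_DOMAIN_MANDATORY = {
    "PA": ("hasActivity",),
    "N": ("hasFood",),
    "C": (),  # needs hasBloodGlucose and/or hasBloodPressure, checked apart
}


class AmbiguousClassification(RuntimeError):
    """An instance satisfied two supposedly disjoint class definitions."""


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------


def verify(
    instance: HLCInstance,
    vocab: ContextVocabulary,
    definitions: Sequence[ClassDefinition] = (),
) -> List[str]:
    """Syntactic and semantic consistency of a candidate instance.

    Returns the list of failures (empty when consistent): unknown domain or
    property, out-of-vocabulary values (range violations), missing
    domain-mandatory properties, interval sanity, and an inferred class that
    contradicts the domain or the disjointness declarations.
    """
    failures: List[str] = []
    if instance.domain not in _DOMAIN_MANDATORY:
        return [f"unknown domain {instance.domain!r}"]
    if instance.end < instance.start:
        failures.append("negative duration (end before start)")
    for prop, value in instance.assertions.items():
        cat = PROPERTY_CATEGORY.get(prop)
        if cat is None:
            failures.append(f"unknown property {prop!r}")
            continue
        if value not in vocab.labels_for(cat):
            failures.append(f"range violation: {prop} value {value!r} not a {cat} term")
    for prop in _DOMAIN_MANDATORY[instance.domain]:
        if prop not in instance.assertions:
            failures.append(f"mandatory property absent: {prop}")
    if instance.domain == "C" and not (
        "hasBloodGlucose" in instance.assertions or "hasBloodPressure" in instance.assertions
    ):
        failures.append("mandatory property absent: hasBloodGlucose/hasBloodPressure")
    if instance.inferred_class not in (None, UNIDENTIFIED):
        domain_classes = set(vocab.hlc_classes.get(instance.domain, ()))
        if instance.inferred_class not in domain_classes:
            failures.append(
                f"inferred class {instance.inferred_class!r} outside domain {instance.domain}"
            )
    return failures


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def matches(instance: HLCInstance, definition: ClassDefinition) -> bool:
    """Does the instance satisfy every axiom of one class definition under
    closure?"""
    if instance.domain != definition.domain:
        return False
    assertions = instance.assertions
    # universal ("only"): every asserted value of a constrained property must
    # be allowed
    for prop, allowed in definition.universal.items():
        if prop in assertions and assertions[prop] not in allowed:
            return False
    # existential ("some"): mandatory witnesses must each be present ...
    optional_hit = False
    has_optional = False
    for prop, (witnesses, mandatory) in definition.existential.items():
        present = prop in assertions and assertions[prop] in witnesses
        if mandatory:
            if not present:
                return False
        else:
            has_optional = True
            optional_hit = optional_hit or present
    # ... and at least one non-mandatory witness pool must be hit, if any exist
    if has_optional and not optional_hit:
        return False
    return True


def _unidentified_reason(
    instance: HLCInstance, candidates: Sequence[ClassDefinition]
) -> str:
    """Why no class matched: the alphabetically first property that is a
    mandatory witness of some candidate class yet absent from the instance;
    ``assertion_mismatch`` when every such property was asserted."""
    missing = sorted(
        prop
        for defn in candidates
        for prop, (_, mandatory) in defn.existential.items()
        if mandatory and prop not in instance.assertions
    )
    if missing:
        return f"missing:{missing[0]}"
    return "assertion_mismatch"


def classify(
    instance: HLCInstance, definitions: Sequence[ClassDefinition]
) -> Tuple[str, Optional[str]]:
    """Return ``(class name, None)`` for the unique matching definition,
    ``(Unidentified, reason)`` when none matches.

    Raises :class:`AmbiguousClassification` if two definitions declared
    disjoint both match — that indicts the definition set, not the instance.
    """
    domain_defs = [d for d in definitions if d.domain == instance.domain]
    hits = [d for d in domain_defs if matches(instance, d)]
    if len(hits) > 1:
        names = sorted(d.name for d in hits)
        raise AmbiguousClassification(
            f"instance matches disjoint classes {names}; fix the class definitions"
        )
    if hits:
        return hits[0].name, None
    return UNIDENTIFIED, _unidentified_reason(instance, domain_defs)


def classify_instances(
    instances: Iterable[HLCInstance], config: ContextConfig
) -> List[HLCInstance]:
    """Classify candidates in place (fills ``inferred_class`` and, for
    unidentified ones, ``unidentified_reason``)."""
    out = []
    for inst in instances:
        cls, reason = classify(inst, config.class_definitions)
        inst.inferred_class = cls
        inst.unidentified_reason = reason
        out.append(inst)
    return out


def classify_stream(
    instances: Sequence[HLCInstance], config: ContextConfig
) -> Tuple[List[HLCInstance], List[HLCInstance]]:
    """Classify a time-ordered stream and emit change-point notifications.

    Every instance receives an inferred class; a notification is emitted only
    when a user's inferred class in a domain differs from that user's previous
    class in the same domain (the first classification of a (user, domain)
    pair always notifies).  Returns ``(classified, notifications)``.
    """
    classified = classify_instances(list(instances), config)
    notifications: List[HLCInstance] = []
    last: Dict[tuple, str] = {}
    for inst in classified:
        key = (inst.user_id, inst.domain)
        if last.get(key) != inst.inferred_class:
            notifications.append(inst)
            last[key] = inst.inferred_class
    return classified, notifications
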