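"""Mapping raw clinical readings onto low-level context labels.

Blood glucose (mg/dL) uses six non-contiguous bands; readings falling between
bands (exactly 70, 108-120, 180-215, 280-314) yield the ``UnspecifiedBG``
sentinel and are excluded from clinical fusion.  Blood pressure categorizes the
systolic and diastolic components independently against ordered bands and
returns the more severe of the two (a standard clinical convention, exposed as
a swappable policy).  Water intake splits strictly at the normal daily volume,
with an optional tolerance band around it.
"""

from __future__ import annotations

from dataclasses import replace
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    UNSPECIFIED_BG,
    UNSPECIFIED_BP,
    ContextConfig,
    LLCRecord,
    RangeRule,
    load_config,
)


def _bands(entries: Sequence[Mapping]) -> tuple:
    return tuple(
        RangeRule(
            label=e["label"],
            lower=e.get("lower"),
            lower_closed=bool(e.get("lower_closed", False)),
            upper=e.get("upper"),
            upper_closed=bool(e.get("upper_closed", False)),
        )
        for e in entries
    )


class ClinicalLabeler:
    """Threshold tables compiled from a :class:`ContextConfig`."""

    def __init__(self, config: ContextConfig):
        lab = config.labeler
        self.bg_bands = _bands(lab["blood_glucose"])
        bp = lab["blood_pressure"]
        self.systolic_bands = _bands(bp["systolic"])
        self.diastolic_bands = _bands(bp["diastolic"])
        self.bp_severity = {label: i for i, label in enumerate(bp["severity_order"])}
        self.bp_policy = bp.get("policy", "severity_max")
        self.water_normal = float(lab["water"]["normal_ml"])
        self.water_tolerance = float(lab["water"].get("tolerance_ml", 0))

    # -- blood glucose ------------------------------------------------------

    def label_blood_glucose(self, value: float) -> str:
        """Label a glucose reading, or return ``UnspecifiedBG`` for values in
        a gap between printed bands."""
        if value < 0:
            raise ValueError(f"negative blood glucose value {value}")
        for band in self.bg_bands:
            if band.contains(value):
                return band.label
        return UNSPECIFIED_BG

    # -- blood pressure -----------------------------------------------------

    def _component(self, bands: tuple, value: float) -> Optional[str]:
        for band in bands:
            if band.contains(value):
                return band.label
        return None

    def label_blood_pressure(self, systolic: float, diastolic: float) -> str:
        """Label a pressure pair as the more severe of the two component
        categories (severity: LowBP < NormalBP < PreHypertension <
        HypertensionStageI < HypertensionStageII)."""
        if systolic <= 0 or diastolic <= 0:
            raise ValueError("blood pressure components must be positive")
        if self.bp_policy != "severity_max":
            raise ValueError(f"unknown blood pressure policy {self.bp_policy!r}")
        sys_label = self._component(self.systolic_bands, systolic)
        dia_label = self._component(self.diastolic_bands, diastolic)
        labels = [l for l in (sys_label, dia_label) if l is not None]
        if not labels:
            return UNSPECIFIED_BP
        return max(labels, key=self.bp_severity.__getitem__)

    # -- water intake -------------------------------------------------------

    def label_water_intake(self, total_ml: float) -> str:
        """Strict three-way split of the accumulated daily volume around the
        normal intake (default 2000 mL, tolerance 0)."""
        if total_ml < 0:
            raise ValueError(f"negative water intake {total_ml}")
        if total_ml > self.water_normal + self.water_tolerance:
            return "OverHydration"
        if total_ml < self.water_normal - self.water_tolerance:
            return "Dehydration"
        return "NormalIntake"

    # -- record streams -----------------------------------------------------

    def label_record(self, record: LLCRecord) -> LLCRecord:
        """Attach a label to a raw clinical record; non-clinical or already
        labeled records pass through unchanged."""
        if record.label is not None or record.raw_value is None:
            return record
        if record.category == "BloodGlucose":
            return replace(record, label=self.label_blood_glucose(record.raw_value))
        if record.category == "BloodPressure":
            sys_v, dia_v = record.raw_value
            return replace(record, label=self.label_blood_pressure(sys_v, dia_v))
        if record.category == "WaterIntake":
            return replace(record, label=self.label_water_intake(record.raw_value))
        return record

    def label_stream(self, records: Iterable[LLCRecord]) -> list:
        return [self.label_record(r) for r in records]


@lru_cache(maxsize=1)
def _default_labeler() -> ClinicalLabeler:
    return ClinicalLabeler(load_config())


def label_blood_glucose(value: float, labeler: Optional[ClinicalLabeler] = None) -> str:
    return (labeler or _default_labeler()).label_blood_glucose(value)


def label_blood_pressure(
    systolic: float, diastolic: float, labeler: Optional[ClinicalLabeler] = None
) -> str:
    return (labeler or _default_labeler()).label_blood_pressure(systolic, diastolic)


def label_water_intake(total_ml: float, labeler: Optional[ClinicalLabeler] = None) -> str:
    return (labeler or _default_labeler()).label_water_intake(total_ml)
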