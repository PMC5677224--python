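"""Seeded multi-user lifelog stream generator with ground-truth annotations.

Each synthetic user follows one of six archetype daily schedules (sedentary,
lightly / moderately / very / extremely active, irregular eater) built from
non-overlapping episodes: sleep, office blocks, meals, archetype-specific gym
sessions, clinical self-measurements and an evening rest block.  Every episode
emits the low-level records a deployed platform would see (activity + location
+ emotion over the episode span; food items at meals; raw glucose / pressure /
water readings as point events), and the generator records the high-level
context and behavioral labels the schedule entails **by construction** — the
behavioral tally is a direct count over the schedule, independent of the rule
engine under test.

Clinical raw values are drawn uniformly inside the target label's band, so a
clean (missingness 0) stream is fully classifiable end to end; the archetype
gym plans are laid out so that each archetype satisfies exactly its intended
behavioral rules.  Degradation (record dropout) is applied separately and
reproducibly by :func:`inject_missingness`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import LLCRecord

SECONDS_PER_DAY = 86400
# Default stream origin: an epoch-day boundary (UTC), so calendar-day grouping
# aligns with schedule days.
DEFAULT_START_DAY = 18519

ARCHETYPES = (
    "sedentary",
    "lightly_active",
    "moderately_active",
    "very_active",
    "extremely_active",
    "irregular_eater",
)

EMOTIONS = ("Happiness", "Disgust", "Boredom", "Anger", "Neutral")

# Uniform sampling bands per clinical label (inside the printed ranges).
BG_BANDS = {
    "DangerouslyLowBG": (30, 50),
    "LowBG": (51, 69),
    "NormalBG": (71, 107),
    "BorderlineBG": (121, 179),
    "HighBG": (216, 279),
    "DangerouslyHighBG": (315, 400),
}
BP_BANDS = {
    "LowBP": ((75, 89), (45, 59)),
    "NormalBP": ((95, 120), (65, 80)),
    "PreHypertension": ((121, 138), (81, 88)),
    "HypertensionStageI": ((141, 158), (91, 98)),
    "HypertensionStageII": ((160, 190), (100, 115)),
}
# Daily draw weights: mostly unremarkable readings with occasional extremes.
BG_WEIGHTS = {
    "NormalBG": 0.50, "BorderlineBG": 0.15, "LowBG": 0.15,
    "HighBG": 0.10, "DangerouslyHighBG": 0.05, "DangerouslyLowBG": 0.05,
}
BP_WEIGHTS = {
    "NormalBP": 0.55, "PreHypertension": 0.15, "LowBP": 0.10,
    "HypertensionStageI": 0.12, "HypertensionStageII": 0.08,
}

# Severity ladder used for the generator's own (construction-side) health
# state; intentionally a flat lookup, not the classifier.
_STATE_NAMES = ("NormalHealthState", "ModerateHealthState",
                "HighRiskHealthState", "VeryHighRiskHealthState")
BG_STATE = {
    "NormalBG": 0, "BorderlineBG": 1, "LowBG": 1,
    "HighBG": 2, "DangerouslyHighBG": 3, "DangerouslyLowBG": 3,
}
BP_STATE = {
    "NormalBP": 0, "PreHypertension": 1, "LowBP": 1,
    "HypertensionStageI": 2, "HypertensionStageII": 3,
}

NUTRIENT_OF = None  # filled lazily from the default config


@dataclass(frozen=True)
class Episode:
    start: int          # seconds from local midnight
    end: int
    activity: str
    location: str
    pa_class: str       # the PA-HLC class this episode realizes


@dataclass(frozen=True)
class Meal:
    start: int
    end: int
    location: str


@dataclass(frozen=True)
class UserProfile:
    """One synthetic user: archetype schedule + clinical draw distributions."""

    user_id: str
    archetype: str = "sedentary"
    start_day: int = DEFAULT_START_DAY
    bg_weights: Dict[str, float] = field(default_factory=lambda: dict(BG_WEIGHTS))
    bp_weights: Dict[str, float] = field(default_factory=lambda: dict(BP_WEIGHTS))
    missingness: float = 0.0

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError("missingness must be in [0, 1]")


# Fixed daily blocks shared by all archetypes.
_BASE_EPISODES = (
    Episode(0, 24300, "Sleeping", "Home", "Sleeping"),          # 00:00-06:45
    Episode(32400, 43200, "Act_Sitting", "Office", "OfficeWork"),  # 09:00-12:00
    Episode(48600, 59400, "Act_Sitting", "Office", "OfficeWork"),  # 13:30-16:30
    Episode(75600, 84600, "Act_LyingDown", "Home", "Inactivity"),  # 21:00-23:30
)
_BG_TIME, _BP_TIME, _WATER_TIME = 27000, 27010, 73800
_BASE_MEALS = (Meal(28800, 30300, "Home"), Meal(70200, 71700, "Home"))
_EXTRA_MEALS = (Meal(45000, 46500, "Restaurant"), Meal(60300, 61800, "Office"))


def _gym(start: int, end: int, activity: str) -> Episode:
    return Episode(start, end, activity, "Loc_Gym", "Exercising")


def gym_sessions(archetype: str, day_index: int) -> Tuple[Episode, ...]:
    """The archetype's gym plan for one schedule day."""
    if archetype == "sedentary":
        # one token 1.5 h walk per week: < 2 h total on < 7 distinct days
        return (_gym(61200, 66600, "Act_Walking"),) if day_index % 7 == 2 else ()
    if archetype == "lightly_active":
        return (_gym(61200, 62400, "Act_Walking"),)          # 20 min daily
    if archetype == "moderately_active":
        return (_gym(61200, 63300, "Act_Running"),)          # 35 min daily
    if archetype == "very_active":
        return (_gym(61200, 68400, "Act_Running"),)          # 2 h daily
    if archetype == "extremely_active":
        return (_gym(43500, 48000, "Act_Running"),           # 12:05-13:20
                _gym(61200, 65700, "Act_Running"))           # 17:00-18:15
    return ()  # irregular_eater


def meals_for(archetype: str) -> Tuple[Meal, ...]:
    if archetype == "irregular_eater":
        return tuple(sorted(_BASE_MEALS + _EXTRA_MEALS, key=lambda m: m.start))
    return _BASE_MEALS


def day_schedule(archetype: str, day_index: int) -> Tuple[Episode, ...]:
    return tuple(
        sorted(_BASE_EPISODES + gym_sessions(archetype, day_index),
               key=lambda e: e.start)
    )


def _nutrient_map() -> Dict[str, str]:
    global NUTRIENT_OF
    if NUTRIENT_OF is None:
        from .model import load_config

        NUTRIENT_OF = dict(load_config().vocabulary.food_nutrient)
    return NUTRIENT_OF


def _weighted_choice(rng: np.random.Generator, weights: Dict[str, float]) -> str:
    labels = sorted(weights)
    p = np.array([weights[l] for l in labels], dtype=float)
    return labels[rng.choice(len(labels), p=p / p.sum())]


def generate_user_stream(
    profile: UserProfile, days: int, seed: int
) -> Tuple[List[LLCRecord], dict]:
    """Generate one user's clean stream plus ground truth.

    Returns ``(records, truth)`` where ``truth`` has keys ``hlc`` (expected
    high-level contexts: user, domain, class, start, end) and ``behavior``
    (expected behavioral labels over the final 7-day window, tallied directly
    from the schedule).  Deterministic for fixed (profile, days, seed).
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    u = profile.user_id
    nutrient_of = _nutrient_map()
    food_items = sorted(nutrient_of)
    records: List[LLCRecord] = []
    hlc_truth: List[dict] = []

    def emit(category, start, end, label=None, raw=None):
        records.append(LLCRecord(u, category, float(start), float(end), label, raw))

    for d in range(days):
        base = (profile.start_day + d) * SECONDS_PER_DAY
        for ep in day_schedule(profile.archetype, d):
            s, e = base + ep.start, base + ep.end
            emit("Activity", s, e, ep.activity)
            emit("Location", s + int(rng.integers(0, 10)), e, ep.location)
            emit("Emotion", s + int(rng.integers(0, 10)), e,
                 EMOTIONS[rng.integers(0, len(EMOTIONS))])
            hlc_truth.append(
                {"user_id": u, "domain": "PA", "cls": ep.pa_class, "start": s, "end": e}
            )
        for meal in meals_for(profile.archetype):
            s, e = base + meal.start, base + meal.end
            item = food_items[rng.integers(0, len(food_items))]
            emit("Activity", s, e, "Eating")
            emit("Food", s + int(rng.integers(0, 10)), e, item)
            emit("Location", s + int(rng.integers(0, 10)), e, meal.location)
            emit("Emotion", s + int(rng.integers(0, 10)), e,
                 EMOTIONS[rng.integers(0, len(EMOTIONS))])
            hlc_truth.append(
                {"user_id": u, "domain": "N", "cls": nutrient_of[item], "start": s, "end": e}
            )
            # an Eating activity also realizes a sedentary PA context
            hlc_truth.append(
                {"user_id": u, "domain": "PA", "cls": "Inactivity", "start": s, "end": e}
            )
        # clinical self-measurements: glucose and pressure 10 s apart (one
        # concurrency group), accumulated water in the evening
        bg_label = _weighted_choice(rng, profile.bg_weights)
        lo, hi = BG_BANDS[bg_label]
        bg_value = float(rng.integers(lo, hi + 1))
        bp_label = _weighted_choice(rng, profile.bp_weights)
        (slo, shi), (dlo, dhi) = BP_BANDS[bp_label]
        bp_value = (float(rng.integers(slo, shi + 1)), float(rng.integers(dlo, dhi + 1)))
        t_bg, t_bp = base + _BG_TIME, base + _BP_TIME
        emit("BloodGlucose", t_bg, t_bg, None, bg_value)
        emit("BloodPressure", t_bp, t_bp, None, bp_value)
        state = _STATE_NAMES[max(BG_STATE[bg_label], BP_STATE[bp_label])]
        hlc_truth.append(
            {"user_id": u, "domain": "C", "cls": state, "start": t_bg, "end": t_bp}
        )
        t_w = base + _WATER_TIME
        emit("WaterIntake", t_w, t_w, None, float(rng.integers(1200, 2900)))

    records.sort(key=lambda r: (r.start, r.category, r.label or ""))
    end_epoch = (profile.start_day + days) * SECONDS_PER_DAY
    truth = {
        "hlc": hlc_truth,
        "behavior": behavior_tally(profile, days),
        "at": float(end_epoch),
    }
    return records, truth


def behavior_tally(profile: UserProfile, days: int) -> List[dict]:
    """Behavioral ground truth over the final 7-day window, counted straight
    off the schedule (no rule engine involved)."""
    u = profile.user_id
    window_days = [d for d in range(days) if days - d <= 7]
    sessions = []  # (day, hours, activity)
    for d in window_days:
        for ep in gym_sessions(profile.archetype, d):
            sessions.append((profile.start_day + d, (ep.end - ep.start) / 3600.0, ep.activity))
    out: List[dict] = []
    total = sum(h for _, h, _ in sessions)
    session_days = {d for d, _, _ in sessions}
    if sessions and total < 2 and len(session_days) < 7:
        out.append({"user_id": u, "label": "SedentaryBehavior", "rule_id": 1})
    walk = [(d, h) for d, h, a in sessions if a == "Act_Walking"]
    walk_total = sum(h for _, h in walk)
    if 1 < walk_total < 3 and len({d for d, _ in walk}) == 7:
        out.append({"user_id": u, "label": "LightlyActive", "rule_id": 2})
    run = [(d, h) for d, h, a in sessions if a == "Act_Running"]
    run_total = sum(h for _, h in run)
    if 3 < run_total < 5 and len({d for d, _ in run}) == 7:
        out.append({"user_id": u, "label": "ModeratelyActive", "rule_id": 3})
    qualifying = [(d, h) for d, h, _ in sessions if 1 < h < 3]
    if len({d for d, _ in qualifying}) == 7:
        out.append({"user_id": u, "label": "VeryActive", "rule_id": 4})
    per_day: Dict[int, int] = {}
    for d, _ in qualifying:
        per_day[d] = per_day.get(d, 0) + 1
    for d in sorted(per_day):
        if per_day[d] == 2:
            out.append({"user_id": u, "label": "ExtremelyActive", "rule_id": 5, "day": d})
    meals = len(meals_for(profile.archetype))
    if meals > 2:
        for d in window_days:
            out.append({"user_id": u, "label": "MealFrequency", "rule_id": 6,
                        "day": profile.start_day + d, "freq": meals})
    return out


def inject_missingness(
    records: Sequence[LLCRecord], rate: float, seed: int
) -> List[LLCRecord]:
    """Independently drop each record with probability ``rate`` (seeded)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0:
        return list(records)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(records)) >= rate
    return [r for r, k in zip(records, keep) if k]


def cohort_profiles(n_users: int, start_day: int = DEFAULT_START_DAY) -> List[UserProfile]:
    return [
        UserProfile(user_id=f"user{i:02d}", archetype=ARCHETYPES[i % len(ARCHETYPES)],
                    start_day=start_day)
        for i in range(n_users)
    ]


def generate_cohort(n_users: int, days: int, seed: int) -> dict:
    """Generate per-user streams and truth for a mixed-archetype cohort.

    Per-user sub-seeds are spawned from the master seed, so streams are
    reproducible and mutually independent.
    """
    if n_users < 1:
        raise ValueError("n_users must be >= 1")
    profiles = cohort_profiles(n_users)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_users) % (2**31 - 1)
    streams: Dict[str, List[LLCRecord]] = {}
    truths: Dict[str, dict] = {}
    for profile, sub_seed in zip(profiles, child_seeds):
        recs, truth = generate_user_stream(profile, days, int(sub_seed))
        streams[profile.user_id] = recs
        truths[profile.user_id] = truth
    return {"profiles": profiles, "streams": streams, "truth": truths}
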