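"""Behavioral rule engine: fixtures for each rule and equivalence with
independent hand-written evaluators on random fact bases."""

import numpy as np
import pytest

from contextfuse import (
    BehavioralContext,
    FactBase,
    HLCInstance,
    LLCRecord,
    duration,
    evaluate_rule,
    run_all_rules,
)

DAY = 86400.0
HOUR = 3600.0


def exercising(user, start, hours, activity="Act_Running", location="Loc_Gym"):
    i = HLCInstance(
        user, "PA",
        {"hasActivity": activity, "hasLocation": location},
        float(start), float(start + hours * HOUR),
    )
    i.inferred_class = "Exercising"
    return i


def eating_llc(user, start):
    return LLCRecord(user, "Activity", float(start), float(start + 1800), "Eating")


def rule(config, rule_id):
    return next(r for r in config.rules if r.id == rule_id)


# ---------------------------------------------------------------------------
# duration builtin
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "start,end,unit,expected",
    [(0, 7200, "Hours", 2.0), (0, 0, "Days", 0.0), (0, 604800, "Days", 7.0),
     (0, 5400, "Hours", 1.5)],
)
def test_duration(start, end, unit, expected):
    assert duration(start, end, unit) == expected


def test_duration_rejects_reversed_interval():
    with pytest.raises(ValueError):
        duration(10, 0, "Hours")


# ---------------------------------------------------------------------------
# per-rule fixtures
# ---------------------------------------------------------------------------


class TestRuleFixtures:
    AT = 100 * DAY

    def test_sedentary_selected_for_single_short_session(self, config):
        facts = FactBase(hlcs=[exercising("u", self.AT - 3 * DAY, 1.5)])
        rows = evaluate_rule(rule(config, 1), facts, self.AT, config.engine)
        assert [r.user_id for r in rows] == ["u"]
        assert rows[0].value("H") == pytest.approx(1.5)

    def test_sedentary_rejected_at_three_hours(self, config):
        facts = FactBase(hlcs=[exercising("u", self.AT - 3 * DAY, 3.0)])
        assert evaluate_rule(rule(config, 1), facts, self.AT, config.engine) == []

    def test_sedentary_needs_gym_location(self, config):
        facts = FactBase(hlcs=[exercising("u", self.AT - 3 * DAY, 1.5, location="Outdoors")])
        assert evaluate_rule(rule(config, 1), facts, self.AT, config.engine) == []

    def test_lightly_active_daily_walking(self, config):
        hlcs = [
            exercising("u", self.AT - (d + 1) * DAY, 0.3, activity="Act_Walking")
            for d in range(7)
        ]
        rows = evaluate_rule(rule(config, 2), facts=FactBase(hlcs=hlcs), at=self.AT,
                             engine=config.engine)
        assert len(rows) == 1 and rows[0].value("H") == pytest.approx(2.1)

    def test_moderately_active_daily_running(self, config):
        hlcs = [exercising("u", self.AT - (d + 1) * DAY, 0.5) for d in range(7)]
        rows = evaluate_rule(rule(config, 3), FactBase(hlcs=hlcs), self.AT, config.engine)
        assert len(rows) == 1 and rows[0].value("H") == pytest.approx(3.5)

    def test_very_active_seven_days_of_two_hours(self, config):
        hlcs = [exercising("u", self.AT - (d + 1) * DAY, 2.0) for d in range(7)]
        rows = evaluate_rule(rule(config, 4), FactBase(hlcs=hlcs), self.AT, config.engine)
        assert len(rows) == 1 and rows[0].value("no_of_days") == 7

    def test_very_active_fails_on_six_days(self, config):
        hlcs = [exercising("u", self.AT - (d + 1) * DAY, 2.0) for d in range(6)]
        assert evaluate_rule(rule(config, 4), FactBase(hlcs=hlcs), self.AT, config.engine) == []

    def test_extremely_active_reports_each_twice_a_day(self, config):
        hlcs = []
        for d in range(3):
            base = self.AT - (d + 1) * DAY
            hlcs += [exercising("u", base, 1.25), exercising("u", base + 6 * HOUR, 1.25)]
        rows = evaluate_rule(rule(config, 5), FactBase(hlcs=hlcs), self.AT, config.engine)
        assert len(rows) == 3
        assert all(r.value("exercise_per_day") == 2 for r in rows)

    def test_meal_frequency_counts_eating_per_day(self, config):
        base = self.AT - 2 * DAY
        llcs = [eating_llc("u", base + k * 3 * HOUR) for k in range(4)]
        rows = evaluate_rule(rule(config, 6), FactBase(llcs=llcs), self.AT, config.engine)
        assert len(rows) == 1 and rows[0].value("freq") == 4

    def test_meal_frequency_requires_more_than_two(self, config):
        base = self.AT - 2 * DAY
        llcs = [eating_llc("u", base + k * 6 * HOUR) for k in range(2)]
        assert evaluate_rule(rule(config, 6), FactBase(llcs=llcs), self.AT, config.engine) == []

    def test_old_contexts_outside_window_ignored(self, config):
        facts = FactBase(hlcs=[exercising("u", self.AT - 20 * DAY, 1.5)])
        assert evaluate_rule(rule(config, 1), facts, self.AT, config.engine) == []


class TestRunAllRules:
    AT = 100 * DAY

    def test_empty_fact_base(self, config):
        assert run_all_rules(FactBase(), self.AT, config) == []

    def test_single_sedentary_fixture(self, config):
        facts = FactBase(hlcs=[exercising("u", self.AT - 3 * DAY, 1.5)])
        rows = run_all_rules(facts, self.AT, config)
        assert [(r.rule_id, r.user_id) for r in rows] == [(1, "u")]

    def test_user_can_satisfy_rule4_and_rule5(self, config):
        hlcs = []
        for d in range(7):
            base = self.AT - (d + 1) * DAY
            hlcs += [exercising("u", base, 1.25), exercising("u", base + 6 * HOUR, 1.25)]
        rows = run_all_rules(FactBase(hlcs=hlcs), self.AT, config)
        assert {r.rule_id for r in rows} == {4, 5}
        assert sum(1 for r in rows if r.rule_id == 5) == 7

    def test_deterministic_ordering(self, config):
        facts = FactBase(hlcs=[
            exercising("zed", self.AT - 2 * DAY, 1.5),
            exercising("amy", self.AT - 3 * DAY, 1.5),
        ])
        rows = run_all_rules(facts, self.AT, config)
        assert [r.user_id for r in rows] == ["amy", "zed"]


# ---------------------------------------------------------------------------
# nested-loop join oracle on random fact bases
# ---------------------------------------------------------------------------


def _window_hlcs(facts, user, lo, hi):
    return [
        h for h in facts.hlcs
        if h.user_id == user and lo <= h.start <= hi and h.inferred_class == "Exercising"
    ]


def _day(t):
    return int(t // DAY)


def oracle_results(facts, at, engine):
    """Direct per-rule evaluation: filter, total/per-context hours, day sets."""
    lo, hi = at - engine.week_seconds, at
    users = sorted({h.user_id for h in facts.hlcs} | {r.user_id for r in facts.llcs})
    out = set()
    for u in users:
        ex = _window_hlcs(facts, u, lo, hi)
        hours = [(c.end - c.start) / HOUR for c in ex]
        days = {_day(c.start) for c in ex}
        total = sum(hours)
        if ex and [c for c in ex if c.assertions.get("hasLocation") == "Loc_Gym"]:
            gym = [c for c in ex if c.assertions.get("hasLocation") == "Loc_Gym"]
            g_total = sum((c.end - c.start) / HOUR for c in gym)
            g_days = {_day(c.start) for c in gym}
            if g_total < 2 and len(g_days) < 7:
                out.add((1, u, None))
        walk = [c for c in ex if c.assertions.get("hasActivity") == "Act_Walking"]
        w_total = sum((c.end - c.start) / HOUR for c in walk)
        if walk and 1 < w_total < 3 and len({_day(c.start) for c in walk}) == 7:
            out.add((2, u, None))
        run = [c for c in ex if c.assertions.get("hasActivity") == "Act_Running"]
        r_total = sum((c.end - c.start) / HOUR for c in run)
        if run and 3 < r_total < 5 and len({_day(c.start) for c in run}) == 7:
            out.add((3, u, None))
        qual = [c for c in ex if 1 < (c.end - c.start) / HOUR < 3]
        if len({_day(c.start) for c in qual}) == 7:
            out.add((4, u, None))
        per_day = {}
        for c in qual:
            per_day.setdefault(_day(c.start), []).append(c)
        for d, cs in per_day.items():
            if len(cs) == 2:
                out.add((5, u, d))
        meals = {}
        for r in facts.llcs:
            if r.user_id == u and r.category == "Activity" and r.label == "Eating" and lo <= r.start <= hi:
                meals.setdefault(_day(r.start), 0)
                meals[_day(r.start)] += 1
        for d, k in meals.items():
            if k > 2:
                out.add((6, u, d))
    return out


def engine_results(rows):
    out = set()
    for b in rows:
        day = b.value("day")
        out.add((b.rule_id, b.user_id, int(day) if day is not None else None))
    return out


def random_fact_base(rng, at):
    users = [f"u{k}" for k in range(int(rng.integers(1, 4)))]
    hlcs, llcs = [], []
    n_facts = int(rng.integers(5, 200))
    for _ in range(n_facts):
        u = users[rng.integers(len(users))]
        start = at - rng.uniform(0, 10 * DAY)
        if rng.random() < 0.75:
            hours = float(rng.choice([0.3, 0.5, 1.25, 1.5, 2.0, 3.5]))
            act = str(rng.choice(["Act_Walking", "Act_Running", "Act_Cycling"]))
            loc = str(rng.choice(["Loc_Gym", "Outdoors"]))
            hlcs.append(exercising(u, start, hours, activity=act, location=loc))
        else:
            llcs.append(eating_llc(u, start))
    return FactBase(hlcs=hlcs, llcs=llcs)


class TestJoinOracleEquivalence:
    def test_random_fact_bases_match_oracle(self, config):
        rng = np.random.default_rng(17)
        at = 200 * DAY
        for _ in range(100):
            facts = random_fact_base(rng, at)
            rows = run_all_rules(facts, at, config)
            assert engine_results(rows) == oracle_results(facts, at, config.engine)

    def test_permutation_invariance(self, config):
        rng = np.random.default_rng(18)
        at = 200 * DAY
        facts = random_fact_base(rng, at)
        shuffled = FactBase(hlcs=list(facts.hlcs), llcs=list(facts.llcs))
        rng.shuffle(shuffled.hlcs)
        rng.shuffle(shuffled.llcs)
        a = engine_results(run_all_rules(facts, at, config))
        b = engine_results(run_all_rules(shuffled, at, config))
        assert a == b

    def test_adding_exercise_only_removes_from_sedentary(self, config):
        """Extra exercising grows the weekly total, so rule 1 selections can
        only shrink."""
        rng = np.random.default_rng(19)
        at = 200 * DAY
        checked = 0
        for _ in range(40):
            facts = random_fact_base(rng, at)
            with_gym = sorted({
                h.user_id
                for h in facts.hlcs
                if h.assertions.get("hasLocation") == "Loc_Gym"
                and at - 7 * DAY <= h.start <= at
            })
            if not with_gym:
                continue
            before = {
                r.user_id for r in run_all_rules(facts, at, config) if r.rule_id == 1
            }
            extra = exercising(with_gym[0], at - rng.uniform(0, 6 * DAY), 1.5)
            bigger = FactBase(hlcs=list(facts.hlcs) + [extra], llcs=list(facts.llcs))
            after = {
                r.user_id for r in run_all_rules(bigger, at, config) if r.rule_id == 1
            }
            assert after <= before  # nobody newly selected
            checked += 1
        assert checked >= 10
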