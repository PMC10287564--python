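"""Tests of endpoint curation, first-event extraction and aggregates."""

import numpy as np
import pandas as pd
import pytest

from alcophewas._errors import ConfigurationError, DataIntegrityError
from alcophewas.endpoints import (EndpointCatalog, EndpointDefinition,
                                  aggregate_endpoint, chapter_of,
                                  curate_endpoint_catalog,
                                  extract_first_events)


def _mini_cohort(n_current_cases, code="K74", n=400):
    """Construct a cohort where exactly `n_current_cases` current drinkers
    have an event of `code`."""
    participants = pd.DataFrame({
        "id": np.arange(n),
        "sex": "M",
        "area": 0,
        "age_baseline": 50.0,
        "death_age": 90.0,
        "censor_age": 62.0,
    })
    exposure = pd.DataFrame({
        "id": np.arange(n),
        "status": np.where(np.arange(n) < n // 2, "current", "occasional"),
    })
    cases = np.arange(n_current_cases)  # all current drinkers
    events = pd.DataFrame({"id": cases, "icd10": code,
                           "age": np.full(len(cases), 55.0)})
    return participants, exposure, events


class TestChapters:
    @pytest.mark.parametrize("code,chapter", [
        ("A15", "I"), ("C15", "II"), ("D69", "III"), ("E04", "IV"),
        ("F10", "V"), ("G45", "VI"), ("H25", "VII"), ("H60", "VIII"),
        ("I63", "IX"), ("J15", "X"), ("K74", "XI"), ("M10", "XIII"),
        ("N40", "XIV"), ("O10", "XV"), ("P05", "XVI"), ("Q20", "XVII"),
        ("R07", "XVIII"), ("S22", "XIX"), ("T98", "XIX"), ("V01", "XX"),
        ("W19", "XX"), ("X60", "XX"),
    ])
    def test_chapter_mapping(self, code, chapter):
        assert chapter_of(code) == chapter

    def test_invalid_codes_rejected(self):
        for bad in ("Z99", "U07", "9A1", "K7"):
            with pytest.raises(DataIntegrityError):
                chapter_of(bad)

    def test_default_catalog_chapters_consistent(self):
        cat = EndpointCatalog.default()
        for ep in cat:
            chapters = {chapter_of(c) for c in ep.codes}
            assert chapters == {ep.chapter}


class TestCuration:
    def test_80_case_endpoint_retained(self):
        p, expo, ev = _mini_cohort(80)
        cat = curate_endpoint_catalog(ev, p, expo, sex="M", min_cases=80)
        assert "K74" in cat

    def test_79_case_endpoint_pooled(self):
        p, expo, ev = _mini_cohort(79)
        cat = curate_endpoint_catalog(ev, p, expo, sex="M", min_cases=80)
        assert "K74" not in cat
        assert "less_common_XI" in cat
        assert "K74" in cat.get("less_common_XI").codes

    def test_pregnancy_chapter_excluded_in_men(self):
        p, expo, ev = _mini_cohort(100, code="O10")
        cat = curate_endpoint_catalog(ev, p, expo, sex="M", min_cases=80)
        assert all(ep.chapter != "XV" for ep in cat)
        # but kept for women
        p["sex"] = "F"
        cat_f = curate_endpoint_catalog(ev, p, expo, sex="F", min_cases=80)
        assert any(ep.chapter == "XV" for ep in cat_f)

    def test_invalid_event_codes_rejected_with_report(self):
        p, expo, ev = _mini_cohort(10)
        ev.loc[0, "icd10"] = "Z99"
        with pytest.raises(DataIntegrityError, match="Z99"):
            curate_endpoint_catalog(ev, p, expo, sex="M")

    def test_idempotent(self, cohort, exposure_table):
        a = curate_endpoint_catalog(cohort.events, cohort.participants,
                                    exposure_table, sex="M")
        b = curate_endpoint_catalog(cohort.events, cohort.participants,
                                    exposure_table, sex="M")
        assert a.ids == b.ids
        assert [e.codes for e in a] == [e.codes for e in b]

    def test_every_code_covered_once(self, cohort, exposure_table):
        cat = curate_endpoint_catalog(cohort.events, cohort.participants,
                                      exposure_table, sex="M")
        seen = {}
        for ep in cat:
            for c in ep.codes:
                # individually retained endpoints and pools are disjoint for
                # codes actually observed
                if c in seen and "less_common" not in ep.endpoint_id:
                    pytest.fail(f"code {c} in two endpoints")
                seen.setdefault(c, ep.endpoint_id)
        men_ids = set(cohort.participants.loc[
            cohort.participants["sex"] == "M", "id"])
        ev = cohort.events[cohort.events["id"].isin(men_ids)]
        from alcophewas.endpoints import chapter_of as ch
        observed = {c for c in ev["icd10"].unique()
                    if ch(c) not in ("XV", "XVI", "XVII")}
        assert observed <= set(seen)


class TestFirstEvents:
    def _participants(self, **kw):
        base = {"id": [0], "age_baseline": [50.0], "death_age": [90.0],
                "censor_age": [62.0]}
        base.update({k: [v] for k, v in kw.items()})
        return pd.DataFrame(base)

    def test_event_before_window_ignored(self):
        ep = EndpointDefinition.from_codes("X", "x", "K74")
        p = self._participants(age_baseline=29.0, censor_age=60.0)
        ev = pd.DataFrame({"id": [0, 0], "icd10": "K74", "age": [30.0, 40.0]})
        out = extract_first_events(ev, ep, p)
        assert out.loc[0, "entry_age"] == 35.0
        assert out.loc[0, "exit_age"] == 40.0
        assert out.loc[0, "event"] == 1

    def test_death_censors(self):
        ep = EndpointDefinition.from_codes("X", "x", "K74")
        p = self._participants(death_age=60.0, censor_age=70.0)
        out = extract_first_events(pd.DataFrame(columns=["id", "icd10", "age"]),
                                   ep, p)
        assert out.loc[0, "exit_age"] == 60.0
        assert out.loc[0, "event"] == 0
        assert out.loc[0, "censor_reason"] == "death"

    def test_first_of_repeated_events(self):
        ep = EndpointDefinition.from_codes("X", "x", "K74")
        p = self._participants(age_baseline=45.0, censor_age=70.0,
                               death_age=95.0)
        ev = pd.DataFrame({"id": [0, 0], "icd10": "K74", "age": [55.0, 50.0]})
        out = extract_first_events(ev, ep, p)
        assert out.loc[0, "exit_age"] == 50.0
        assert out.loc[0, "event"] == 1

    def test_age_85_truncation(self):
        ep = EndpointDefinition.from_codes("X", "x", "K74")
        p = self._participants(age_baseline=79.0, censor_age=91.0,
                               death_age=99.0)
        ev = pd.DataFrame({"id": [0], "icd10": "K74", "age": [87.0]})
        out = extract_first_events(ev, ep, p)
        assert out.loc[0, "exit_age"] == 85.0
        assert out.loc[0, "event"] == 0
        assert out.loc[0, "censor_reason"] == "age-85"

    def test_event_outside_followup_raises(self):
        ep = EndpointDefinition.from_codes("X", "x", "K74")
        p = self._participants(censor_age=60.0)
        ev = pd.DataFrame({"id": [0], "icd10": "K74", "age": [61.0]})
        with pytest.raises(DataIntegrityError):
            extract_first_events(ev, ep, p)


class TestAggregates:
    def test_earliest_across_members(self):
        a = EndpointDefinition.from_codes("A", "a", "K74")
        b = EndpointDefinition.from_codes("B", "b", "I63")
        agg = aggregate_endpoint([a, b], "AGG", "agg")
        p = pd.DataFrame({"id": [0], "age_baseline": [40.0],
                          "death_age": [90.0], "censor_age": [70.0]})
        ev = pd.DataFrame({"id": [0, 0], "icd10": ["K74", "I63"],
                           "age": [50.0, 45.0]})
        out = extract_first_events(ev, agg, p)
        assert out.loc[0, "exit_age"] == 45.0

    def test_singleton_aggregate_identity(self, cohort):
        a = EndpointDefinition.from_codes("A", "a", "I63")
        agg = aggregate_endpoint([a], "AGG", "agg")
        s1 = extract_first_events(cohort.events, a, cohort.participants)
        s2 = extract_first_events(cohort.events, agg, cohort.participants)
        pd.testing.assert_frame_equal(s1, s2)

    def test_counting_inequality(self, cohort):
        a = EndpointDefinition.from_codes("A", "a", "I63")
        b = EndpointDefinition.from_codes("B", "b", "K74")
        agg = aggregate_endpoint([a, b], "AGG", "agg")
        n = sum(extract_first_events(cohort.events, e, cohort.participants)
                ["event"].sum() for e in (a, b))
        n_agg = extract_first_events(cohort.events, agg,
                                     cohort.participants)["event"].sum()
        assert n_agg <= n

    def test_empty_member_list_rejected(self):
        with pytest.raises(ConfigurationError):
            aggregate_endpoint([], "AGG", "agg")
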