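"""Cohort construction rules."""

import numpy as np
import pandas as pd
import pytest

from seekpaths.cohort import (
    CohortConfig,
    build_profiles,
    match_cancer_queries,
    partition_severity,
)
from seekpaths.lexicon import default_lexicon


def lex_with_severity():
    return partition_severity(default_lexicon())


def make_events(rows):
    df = pd.DataFrame(
        rows, columns=["user_id", "day", "query_text", "cancers", "page_id", "category"]
    )
    return df


class TestMatchCancerQueries:
    def test_simple_match_and_boundary_guard(self):
        events = make_events(
            [
                (1, 0, "breast cancer symptoms", "", 10, "symptoms"),
                (2, 1, "cancun hotels cheap", "", 11, "other"),
            ]
        )
        out = match_cancer_queries(events, default_lexicon())
        assert list(out["user_id"]) == [1]
        assert out.iloc[0]["cancers"] == "breast cancer"

    def test_case_insensitive_and_synonyms(self):
        events = make_events(
            [
                (1, 0, "NHL treatment options", "", 1, "treatment"),
                (2, 0, "Leukaemia in children", "", 2, "information"),
            ]
        )
        out = match_cancer_queries(events, default_lexicon())
        assert set(out["cancers"]) == {"non-hodgkin lymphoma", "leukemia"}

    def test_toy_log_retains_expected_rows(self):
        rows = [
            (1, 0, "melanoma pictures", "", 1, "information"),
            (1, 1, "weather tomorrow", "", 2, "other"),
            (2, 0, "best pizza near me", "", 3, "other"),
            (2, 1, "lung cancer prognosis", "", 4, "information"),
            (3, 0, "concerts tonight", "", 5, "other"),
            (3, 1, "football scores", "", 6, "other"),
        ]
        out = match_cancer_queries(make_events(rows), default_lexicon())
        assert len(out) == 2
        assert set(out["cancers"]) == {"melanoma", "lung cancer"}

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            match_cancer_queries(make_events([]), default_lexicon().iloc[:0])


class TestPartitionSeverity:
    def test_median_rule(self):
        lex = pd.DataFrame(
            {
                "cancer": list("abcd"),
                "synonyms": [""] * 4,
                "incidence_per_100k": [1.0] * 4,
                "survival_5yr_pct": [10.0, 20.0, 60.0, 80.0],
                "median_age_dx": [60.0] * 4,
            }
        )
        out = partition_severity(lex)
        assert list(out["severity"]) == ["aggressive", "aggressive", "indolent", "indolent"]

    def test_all_equal_survival_is_all_indolent(self):
        lex = default_lexicon().iloc[:4].copy()
        lex["survival_5yr_pct"] = 50.0
        assert (partition_severity(lex)["severity"] == "indolent").all()

    def test_odd_count_median(self):
        lex = default_lexicon().iloc[:3].copy()
        lex["survival_5yr_pct"] = [10.0, 50.0, 90.0]
        assert list(partition_severity(lex)["severity"]) == [
            "aggressive", "indolent", "indolent",
        ]

    def test_missing_survival_rejected(self):
        lex = default_lexicon().copy()
        lex.loc[0, "survival_5yr_pct"] = np.nan
        with pytest.raises(ValueError):
            partition_severity(lex)


def profile_events(rows):
    return pd.DataFrame(
        rows, columns=["user_id", "day", "query_text", "cancers", "page_id", "category"]
    )


class TestBuildProfiles:
    def test_gates_and_fields(self):
        rows = (
            # user 1: 4 categorised pages -> excluded at page gate
            [(1, d, "q", "breast cancer", d, "symptoms") for d in range(4)]
            # user 2: 6 pages all `information` -> excluded at category gate
            + [(2, d, "q", "breast cancer", d, "information") for d in range(6)]
            # user 3: included; breast x3, lung x2; days 3..12
            + [
                (3, 3, "q", "breast cancer", 1, "symptoms"),
                (3, 5, "q", "lung cancer", 2, "information"),
                (3, 7, "q", "breast cancer", 3, "treatment"),
                (3, 9, "q", "lung cancer", 4, "information"),
                (3, 12, "q", "breast cancer", 5, "support"),
            ]
        )
        profiles, tally = build_profiles(profile_events(rows), lex_with_severity())
        assert tally["n_users_total"] == 3
        assert tally["n_excluded_page_gate"] == 1
        assert tally["n_excluded_category_gate"] == 1
        assert tally["n_included"] == 1
        p = profiles.iloc[0]
        assert p["user_id"] == 3
        assert p["dominant_disease"] == "breast cancer"
        assert p["severity"] == "indolent"
        assert p["first_day"] == 3 and p["last_day"] == 12
        assert p["search_period_days"] == 10
        assert p["n_pages"] == 5 and p["n_categories"] == 4
        assert p["category_sequence"] == [
            "symptoms", "information", "treatment", "information", "support",
        ]
        assert p["n_information"] == 2

    def test_unknown_category_events_dropped_before_counting(self):
        rows = [(1, d, "q", "melanoma", d, "NA") for d in range(9)] + [
            (1, 9, "q", "melanoma", 9, "symptoms"),
            (1, 10, "q", "melanoma", 10, "causes"),
        ]
        profiles, tally = build_profiles(profile_events(rows), lex_with_severity())
        assert tally["n_included"] == 0  # only 2 categorised pages

    def test_dominant_tie_breaks_lexicographic(self):
        rows = [
            (1, 0, "q", "lung cancer", 1, "symptoms"),
            (1, 1, "q", "breast cancer", 2, "causes"),
            (1, 2, "q", "lung cancer", 3, "information"),
            (1, 3, "q", "breast cancer", 4, "treatment"),
            (1, 4, "q", "melanoma", 5, "support"),
        ]
        profiles, _ = build_profiles(profile_events(rows), lex_with_severity())
        assert profiles.iloc[0]["dominant_disease"] == "breast cancer"

    def test_multi_cancer_events_count_toward_each(self):
        rows = [
            (1, 0, "q", "breast cancer,lung cancer", 1, "symptoms"),
            (1, 1, "q", "lung cancer", 2, "causes"),
            (1, 2, "q", "lung cancer", 3, "information"),
            (1, 3, "q", "breast cancer", 4, "treatment"),
            (1, 4, "q", "melanoma", 5, "support"),
        ]
        profiles, _ = build_profiles(profile_events(rows), lex_with_severity())
        assert profiles.iloc[0]["dominant_disease"] == "lung cancer"
        assert profiles.iloc[0]["cancers"] == "breast cancer,lung cancer,melanoma"

    def test_empty_input(self):
        profiles, tally = build_profiles(profile_events([]), lex_with_severity())
        assert len(profiles) == 0 and tally["n_included"] == 0

    def test_gate_order_independence(self, rng):
        # page-gate-then-category-gate membership equals the reverse order
        rows = []
        for u in range(60):
            n = int(rng.integers(1, 10))
            for d in range(n):
                cat = ["symptoms", "information"][int(rng.integers(0, 2))]
                if rng.random() < 0.4:
                    cat = "symptoms"
                rows.append((u, d, "q", "melanoma", d, cat))
        ev = profile_events(rows)
        lex = lex_with_severity()
        joint, _ = build_profiles(ev, lex, CohortConfig(5, 2))
        page_first, _ = build_profiles(ev, lex, CohortConfig(5, 1))
        page_then_cat = set(
            page_first.loc[page_first["n_categories"] >= 2, "user_id"]
        )
        cat_first, _ = build_profiles(ev, lex, CohortConfig(1, 2))
        cat_then_page = set(cat_first.loc[cat_first["n_pages"] >= 5, "user_id"])
        assert set(joint["user_id"]) == page_then_cat == cat_then_page

    def test_dominant_assignment_invariant_within_day(self):
        rows = [
            (1, 0, "q", "breast cancer", 1, "symptoms"),
            (1, 0, "q", "lung cancer", 2, "causes"),
            (1, 0, "q", "breast cancer", 3, "information"),
            (1, 1, "q", "breast cancer", 4, "treatment"),
            (1, 1, "q", "lung cancer", 5, "support"),
        ]
        base, _ = build_profiles(profile_events(rows), lex_with_severity())
        flipped = rows[:3][::-1] + rows[3:]
        alt, _ = build_profiles(profile_events(flipped), lex_with_severity())
        assert base.iloc[0]["dominant_disease"] == alt.iloc[0]["dominant_disease"]
        assert base.iloc[0]["n_pages"] == alt.iloc[0]["n_pages"]


def test_cohort_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(min_pages=0)
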