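"""Co-search pair detection and pair statistics."""

import numpy as np
import pandas as pd
import pytest

from seekpaths.categories import CATEGORIES
from seekpaths.social import (
    category_preference_contrast,
    enrichment_vs_chance,
    find_pairs,
    lag_duration_contrasts,
    overlap_stats,
)


def make_profiles(rows):
    """rows: (user_id, disease, severity, n_pages, first, last, cancers)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "user_id", "dominant_disease", "severity", "n_pages",
            "first_day", "last_day", "cancers",
        ],
    )
    df["n_categories"] = 2
    df["search_period_days"] = df["last_day"] - df["first_day"] + 1
    df["category_sequence"] = [[] for _ in range(len(df))]
    for c in CATEGORIES:
        df[f"n_{c}"] = 1
    return df


FIXTURE = make_profiles(
    [
        (1, "breast cancer", "indolent", 8, 3, 10, "breast cancer"),
        (2, "breast cancer", "indolent", 6, 12, 20, "breast cancer,lung cancer"),
        (3, "lung cancer", "aggressive", 10, 5, 9, "lung cancer"),
        (4, "melanoma", "indolent", 7, 5, 30, "melanoma"),
        (5, "pancreatic cancer", "aggressive", 9, 0, 40, "pancreatic cancer"),
    ]
)

EDGES = np.array(
    [
        (1, 2),   # qualifying: lag 9, overlap via breast
        (3, 4),   # qualifying: tie on day 5 -> 3 first (10 > 7 pages)
        (5, 1),   # qualifying: 5 first (day 0)
        (2, 99),  # endpoint not in cohort
        (98, 97), # neither endpoint
    ]
)


class TestFindPairs:
    def test_fixture_hand_checked(self):
        pairs = find_pairs(FIXTURE, EDGES)
        assert len(pairs) == 3
        p12 = pairs[pairs["second_searcher"] == 2].iloc[0]
        assert p12["first_searcher"] == 1
        assert p12["lag_days"] == 9
        assert p12["first_duration_days"] == 8
        assert p12["second_duration_days"] == 9
        assert p12["severity"] == "indolent"
        assert bool(p12["overlap"])
        assert p12["second_n_diseases"] == 2

        p34 = pairs[pairs["second_searcher"] == 4].iloc[0]
        assert p34["first_searcher"] == 3  # same day, more pages
        assert p34["lag_days"] == 0
        assert p34["severity"] == "aggressive"
        assert not bool(p34["overlap"])

    def test_non_cohort_endpoint_yields_no_pair(self):
        pairs = find_pairs(FIXTURE, np.array([(2, 99)]))
        assert len(pairs) == 0

    def test_orientation_and_order_invariance(self):
        flipped = EDGES[:, ::-1]
        shuffled = EDGES[::-1]
        base = find_pairs(FIXTURE, EDGES).sort_values("first_searcher").reset_index(drop=True)
        for variant in (flipped, shuffled):
            alt = (
                find_pairs(FIXTURE, variant)
                .sort_values("first_searcher")
                .reset_index(drop=True)
            )
            pd.testing.assert_frame_equal(base, alt)


class TestEnrichment:
    def test_no_edges_rejected(self):
        with pytest.raises(ValueError):
            enrichment_vs_chance(0, FIXTURE, np.zeros((0, 2)), 100, 0)

    def test_null_assignment_gives_fold_near_one(self, rng):
        # labels drawn by the null itself: observed count is one more draw
        # from the permutation distribution
        n_nodes, m = 2_000, 200
        a = rng.integers(0, n_nodes, 6_000)
        b = rng.integers(0, n_nodes, 6_000)
        keep = a != b
        edges = np.column_stack([a[keep], b[keep]])
        included = rng.choice(n_nodes, m, replace=False)
        profiles = pd.DataFrame({"user_id": included})
        incl = np.zeros(n_nodes, bool)
        incl[included] = True
        observed = int((incl[edges[:, 0]] & incl[edges[:, 1]]).sum())
        res = enrichment_vs_chance(
            observed, profiles, edges, n_permutations=1_000, seed=5,
            population=np.arange(n_nodes),
        )
        assert res["fold_enrichment"] == pytest.approx(1.0, abs=0.35)
        assert res["p_value"] > 0.01

    def test_planted_enrichment_recovered(self, default_sim, default_pairs):
        res = enrichment_vs_chance(
            len(default_pairs),
            default_sim["profiles"],
            default_sim["contacts"].to_numpy(),
            n_permutations=300,
            seed=3,
        )
        assert res["fold_enrichment"] == pytest.approx(6.0, rel=0.2)
        assert res["p_value"] < 0.01


class TestOverlapStats:
    def test_all_pairs_share(self):
        pairs = find_pairs(FIXTURE, np.array([(1, 2)]))
        res = overlap_stats(pairs, FIXTURE, seed=0)
        assert res["observed_overlap"] == 1.0

    def test_unique_diseases_zero_baseline(self):
        profiles = make_profiles(
            [
                (i, f"d{i}", "indolent", 6, i, i + 5, f"d{i}")
                for i in range(1, 6)
            ]
        )
        pairs = find_pairs(profiles, np.array([(1, 2)]))
        res = overlap_stats(pairs, profiles, seed=0, n_draws=2_000)
        assert res["random_match_baseline"] == 0.0
        assert res["observed_overlap"] == 0.0

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            overlap_stats(find_pairs(FIXTURE, np.zeros((0, 2), int)), FIXTURE)


class TestLagDurationContrasts:
    def test_equal_lags_rank_sum_flat(self):
        rows = []
        for i in range(1, 21):
            sev = "aggressive" if i % 2 else "indolent"
            rows.append((i, "x", sev, 6, 0, 4, "x"))
            rows.append((100 + i, "x", sev, 6, 7, 11, "x"))
        profiles = make_profiles(rows)
        edges = np.array([(i, 100 + i) for i in range(1, 21)])
        pairs = find_pairs(profiles, edges)
        res = lag_duration_contrasts(pairs)
        assert res["lag_rank_sum"]["p_value"] == pytest.approx(1.0)
        # durations identical within every pair -> sign test p = 1
        for sev in ("aggressive", "indolent"):
            assert res["strata"][sev]["duration_sign_test"]["p_value"] == 1.0

    def test_small_stratum_flagged(self):
        profiles = make_profiles(
            [
                (1, "x", "aggressive", 6, 0, 4, "x"),
                (2, "x", "aggressive", 6, 6, 9, "x"),
            ]
        )
        pairs = find_pairs(profiles, np.array([(1, 2)]))
        res = lag_duration_contrasts(pairs)
        assert res["lag_rank_sum"].get("skipped")
        assert res["strata"]["indolent"]["duration_sign_test"].get("skipped")

    def test_planted_indolent_duration_contrast(self, default_pairs):
        ind = default_pairs[default_pairs["severity"] == "indolent"]
        assert len(ind) >= 100
        res = lag_duration_contrasts(default_pairs)
        stratum = res["strata"]["indolent"]
        assert stratum["second_duration_mean"] < stratum["first_duration_mean"]
        assert stratum["duration_sign_test"]["p_value"] < 0.05

    def test_planted_lag_ordering(self, default_pairs):
        res = lag_duration_contrasts(default_pairs)
        assert (
            res["strata"]["indolent"]["lag_mean"]
            > res["strata"]["aggressive"]["lag_mean"]
        )

    def test_planted_disease_breadth_contrast(self, default_pairs):
        res = lag_duration_contrasts(default_pairs)
        assert res["diseases_signed_rank"]["first_over_second_ratio"] > 1.1


class TestCategoryPreference:
    def test_identical_profiles_unit_ratios(self):
        pairs = find_pairs(FIXTURE, np.array([(1, 2), (5, 1)]))
        res = category_preference_contrast(pairs)
        for c in CATEGORIES:
            assert res[c]["first_over_second_ratio"] == pytest.approx(1.0)

    def test_constructed_two_fold_treatment(self):
        profiles = make_profiles(
            [
                (1, "x", "indolent", 10, 0, 4, "x"),
                (2, "x", "indolent", 10, 6, 9, "x"),
            ]
        )
        # first searcher views treatment twice as often (same total views)
        profiles.loc[profiles["user_id"] == 1, "n_treatment"] = 2
        profiles.loc[profiles["user_id"] == 1, "n_other"] = 0
        pairs = find_pairs(profiles, np.array([(1, 2)]))
        res = category_preference_contrast(pairs)
        assert res["treatment"]["first_over_second_ratio"] == pytest.approx(2.0)

    def test_zero_view_category_flagged(self):
        profiles = make_profiles(
            [
                (1, "x", "indolent", 10, 0, 4, "x"),
                (2, "x", "indolent", 10, 6, 9, "x"),
            ]
        )
        for u in (1, 2):
            profiles.loc[profiles["user_id"] == u, "n_pets"] = 0
        pairs = find_pairs(profiles, np.array([(1, 2)]))
        assert not category_preference_contrast(pairs)["pets"]["defined"]

    def test_planted_role_preferences(self, default_pairs):
        res = category_preference_contrast(default_pairs)
        # probands lean toward treatment pages, acquaintances toward causes
        assert res["treatment"]["first_over_second_ratio"] > 1.0
        assert res["causes"]["first_over_second_ratio"] < 1.0
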