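"""Cohort construction from a raw query log.

Implements the study-selection rules: keep only queries naming one of
the lexicon's cancers (word-boundary, case-insensitive), split cancers
into aggressive/indolent by the median 5-year survival across the
lexicon, and retain users who visited at least ``min_pages`` categorised
pages spanning at least ``min_categories`` distinct categories. Each
retained user gets a profile carrying their dominant disease (the cancer
they queried most often), severity stratum, ordered category sequence,
and inclusive search-period day span.

Events with unknown category are dropped before any counting: the
analysis operates on the categorised popular-page universe, and an open
observation alphabet would break the journey models downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import CATEGORIES, UNKNOWN_CATEGORY
from .lexicon import lexicon_terms


@dataclass(frozen=True)
class CohortConfig:
    """Inclusion gates: page-count and category-breadth thresholds."""

    min_pages: int = 5
    min_categories: int = 2

    def __post_init__(self) -> None:
        if self.min_pages < 1 or self.min_categories < 1:
            raise ValueError("cohort thresholds must be >= 1")


def partition_severity(lexicon: pd.DataFrame) -> pd.DataFrame:
    """Label each cancer aggressive or indolent by the median 5-year survival.

    Entries with survival strictly below the median over all entries are
    aggressive; the rest (including exact ties with the median) indolent.
    """
    if len(lexicon) < 2:
        raise ValueError("severity partition needs at least 2 lexicon entries")
    surv = lexicon["survival_5yr_pct"]
    if surv.isna().any():
        raise ValueError("missing 5-year survival values in lexicon")
    med = float(surv.median())
    out = lexicon.copy()
    out["severity"] = np.where(surv < med, "aggressive", "indolent")
    return out


def _compile_patterns(lexicon: pd.DataFrame) -> dict[str, re.Pattern]:
    pats = {}
    for cancer, terms in lexicon_terms(lexicon).items():
        alts = "|".join(re.escape(t) for t in sorted(terms, key=len, reverse=True))
        pats[cancer] = re.compile(rf"\b(?:{alts})\b", re.IGNORECASE)
    return pats


def match_cancer_queries(events: pd.DataFrame, lexicon: pd.DataFrame) -> pd.DataFrame:
    """Retain events whose query text names a lexicon cancer; annotate matches.

    Matching is case-insensitive on word boundaries (so "cancun hotels"
    never matches a "cancer" term). The returned copy carries a
    ``cancers`` column with the comma-joined sorted matched names; events
    matching nothing are dropped.
    """
    if len(lexicon) == 0:
        raise ValueError("empty lexicon")
    pats = _compile_patterns(lexicon)
    texts = events["query_text"].astype(str)
    names = list(pats)
    mat = np.zeros((len(names), len(events)), dtype=bool)
    for i, name in enumerate(names):
        mat[i] = texts.str.contains(pats[name], regex=True).to_numpy()
    any_match = mat.any(axis=0)
    out = events.loc[any_match].copy()
    sub = mat[:, any_match]
    names_arr = np.asarray(names, dtype=object)
    out["cancers"] = [",".join(sorted(names_arr[sub[:, j]])) for j in range(sub.shape[1])]
    return out


def build_profiles(
    events: pd.DataFrame,
    lexicon: pd.DataFrame,
    config: CohortConfig = CohortConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Derive per-user profiles and apply the inclusion gates.

    ``events`` must carry ``cancers`` annotations (from
    :func:`match_cancer_queries` or a pre-annotated synthetic log) and a
    ``category`` column. Returns ``(profiles, tally)`` where the tally
    reports the users removed at the page gate and, among its survivors,
    at the category gate. Category sequences are ordered by day with the
    input order breaking ties (stable sort).
    """
    lex = lexicon if "severity" in lexicon.columns else partition_severity(lexicon)
    sev_of = dict(zip(lex["cancer"], lex["severity"]))

    ev = events
    known = ev["category"].isin(CATEGORIES) & (ev["category"] != UNKNOWN_CATEGORY)
    has_cancer = ev["cancers"].astype(str).str.len() > 0
    ev = ev.loc[known & has_cancer]
    n_total = int(events["user_id"].nunique())
    if len(ev) == 0:
        profiles = _empty_profiles()
        return profiles, {
            "n_users_total": n_total,
            "n_excluded_page_gate": n_total,
            "n_excluded_category_gate": 0,
            "n_included": 0,
        }

    ev = ev.sort_values("day", kind="stable")  # stable: input order breaks ties
    grp = ev.groupby("user_id", sort=True)
    n_pages = grp.size()
    n_cats = grp["category"].nunique()

    page_pass = n_pages >= config.min_pages
    cat_pass = n_cats >= config.min_categories
    included_ids = n_pages.index[page_pass & cat_pass]

    n_seen = int(n_pages.size)
    tally = {
        "n_users_total": n_total,
        "n_excluded_page_gate": int(n_total - int(page_pass.sum())),
        "n_excluded_category_gate": int((page_pass & ~cat_pass).sum()),
        "n_included": int(len(included_ids)),
        "n_users_with_categorized_events": n_seen,
    }
    if len(included_ids) == 0:
        return _empty_profiles(), tally

    sub = ev[ev["user_id"].isin(included_ids)]
    g = sub.groupby("user_id", sort=True)
    first_day = g["day"].first()
    last_day = g["day"].last()
    seqs = g["category"].agg(list)

    # dominant disease: per-user cancer frequency, ties broken by name
    pairs = sub[["user_id", "cancers"]].copy()
    pairs["cancers"] = pairs["cancers"].str.split(",")
    pairs = pairs.explode("cancers")
    freq = (
        pairs.groupby(["user_id", "cancers"], sort=True)
        .size()
        .reset_index(name="n")
        .sort_values(["user_id", "n", "cancers"], ascending=[True, False, True], kind="stable")
    )
    dominant = freq.drop_duplicates("user_id").set_index("user_id")["cancers"]
    cancer_sets = pairs.groupby("user_id")["cancers"].agg(
        lambda s: ",".join(sorted(set(s)))
    )

    counts = (
        pd.crosstab(sub["user_id"], sub["category"])
        .reindex(columns=list(CATEGORIES), fill_value=0)
        .astype(np.int64)
    )
    counts.columns = [f"n_{c}" for c in counts.columns]

    profiles = pd.DataFrame(
        {
            "user_id": included_ids,
            "dominant_disease": dominant.loc[included_ids].to_numpy(),
            "n_pages": n_pages.loc[included_ids].to_numpy(),
            "n_categories": n_cats.loc[included_ids].to_numpy(),
            "first_day": first_day.loc[included_ids].to_numpy(),
            "last_day": last_day.loc[included_ids].to_numpy(),
            "cancers": cancer_sets.loc[included_ids].to_numpy(),
            "category_sequence": seqs.loc[included_ids].to_numpy(),
        }
    )
    profiles["severity"] = profiles["dominant_disease"].map(sev_of)
    profiles["search_period_days"] = profiles["last_day"] - profiles["first_day"] + 1
    profiles = profiles.join(counts.loc[included_ids].reset_index(drop=True))
    return profiles.reset_index(drop=True), tally


def _empty_profiles() -> pd.DataFrame:
    cols = {
        "user_id": np.int64,
        "dominant_disease": object,
        "n_pages": np.int64,
        "n_categories": np.int64,
        "first_day": np.int64,
        "last_day": np.int64,
        "cancers": object,
        "category_sequence": object,
        "severity": object,
        "search_period_days": np.int64,
    }
    df = pd.DataFrame({k: pd.Series([], dtype=v) for k, v in cols.items()})
    for c in CATEGORIES:
        df[f"n_{c}"] = pd.Series([], dtype=np.int64)
    return df
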