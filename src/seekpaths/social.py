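"""Co-searching acquaintance pairs on the contact graph.

A *co-search pair* is a contact-graph edge whose two endpoints both
passed the cohort gates. The earlier first-search day designates the
*proband* (first searcher); the acquaintance follows after a lag. The
module measures how strongly co-searching concentrates on the social
graph (fold enrichment over a label-permutation null), whether
acquaintances search the same disease (overlap vs random matching), and
how lags, search durations, breadth of diseases and category preferences
differ between roles and severity strata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .categories import CATEGORIES
from .stats import rank_sum, sign_test, signed_rank

PAIR_COLUMNS = [
    "first_searcher",
    "second_searcher",
    "lag_days",
    "first_duration_days",
    "second_duration_days",
    "severity",
    "overlap",
    "first_n_diseases",
    "second_n_diseases",
]


def find_pairs(profiles: pd.DataFrame, edges) -> pd.DataFrame:
    """One co-search pair per contact edge with both endpoints in the cohort.

    The first searcher is the endpoint with the earlier ``first_day``
    (ties: more total pages, then smaller user id). ``lag_days`` is the
    difference of first-search days; ``severity`` is the first searcher's
    stratum; ``overlap`` flags any shared queried cancer. Per-category
    page-view counts for both roles are carried as ``first_n_<cat>`` /
    ``second_n_<cat>`` columns.
    """
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    prof = profiles.set_index("user_id")
    member = pd.Index(prof.index)
    amask = member.get_indexer(edges[:, 0]) >= 0
    bmask = member.get_indexer(edges[:, 1]) >= 0
    qedges = edges[amask & bmask]
    if qedges.size == 0:
        return _empty_pairs()
    # deduplicate regardless of orientation
    lo = np.minimum(qedges[:, 0], qedges[:, 1])
    hi = np.maximum(qedges[:, 0], qedges[:, 1])
    qedges = np.unique(np.column_stack([lo, hi]), axis=0)

    a = prof.loc[qedges[:, 0]]
    b = prof.loc[qedges[:, 1]]
    a_first = (
        (a["first_day"].to_numpy() < b["first_day"].to_numpy())
        | (
            (a["first_day"].to_numpy() == b["first_day"].to_numpy())
            & (a["n_pages"].to_numpy() > b["n_pages"].to_numpy())
        )
        | (
            (a["first_day"].to_numpy() == b["first_day"].to_numpy())
            & (a["n_pages"].to_numpy() == b["n_pages"].to_numpy())
            & (qedges[:, 0] < qedges[:, 1])
        )
    )
    first_id = np.where(a_first, qedges[:, 0], qedges[:, 1])
    second_id = np.where(a_first, qedges[:, 1], qedges[:, 0])
    first = prof.loc[first_id]
    second = prof.loc[second_id]

    f_sets = first["cancers"].str.split(",").apply(set).to_numpy()
    s_sets = second["cancers"].str.split(",").apply(set).to_numpy()
    overlap = np.array([bool(x & y) for x, y in zip(f_sets, s_sets)])

    pairs = pd.DataFrame(
        {
            "first_searcher": first_id,
            "second_searcher": second_id,
            "lag_days": second["first_day"].to_numpy() - first["first_day"].to_numpy(),
            "first_duration_days": first["search_period_days"].to_numpy(),
            "second_duration_days": second["search_period_days"].to_numpy(),
            "severity": first["severity"].to_numpy(),
            "overlap": overlap,
            "first_n_diseases": [len(s) for s in f_sets],
            "second_n_diseases": [len(s) for s in s_sets],
        }
    )
    for c in CATEGORIES:
        pairs[f"first_n_{c}"] = first[f"n_{c}"].to_numpy()
        pairs[f"second_n_{c}"] = second[f"n_{c}"].to_numpy()
    return pairs


def _empty_pairs() -> pd.DataFrame:
    df = pd.DataFrame(columns=PAIR_COLUMNS)
    for c in CATEGORIES:
        df[f"first_n_{c}"] = pd.Series([], dtype=np.int64)
        df[f"second_n_{c}"] = pd.Series([], dtype=np.int64)
    return df


def enrichment_vs_chance(
    observed_pairs: int,
    profiles: pd.DataFrame,
    edges,
    n_permutations: int = 1000,
    seed: int = 0,
    population: np.ndarray | None = None,
) -> dict:
    """Fold enrichment of co-search pairs over a label-permutation null.

    The null keeps the graph fixed and reassigns the "included searcher"
    labels uniformly at random over the node population (preserving the
    number of included users); the chance expectation is the mean
    qualifying-edge count over permutations, and the one-sided p-value is
    the fraction of permutations reaching the observed count.
    """
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if edges.shape[0] == 0:
        raise ValueError("no contact edges: enrichment undefined")
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    if population is None:
        population = np.unique(edges)
    population = np.asarray(population)
    n_pop = population.size
    node_index = {u: i for i, u in enumerate(population.tolist())}
    included = profiles["user_id"].to_numpy()
    m = int(pd.Index(included).isin(population).sum())
    ea = np.array([node_index.get(u, -1) for u in edges[:, 0].tolist()], dtype=np.int64)
    eb = np.array([node_index.get(u, -1) for u in edges[:, 1].tolist()], dtype=np.int64)
    valid = (ea >= 0) & (eb >= 0)
    ea, eb = ea[valid], eb[valid]

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_permutations, dtype=np.int64)
    incl = np.zeros(n_pop, dtype=bool)
    for i in range(n_permutations):
        incl[:] = False
        incl[rng.permutation(n_pop)[:m]] = True
        null_counts[i] = np.count_nonzero(incl[ea] & incl[eb])
    expected = float(null_counts.mean())
    p = float((1 + np.count_nonzero(null_counts >= observed_pairs)) / (n_permutations + 1))
    if expected == 0:
        return {
            "observed": int(observed_pairs),
            "expected_by_chance": 0.0,
            "fold_enrichment": float("nan"),
            "fold_defined": False,
            "p_value": p,
            "n_permutations": n_permutations,
        }
    return {
        "observed": int(observed_pairs),
        "expected_by_chance": expected,
        "fold_enrichment": float(observed_pairs / expected),
        "fold_defined": True,
        "p_value": p,
        "n_permutations": n_permutations,
    }


def overlap_stats(
    pairs: pd.DataFrame,
    profiles: pd.DataFrame,
    seed: int = 0,
    n_draws: int = 10_000,
) -> dict:
    """Observed disease overlap in pairs vs uniformly random user matching."""
    if len(pairs) == 0:
        raise ValueError("no pairs")
    observed = float(pairs["overlap"].mean())
    sets = profiles["cancers"].str.split(",").apply(set).to_numpy()
    n = len(sets)
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, n_draws)
    j = rng.integers(0, n - 1, n_draws)
    j = np.where(j >= i, j + 1, j)  # distinct partners
    baseline = float(np.mean([bool(sets[x] & sets[y]) for x, y in zip(i, j)]))
    return {
        "observed_overlap": observed,
        "random_match_baseline": baseline,
        "n_pairs": int(len(pairs)),
        "n_random_draws": n_draws,
    }


def lag_duration_contrasts(pairs: pd.DataFrame) -> dict:
    """Per-severity lag and duration summaries with nonparametric tests.

    Reports mean±SD of the onset lag and of both searchers' durations per
    severity stratum; a rank-sum test comparing lags between strata; a
    per-stratum paired sign test of first- vs second-searcher durations;
    and a signed-rank test of the number of distinct diseases searched by
    the two roles. Strata with fewer than 2 pairs have their tests
    flagged as skipped.
    """
    out: dict = {"strata": {}}
    for sev in ("aggressive", "indolent"):
        sub = pairs[pairs["severity"] == sev]
        stratum = {"n_pairs": int(len(sub))}
        if len(sub):
            stratum.update(
                lag_mean=float(sub["lag_days"].mean()),
                lag_sd=float(sub["lag_days"].std(ddof=1)) if len(sub) > 1 else 0.0,
                first_duration_mean=float(sub["first_duration_days"].mean()),
                first_duration_sd=float(sub["first_duration_days"].std(ddof=1)) if len(sub) > 1 else 0.0,
                second_duration_mean=float(sub["second_duration_days"].mean()),
                second_duration_sd=float(sub["second_duration_days"].std(ddof=1)) if len(sub) > 1 else 0.0,
            )
        if len(sub) >= 2:
            stat, p, nn = sign_test(sub["first_duration_days"], sub["second_duration_days"])
            stratum["duration_sign_test"] = {"statistic": stat, "p_value": p, "n": nn}
        else:
            stratum["duration_sign_test"] = {"skipped": True}
        out["strata"][sev] = stratum

    agg = pairs[pairs["severity"] == "aggressive"]["lag_days"]
    ind = pairs[pairs["severity"] == "indolent"]["lag_days"]
    if len(agg) >= 2 and len(ind) >= 2:
        stat, p, nn = rank_sum(ind, agg)
        out["lag_rank_sum"] = {"statistic": stat, "p_value": p, "n": nn}
    else:
        out["lag_rank_sum"] = {"skipped": True}

    if len(pairs) >= 2:
        stat, p, nn = signed_rank(pairs["first_n_diseases"], pairs["second_n_diseases"])
        ratio = float(pairs["first_n_diseases"].mean() / pairs["second_n_diseases"].mean())
        out["diseases_signed_rank"] = {
            "statistic": stat,
            "p_value": p,
            "n": nn,
            "first_over_second_ratio": ratio,
        }
    else:
        out["diseases_signed_rank"] = {"skipped": True}
    return out


def category_preference_contrast(pairs: pd.DataFrame) -> dict:
    """First- vs second-searcher category preferences.

    For each category, each searcher's preference is their fraction of
    page views in that category; the contrast is the ratio of the mean
    first-searcher preference to the mean second-searcher preference,
    also expressed as a percentage difference, with a two-sided rank-sum
    p-value across pairs. Categories viewed by neither role are flagged
    undefined.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs")
    f_tot = sum(pairs[f"first_n_{c}"] for c in CATEGORIES).to_numpy(dtype=float)
    s_tot = sum(pairs[f"second_n_{c}"] for c in CATEGORIES).to_numpy(dtype=float)
    out = {}
    for c in CATEGORIES:
        f = pairs[f"first_n_{c}"].to_numpy(dtype=float) / np.maximum(f_tot, 1)
        s = pairs[f"second_n_{c}"].to_numpy(dtype=float) / np.maximum(s_tot, 1)
        if f.sum() == 0 and s.sum() == 0:
            out[c] = {"defined": False}
            continue
        mf, ms = float(f.mean()), float(s.mean())
        ratio = mf / ms if ms > 0 else float("inf")
        stat, p, nn = rank_sum(f, s)
        out[c] = {
            "defined": True,
            "first_mean_share": mf,
            "second_mean_share": ms,
            "first_over_second_ratio": float(ratio),
            "pct_difference": float((ratio - 1.0) * 100.0) if np.isfinite(ratio) else float("inf"),
            "rank_sum_p": p,
        }
    return out
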