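"""Crowd-label aggregation and vector-space ambiguity analysis.

Each page is labeled by five independent crowd workers into one of the
ten canonical categories. A page is *decided* when at least three votes
agree; otherwise it is *ambiguous* and the vote pattern (2+2+1,
2+1+1+1, or five singletons) is recorded.

To probe whether ambiguous pages are genuinely mixed-content rather than
badly labeled, pages are embedded in a term-frequency vector space
(lowercased, English stop words removed) and compared with the centroid
of every decided category. For each page, the *relative spread* of its
cosine distances to the categories its labelers voted for —
``(max − min) / mean`` — measures how sharply the text discriminates
between the candidate labels; decided pages should show a markedly
larger spread than ambiguous ones (rank-sum test).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.metrics.pairwise import cosine_distances

from .categories import CATEGORIES

BALLOT_SIZE = 5
MAJORITY = 3


@dataclass(frozen=True)
class AggregatedLabel:
    """Outcome of aggregating one 5-vote ballot."""

    page_id: object
    decided: str | None  # category token, or None when ambiguous
    pattern: str  # sorted vote-count pattern, e.g. "3+2" or "2+2+1"

    @property
    def is_ambiguous(self) -> bool:
        return self.decided is None


def aggregate_labels(page_id, votes) -> AggregatedLabel:
    """Majority aggregation of one ballot of exactly five votes.

    Returns the category with >= 3 votes when one exists; otherwise an
    ambiguous result carrying the vote pattern. Invariant to vote order.
    """
    votes = list(votes)
    if len(votes) != BALLOT_SIZE:
        raise ValueError(f"a ballot must have exactly {BALLOT_SIZE} votes, got {len(votes)}")
    unknown = set(votes) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown category tokens in ballot: {sorted(unknown)}")
    counts = Counter(votes)
    top, top_n = counts.most_common(1)[0]
    pattern = "+".join(str(c) for c in sorted(counts.values(), reverse=True))
    if top_n >= MAJORITY:
        return AggregatedLabel(page_id, top, pattern)
    return AggregatedLabel(page_id, None, pattern)


def aggregate_ballot_table(ballots: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a wide ballot table (``page_id, v1..v5``)."""
    vote_cols = [c for c in ballots.columns if c != "page_id"]
    rows = []
    for r in ballots.itertuples(index=False):
        res = aggregate_labels(r.page_id, [getattr(r, c) for c in vote_cols])
        rows.append((res.page_id, res.decided, res.pattern, res.is_ambiguous))
    return pd.DataFrame(rows, columns=["page_id", "decided", "pattern", "ambiguous"])


def term_vectors(texts: dict | pd.Series) -> pd.DataFrame:
    """Term-frequency vectors for page texts (lowercase, stop words removed)."""
    if isinstance(texts, dict):
        texts = pd.Series(texts)
    vec = CountVectorizer(lowercase=True, stop_words="english")
    mat = vec.fit_transform(texts.astype(str).tolist())
    return pd.DataFrame(
        mat.toarray(), index=texts.index, columns=vec.get_feature_names_out()
    )


def centroid_distances(
    vectors: pd.DataFrame, decided: dict | pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Cosine distance from every page to every decided-category centroid.

    ``decided`` maps page id -> decided category for majority-labeled
    pages. The centroid of a category is the arithmetic mean of its
    decided pages' term vectors. Returns ``(distances, skipped)`` where
    ``distances`` is pages × categories and ``skipped`` lists categories
    with no decided page (their centroid is undefined).
    """
    if isinstance(decided, dict):
        decided = pd.Series(decided)
    decided = decided.dropna()
    cats_present = [c for c in CATEGORIES if (decided == c).any()]
    skipped = [c for c in CATEGORIES if c not in cats_present]
    if not cats_present:
        raise ValueError("no decided pages: every centroid is undefined")
    centroids = np.vstack(
        [vectors.loc[decided.index[decided == c]].mean(axis=0).to_numpy() for c in cats_present]
    )
    dist = cosine_distances(vectors.to_numpy(), centroids)
    return pd.DataFrame(dist, index=vectors.index, columns=cats_present), skipped


def relative_gap(distances: np.ndarray) -> float:
    """Relative spread ``(max − min) / mean`` of a page's candidate distances."""
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        return float("nan")
    m = d.mean()
    if m == 0:
        return 0.0
    return float((d.max() - d.min()) / m)


def ambiguity_contrast(
    distances: pd.DataFrame,
    voted_categories: dict,
    decided_pages,
    ambiguous_pages,
) -> dict:
    """Contrast the distance spread of decided vs ambiguous pages.

    ``voted_categories`` maps page id -> the set of categories that
    received at least one vote for that page (restricted automatically to
    categories with defined centroids). Reports the mean relative gap in
    both groups, their ratio, and the two-sided rank-sum p-value; groups
    smaller than 2 yield an undefined, flagged p-value.
    """
    decided_pages = [p for p in decided_pages if p in distances.index]
    ambiguous_pages = [p for p in ambiguous_pages if p in distances.index]
    if not decided_pages or not ambiguous_pages:
        raise ValueError("both page groups must be non-empty")

    def gaps(pages):
        out = []
        for p in pages:
            cats = [c for c in voted_categories[p] if c in distances.columns]
            if len(cats) < 2:
                continue
            out.append(relative_gap(distances.loc[p, cats].to_numpy()))
        return np.asarray(out, dtype=float)

    g_dec, g_amb = gaps(decided_pages), gaps(ambiguous_pages)
    flagged = len(g_dec) < 2 or len(g_amb) < 2
    if flagged:
        p = float("nan")
    else:
        p = float(sps.ranksums(g_dec, g_amb).pvalue)
    return {
        "mean_gap_decided": float(g_dec.mean()) if len(g_dec) else float("nan"),
        "mean_gap_ambiguous": float(g_amb.mean()) if len(g_amb) else float("nan"),
        "n_decided": int(len(g_dec)),
        "n_ambiguous": int(len(g_amb)),
        "rank_sum_p": p,
        "p_undefined": flagged,
    }
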