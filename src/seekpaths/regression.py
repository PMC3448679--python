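"""Query-share vs epidemiology regression.

If intensive cancer searchers are mostly real patients and their close
contacts, the share of the query log devoted to each cancer should track
that cancer's population burden. This module regresses each disease's
query share (percent of the cohort, by dominant disease or by query) on
its age-adjusted incidence, 5-year relative survival and median age at
diagnosis, jointly, by OLS — incidence is expected to dominate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

COVARIATES = ["incidence_per_100k", "survival_5yr_pct", "median_age_dx"]

#: condition numbers above this flag a near-collinear design
CONDITION_LIMIT = 1e8


def disease_frequency_records(
    profiles: pd.DataFrame, lexicon: pd.DataFrame, per: str = "user"
) -> pd.DataFrame:
    """Per-cancer query shares joined with lexicon epidemiology.

    ``per='user'`` (default) counts each included user once under their
    dominant disease; ``per='query'`` weights by the user's page count
    instead. Shares are percentages summing to 100 over the lexicon.
    """
    if per not in ("user", "query"):
        raise ValueError("per must be 'user' or 'query'")
    if per == "user":
        counts = profiles.groupby("dominant_disease").size()
    else:
        counts = profiles.groupby("dominant_disease")["n_pages"].sum()
    share = counts.reindex(lexicon["cancer"], fill_value=0).astype(float)
    total = share.sum()
    if total > 0:
        share = 100.0 * share / total
    rec = lexicon[["cancer", *COVARIATES]].copy()
    rec["query_share"] = share.to_numpy()
    return rec


def incidence_regression(records: pd.DataFrame) -> dict:
    """OLS of query share on incidence, survival and median age at diagnosis.

    Returns R², per-covariate coefficients with two-sided p-values, and a
    collinearity flag based on the design's condition number. Requires at
    least 5 records and non-constant covariates.
    """
    if len(records) < 5:
        raise ValueError("need at least 5 disease records")
    X = records[COVARIATES].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate in regression design")
    y = records["query_share"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        # constant response: nothing to explain
        return {
            "r2": 0.0,
            "n": int(len(records)),
            "coefficients": {c: 0.0 for c in COVARIATES},
            "p_values": {c: 1.0 for c in COVARIATES},
            "intercept": float(y[0]),
            "condition_number": float("nan"),
            "collinearity_flagged": False,
        }
    design = sm.add_constant(pd.DataFrame(X, columns=COVARIATES))
    fit = sm.OLS(y, design).fit()
    flagged = bool(fit.condition_number > CONDITION_LIMIT)
    return {
        "r2": float(fit.rsquared),
        "n": int(len(records)),
        "coefficients": {c: float(fit.params[c]) for c in COVARIATES},
        "p_values": {c: float(fit.pvalues[c]) for c in COVARIATES},
        "intercept": float(fit.params["const"]),
        "condition_number": float(fit.condition_number),
        "collinearity_flagged": flagged,
    }
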