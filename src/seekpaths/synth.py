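"""Synthetic query logs, contact graphs and crowd-label tables.

The study's raw material — three months of cancer-specific web queries
with an instant-messenger contact graph — is private, so every
downstream stage of this package is exercised on synthetic data that
reproduces the reported statistical structure:

* pages viewed per user and users per page follow discrete power laws
  (default slopes −2.19 and −2.25);
* contacts per user follow a power law with slope −0.99 and lower
  median 6 (the slow decay forces an upper truncation, solved from the
  median);
* users search over windows whose length is lognormal with mean 10.0
  and SD 14.5 days inside a 92-day study period;
* category journeys are emitted by severity-specific ground-truth HMMs
  (five states each) whose qualitative shape matches the reported
  contrast: a string-like chain with stable early states for aggressive
  cancers, an interconnected chain with stable late states — and a
  visible ``support`` signature — for indolent ones;
* acquaintance co-search pairs are planted at a configurable fold over
  the label-permutation chance expectation (default 6×), with
  severity-specific onset lags and search durations and a configurable
  dominant-disease concordance (default 0.56).

The contact universe is ``network_scale`` times larger than the searcher
population: a messenger graph spans everyone while only a minority ever
query cancer, and this ratio is what keeps co-search pairs a small,
plantable subset of the cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from . import hmm as hmm_mod
from .categories import CATEGORIES, CATEGORY_INDEX, N_CATEGORIES
from .cohort import partition_severity
from .heavytail import sample_power_law, solve_xmax_for_median
from .hmm import CategoryHMM
from .lexicon import default_lexicon

STUDY_DAYS = 92

#: one templated topic word per category, used to build query texts
TOPIC_WORDS = {
    "causes": "causes",
    "prevention": "screening",
    "symptoms": "symptoms",
    "information": "prognosis",
    "treatment": "treatment",
    "social_media": "forum",
    "support": "support group",
    "celebrity": "celebrity",
    "pets": "in dogs",
    "other": "news",
}

#: multiplicative emission tilts for the two co-search roles, matching the
#: reported first- vs second-searcher category contrasts (treatment +25%,
#: information +14% for probands; causes +116%, social media +75% for
#: acquaintances)
PROBAND_TILT = {"treatment": 1.25, "information": 1.14}
ACQUAINTANCE_TILT = {"causes": 2.16, "social_media": 1.75}

LOG_COLUMNS = ["user_id", "day", "query_text", "cancers", "page_id", "category"]
CONTACT_COLUMNS = ["user_a", "user_b"]


def default_aggressive_hmm() -> CategoryHMM:
    """Ground-truth journey model for aggressive (low-survival) cancers.

    String-like: each state hands over mainly to the next, the first two
    states are the most stable, treatment dominates late states, and
    ``support`` never exceeds the 0.05 signature threshold.
    """
    c = CATEGORY_INDEX
    E = np.zeros((5, N_CATEGORIES))
    # Each state has a distinct dominant category, so the journey phase is
    # readable from the page stream itself — the property that makes the
    # state count recoverable by holdout prediction.
    # Emission supports are disjoint across states (each category belongs
    # to one journey phase), which makes the phase readable from the page
    # stream — the property that lets holdout prediction recover the
    # state count. `support` is never emitted for aggressive cancers.
    E[0, [c["symptoms"], c["prevention"]]] = [0.92, 0.08]
    E[1, [c["information"]]] = [1.0]
    E[2, [c["causes"], c["pets"]]] = [0.92, 0.08]
    E[3, [c["treatment"], c["social_media"]]] = [0.92, 0.08]
    E[4, [c["other"], c["celebrity"]]] = [0.90, 0.10]
    # Strictly string-like: each phase hands over only to the next, with
    # a treatment <-> wrap-up cycle at the end. The first two states are
    # the most stable.
    A = np.array(
        [
            [0.70, 0.30, 0.00, 0.00, 0.00],
            [0.00, 0.65, 0.35, 0.00, 0.00],
            [0.00, 0.00, 0.60, 0.40, 0.00],
            [0.00, 0.00, 0.00, 0.60, 0.40],
            [0.00, 0.00, 0.00, 0.38, 0.62],
        ]
    )
    pi = np.array([0.55, 0.22, 0.12, 0.06, 0.05])
    return CategoryHMM(initial=pi, transition=A, emission=E)


def default_indolent_hmm() -> CategoryHMM:
    """Ground-truth journey model for indolent (high-survival) cancers.

    Interconnected and roughly symmetric, the last three states are the
    most stable, treatment appears early, and one state carries a strong
    ``support`` signature.
    """
    c = CATEGORY_INDEX
    E = np.zeros((5, N_CATEGORIES))
    E[0, [c["information"], c["causes"]]] = [0.92, 0.08]
    E[1, [c["treatment"], c["prevention"]]] = [0.92, 0.08]
    E[2, [c["support"], c["other"]]] = [0.92, 0.08]
    E[3, [c["symptoms"], c["pets"]]] = [0.92, 0.08]
    E[4, [c["social_media"], c["celebrity"]]] = [0.88, 0.12]
    # disjoint supports, as for the aggressive truth; `support` is a
    # signature output here only
    A = np.array(
        [
            [0.46, 0.15, 0.13, 0.13, 0.13],
            [0.15, 0.48, 0.13, 0.12, 0.12],
            [0.12, 0.12, 0.60, 0.08, 0.08],
            [0.11, 0.11, 0.08, 0.62, 0.08],
            [0.10, 0.10, 0.08, 0.08, 0.64],
        ]
    )
    pi = np.array([0.30, 0.26, 0.14, 0.15, 0.15])
    return CategoryHMM(initial=pi, transition=A, emission=E)


def default_truth_hmm() -> CategoryHMM:
    """The generator's default single-group ground truth (aggressive)."""
    return default_aggressive_hmm()


def tilt_occupancy(model: CategoryHMM, tilt: dict[str, float]) -> CategoryHMM:
    """Bias a journey model's state occupancy toward tilted categories.

    Each state receives a multiplier ``Π_cat (1 + (f_cat − 1)·E[s, cat])``
    applied to all transition (and initial) probability flowing into it,
    rows renormalised. States dominated by a tilted category see their
    occupancy — and hence the category's page-view share — scaled by
    roughly the tilt factor, while emissions stay untouched.
    """
    m = np.ones(model.K)
    for cat, factor in tilt.items():
        m *= 1.0 + (factor - 1.0) * model.emission[:, CATEGORY_INDEX[cat]]
    A = model.transition * m[None, :]
    A /= A.sum(axis=1, keepdims=True)
    pi = model.initial * m
    pi /= pi.sum()
    return CategoryHMM(initial=pi, transition=A, emission=model.emission)


@dataclass
class SyntheticConfig:
    """Full parameterisation of the generator.

    Defaults are calibrated to the study's reported values; see module
    docstring. ``network_scale`` sets the contact-universe size as a
    multiple of ``n_users``.
    """

    n_users: int = 20_000
    pageview_exponent: float = -2.19
    pagepop_exponent: float = -2.25
    degree_exponent: float = -0.99
    target_degree_median: int = 6
    hmm_truth_aggressive: CategoryHMM = field(default_factory=default_aggressive_hmm)
    hmm_truth_indolent: CategoryHMM = field(default_factory=default_indolent_hmm)
    mean_search_days: float = 10.0
    sd_search_days: float = 14.5
    pair_enrichment: float = 6.0
    lag_aggressive_days: float = 9.0
    lag_indolent_days: float = 15.0
    acq_duration_aggressive_days: float = 12.5
    acq_duration_sd_aggressive: float = 17.3
    acq_duration_indolent_days: float = 5.1
    acq_duration_sd_indolent: float = 8.1
    proband_duration_aggressive_days: float = 11.0
    proband_duration_sd_aggressive: float = 14.7
    proband_duration_indolent_days: float = 13.9
    proband_duration_sd_indolent: float = 18.9
    overlap_prob: float = 0.56
    multi_category_fraction: float = 0.415
    extra_disease_rate_proband: float = 0.9
    extra_disease_rate_other: float = 0.5
    incidence_r2_target: float = 0.72
    network_scale: int = 4
    n_days: int = STUDY_DAYS
    page_count_xmax: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("pageview_exponent", "pagepop_exponent", "degree_exponent"):
            if getattr(self, name) >= 0:
                raise ValueError(f"{name} must be negative")
        day_params = (
            "mean_search_days sd_search_days lag_aggressive_days lag_indolent_days "
            "acq_duration_aggressive_days acq_duration_sd_aggressive "
            "acq_duration_indolent_days acq_duration_sd_indolent "
            "proband_duration_aggressive_days proband_duration_sd_aggressive "
            "proband_duration_indolent_days proband_duration_sd_indolent"
        ).split()
        for name in day_params:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("overlap_prob", "multi_category_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_users < 0:
            raise ValueError("n_users must be >= 0")
        if self.pair_enrichment < 1.0:
            raise ValueError("pair_enrichment must be >= 1 (1 = no planting)")
        if self.network_scale < 1:
            raise ValueError("network_scale must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        self.hmm_truth_aggressive.validate()
        self.hmm_truth_indolent.validate()

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if not isinstance(v, CategoryHMM)}
        d["hmm_truth_aggressive"] = self.hmm_truth_aggressive.to_dict()
        d["hmm_truth_indolent"] = self.hmm_truth_indolent.to_dict()
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        for key in ("hmm_truth_aggressive", "hmm_truth_indolent"):
            if key in d:
                d[key] = CategoryHMM.from_dict(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# helpers


def _rng(config_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stage])


def lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (mu, sigma) of a lognormal with given mean and SD."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_spans(
    mean: float, sd: float, size: int, rng: np.random.Generator, n_days: int
) -> np.ndarray:
    """Integer search-window lengths from a lognormal, clipped to [1, n_days]."""
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    if sd == 0:
        d = np.full(size, mean)
    else:
        mu, sigma = lognormal_moments(mean, sd)
        d = rng.lognormal(mu, sigma, size)
    return np.clip(np.rint(d), 1, n_days).astype(np.int64)


def disease_share_weights(
    lexicon: pd.DataFrame, r2_target: float, rng: np.random.Generator
) -> np.ndarray:
    """Disease popularity weights proportional to incidence plus noise.

    The additive Gaussian noise is scaled so that incidence explains about
    ``r2_target`` of the variance of the resulting query shares.
    """
    inc = lexicon["incidence_per_100k"].to_numpy(dtype=float)
    if not 0.0 < r2_target < 1.0:
        raise ValueError("r2_target must be in (0, 1)")
    noise_sd = inc.std() * np.sqrt((1.0 - r2_target) / r2_target)
    w = inc + rng.normal(0.0, noise_sd, inc.size)
    w = np.maximum(w, 0.02 * inc.min())
    return w / w.sum()


def simulate_contact_graph(
    n_nodes: int,
    exponent: float = -0.99,
    median_target: int = 6,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Power-law contact graph via configuration-model stub pairing.

    Returns ``(edges, degrees)``: a deduplicated ``(E, 2)`` array of
    undirected edges with no self-loops (``lo < hi``), and the realised
    degree sequence over all ``n_nodes`` nodes. The degree distribution's
    upper truncation is solved so its lower median equals
    ``median_target``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_nodes < 2:
        return np.zeros((0, 2), dtype=np.int64), np.zeros(n_nodes, dtype=np.int64)
    xmax = solve_xmax_for_median(exponent, median_target)
    deg = sample_power_law(exponent, n_nodes, rng, xmin=1, xmax=xmax)
    if deg.sum() % 2:
        deg[rng.integers(0, n_nodes)] += 1
    stubs = np.repeat(np.arange(n_nodes, dtype=np.int64), deg)
    rng.shuffle(stubs)
    a, b = stubs[0::2], stubs[1::2]
    keep = a != b
    lo = np.minimum(a[keep], b[keep])
    hi = np.maximum(a[keep], b[keep])
    keys = np.unique(lo * np.int64(n_nodes) + hi)
    edges = np.column_stack([keys // n_nodes, keys % n_nodes])
    degrees = np.bincount(edges.ravel(), minlength=n_nodes).astype(np.int64)
    return edges, degrees


def realized_degrees(edges: np.ndarray, n_nodes: int) -> np.ndarray:
    return np.bincount(np.asarray(edges).ravel(), minlength=n_nodes).astype(np.int64)


# ---------------------------------------------------------------------------
# the generator


def _empty_outputs(lexicon: pd.DataFrame):
    events = pd.DataFrame(
        {
            "user_id": pd.Series([], dtype=np.int64),
            "day": pd.Series([], dtype=np.int64),
            "query_text": pd.Series([], dtype=object),
            "cancers": pd.Series([], dtype=object),
            "page_id": pd.Series([], dtype=np.int64),
            "category": pd.Series([], dtype=object),
        }
    )
    contacts = pd.DataFrame(
        {"user_a": pd.Series([], dtype=np.int64), "user_b": pd.Series([], dtype=np.int64)}
    )
    return events, contacts, lexicon.copy()


def simulate_log(
    config: SyntheticConfig,
    with_network: bool = True,
    lexicon: pd.DataFrame | None = None,
):
    """Generate a synthetic query log, contact edge list and lexicon.

    Returns ``(events, contacts, lexicon)`` DataFrames following the
    package's file dialects (see :mod:`seekpaths.io`). Fully reproducible
    for a given ``config.seed``; ``with_network=False`` skips the contact
    graph and co-search planting (useful for cohort-only studies, where
    the network dominates cost).
    """
    config.validate()
    if lexicon is None:
        lexicon = default_lexicon()
    if config.n_users == 0:
        return _empty_outputs(lexicon)
    if config.n_users == 1:
        raise ValueError("n_users must be 0 (empty) or >= 2")

    lex = partition_severity(lexicon)
    names = lex["cancer"].to_numpy()
    aggressive_disease = (lex["severity"] == "aggressive").to_numpy()
    D = len(lex)
    n = config.n_users
    n_days = config.n_days

    # --- per-user skeleton -------------------------------------------------
    rng_u = _rng(config.seed, 1)
    p_disease = disease_share_weights(lex, config.incidence_r2_target, rng_u)
    n_pages = sample_power_law(
        config.pageview_exponent, n, rng_u, xmin=1, xmax=config.page_count_xmax
    )
    disease = rng_u.choice(D, size=n, p=p_disease)
    multi = rng_u.random(n) < config.multi_category_fraction
    eligible = (n_pages >= 5) & multi

    spans = _draw_spans(config.mean_search_days, config.sd_search_days, n, rng_u, n_days)
    starts = rng_u.integers(0, n_days - spans + 1)

    # roles: 0 = generic, 1 = proband (first searcher), 2 = acquaintance
    role = np.zeros(n, dtype=np.int8)

    # --- contact graph and co-search planting ------------------------------
    contacts_edges = np.zeros((0, 2), dtype=np.int64)
    if with_network:
        rng_g = _rng(config.seed, 2)
        n_net = config.network_scale * n
        edges, _ = simulate_contact_graph(
            n_net, config.degree_exponent, config.target_degree_median, rng=rng_g
        )
        edges, disease, starts, spans, role = _plant_pairs(
            config, edges, n_net, eligible, aggressive_disease, disease,
            starts, spans, role, rng_g,
        )
        contacts_edges = edges

    # --- category sequences ------------------------------------------------
    rng_s = _rng(config.seed, 3)
    user_aggressive = aggressive_disease[disease]
    seq_codes: list[np.ndarray | None] = [None] * n
    truths = {True: config.hmm_truth_aggressive, False: config.hmm_truth_indolent}
    for agg in (True, False):
        base = truths[agg]
        # single-category users: one category drawn from the stationary mixture
        smask = np.where(~multi & (user_aggressive == agg))[0]
        if smask.size:
            mix = hmm_mod.stationary_emission_mixture(base)
            cats = rng_s.choice(N_CATEGORIES, size=smask.size, p=mix / mix.sum())
            for i, cat in zip(smask, cats):
                seq_codes[i] = np.full(n_pages[i], cat, dtype=np.int64)
        for r, variant in (
            (0, base),
            (1, tilt_occupancy(base, PROBAND_TILT)),
            (2, tilt_occupancy(base, ACQUAINTANCE_TILT)),
        ):
            idx = np.where(multi & (user_aggressive == agg) & (role == r))[0]
            if idx.size == 0:
                continue
            seqs = hmm_mod.sample_sequences(variant, n_pages[idx], rng_s)
            # multi-category users must realise >= 2 distinct categories:
            # resample the rare constant sequences so the configured
            # multi-category fraction is what the cohort actually sees
            for _ in range(10):
                const = [
                    j for j, s in enumerate(seqs)
                    if len(s) >= 2 and (s == s[0]).all()
                ]
                if not const:
                    break
                redraw = hmm_mod.sample_sequences(
                    variant, n_pages[idx[const]], rng_s
                )
                for j, s in zip(const, redraw):
                    seqs[j] = s
            for i, s in zip(idx, seqs):
                seq_codes[i] = s

    # --- flatten events ----------------------------------------------------
    rng_e = _rng(config.seed, 4)
    lens = n_pages.astype(np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    E_total = int(offsets[-1])
    user_rep = np.repeat(np.arange(n, dtype=np.int64), lens)
    cat_flat = np.concatenate(seq_codes)

    day_raw = np.repeat(starts, lens) + np.floor(
        rng_e.random(E_total) * np.repeat(spans, lens)
    ).astype(np.int64)
    key = user_rep * np.int64(128) + day_raw
    key.sort(kind="stable")
    day = key % 128
    day[offsets[:-1]] = starts
    last = offsets[1:] - 1
    day[last] = starts + spans - 1
    # single-event users: the window collapses to its first day
    one = lens == 1
    day[offsets[:-1][one]] = starts[one]

    # queried disease per event: dominant by default, occasional extras
    ev_disease = np.repeat(disease, lens)
    lam = np.where(role == 1, config.extra_disease_rate_proband, config.extra_disease_rate_other)
    n_extra = np.minimum(rng_e.poisson(lam), np.maximum(lens - 2, 0)).astype(np.int64)
    users_x = np.where(n_extra > 0)[0]
    if users_x.size:
        tot_x = int(n_extra[users_x].sum())
        x_user = np.repeat(users_x, n_extra[users_x])
        x_dis = rng_e.integers(0, D, size=tot_x)
        ok = x_dis != disease[x_user]
        x_user, x_dis = x_user[ok], x_dis[ok]
        # interior positions only, so window endpoints keep the dominant query
        pos = offsets[x_user] + 1 + np.floor(
            rng_e.random(x_user.size) * (lens[x_user] - 2)
        ).astype(np.int64)
        ev_disease[pos] = x_dis

    # page popularity: capacities drawn from the users-per-page power law
    caps = []
    total = 0
    while total < E_total:
        block = sample_power_law(
            config.pagepop_exponent, max(1024, E_total // 2), rng_e, xmin=1,
            xmax=config.page_count_xmax,
        )
        caps.append(block)
        total += int(block.sum())
    caps = np.concatenate(caps)
    cut = int(np.searchsorted(np.cumsum(caps), E_total)) + 1
    page_rep = np.repeat(np.arange(cut, dtype=np.int64), caps[:cut])[:E_total]
    rng_e.shuffle(page_rep)

    cat_tokens = np.asarray(CATEGORIES, dtype=object)[cat_flat]
    ev_names = names[ev_disease]
    topics = np.asarray([TOPIC_WORDS[c] for c in CATEGORIES], dtype=object)[cat_flat]
    query_text = pd.Series(ev_names, dtype=object).str.cat(
        pd.Series(topics, dtype=object), sep=" "
    )

    events = pd.DataFrame(
        {
            "user_id": user_rep,
            "day": day,
            "query_text": query_text.to_numpy(),
            "cancers": ev_names,
            "page_id": page_rep,
            "category": cat_tokens,
        }
    )
    contacts = pd.DataFrame(
        {"user_a": contacts_edges[:, 0], "user_b": contacts_edges[:, 1]}
    )
    return events, contacts, lexicon.copy()


def _plant_pairs(
    config: SyntheticConfig,
    edges: np.ndarray,
    n_net: int,
    eligible: np.ndarray,
    aggressive_disease: np.ndarray,
    disease: np.ndarray,
    starts: np.ndarray,
    spans: np.ndarray,
    role: np.ndarray,
    rng: np.random.Generator,
):
    """Plant co-search structure on the contact graph.

    Adds edges between unused eligible searchers until the count of
    eligible-eligible edges reaches ``pair_enrichment`` times the
    label-permutation chance expectation, then walks every qualifying
    component from its highest-degree node outward assigning first-search
    days, severity-specific onset lags and durations, and dominant-disease
    concordance.
    """
    n = eligible.size
    m = int(eligible.sum())
    f = config.pair_enrichment
    if m < 2 or edges.shape[0] == 0:
        return edges, disease, starts, spans, role

    is_elig = np.zeros(n_net, dtype=bool)
    is_elig[np.where(eligible)[0]] = True
    qmask = is_elig[edges[:, 0]] & is_elig[edges[:, 1]]
    c0 = int(qmask.sum())
    q = m * (m - 1) / (n_net * (n_net - 1))
    E0 = edges.shape[0]
    # plant (f-1) x the chance expectation ON TOP of the chance pairs that
    # occurred naturally; topping the count up to f x the mean instead
    # would censor downward fluctuations and bias the fold upward at f=1
    target = (f - 1.0) * q * E0 / max(1.0 - (f - 1.0) * q, 1e-12)
    n_plant = max(int(round(target)), 0)

    q_edges = [tuple(e) for e in edges[qmask]]
    used = set(np.asarray(edges[qmask]).ravel().tolist())
    pool = np.array([u for u in np.where(eligible)[0] if u not in used], dtype=np.int64)
    rng.shuffle(pool)
    n_plant = min(n_plant, pool.size // 2)
    planted = pool[: 2 * n_plant].reshape(-1, 2)
    if planted.size:
        lo = np.minimum(planted[:, 0], planted[:, 1])
        hi = np.maximum(planted[:, 0], planted[:, 1])
        edges = np.vstack([edges, np.column_stack([lo, hi])])
        q_edges.extend(zip(lo.tolist(), hi.tolist()))

    # orient and type every qualifying component
    G = nx.Graph()
    G.add_edges_from(q_edges)
    lag_mean = {True: config.lag_aggressive_days, False: config.lag_indolent_days}
    prob_dur = {
        True: (config.proband_duration_aggressive_days, config.proband_duration_sd_aggressive),
        False: (config.proband_duration_indolent_days, config.proband_duration_sd_indolent),
    }
    acq_dur = {
        True: (config.acq_duration_aggressive_days, config.acq_duration_sd_aggressive),
        False: (config.acq_duration_indolent_days, config.acq_duration_sd_indolent),
    }
    n_days = config.n_days
    D = aggressive_disease.size
    for comp in nx.connected_components(G):
        comp = list(comp)
        root = max(comp, key=lambda u: (G.degree[u], -u))
        agg_root = bool(aggressive_disease[disease[root]])
        mu, sd = prob_dur[agg_root]
        offset = {root: 0}
        span_of = {root: int(_draw_spans(mu, sd, 1, rng, n_days)[0])}
        role[root] = 1
        for parent, child in nx.bfs_edges(G, root):
            agg_p = bool(aggressive_disease[disease[parent]])
            if rng.random() < config.overlap_prob:
                disease[child] = disease[parent]
            elif disease[child] == disease[parent]:
                others = [d for d in range(D) if d != disease[parent]]
                disease[child] = others[int(rng.integers(0, D - 1))]
            lag = max(1, int(np.rint(rng.exponential(lag_mean[agg_p]))))
            offset[child] = offset[parent] + lag
            mu_a, sd_a = acq_dur[agg_p]
            span_of[child] = int(_draw_spans(mu_a, sd_a, 1, rng, n_days)[0])
            role[child] = 2
        extent = max(offset[u] + span_of[u] for u in comp)
        s0 = int(rng.integers(0, max(n_days - extent, 0) + 1))
        for u in comp:
            d0 = min(s0 + offset[u], n_days - 1)
            starts[u] = d0
            spans[u] = min(span_of[u], n_days - d0)
    return edges, disease, starts, spans, role


# ---------------------------------------------------------------------------
# crowd labelers


def simulate_labelers(
    truth,
    n_labelers: int = 5,
    accuracy: float = 0.9,
    ambiguous_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate independent crowd labelers voting on page categories.

    ``truth`` maps page id to true category (dict or DataFrame with
    ``page_id``/``category`` columns). Each labeler reports the true
    category with probability ``accuracy`` and a uniformly random other
    category otherwise. A ``ambiguous_fraction`` of pages instead gets a
    vote pattern engineered to lack any 3-vote majority (only defined for
    5 labelers): 2+2+1 with probability .46, 2+1+1+1 with .48, five
    singletons otherwise — the split reported for real disagreements.
    """
    if n_labelers < 1:
        raise ValueError("n_labelers must be >= 1")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {accuracy}")
    if not 0.0 <= ambiguous_fraction <= 1.0:
        raise ValueError("ambiguous_fraction must be in [0, 1]")
    if isinstance(truth, pd.DataFrame):
        pages = truth["page_id"].tolist()
        cats = truth["category"].tolist()
    else:
        pages = list(truth.keys())
        cats = [truth[p] for p in pages]
    codes = np.array([CATEGORY_INDEX[c] for c in cats], dtype=np.int64)
    rng = np.random.default_rng(seed)
    n_pages = len(pages)
    amb = rng.random(n_pages) < ambiguous_fraction
    if amb.any() and n_labelers != 5:
        raise ValueError("ambiguous vote engineering requires exactly 5 labelers")

    votes = np.empty((n_pages, n_labelers), dtype=np.int64)
    truthful = rng.random((n_pages, n_labelers)) < accuracy
    shift = rng.integers(1, N_CATEGORIES, size=(n_pages, n_labelers))
    votes[:] = np.where(truthful, codes[:, None], (codes[:, None] + shift) % N_CATEGORIES)

    for i in np.where(amb)[0]:
        true = codes[i]
        others = [c for c in range(N_CATEGORIES) if c != true]
        rng.shuffle(others)
        u = rng.random()
        if u < 0.46:
            ballot = [true, true, others[0], others[0], others[1]]
        elif u < 0.94:
            ballot = [true, true, others[0], others[1], others[2]]
        else:
            ballot = [true, others[0], others[1], others[2], others[3]]
        rng.shuffle(ballot)
        votes[i] = ballot

    cat_arr = np.asarray(CATEGORIES, dtype=object)
    data = {"page_id": pages}
    for j in range(n_labelers):
        data[f"v{j + 1}"] = cat_arr[votes[:, j]]
    return pd.DataFrame(data)
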