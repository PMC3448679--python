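"""Discrete-emission hidden Markov models over page categories.

The central model of the package: a user's journey through cancer
information is treated as a latent Markov chain with ``K`` hidden states,
each state emitting one of the ten canonical page categories per page
visit. The module provides

* Baum–Welch (EM) training with scaled forward–backward recursions,
  batched across users (:func:`train_hmm`);
* exact one-step-ahead predictive distributions via the forward
  recursion (:func:`predict_next_category`);
* holdout prediction error (:func:`holdout_prediction_error`) and
  holdout selection of the number of hidden states with random restarts
  (:func:`select_num_states`);
* the descriptive summaries used to characterise fitted journeys:
  signature output categories per state (:func:`signature_states`) and
  the state stability ranking (:func:`stability_ranking`).

Numerical conventions: training stops when the relative log-likelihood
improvement falls below ``tol`` (default 1e-6) or after ``n_iter``
(default 500) iterations; emission rows receive a small additive
(Laplace) smoothing count (default 1e-3) at each M-step so held-out
tokens are never assigned probability zero; argmax ties are broken in
canonical category order, and tied model-selection errors resolve to the
smaller state count. The initial state distribution is estimated freely,
which accommodates journeys whose true beginning predates the
observation window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .categories import CATEGORIES, N_CATEGORIES, decode, encode

_ROW_TOL = 1e-9


@dataclass
class CategoryHMM:
    """A ``K``-state HMM over the 10 canonical categories.

    ``initial`` is length ``K``; ``transition`` is ``K×K`` row-stochastic;
    ``emission`` is ``K×10`` row-stochastic.
    """

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=np.float64)
        self.transition = np.asarray(self.transition, dtype=np.float64)
        self.emission = np.asarray(self.emission, dtype=np.float64)
        self.validate()

    @property
    def K(self) -> int:
        return int(self.initial.shape[0])

    def validate(self) -> None:
        K = self.K
        if self.transition.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if self.emission.shape != (K, N_CATEGORIES):
            raise ValueError(
                f"emission matrix must be K×{N_CATEGORIES}, got {self.emission.shape}"
            )
        for name, arr in (
            ("initial", self.initial),
            ("transition", self.transition),
            ("emission", self.emission),
        ):
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
        if abs(self.initial.sum() - 1.0) > _ROW_TOL:
            raise ValueError("initial distribution does not sum to 1")
        for name, arr in (("transition", self.transition), ("emission", self.emission)):
            if np.max(np.abs(arr.sum(axis=1) - 1.0)) > _ROW_TOL:
                raise ValueError(f"{name} rows do not sum to 1")

    def permuted(self, order) -> "CategoryHMM":
        """Relabel hidden states by ``order`` (new state i = old order[i])."""
        order = np.asarray(order)
        return CategoryHMM(
            initial=self.initial[order],
            transition=self.transition[np.ix_(order, order)],
            emission=self.emission[order],
        )

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "categories": list(CATEGORIES),
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryHMM":
        return cls(
            initial=np.array(d["initial"]),
            transition=np.array(d["transition"]),
            emission=np.array(d["emission"]),
        )


@dataclass
class ModelSelectionResult:
    """Outcome of holdout selection of the hidden-state count."""

    candidate_Ks: list[int]
    mean_error: dict[int, float]
    best_K: int
    n_restarts: int
    train_fraction: float
    seed: int
    infeasible_Ks: list[int] = field(default_factory=list)
    train_loglik: dict[int, float] = field(default_factory=dict)
    models: dict[int, CategoryHMM] = field(default_factory=dict)

    def error_curve(self) -> list[tuple[int, float]]:
        return [(k, self.mean_error[k]) for k in sorted(self.mean_error)]


# ---------------------------------------------------------------------------
# sequence plumbing


def _as_code_sequences(sequences) -> list[np.ndarray]:
    """Normalise input sequences (tokens or codes) to int arrays."""
    out = []
    for seq in sequences:
        if len(seq) == 0:
            raise ValueError("sequences must be non-empty")
        if isinstance(seq[0], str):
            codes = np.array(encode(seq), dtype=np.int64)
        else:
            codes = np.asarray(seq, dtype=np.int64)
            if codes.min() < 0 or codes.max() >= N_CATEGORIES:
                raise ValueError("category code out of range")
        out.append(codes)
    return out


def _pad(code_seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack ragged sequences into a padded matrix with -1 fill + mask."""
    n = len(code_seqs)
    tmax = max(len(s) for s in code_seqs)
    X = np.full((n, tmax), -1, dtype=np.int64)
    for i, s in enumerate(code_seqs):
        X[i, : len(s)] = s
    return X, X >= 0


# ---------------------------------------------------------------------------
# forward/backward core


def _forward_pass(model: CategoryHMM, X: np.ndarray, mask: np.ndarray):
    """Scaled forward recursion batched over sequences.

    Returns (alpha_hat, scale) with shapes (N, T, K) and (N, T); at padded
    positions alpha_hat carries the last active value and scale is 1, so
    the total log-likelihood is ``log(scale).sum()``.
    """
    N, T = X.shape
    K = model.K
    Xs = np.where(mask, X, 0)
    alpha = np.empty((N, T, K))
    scale = np.ones((N, T))

    a = model.initial[None, :] * model.emission[:, Xs[:, 0]].T
    c = a.sum(axis=1)
    c = np.where(c > 0, c, 1.0)
    a = a / c[:, None]
    alpha[:, 0] = a
    scale[:, 0] = c
    for t in range(1, T):
        act = mask[:, t]
        if not act.any():
            alpha[:, t] = a
            continue
        bt = model.emission[:, Xs[:, t]].T
        a_new = (a @ model.transition) * bt
        ct = a_new.sum(axis=1)
        ct = np.where(ct > 0, ct, 1.0)
        a_new = a_new / ct[:, None]
        a = np.where(act[:, None], a_new, a)
        alpha[:, t] = a
        scale[:, t] = np.where(act, ct, 1.0)
    return alpha, scale


def _loglik_from_scale(scale: np.ndarray) -> float:
    return float(np.log(scale).sum())


def _e_step(model: CategoryHMM, X: np.ndarray, mask: np.ndarray):
    """One EM expectation step; returns sufficient statistics and loglik."""
    N, T = X.shape
    K = model.K
    Xs = np.where(mask, X, 0)
    alpha, scale = _forward_pass(model, X, mask)
    ll = _loglik_from_scale(scale)

    pi_stat = np.zeros(K)
    trans_stat = np.zeros((K, K))
    sym_stat = np.zeros((N_CATEGORIES, K))

    bh = np.ones((N, K))  # scaled beta at position t (initialised at each tail)
    for t in range(T - 1, -1, -1):
        act = mask[:, t]
        gamma = alpha[:, t] * bh
        if act.any():
            np.add.at(sym_stat, Xs[act, t], gamma[act])
            if t == 0:
                pi_stat += gamma[act].sum(axis=0)
        if t > 0:
            # transition statistics for step t-1 -> t, and beta recursion
            bt = model.emission[:, Xs[:, t]].T
            w = bt * bh / scale[:, t][:, None]
            a_prev = alpha[:, t - 1]
            trans_stat += model.transition * (a_prev[act].T @ w[act])
            bh_new = w @ model.transition.T
            bh = np.where(act[:, None], bh_new, bh)
    return pi_stat, trans_stat, sym_stat, ll


def _normalise_rows(mat: np.ndarray) -> np.ndarray:
    sums = mat.sum(axis=1, keepdims=True)
    out = np.where(sums > 0, mat / np.where(sums > 0, sums, 1.0), 1.0 / mat.shape[1])
    return out


def random_hmm(K: int, rng: np.random.Generator) -> CategoryHMM:
    """Random fully-supported model used for EM restarts and tests."""
    return CategoryHMM(
        initial=rng.dirichlet(np.ones(K)),
        transition=rng.dirichlet(np.ones(K), size=K),
        emission=rng.dirichlet(np.ones(N_CATEGORIES), size=K),
    )


def _data_driven_init(X: np.ndarray, mask: np.ndarray, K: int, rng) -> CategoryHMM:
    """Randomised anchor initialisation for EM restarts.

    Each of the first min(K, 10) states is anchored on one of the most
    frequent observed categories (order jittered per restart), and the
    transition matrix is seeded from soft bigram counts under that
    anchoring, plus multiplicative noise. Purely random initialisation
    frequently converges to merge/split local optima on sharply
    structured sequences; seeding states on distinct categories breaks
    that symmetry while restarts stay genuinely random.
    """
    tokens = X[mask]
    freq = np.bincount(tokens, minlength=N_CATEGORIES).astype(float)
    freq /= max(freq.sum(), 1.0)
    n_anchor = min(K, N_CATEGORIES)
    jitter = rng.gumbel(size=N_CATEGORIES) * 0.15
    anchors = np.argsort(-(np.log(freq + 1e-9) + jitter))[:n_anchor]
    base = (freq + 0.01) / (freq + 0.01).sum()
    E = np.tile(0.3 * base, (K, 1))
    for k in range(n_anchor):
        E[k, anchors[k]] += 0.7
    for k in range(n_anchor, K):
        E[k] = rng.dirichlet(np.ones(N_CATEGORIES))
    E /= E.sum(axis=1, keepdims=True)

    resp = E / E.sum(axis=0, keepdims=True)  # P(state | token) under anchoring
    a = X[:, :-1][mask[:, 1:]]
    b = X[:, 1:][mask[:, 1:]]
    C = np.zeros((N_CATEGORIES, N_CATEGORIES))
    np.add.at(C, (a, b), 1.0)
    A = resp @ C @ resp.T
    A += rng.gamma(1.0, 1.0, size=(K, K)) * (A.sum() / K**2) * 0.2
    A /= A.sum(axis=1, keepdims=True)
    first = np.bincount(X[:, 0], minlength=N_CATEGORIES).astype(float)
    pi = resp @ first + 0.1
    pi /= pi.sum()
    return CategoryHMM(initial=pi, transition=A, emission=E)


def train_hmm(
    sequences,
    K: int,
    seed: int = 0,
    n_iter: int = 500,
    tol: float = 1e-6,
    smoothing: float = 1e-3,
    init: CategoryHMM | None = None,
) -> tuple[CategoryHMM, list[float]]:
    """Fit a ``K``-state model by Baum–Welch; returns (model, loglik history).

    The log-likelihood is asserted non-decreasing across iterations (up to
    1e-8 relative numerical slack). ``smoothing`` is added to every
    emission count at each M-step.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    code_seqs = _as_code_sequences(sequences)
    total = sum(len(s) for s in code_seqs)
    if K > total:
        raise ValueError(f"K={K} exceeds the total event count {total}")
    X, mask = _pad(code_seqs)
    rng = np.random.default_rng(seed)
    model = init if init is not None else _data_driven_init(X, mask, K, rng)
    if model.K != K:
        raise ValueError("init model has wrong K")

    history: list[float] = []
    for _ in range(n_iter):
        pi_stat, trans_stat, sym_stat, ll = _e_step(model, X, mask)
        if history and ll < history[-1] - 1e-8 * (1.0 + abs(history[-1])):
            raise AssertionError(
                f"Baum-Welch log-likelihood decreased: {history[-1]} -> {ll}"
            )
        converged = bool(history) and (ll - history[-1]) < tol * abs(history[-1])
        history.append(ll)
        if converged:
            break
        model = CategoryHMM(
            initial=_normalise_rows(pi_stat[None, :])[0],
            transition=_normalise_rows(trans_stat + 1e-12),
            emission=_normalise_rows(sym_stat.T + smoothing),
        )
    return model, history


def loglikelihood(model: CategoryHMM, sequences) -> float:
    """Total log-likelihood of ``sequences`` under ``model``."""
    X, mask = _pad(_as_code_sequences(sequences))
    _, scale = _forward_pass(model, X, mask)
    return _loglik_from_scale(scale)


# ---------------------------------------------------------------------------
# prediction


def predict_next_category(model: CategoryHMM, prefix) -> np.ndarray:
    """Exact filtered one-step predictive distribution over the 10 categories.

    With an empty prefix this is the marginal first-emission distribution
    ``initial @ emission``.
    """
    prefix = list(prefix)
    if not prefix:
        f = model.initial
    else:
        codes = _as_code_sequences([prefix])[0]
        f = model.initial * model.emission[:, codes[0]]
        s = f.sum()
        if s <= 0:
            raise ValueError("prefix has zero probability under the model")
        f = f / s
        for c in codes[1:]:
            f = (f @ model.transition) * model.emission[:, c]
            s = f.sum()
            if s <= 0:
                raise ValueError("prefix has zero probability under the model")
            f = f / s
        f = f @ model.transition
    return f @ model.emission


def holdout_prediction_error(model: CategoryHMM, sequences, metric: str = "argmax") -> float:
    """Prediction error of ``model`` on held-out sequences.

    ``metric='argmax'`` (default): for every position from the second
    onward, predict the category maximising the filtered one-step
    predictive distribution given the true prefix, and score 0/1
    mismatches; returns the mismatch fraction over all scored positions.
    ``metric='logloss'`` returns the mean negative predictive log
    probability instead.
    """
    if metric not in ("argmax", "logloss"):
        raise ValueError("metric must be 'argmax' or 'logloss'")
    code_seqs = _as_code_sequences(sequences)
    if all(len(s) < 2 for s in code_seqs):
        raise ValueError("no scorable positions (all sequences shorter than 2)")
    X, mask = _pad(code_seqs)
    N, T = X.shape
    Xs = np.where(mask, X, 0)

    a = model.initial[None, :] * model.emission[:, Xs[:, 0]].T
    c = a.sum(axis=1)
    a = a / np.where(c > 0, c, 1.0)[:, None]
    n_scored = 0
    wrong = 0.0
    logloss = 0.0
    for t in range(1, T):
        act = mask[:, t]
        if not act.any():
            break
        pred = (a @ model.transition) @ model.emission
        truth = Xs[:, t]
        if metric == "argmax":
            wrong += np.count_nonzero(pred[act].argmax(axis=1) != truth[act])
        else:
            p = pred[np.arange(N), truth]
            logloss += -np.log(np.maximum(p[act], 1e-300)).sum()
        n_scored += int(act.sum())
        bt = model.emission[:, truth].T
        a_new = (a @ model.transition) * bt
        ct = a_new.sum(axis=1)
        a_new = a_new / np.where(ct > 0, ct, 1.0)[:, None]
        a = np.where(act[:, None], a_new, a)
    if metric == "argmax":
        return float(wrong / n_scored)
    return float(logloss / n_scored)


# ---------------------------------------------------------------------------
# model selection


def select_num_states(
    sequences,
    candidate_Ks,
    train_fraction: float = 0.75,
    n_restarts: int = 5,
    seed: int = 0,
    metric: str = "argmax",
    n_iter: int = 500,
    tol: float = 1e-6,
    keep_models: bool = False,
) -> ModelSelectionResult:
    """Select the hidden-state count by holdout prediction error.

    Users (sequences) are split once into a ``train_fraction`` training
    set and a held-out test set. For each candidate ``K`` the model is
    fitted ``n_restarts`` times from random initialisations; the restart
    with the best *training* log-likelihood is scored on the held-out
    users (restart selection never sees the test set). The chosen ``K``
    minimises the holdout error, ties resolving to the smaller count.
    """
    candidate_Ks = sorted(set(int(k) for k in candidate_Ks))
    if not candidate_Ks:
        raise ValueError("candidate_Ks is empty")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    code_seqs = _as_code_sequences(sequences)
    n = len(code_seqs)
    if n < 8:
        raise ValueError("need at least 8 sequences for a meaningful split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train = [code_seqs[i] for i in order[:n_train]]
    test = [code_seqs[i] for i in order[n_train:]]

    mean_error: dict[int, float] = {}
    train_ll: dict[int, float] = {}
    models: dict[int, CategoryHMM] = {}
    infeasible: list[int] = []
    total_train = sum(len(s) for s in train)
    for K in candidate_Ks:
        if K > total_train:
            infeasible.append(K)
            mean_error[K] = float("nan")
            continue
        best_model = None
        best_ll = -np.inf
        for _ in range(n_restarts):
            restart_seed = int(rng.integers(0, 2**31 - 1))
            model, history = train_hmm(
                train, K, seed=restart_seed, n_iter=n_iter, tol=tol
            )
            if history[-1] > best_ll:
                best_ll = history[-1]
                best_model = model
        mean_error[K] = holdout_prediction_error(best_model, test, metric=metric)
        train_ll[K] = best_ll
        if keep_models:
            models[K] = best_model
    feasible = [k for k in candidate_Ks if k not in infeasible]
    if not feasible:
        raise ValueError("no feasible candidate K for this training set")
    best_K = min(feasible, key=lambda k: (mean_error[k], k))
    return ModelSelectionResult(
        candidate_Ks=candidate_Ks,
        mean_error=mean_error,
        best_K=int(best_K),
        n_restarts=n_restarts,
        train_fraction=train_fraction,
        seed=seed,
        infeasible_Ks=infeasible,
        train_loglik=train_ll,
        models=models,
    )


# ---------------------------------------------------------------------------
# descriptive summaries


def signature_states(model: CategoryHMM, threshold: float = 0.05):
    """Per-state signature output categories.

    For each hidden state, the categories emitted with probability
    strictly above ``threshold``, ordered by decreasing probability (ties
    in canonical category order and flagged).
    """
    out = []
    for k in range(model.K):
        row = model.emission[k]
        idx = np.where(row > threshold)[0]
        entries = sorted(
            ((CATEGORIES[i], float(row[i])) for i in idx),
            key=lambda e: (-e[1], CATEGORY_ORDER[e[0]]),
        )
        probs = [p for _, p in entries]
        tied = len(probs) != len(set(probs))
        out.append({"state": k, "signature": entries, "ties": tied})
    return out


CATEGORY_ORDER = {c: i for i, c in enumerate(CATEGORIES)}


def stability_ranking(model: CategoryHMM):
    """States ordered by self-transition probability, most stable first."""
    diag = np.diag(model.transition)
    order = sorted(range(model.K), key=lambda k: (-diag[k], k))
    tied = len(set(np.round(diag, 12))) != model.K
    return {
        "ranking": [(int(k), float(diag[k])) for k in order],
        "ties": tied,
    }


def sample_sequences(
    model: CategoryHMM, lengths, rng: np.random.Generator, tokens: bool = False
):
    """Simulate category sequences from a model, one per entry of ``lengths``.

    Vectorised across sequences; returns lists of integer codes, or of
    category tokens when ``tokens=True``.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        return []
    if lengths.min() < 1:
        raise ValueError("sequence lengths must be >= 1")
    n = lengths.size
    tmax = int(lengths.max())
    init_cdf = np.cumsum(model.initial)
    trans_cdf = np.cumsum(model.transition, axis=1)
    emit_cdf = np.cumsum(model.emission, axis=1)

    # process sequences longest-first so the active set is always a
    # prefix; memory stays O(total events) even for heavy-tailed lengths
    order = np.argsort(-lengths, kind="stable")
    sorted_len = lengths[order]
    state = np.searchsorted(init_cdf, rng.random(n), side="right").clip(0, model.K - 1)
    state = state[order]
    cols: list[np.ndarray] = []
    for t in range(tmax):
        k = int(np.searchsorted(-sorted_len, -(t + 1), side="right"))
        if k == 0:
            break
        if t > 0:
            u = rng.random(k)
            state[:k] = (trans_cdf[state[:k]] < u[:, None]).sum(axis=1)
        u = rng.random(k)
        cols.append((emit_cdf[state[:k]] < u[:, None]).sum(axis=1))
    col_offsets = np.concatenate([[0], np.cumsum([len(c) for c in cols])])[:-1]
    flat = np.concatenate(cols)
    seqs: list[np.ndarray | None] = [None] * n
    for i_sorted in range(n):
        L = sorted_len[i_sorted]
        seqs[order[i_sorted]] = flat[col_offsets[:L] + i_sorted]
    if tokens:
        return [decode(s) for s in seqs]
    return seqs


def stationary_emission_mixture(model: CategoryHMM) -> np.ndarray:
    """Category distribution under the chain's stationary state mixture."""
    vals, vecs = np.linalg.eig(model.transition.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    return pi @ model.emission
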