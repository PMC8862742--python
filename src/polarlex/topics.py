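"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The sampler integrates out the topic mixtures θ and the topic-word
distributions φ and resamples the topic assignment of every token from
its conditional

    p(z = k | rest) ∝ (n_kw + β) / (n_k + Vβ) · (n_dk + α),

where n_kw / n_k are topic-word and topic counts and n_dk the document-
topic counts, all excluding the token being resampled.  φ and θ are
reported as posterior means over thinned post-burn-in count snapshots
(φ ∝ n_kw + β, θ ∝ n_dk + α), which is more stable than a single final
state.  The per-token loop is JIT-compiled with numba; the sampler is
deterministic for a fixed seed.

Topic-count selection follows the usual practice of scanning a K grid
and scoring each fit with intrinsic (UMass) coherence over the top words
of every topic; because coherence alone does not settle interpretability,
``select_k`` also emits a human-review sheet of top words and top tweets
per topic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse
from scipy.optimize import linear_sum_assignment
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .ingest import TweetRecord

logger = logging.getLogger(__name__)

DEFAULT_STOPWORDS = frozenset(ENGLISH_STOP_WORDS)


@dataclass
class TopicModelParams:
    """Sampler and vocabulary-pruning configuration.

    ``alpha`` defaults to 50/K and ``beta`` to 0.01 — common practice for
    LDA on short documents.  ``min_doc_freq`` / ``max_doc_prop`` prune
    rare and near-ubiquitous terms; stopwords are removed before either
    threshold applies.
    """

    K: int = 25
    alpha: float | None = None
    beta: float = 0.01
    n_iterations: int = 500
    burn_in: int = 250
    thin: int = 10
    seed: int = 0
    n_restarts: int = 3
    min_doc_freq: int = 2
    max_doc_prop: float = 0.5
    stopwords: frozenset[str] = DEFAULT_STOPWORDS

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be positive")
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if not 0.0 <= self.max_doc_prop <= 1.0:
            raise ValueError("max_doc_prop must lie in [0, 1]")
        if self.beta <= 0 or (self.alpha is not None and self.alpha <= 0):
            raise ValueError("alpha and beta must be positive")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 50.0 / self.K


@dataclass
class DocTermData:
    """Tokenized corpus after stopword removal and pruning."""

    docs: list[np.ndarray]        # per-document word-id sequences
    vocabulary: list[str]
    doc_ids: list[str]
    dtm: sparse.csr_matrix        # document-term count matrix
    dropped_ids: list[str] = field(default_factory=list)

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    @property
    def n_terms(self) -> int:
        return len(self.vocabulary)


@dataclass
class TopicModel:
    """Fitted LDA model: topic-word (φ) and document-topic (θ) matrices."""

    vocabulary: list[str]
    phi: np.ndarray               # (K, V), rows sum to 1
    theta: np.ndarray             # (D, K), rows sum to 1
    doc_ids: list[str]
    log_likelihood_trace: np.ndarray
    params: TopicModelParams
    coherence: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.phi.shape[0]


def build_dtm(records: Sequence[TweetRecord],
              params: TopicModelParams) -> DocTermData:
    """Build word-id sequences and a document-term matrix.

    Stopwords are removed, then terms appearing in fewer than
    ``min_doc_freq`` documents or in more than ``max_doc_prop`` of
    documents are pruned.  Documents emptied by pruning are dropped and
    their ids logged.  Raises if the surviving vocabulary is smaller
    than K.
    """
    stop = params.stopwords
    token_lists = [[t for t in rec.tokens if t not in stop]
                   for rec in records]

    df_counts: dict[str, int] = {}
    for toks in token_lists:
        for t in set(toks):
            df_counts[t] = df_counts.get(t, 0) + 1
    n_docs = len(records)
    max_df = params.max_doc_prop * n_docs
    vocabulary = sorted(t for t, c in df_counts.items()
                        if c >= params.min_doc_freq and c <= max_df)
    if len(vocabulary) < params.K:
        raise ValueError(
            f"vocabulary ({len(vocabulary)} terms) smaller than K={params.K}")
    index = {t: i for i, t in enumerate(vocabulary)}

    docs: list[np.ndarray] = []
    doc_ids: list[str] = []
    dropped: list[str] = []
    for rec, toks in zip(records, token_lists):
        ids = np.array([index[t] for t in toks if t in index], dtype=np.int32)
        if len(ids):
            docs.append(ids)
            doc_ids.append(rec.id)
        else:
            dropped.append(rec.id)
    if dropped:
        logger.info("dropped %d documents emptied by pruning: %s%s",
                    len(dropped), dropped[:10],
                    "..." if len(dropped) > 10 else "")
    if not docs:
        raise ValueError("all documents were emptied by pruning")

    rows = np.concatenate([np.full(len(d), i, dtype=np.int64)
                           for i, d in enumerate(docs)])
    cols = np.concatenate(docs)
    dtm = sparse.coo_matrix(
        (np.ones(len(cols), dtype=np.int64), (rows, cols)),
        shape=(len(docs), len(vocabulary))).tocsr()
    return DocTermData(docs=docs, vocabulary=vocabulary, doc_ids=doc_ids,
                       dtm=dtm, dropped_ids=dropped)


@njit(cache=True)
def _gibbs(token_word, token_doc, D, K, V, alpha, beta,
           n_iterations, burn_in, thin, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    N = token_word.shape[0]
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    z = np.empty(N, dtype=np.int32)
    for t in range(N):
        k = np.random.randint(0, K)
        z[t] = k
        n_dk[token_doc[t], k] += 1
        n_kw[k, token_word[t]] += 1
        n_k[k] += 1

    phi_sum = np.zeros((K, V))
    theta_sum = np.zeros((D, K))
    n_snapshots = 0
    ll_trace = np.empty(n_iterations)
    p = np.empty(K)
    v_beta = V * beta

    for it in range(n_iterations):
        for t in range(N):
            w = token_word[t]
            d = token_doc[t]
            k = z[t]
            n_dk[d, k] -= 1
            n_kw[k, w] -= 1
            n_k[k] -= 1
            total = 0.0
            for j in range(K):
                pj = (n_kw[j, w] + beta) / (n_k[j] + v_beta) \
                    * (n_dk[d, j] + alpha)
                total += pj
                p[j] = total
            u = np.random.random() * total
            k = 0
            while k < K - 1 and p[k] < u:
                k += 1
            z[t] = k
            n_dk[d, k] += 1
            n_kw[k, w] += 1
            n_k[k] += 1

        # Collapsed joint log p(w, z): topic-word and document-topic parts.
        ll = K * (math.lgamma(v_beta) - V * math.lgamma(beta))
        a_k = K * alpha
        for j in range(K):
            for w2 in range(V):
                if n_kw[j, w2] > 0:
                    ll += math.lgamma(n_kw[j, w2] + beta) - math.lgamma(beta)
            ll -= math.lgamma(n_k[j] + v_beta) - math.lgamma(v_beta)
        for d2 in range(D):
            nd = 0
            for j in range(K):
                if n_dk[d2, j] > 0:
                    ll += math.lgamma(n_dk[d2, j] + alpha) - math.lgamma(alpha)
                nd += n_dk[d2, j]
            ll -= math.lgamma(nd + a_k) - math.lgamma(a_k)
        ll_trace[it] = ll

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_snapshots += 1
            for j in range(K):
                denom = n_k[j] + v_beta
                for w2 in range(V):
                    phi_sum[j, w2] += (n_kw[j, w2] + beta) / denom
            for d2 in range(D):
                nd = 0
                for j in range(K):
                    nd += n_dk[d2, j]
                denom = nd + a_k
                for j in range(K):
                    theta_sum[d2, j] += (n_dk[d2, j] + alpha) / denom

    return phi_sum / n_snapshots, theta_sum / n_snapshots, ll_trace


def fit_lda(data: DocTermData, params: TopicModelParams) -> TopicModel:
    """Fit LDA by collapsed Gibbs sampling; deterministic in the seed.

    Runs ``n_restarts`` independent chains (seeds derived from
    ``params.seed``) and keeps the one with the highest mean post-burn-in
    joint log-likelihood — collapsed Gibbs can stick in a merged-topic
    mode, and stuck chains are readily identified by their likelihood.
    """
    D, V, K = data.n_docs, data.n_terms, params.K
    if D == 0 or data.dtm.nnz == 0:
        raise ValueError("empty document-term data")
    if K > D:
        warnings.warn(f"K={K} exceeds the number of documents ({D})")
    token_word = np.concatenate(data.docs).astype(np.int32)
    token_doc = np.concatenate(
        [np.full(len(d), i, dtype=np.int32)
         for i, d in enumerate(data.docs)])
    best = None
    for r in range(max(params.n_restarts, 1)):
        chain_seed = (params.seed + 9973 * r) % (2 ** 32)
        phi, theta, ll = _gibbs(
            token_word, token_doc, D, K, V,
            float(params.effective_alpha), float(params.beta),
            params.n_iterations, params.burn_in, params.thin, chain_seed)
        score = float(ll[params.burn_in:].mean())
        if best is None or score > best[0]:
            best = (score, phi, theta, ll)
    _, phi, theta, ll = best
    return TopicModel(vocabulary=list(data.vocabulary), phi=phi, theta=theta,
                      doc_ids=list(data.doc_ids), log_likelihood_trace=ll,
                      params=params)


def benchmark_fit_params(seed: int = 43, n_iterations: int = 500,
                         n_restarts: int = 3) -> TopicModelParams:
    """Sampler settings for the standard recovery benchmark.

    Uses alpha = 0.1 rather than the 50/K default: with ~15-token
    documents a symmetric prior of 50/K pseudo-counts per topic would
    outweigh the data and flatten the document-topic posteriors, so a
    sparse prior is the appropriate choice for short texts.
    """
    return TopicModelParams(K=5, alpha=0.1, beta=0.01,
                            n_iterations=n_iterations,
                            burn_in=n_iterations // 2, seed=seed,
                            n_restarts=n_restarts)


# --------------------------------------------------------------------------
# Coherence and K selection
# --------------------------------------------------------------------------

def coherence_score(model: TopicModel, data: DocTermData,
                    top_n: int = 10) -> np.ndarray:
    """UMass intrinsic coherence of each topic's ``top_n`` words.

    For the rank-ordered top words w_1..w_M of a topic the score is
    Σ_{m=2..M} Σ_{l<m} log((D(w_m, w_l) + 1) / D(w_l)), with D(·) the
    document frequency and D(·,·) the codocument frequency in ``data``.
    Higher (closer to 0) is better.  Top words with zero document
    frequency are excluded from pairs with a warning.
    """
    binary = (data.dtm > 0).astype(np.int64)
    doc_freq = np.asarray(binary.sum(axis=0)).ravel()
    scores = np.empty(model.K)
    for k in range(model.K):
        top = np.argsort(-model.phi[k])[:top_n]
        top = [w for w in top if doc_freq[w] > 0 or
               _warn_zero_df(model.vocabulary[w], k)]
        top = [w for w in top if doc_freq[w] > 0]
        sub = binary[:, top]
        co = (sub.T @ sub).toarray()
        s = 0.0
        for m in range(1, len(top)):
            for l in range(m):
                s += np.log((co[m, l] + 1.0) / doc_freq[top[l]])
        scores[k] = s
    return scores


def _warn_zero_df(word: str, topic: int) -> bool:
    warnings.warn(f"top word {word!r} of topic {topic} has zero document "
                  "frequency; excluded from coherence pairs")
    return False


def select_k(data: DocTermData, k_grid: Sequence[int],
             params: TopicModelParams,
             records: Sequence[TweetRecord] | None = None,
             top_n: int = 10) -> dict:
    """Fit one model per K and recommend the coherence-maximizing K.

    Every fit uses the same seed and sampler settings from ``params``.
    Infeasible K values (> vocabulary size) are skipped and noted.  The
    result includes a human-review sheet (top words, and top tweets when
    ``records`` is given) because the final choice of K conventionally
    involves manual review of topic interpretability.
    """
    if not len(k_grid):
        raise ValueError("k_grid must be nonempty")
    rows, models, review = [], {}, {}
    for K in k_grid:
        if K > data.n_terms:
            logger.warning("K=%d exceeds vocabulary size %d; skipped",
                           K, data.n_terms)
            rows.append({"K": K, "mean_coherence": np.nan,
                         "final_log_likelihood": np.nan, "skipped": True})
            continue
        p = TopicModelParams(
            K=K, alpha=params.alpha, beta=params.beta,
            n_iterations=params.n_iterations, burn_in=params.burn_in,
            thin=params.thin, seed=params.seed,
            min_doc_freq=params.min_doc_freq,
            max_doc_prop=params.max_doc_prop, stopwords=params.stopwords)
        try:
            model = fit_lda(data, p)
        except ValueError as exc:
            logger.warning("K=%d failed: %s", K, exc)
            rows.append({"K": K, "mean_coherence": np.nan,
                         "final_log_likelihood": np.nan, "skipped": True})
            continue
        model.coherence = coherence_score(model, data, top_n=top_n)
        models[K] = model
        rows.append({"K": K,
                     "mean_coherence": float(np.mean(model.coherence)),
                     "final_log_likelihood": float(model.log_likelihood_trace[-1]),
                     "skipped": False})
        sheet = {k: {"top_words": top_words(model, k, top_n)} for k in range(K)}
        if records is not None:
            by_id = {r.id: r for r in records}
            for k in range(K):
                ids = top_tweets(model, k, top_n)
                sheet[k]["top_tweets"] = [by_id[i].text for i in ids
                                          if i in by_id]
        review[K] = sheet
    report = pd.DataFrame(rows)
    valid = report.dropna(subset=["mean_coherence"])
    recommended = (int(valid.loc[valid["mean_coherence"].idxmax(), "K"])
                   if len(valid) else None)
    return {"report": report, "recommended_k": recommended,
            "models": models, "review_sheet": review}


# --------------------------------------------------------------------------
# Topic summaries
# --------------------------------------------------------------------------

def top_words(model: TopicModel, topic: int, n: int = 10) -> list[str]:
    """Top-``n`` words of one topic, by φ descending (ties by term)."""
    if not 0 <= topic < model.K:
        raise IndexError(f"topic {topic} out of range [0, {model.K})")
    order = sorted(range(len(model.vocabulary)),
                   key=lambda w: (-model.phi[topic, w], model.vocabulary[w]))
    return [model.vocabulary[w] for w in order[:n]]


def top_tweets(model: TopicModel, topic: int, n: int = 10) -> list[str]:
    """Ids of the ``n`` tweets most associated with a topic (θ descending,
    ties broken by id for determinism)."""
    if not 0 <= topic < model.K:
        raise IndexError(f"topic {topic} out of range [0, {model.K})")
    order = sorted(range(len(model.doc_ids)),
                   key=lambda d: (-model.theta[d, topic], model.doc_ids[d]))
    return [model.doc_ids[d] for d in order[:n]]


def sample_tweets(model: TopicModel, topic: int, n: int = 20,
                  seed: int = 0) -> list[str]:
    """Random sample of tweets whose modal topic is ``topic``."""
    if not 0 <= topic < model.K:
        raise IndexError(f"topic {topic} out of range [0, {model.K})")
    modal = np.argmax(model.theta, axis=1)
    pool = [model.doc_ids[d] for d in np.flatnonzero(modal == topic)]
    rng = np.random.default_rng(seed)
    if len(pool) <= n:
        return sorted(pool)
    return sorted(rng.choice(np.array(pool, dtype=object), size=n,
                             replace=False).tolist())


# --------------------------------------------------------------------------
# Recovery diagnostics
# --------------------------------------------------------------------------

def recovery_cosine(model: TopicModel, truth_vocabulary: Sequence[str],
                    truth_phi: np.ndarray) -> np.ndarray:
    """Hungarian-matched cosines between fitted and planted topics.

    Restricts both topic-word matrices to the shared vocabulary (pruning
    removes planted words and adds lexicon fillers), renormalizes, and
    matches topics one-to-one by cosine similarity.
    """
    vmap = {w: i for i, w in enumerate(truth_vocabulary)}
    keep = [i for i, w in enumerate(model.vocabulary) if w in vmap]
    if not keep:
        raise ValueError("no shared vocabulary between model and truth")
    cols = [vmap[model.vocabulary[i]] for i in keep]
    phi_true = truth_phi[:, cols]
    phi_true = phi_true / phi_true.sum(axis=1, keepdims=True)
    phi_est = model.phi[:, keep]
    phi_est = phi_est / phi_est.sum(axis=1, keepdims=True)
    return matched_cosine(phi_est, phi_true)[1]


def matched_cosine(phi_est: np.ndarray, phi_true: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian-match estimated to true topics by cosine similarity.

    Returns (assignment, cosines): ``assignment[j]`` is the estimated
    topic matched to true topic j, and ``cosines[j]`` their cosine
    similarity.  Used for planted-topic recovery checks.
    """
    a = phi_est / np.linalg.norm(phi_est, axis=1, keepdims=True)
    b = phi_true / np.linalg.norm(phi_true, axis=1, keepdims=True)
    sim = b @ a.T                       # (K_true, K_est)
    row, col = linear_sum_assignment(-sim)
    return col, sim[row, col]
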