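"""Latent topic modelling of abstracts.

Abstracts are preprocessed (lowercasing, punctuation/number stripping,
stopword removal, Porter stemming, document-frequency pruning) and fitted
with the standard mixture-of-topics generative model: each document draws a
topic-weight vector θ_d from a symmetric Dirichlet(α), each topic k a word
distribution φ_k from Dirichlet(β), and every token draws a topic from θ_d
then a word from φ_z.  Estimation is by collapsed Gibbs sampling, with the
document- and word-probability tables reported as posterior means averaged
over post-burn-in samples.

The headline summaries follow the audit's reporting conventions: each
abstract is *assigned* to its most probable topic, and the **dominance
ratio** — the weight of the top topic over the runner-up — is averaged over
the abstracts assigned to each topic, quantifying how decisively documents
belong where they were put.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .records import BiblioRecord, CorpusError
from .stemming import STOPWORDS, porter_stem

__all__ = [
    "PreprocessConfig", "TopicModel", "TopicSummary", "preprocess_abstracts",
    "preprocess_texts", "fit_topic_model", "dominant_topic_assignment",
    "topic_summary", "perplexity_by_k",
]

_TOKEN = re.compile(r"[a-z]+")


@dataclass
class PreprocessConfig:
    min_df: int = 1          # documents a token must appear in
    max_df_frac: float = 1.0  # fraction of documents a token may appear in
    min_token_len: int = 2
    stem: bool = True


def _tokenize(text: str, config: PreprocessConfig) -> list[str]:
    toks = _TOKEN.findall(text.lower())
    toks = [t for t in toks
            if len(t) >= config.min_token_len and t not in STOPWORDS]
    if config.stem:
        toks = [porter_stem(t) for t in toks]
    return toks


def preprocess_texts(texts: Sequence[str],
                     config: PreprocessConfig | None = None
                     ) -> tuple[list[list[str]], list[str], list[int]]:
    """Tokenize + stem + prune; returns (token lists, vocabulary, kept idx).

    Documents left empty after preprocessing are dropped; their original
    indices are omitted from ``kept``.
    """
    config = config or PreprocessConfig()
    tokenized = [_tokenize(t, config) for t in texts]
    n_docs_nonempty = sum(bool(t) for t in tokenized)
    if n_docs_nonempty == 0:
        raise CorpusError("all documents empty after preprocessing")
    df: dict[str, int] = {}
    for toks in tokenized:
        for t in set(toks):
            df[t] = df.get(t, 0) + 1
    max_df = config.max_df_frac * n_docs_nonempty
    vocab = sorted(t for t, n in df.items()
                   if n >= config.min_df and n <= max_df)
    vset = set(vocab)
    out_tokens: list[list[str]] = []
    kept: list[int] = []
    for i, toks in enumerate(tokenized):
        toks = [t for t in toks if t in vset]
        if toks:
            out_tokens.append(toks)
            kept.append(i)
    if not out_tokens:
        raise CorpusError("all documents empty after vocabulary pruning")
    return out_tokens, vocab, kept


def preprocess_abstracts(records: Sequence[BiblioRecord],
                         config: PreprocessConfig | None = None
                         ) -> tuple[list[list[str]], list[str], list[str]]:
    """Preprocess record abstracts; empty-abstract records are dropped.

    Returns (token lists, vocabulary, record ids kept, in order).
    """
    recs = [r for r in records if r.abstract.strip()]
    if not recs:
        raise CorpusError("no non-empty abstracts to model")
    tokens, vocab, kept = preprocess_texts([r.abstract for r in recs], config)
    return tokens, vocab, [recs[i].record_id for i in kept]


@dataclass
class TopicModel:
    k: int
    word_topic: np.ndarray   # (k, V) rows sum to 1
    doc_topic: np.ndarray    # (n_docs, k) rows sum to 1
    vocabulary: list[str]
    doc_ids: list[str]
    seed: int
    alpha: float
    beta: float
    n_iter: int
    burn_in: int

    def top_words(self, topic: int, n: int = 7) -> list[tuple[str, float]]:
        order = np.argsort(-self.word_topic[topic])[:n]
        return [(self.vocabulary[i], float(self.word_topic[topic, i]))
                for i in order]


@njit(cache=True)
def _gibbs_kernel(doc_of, word_of, n_docs, V, K, alpha, beta,
                  n_iter, burn_in, sample_every, seed):  # pragma: no cover
    np.random.seed(seed)
    N = doc_of.shape[0]
    z = np.empty(N, dtype=np.int64)
    ndk = np.zeros((n_docs, K), dtype=np.float64)
    nkw = np.zeros((K, V), dtype=np.float64)
    nk = np.zeros(K, dtype=np.float64)
    for i in range(N):
        t = np.int64(np.random.randint(0, K))
        z[i] = t
        ndk[doc_of[i], t] += 1.0
        nkw[t, word_of[i]] += 1.0
        nk[t] += 1.0
    acc_doc = np.zeros((n_docs, K), dtype=np.float64)
    acc_word = np.zeros((K, V), dtype=np.float64)
    n_samples = 0
    p = np.empty(K, dtype=np.float64)
    for it in range(n_iter):
        for i in range(N):
            d = doc_of[i]
            w = word_of[i]
            t = z[i]
            ndk[d, t] -= 1.0
            nkw[t, w] -= 1.0
            nk[t] -= 1.0
            total = 0.0
            for k in range(K):
                pk = (ndk[d, k] + alpha) * (nkw[k, w] + beta) / (nk[k] + V * beta)
                total += pk
                p[k] = total
            u = np.random.random() * total
            t_new = K - 1
            for k in range(K):
                if u <= p[k]:
                    t_new = k
                    break
            z[i] = t_new
            ndk[d, t_new] += 1.0
            nkw[t_new, w] += 1.0
            nk[t_new] += 1.0
        if it >= burn_in and (it - burn_in) % sample_every == 0:
            n_samples += 1
            for d in range(n_docs):
                row_total = 0.0
                for k in range(K):
                    row_total += ndk[d, k]
                for k in range(K):
                    acc_doc[d, k] += (ndk[d, k] + alpha) / (row_total + K * alpha)
            for k in range(K):
                for w in range(V):
                    acc_word[k, w] += (nkw[k, w] + beta) / (nk[k] + V * beta)
    return acc_doc / n_samples, acc_word / n_samples


def fit_topic_model(token_lists: Sequence[Sequence[str]], k: int,
                    alpha: float | None = None, beta: float = 0.01,
                    n_iter: int = 2000, burn_in: int = 500,
                    sample_every: int = 10, seed: int = 0,
                    vocabulary: Sequence[str] | None = None,
                    doc_ids: Sequence[str] | None = None) -> TopicModel:
    """Collapsed-Gibbs fit of the mixture-of-topics model.

    ``alpha`` defaults to 1/k (a weakly informative symmetric prior under
    which near-single-topic documents stay near-single-topic in the
    posterior mean); ``beta`` defaults to 0.01.  Deterministic given ``seed``.
    """
    if k < 2:
        raise CorpusError("topic model needs k >= 2")
    if len(token_lists) < k:
        raise CorpusError("need at least k documents")
    if alpha is None:
        alpha = 1.0 / k
    if vocabulary is None:
        vocabulary = sorted({t for toks in token_lists for t in toks})
    if len(vocabulary) < 2:
        raise CorpusError("vocabulary smaller than 2")
    index = {t: i for i, t in enumerate(vocabulary)}
    doc_of, word_of = [], []
    for d, toks in enumerate(token_lists):
        for t in toks:
            doc_of.append(d)
            word_of.append(index[t])
    if not doc_of:
        raise CorpusError("no tokens to model")
    doc_arr = np.asarray(doc_of, dtype=np.int64)
    word_arr = np.asarray(word_of, dtype=np.int64)
    if burn_in >= n_iter:
        raise CorpusError("burn_in must be smaller than n_iter")
    doc_topic, word_topic = _gibbs_kernel(
        doc_arr, word_arr, len(token_lists), len(vocabulary), k,
        float(alpha), float(beta), int(n_iter), int(burn_in),
        int(sample_every), int(seed) % (2 ** 31))
    return TopicModel(
        k=k, word_topic=word_topic, doc_topic=doc_topic,
        vocabulary=list(vocabulary),
        doc_ids=list(doc_ids) if doc_ids is not None
        else [str(i) for i in range(len(token_lists))],
        seed=seed, alpha=float(alpha), beta=float(beta),
        n_iter=n_iter, burn_in=burn_in)


def dominant_topic_assignment(model: TopicModel
                              ) -> dict[str, tuple[int, float]]:
    """Per-document most probable topic and its dominance ratio.

    The ratio is top weight / second weight (≥ 1); ties go to the lowest
    topic id and score a ratio of exactly 1.
    """
    if model.k < 2:
        raise CorpusError("dominance needs k >= 2")
    out: dict[str, tuple[int, float]] = {}
    for i, doc_id in enumerate(model.doc_ids):
        weights = model.doc_topic[i]
        order = np.lexsort((np.arange(model.k), -weights))
        top, second = order[0], order[1]
        ratio = float(weights[top] / weights[second])
        out[doc_id] = (int(top), ratio)
    return out


@dataclass
class TopicSummary:
    """Per-topic document share (%), mean dominance ratio, top stems."""

    shares_pct: dict[int, float]
    mean_ratio: dict[int, float]
    top_words: dict[int, list[tuple[str, float]]]
    n_documents: int = 0

    def to_frame(self):
        import pandas as pd

        rows = []
        for t in sorted(self.shares_pct):
            rows.append({
                "topic": t,
                "share_pct": self.shares_pct[t],
                "mean_dominance_ratio": self.mean_ratio[t],
                "top_words": " ".join(w for w, _ in self.top_words[t]),
            })
        return pd.DataFrame(rows)


def topic_summary(model: TopicModel,
                  assignments: dict[str, tuple[int, float]] | None = None,
                  top_n: int = 7) -> TopicSummary:
    """Document shares, mean dominance ratios, and top-n stems per topic."""
    if assignments is None:
        assignments = dominant_topic_assignment(model)
    n = len(assignments)
    shares: dict[int, float] = {}
    ratios: dict[int, float] = {}
    for t in range(model.k):
        docs = [r for (tt, r) in assignments.values() if tt == t]
        shares[t] = round(100.0 * len(docs) / n, 1) if n else 0.0
        ratios[t] = round(float(np.mean(docs)), 2) if docs else float("nan")
    top = {t: model.top_words(t, top_n) for t in range(model.k)}
    return TopicSummary(shares, ratios, top, n_documents=n)


def perplexity_by_k(token_lists: Sequence[Sequence[str]],
                    k_values: Sequence[int], seed: int = 0,
                    **fit_kwargs) -> dict[int, float]:
    """Helper: held-in perplexity across candidate k (no automatic choice)."""
    out: dict[int, float] = {}
    for k in k_values:
        model = fit_topic_model(token_lists, k, seed=seed, **fit_kwargs)
        index = {t: i for i, t in enumerate(model.vocabulary)}
        ll = 0.0
        n_tok = 0
        for d, toks in enumerate(token_lists):
            probs = model.doc_topic[d] @ model.word_topic
            for t in toks:
                ll += float(np.log(probs[index[t]] + 1e-300))
                n_tok += 1
        out[k] = float(np.exp(-ll / n_tok))
    return out
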