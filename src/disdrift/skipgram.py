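"""Minimal seeded skip-gram trainer with negative sampling.

Classic sequential SGD (one update per center/context pair), with the
inner loop JIT-compiled via numba.  Deterministic under a fixed seed:
vocabulary order is fixed by (count desc, token asc), per-epoch pair
order and negative samples are pre-drawn from one
``numpy.random.Generator``, and the update loop is single-threaded.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
from numba import njit

__all__ = ["train_skipgram"]


def _build_vocab(
    sentences: Sequence[Sequence[str]], min_count: int
) -> tuple[list[str], dict[str, int], np.ndarray]:
    counts = Counter(tok for sent in sentences for tok in sent)
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    if not kept:
        raise ValueError("all tokens fall below min_count; empty vocabulary")
    index = {t: i for i, t in enumerate(kept)}
    freqs = np.array([counts[t] for t in kept], dtype=float)
    return kept, index, freqs


def _build_pairs(
    sentences: Sequence[Sequence[str]], index: dict[str, int], window: int
) -> tuple[np.ndarray, np.ndarray]:
    centers: list[int] = []
    contexts: list[int] = []
    for sent in sentences:
        ids = [index[t] for t in sent if t in index]
        n = len(ids)
        for i, c in enumerate(ids):
            lo = max(0, i - window)
            hi = min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    if not centers:
        raise ValueError("corpus yields no training pairs")
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


@njit(cache=True)
def _sgd_epoch(
    W_in, W_out, centers, contexts, order, negs, step0, total_steps, lr_start
):  # pragma: no cover - exercised through train_skipgram
    n = order.shape[0]
    k = negs.shape[1]
    dim = W_in.shape[1]
    for ii in range(n):
        frac = (step0 + ii) / total_steps
        lr = np.float32(lr_start * max(1.0 - frac, 1e-4))
        i = order[ii]
        c = centers[i]
        o = contexts[i]
        gv = np.zeros(dim, dtype=np.float32)
        # positive pair, label 1
        s = np.float32(0.0)
        for d in range(dim):
            s += W_in[c, d] * W_out[o, d]
        if s > 30.0:
            s = np.float32(30.0)
        elif s < -30.0:
            s = np.float32(-30.0)
        g = np.float32((1.0 / (1.0 + np.exp(-s)) - 1.0) * lr)
        for d in range(dim):
            gv[d] += g * W_out[o, d]
            W_out[o, d] -= g * W_in[c, d]
        # negative samples, label 0
        for kk in range(k):
            t = negs[ii, kk]
            if t == o:
                continue
            s = np.float32(0.0)
            for d in range(dim):
                s += W_in[c, d] * W_out[t, d]
            if s > 30.0:
                s = np.float32(30.0)
            elif s < -30.0:
                s = np.float32(-30.0)
            g = np.float32((1.0 / (1.0 + np.exp(-s))) * lr)
            for d in range(dim):
                gv[d] += g * W_out[t, d]
                W_out[t, d] -= g * W_in[c, d]
        for d in range(dim):
            W_in[c, d] -= gv[d]


def train_skipgram(
    sentences: Sequence[Sequence[str]],
    dim: int = 64,
    window: int = 10,
    epochs: int = 10,
    min_count: int = 1,
    negative: int = 5,
    learning_rate: float = 0.025,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Train skip-gram embeddings with negative sampling.

    Returns a token -> vector map (float32, length ``dim``).  The
    exposed vector is the sum of the input (center) and output (context)
    vectors: the cross terms of the dot product then carry first-order
    co-occurrence (a token that directly co-occurs with an outcome token
    scores high), while the within-matrix terms carry distributional
    similarity.  Negative samples follow the unigram distribution raised
    to 3/4; the learning rate decays linearly over all pair updates.
    """
    vocab, index, freqs = _build_vocab(sentences, min_count)
    centers, contexts = _build_pairs(sentences, index, window)
    n_vocab, n_pairs = len(vocab), centers.shape[0]

    rng = np.random.default_rng(seed)
    W_in = ((rng.random((n_vocab, dim)) - 0.5) / dim).astype(np.float32)
    W_out = np.zeros((n_vocab, dim), dtype=np.float32)

    noise = freqs**0.75
    noise /= noise.sum()

    total_steps = max(epochs * n_pairs, 1)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        negs = rng.choice(n_vocab, size=(n_pairs, negative), p=noise).astype(np.int64)
        _sgd_epoch(
            W_in, W_out, centers, contexts, order, negs, step, total_steps, learning_rate
        )
        step += n_pairs

    combined = W_in + W_out
    return {t: combined[i].copy() for t, i in index.items()}
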