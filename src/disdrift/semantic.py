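"""Semantic characterization: embeddings of health care events and
chunk-tagged outcome tokens, and similarity-shift ranking.

High-granularity cohorts become per-patient token sequences with the
chunk-specific outcome token appended; low-granularity cohorts are
discretized and turned into a bipartite patient-attribute graph whose
random walks feed the same skip-gram trainer.  All chunks are embedded
in ONE shared space so outcome tokens from different chunks are
mutually comparable.  A TF-IDF + spectral-clustering comparator is
included as the non-semantic baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering
from sklearn.feature_extraction.text import TfidfTransformer
from sklearn.metrics import silhouette_score
from sklearn.metrics.pairwise import cosine_similarity

from disdrift.data_model import (
    ChunkedDataset,
    Mode,
    PatientRecord,
    one_hot_matrix,
    outcome_token_id,
)
from disdrift.skipgram import train_skipgram

PATIENT_PREFIX = "patient:"


# ---------------------------------------------------------------------------
# corpus construction (high granularity)
# ---------------------------------------------------------------------------


@dataclass
class TokenCorpus:
    """Per-patient ordered token sequences ending in a chunk-tagged
    outcome token."""

    sequences: list[list[str]]
    outcome_token_map: dict[tuple[str, str], str]
    n_empty_patients: int = 0


def build_sequence_corpus(
    dataset: ChunkedDataset, include_survivors: bool = True
) -> TokenCorpus:
    """Per patient: temporally ordered events followed by the
    (category, chunk)-specific outcome token.  Both outcome categories
    get distinct tokens; ``include_survivors=False`` drops the
    non-interest category's token (sequences then end with the last
    event)."""
    if dataset.mode is not Mode.HIGH:
        raise ValueError("sequence corpora require a high-granularity cohort")
    interest = dataset.outcome_categories[0] if dataset.outcome_categories else None
    sequences: list[list[str]] = []
    token_map: dict[tuple[str, str], str] = {}
    n_empty = 0
    for rec in dataset.records:
        seq = list(rec.events or ())
        if not seq:
            n_empty += 1
        if rec.outcome is not None and (include_survivors or rec.outcome == interest):
            tok = outcome_token_id(rec.outcome, rec.chunk_label)
            token_map[(rec.outcome, rec.chunk_label)] = tok
            seq.append(tok)
        sequences.append(seq)
    if n_empty:
        warnings.warn(
            f"{n_empty} patient(s) had zero events; included as outcome-only sequences",
            stacklevel=2,
        )
    return TokenCorpus(sequences, token_map, n_empty)


# ---------------------------------------------------------------------------
# discretization + patient graph (low granularity)
# ---------------------------------------------------------------------------


def discretize_continuous(
    dataset: ChunkedDataset, n_bins: int = 5
) -> ChunkedDataset:
    """Tokenize a low-granularity cohort: continuous features by
    equal-width binning on the pooled cohort range (``feature=binK``,
    edges left-closed/right-open, top bin right-closed; a value exactly
    on an interior edge goes to the upper bin), categorical features as
    ``feature=value`` tokens.  Returns a high-granularity-shaped cohort
    whose per-patient "events" are the attribute tokens."""
    if dataset.mode is not Mode.LOW:
        raise ValueError("discretize_continuous expects a low-granularity cohort")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    frame = pd.DataFrame([r.attributes for r in dataset.records])
    numeric_cols = list(frame.select_dtypes(include=[np.number]).columns)
    other_cols = [c for c in frame.columns if c not in numeric_cols]

    edges: dict[str, np.ndarray] = {}
    for col in numeric_cols:
        lo, hi = float(frame[col].min()), float(frame[col].max())
        if not np.isfinite(lo) or not np.isfinite(hi):
            raise ValueError(f"feature {col!r} has non-finite values")
        if lo == hi:
            warnings.warn(f"feature {col!r} is constant; single bin", stacklevel=2)
            edges[col] = np.array([])
        else:
            edges[col] = np.linspace(lo, hi, n_bins + 1)[1:-1]  # interior edges

    records: list[PatientRecord] = []
    for row_idx, rec in enumerate(dataset.records):
        tokens: list[str] = []
        for col in numeric_cols:
            value = float(frame.iloc[row_idx][col])
            b = int(np.digitize(value, edges[col], right=False)) if edges[col].size else 0
            tokens.append(f"{col}=bin{b}")
        for col in other_cols:
            tokens.append(f"{col}={frame.iloc[row_idx][col]}")
        records.append(
            PatientRecord(
                patient_id=rec.patient_id,
                chunk_label=rec.chunk_label,
                events=tuple(tokens),
                outcome=rec.outcome,
            )
        )
    return ChunkedDataset(
        mode=Mode.HIGH,
        chunks=dataset.chunks,
        records=tuple(records),
        reference_chunk=dataset.reference_chunk,
        outcome_categories=dataset.outcome_categories,
    )


def build_patient_graph(dataset: ChunkedDataset) -> nx.Graph:
    """Bipartite patient-token graph: one node per patient, attribute
    token and (outcome, chunk) token; an edge for each attribute a
    patient holds and one to the patient's chunk-specific outcome node."""
    if dataset.mode is not Mode.HIGH:
        raise ValueError("build_patient_graph expects a tokenized (discretized) cohort")
    g = nx.Graph()
    for rec in dataset.records:
        pnode = f"{PATIENT_PREFIX}{rec.patient_id}"
        g.add_node(pnode, bipartite=0)
        for tok in rec.events or ():
            g.add_node(tok, bipartite=1)
            g.add_edge(pnode, tok, weight=1.0)
        if rec.outcome is not None:
            onode = outcome_token_id(rec.outcome, rec.chunk_label)
            g.add_node(onode, bipartite=1)
            g.add_edge(pnode, onode, weight=1.0)
    return g


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingTable:
    """Token -> vector map from one training run, with cosine queries."""

    dimension: int
    vectors: dict[str, np.ndarray]
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tok, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise ValueError(f"vector for {tok!r} has wrong dimension")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def similarity(self, a: str, b: str) -> float:
        u, v = self.vectors[a], self.vectors[b]
        return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

    def save_word2vec(self, path) -> None:
        """Word2vec text format: header ``count dim`` then one token and
        its floats per line."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vectors)} {self.dimension}\n")
            for tok in sorted(self.vectors):
                floats = " ".join(f"{x:.6f}" for x in self.vectors[tok])
                fh.write(f"{tok} {floats}\n")

    @classmethod
    def load_word2vec(cls, path) -> "EmbeddingTable":
        with open(path) as fh:
            n, dim = (int(x) for x in fh.readline().split())
            vectors = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]], dtype=np.float32)
        if len(vectors) != n:
            raise ValueError("word2vec file header disagrees with line count")
        return cls(dim, vectors)


def train_sequence_embeddings(
    corpus: TokenCorpus,
    dimension: int = 64,
    window: int = 10,
    epochs: int = 10,
    min_count: int = 1,
    negative: int = 5,
    learning_rate: float = 0.05,
    seed: int = 0,
) -> EmbeddingTable:
    """One joint skip-gram model over all sequences so per-chunk outcome
    tokens share a space and are mutually comparable."""
    if not corpus.sequences:
        raise ValueError("empty corpus")
    vectors = train_skipgram(
        corpus.sequences,
        dim=dimension,
        window=window,
        epochs=epochs,
        min_count=min_count,
        negative=negative,
        learning_rate=learning_rate,
        seed=seed,
    )
    meta = {
        "algorithm": "sgns",
        "window": window,
        "epochs": epochs,
        "min_count": min_count,
        "seed": seed,
    }
    return EmbeddingTable(dimension, vectors, meta)


def generate_walks(
    graph: nx.Graph,
    walk_length: int = 20,
    walks_per_node: int = 10,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
) -> list[list[str]]:
    """Second-order biased random walks (node2vec style).  ``p`` is the
    return parameter, ``q`` the in-out parameter; with p = q = 1 walks
    reduce to uniform first-order walks.  Isolated nodes are excluded
    with a warning."""
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    neighbors = {n: sorted(graph.neighbors(n)) for n in nodes}
    isolated = [n for n in nodes if not neighbors[n]]
    if isolated:
        warnings.warn(
            f"{len(isolated)} isolated node(s) excluded from walks", stacklevel=2
        )
    walks: list[list[str]] = []
    uniform = p == 1.0 and q == 1.0
    for _ in range(walks_per_node):
        for start in nodes:
            if not neighbors[start]:
                continue
            walk = [start]
            while len(walk) < walk_length:
                cur = walk[-1]
                nbrs = neighbors[cur]
                if not nbrs:
                    break
                if uniform or len(walk) == 1:
                    nxt = nbrs[rng.integers(len(nbrs))]
                else:
                    prev = walk[-2]
                    prev_nbrs = set(neighbors[prev])
                    w = np.empty(len(nbrs))
                    for i, cand in enumerate(nbrs):
                        if cand == prev:
                            w[i] = 1.0 / p
                        elif cand in prev_nbrs:
                            w[i] = 1.0
                        else:
                            w[i] = 1.0 / q
                    w /= w.sum()
                    nxt = nbrs[rng.choice(len(nbrs), p=w)]
                walk.append(nxt)
            walks.append(walk)
    return walks


def train_graph_embeddings(
    graph: nx.Graph,
    dimension: int = 64,
    walk_length: int = 20,
    walks_per_node: int = 10,
    p: float = 1.0,
    q: float = 1.0,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    learning_rate: float = 0.05,
    seed: int = 0,
) -> EmbeddingTable:
    """Random-walk corpora fed to the shared skip-gram trainer."""
    walks = generate_walks(
        graph,
        walk_length=walk_length,
        walks_per_node=walks_per_node,
        p=p,
        q=q,
        seed=seed,
    )
    vectors = train_skipgram(
        walks,
        dim=dimension,
        window=window,
        epochs=epochs,
        min_count=1,
        negative=negative,
        learning_rate=learning_rate,
        seed=seed,
    )
    meta = {
        "algorithm": "node2vec-sgns",
        "walk_length": walk_length,
        "walks_per_node": walks_per_node,
        "p": p,
        "q": q,
        "window": window,
        "epochs": epochs,
        "seed": seed,
    }
    return EmbeddingTable(dimension, vectors, meta)


# ---------------------------------------------------------------------------
# similarity shifts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimilarityDelta:
    """Change in a token's cosine similarity to the outcome between the
    first and last chunk."""

    token_id: str
    sim_first: float
    sim_last: float
    delta: float
    direction: str
    chapter: str | None = None


def similarity_change(
    embeddings: EmbeddingTable,
    outcome_category: str,
    first_chunk: str,
    last_chunk: str,
    tokens: Sequence[str] | None = None,
    chapter_map: Mapping[str, str] | None = None,
) -> list[SimilarityDelta]:
    """Per token, ``cos(token, outcome@last) - cos(token, outcome@first)``,
    sorted descending (ties by token id)."""
    tok_first = outcome_token_id(outcome_category, first_chunk)
    tok_last = outcome_token_id(outcome_category, last_chunk)
    for tok, chunk in ((tok_first, first_chunk), (tok_last, last_chunk)):
        if tok not in embeddings:
            raise ValueError(f"outcome token for chunk {chunk!r} not embedded ({tok!r})")
    if tokens is None:
        tokens = [t for t in embeddings.vectors if "@" not in t and not t.startswith(PATIENT_PREFIX)]
    deltas = []
    for tok in tokens:
        if tok not in embeddings:
            raise ValueError(f"token {tok!r} not embedded")
        s1 = embeddings.similarity(tok, tok_first)
        s2 = embeddings.similarity(tok, tok_last)
        d = s2 - s1
        deltas.append(
            SimilarityDelta(
                token_id=tok,
                sim_first=s1,
                sim_last=s2,
                delta=d,
                direction="more similar" if d >= 0 else "less similar",
                chapter=chapter_map.get(tok) if chapter_map else None,
            )
        )
    return sorted(deltas, key=lambda x: (-x.delta, x.token_id))


def deltas_to_frame(deltas: Sequence[SimilarityDelta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "token": d.token_id,
                "chapter": d.chapter,
                "sim_first": d.sim_first,
                "sim_last": d.sim_last,
                "delta": d.delta,
                "direction": d.direction,
            }
            for d in deltas
        ]
    )


def aggregate_by_chapter(
    deltas: Sequence[SimilarityDelta], chapter_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Chapter-level table: unweighted mean of member deltas, member
    count and direction, sorted by delta descending."""
    rows = []
    for d in deltas:
        chapter = d.chapter if chapter_map is None else chapter_map.get(d.token_id)
        rows.append((d.token_id, chapter, d.delta))
    unmapped = sorted({t for t, ch, _ in rows if ch is None})
    if unmapped:
        raise ValueError(f"tokens without a chapter mapping: {unmapped}")
    df = pd.DataFrame(rows, columns=["token", "chapter", "delta"])
    # fixed member order => permutation-invariant floating-point means
    df = df.sort_values("token", kind="stable")
    agg = (
        df.groupby("chapter")["delta"]
        .agg(delta="mean", n_tokens="count")
        .reset_index()
        .sort_values(["delta", "chapter"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    agg["direction"] = np.where(agg["delta"] >= 0, "more similar", "less similar")
    return agg


# ---------------------------------------------------------------------------
# TF-IDF + spectral clustering comparator
# ---------------------------------------------------------------------------


@dataclass
class TfidfClusterResult:
    k: int
    assignments: np.ndarray
    silhouette_by_k: dict[int, float]
    top_features: dict[int, list[str]]
    chunk_cluster_frequency: pd.DataFrame


def tfidf_cluster_baseline(
    dataset: ChunkedDataset,
    k_range: tuple[int, int] = (2, 8),
    top_n: int = 5,
    seed: int = 0,
) -> TfidfClusterResult:
    """Patient = document, event = term.  TF-IDF matrix, spectral
    clustering on the cosine-similarity affinity for each k in
    ``k_range`` (inclusive), k chosen by max silhouette (cosine metric);
    reports the top-``top_n`` highest-mean-TF-IDF terms per cluster and
    the relative cluster frequency per chunk."""
    lo, hi = k_range
    if lo < 2:
        raise ValueError("k_range lower bound must be >= 2")
    counts, vocab, records = one_hot_matrix(dataset, binary=False)
    tfidf = TfidfTransformer().fit_transform(counts).toarray()
    affinity = np.clip(cosine_similarity(tfidf), 0.0, None)

    best_k, best_sil, best_labels = None, -np.inf, None
    sil_by_k: dict[int, float] = {}
    for k in range(lo, min(hi, len(records) - 1) + 1):
        sc = SpectralClustering(
            n_clusters=k, affinity="precomputed", random_state=seed, assign_labels="kmeans"
        )
        labels = sc.fit_predict(affinity)
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(tfidf, labels, metric="cosine"))
        sil_by_k[k] = sil
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels
    if best_k is None:
        raise ValueError("no k in range produced a valid clustering")

    top_features: dict[int, list[str]] = {}
    for c in range(best_k):
        mean_tfidf = tfidf[best_labels == c].mean(axis=0)
        order = sorted(range(len(vocab)), key=lambda i: (-mean_tfidf[i], vocab[i]))
        top_features[c] = [vocab[i] for i in order[:top_n]]

    chunk_of = [r.chunk_label for r in records]
    freq = (
        pd.crosstab(pd.Series(chunk_of, name="chunk"), pd.Series(best_labels, name="cluster"))
        .reindex(list(dataset.chunks))
        .fillna(0.0)
    )
    freq = freq.div(freq.sum(axis=1), axis=0)

    return TfidfClusterResult(
        k=best_k,
        assignments=best_labels,
        silhouette_by_k=sil_by_k,
        top_features=top_features,
        chunk_cluster_frequency=freq,
    )
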