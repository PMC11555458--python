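import numpy as np
import networkx as nx
import pytest
from sklearn.metrics import adjusted_rand_score

from disdrift.data_model import ChunkedDataset, Mode, PatientRecord
from disdrift.semantic import (
    EmbeddingTable,
    aggregate_by_chapter,
    build_patient_graph,
    build_sequence_corpus,
    discretize_continuous,
    generate_walks,
    similarity_change,
    SimilarityDelta,
    tfidf_cluster_baseline,
    train_graph_embeddings,
    train_sequence_embeddings,
)
from disdrift.skipgram import train_skipgram
from disdrift.synthetic import CohortConfig, generate_low_granularity


class TestSequenceCorpus:
    def test_outcome_token_appended(self):
        ds = ChunkedDataset(
            mode=Mode.HIGH,
            chunks=("2020",),
            records=(PatientRecord("p", "2020", events=("a", "b"), outcome="death"),),
        )
        corpus = build_sequence_corpus(ds)
        assert corpus.sequences == [["a", "b", "death@2020"]]

    def test_distinct_outcome_tokens_per_chunk(self, tiny_high):
        corpus = build_sequence_corpus(tiny_high)
        flat = {t for s in corpus.sequences for t in s}
        assert {"deceased@A", "deceased@B", "not_deceased@A", "not_deceased@B"} <= flat

    def test_one_sequence_per_patient(self, small_cohort):
        corpus = build_sequence_corpus(small_cohort)
        assert len(corpus.sequences) == small_cohort.n_patients

    def test_zero_event_patient_warned_and_included(self):
        ds = ChunkedDataset(
            mode=Mode.HIGH,
            chunks=("A",),
            records=(
                PatientRecord("p1", "A", events=(), outcome="deceased"),
                PatientRecord("p2", "A", events=("a",), outcome="deceased"),
            ),
        )
        with pytest.warns(UserWarning, match="zero events"):
            corpus = build_sequence_corpus(ds)
        assert corpus.sequences[0] == ["deceased@A"]
        assert corpus.n_empty_patients == 1

    def test_survivor_tokens_droppable(self, tiny_high):
        corpus = build_sequence_corpus(tiny_high, include_survivors=False)
        flat = {t for s in corpus.sequences for t in s}
        assert "not_deceased@A" not in flat
        assert "deceased@A" in flat


class TestDiscretize:
    def _ds(self, values, chunk="A"):
        recs = tuple(
            PatientRecord(f"p{i}", chunk, attributes={"v": float(x)}, outcome="not_deceased")
            for i, x in enumerate(values)
        )
        return ChunkedDataset(mode=Mode.LOW, chunks=(chunk,), records=recs)

    def test_equal_width_two_bins_with_closed_top(self):
        ds = discretize_continuous(self._ds(range(11)), n_bins=2)
        tokens = [r.events[0] for r in ds.records]
        assert tokens[:5] == ["v=bin0"] * 5
        assert tokens[5:] == ["v=bin1"] * 6  # 5..10 including max

    def test_interior_edge_goes_to_upper_bin(self):
        # range 0..10, 2 bins -> edge at 5; value 5 must land in bin1
        ds = discretize_continuous(self._ds([0, 5, 10]), n_bins=2)
        assert [r.events[0] for r in ds.records] == ["v=bin0", "v=bin1", "v=bin1"]

    def test_uniform_occupancy_four_bins(self):
        rng = np.random.default_rng(0)
        ds = discretize_continuous(self._ds(rng.uniform(0, 1, 4000)), n_bins=4)
        counts = np.zeros(4)
        for r in ds.records:
            counts[int(r.events[0].split("bin")[1])] += 1
        np.testing.assert_allclose(counts / 4000, 0.25, atol=0.03)

    def test_constant_feature_single_bin_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            ds = discretize_continuous(self._ds([2, 2, 2]), n_bins=3)
        assert {r.events[0] for r in ds.records} == {"v=bin0"}

    def test_categoricals_become_value_tokens(self, tiny_low):
        ds = discretize_continuous(tiny_low, n_bins=2)
        flat = {t for r in ds.records for t in r.events}
        assert "sex=female" in flat and "sex=male" in flat

    def test_bad_bins_rejected(self, tiny_low):
        with pytest.raises(ValueError):
            discretize_continuous(tiny_low, n_bins=1)


class TestPatientGraph:
    def test_counts_single_patient(self):
        ds = ChunkedDataset(
            mode=Mode.HIGH,
            chunks=("A",),
            records=(PatientRecord("p", "A", events=("x", "y", "z"), outcome="death"),),
        )
        g = build_patient_graph(ds)
        assert g.number_of_nodes() == 5  # patient + 3 attributes + outcome
        assert g.number_of_edges() == 4

    def test_shared_token_degree(self):
        ds = ChunkedDataset(
            mode=Mode.HIGH,
            chunks=("A",),
            records=(
                PatientRecord("p1", "A", events=("x",), outcome="death"),
                PatientRecord("p2", "A", events=("x",), outcome="death"),
            ),
        )
        g = build_patient_graph(ds)
        assert g.degree["x"] == 2

    def test_bipartite(self, tiny_low):
        g = build_patient_graph(discretize_continuous(tiny_low, n_bins=2))
        assert nx.is_bipartite(g)

    def test_outcome_nodes_chunk_specific(self, tiny_low):
        g = build_patient_graph(discretize_continuous(tiny_low, n_bins=2))
        assert "deceased@A" in g.nodes
        assert "not_deceased@B" in g.nodes


class TestSkipgramTraining:
    def test_coverage_and_dimension(self, small_cohort):
        corpus = build_sequence_corpus(small_cohort)
        table = train_sequence_embeddings(corpus, dimension=16, epochs=2, seed=0)
        all_tokens = {t for s in corpus.sequences for t in s}
        assert set(table.vectors) == all_tokens
        assert all(v.shape == (16,) for v in table.vectors.values())

    def test_seeded_determinism(self, small_cohort):
        corpus = build_sequence_corpus(small_cohort)
        a = train_sequence_embeddings(corpus, dimension=8, epochs=2, seed=3)
        b = train_sequence_embeddings(corpus, dimension=8, epochs=2, seed=3)
        for tok in a.vectors:
            np.testing.assert_array_equal(a.vectors[tok], b.vectors[tok])

    def test_cooccurrence_recovery(self):
        rng = np.random.default_rng(1)
        sents = []
        for i in range(1500):
            filler = [f"f{j}" for j in rng.integers(0, 8, 4)]
            sents.append(filler + (["x", "death@C"] if i % 2 == 0 else ["z", "alive@C"]))
        vec = train_skipgram(sents, dim=32, window=5, epochs=5, seed=2)

        def cos(a, b):
            u, v = vec[a], vec[b]
            return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

        assert cos("x", "death@C") > cos("z", "death@C")

    def test_min_count_filters_vocabulary(self):
        sents = [["a", "a", "b"]]
        vec = train_skipgram(sents, dim=4, min_count=2, epochs=1, seed=0)
        assert set(vec) == {"a"}

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            train_skipgram([["a"]], min_count=5)


class TestGraphEmbeddings:
    def _graph(self):
        ds = ChunkedDataset(
            mode=Mode.HIGH,
            chunks=("A",),
            records=tuple(
                PatientRecord(f"p{i}", "A", events=("x", "y") if i % 2 == 0 else ("u", "v"),
                              outcome="death")
                for i in range(20)
            ),
        )
        return build_patient_graph(ds)

    def test_all_connected_nodes_embedded(self):
        g = self._graph()
        table = train_graph_embeddings(g, dimension=8, walk_length=5, walks_per_node=2, epochs=2, seed=0)
        assert set(table.vectors) == set(g.nodes)

    def test_walks_deterministic(self):
        g = self._graph()
        assert generate_walks(g, seed=5) == generate_walks(g, seed=5)

    def test_isolated_node_excluded_with_warning(self):
        g = self._graph()
        g.add_node("lonely")
        with pytest.warns(UserWarning, match="isolated"):
            walks = generate_walks(g, walk_length=3, walks_per_node=1, seed=0)
        assert all("lonely" not in w for w in walks)

    def test_structural_equivalence_recovery(self):
        # tokens attached to identical patient sets embed closer than
        # tokens with disjoint patient sets
        g = self._graph()
        table = train_graph_embeddings(g, dimension=16, walk_length=10, walks_per_node=5, epochs=3, seed=1)
        assert table.similarity("x", "y") > table.similarity("x", "u")

    def test_biased_walk_parameters_accepted(self):
        g = self._graph()
        walks = generate_walks(g, walk_length=5, walks_per_node=1, p=0.5, q=2.0, seed=3)
        assert walks and all(len(w) <= 5 for w in walks)


class TestSimilarityChange:
    def _table(self):
        vecs = {
            "a": np.array([1.0, 0.0, 0.0], dtype=np.float32),
            "b": np.array([0.0, 1.0, 0.0], dtype=np.float32),
            "death@C0": np.array([1.0, 1.0, 0.0], dtype=np.float32),
            "death@C1": np.array([0.0, 1.0, 1.0], dtype=np.float32),
        }
        return EmbeddingTable(3, vecs)

    def test_outcome_token_self_similarity(self):
        table = self._table()
        deltas = similarity_change(table, "death", "C0", "C1", tokens=["death@C0"])
        assert deltas[0].sim_first == pytest.approx(1.0)

    def test_hand_computed_deltas_and_order(self):
        deltas = similarity_change(self._table(), "death", "C0", "C1", tokens=["a", "b"])
        by_tok = {d.token_id: d for d in deltas}
        assert by_tok["a"].delta == pytest.approx(0.0 - 1 / np.sqrt(2))
        assert by_tok["b"].delta == pytest.approx(1 / np.sqrt(2) - 1 / np.sqrt(2), abs=1e-7)
        assert deltas[0].token_id == "b"  # sorted descending
        assert by_tok["a"].direction == "less similar"

    def test_missing_outcome_token_named(self):
        with pytest.raises(ValueError, match="C9"):
            similarity_change(self._table(), "death", "C0", "C9", tokens=["a"])

    def test_deltas_bounded(self, small_cohort):
        corpus = build_sequence_corpus(small_cohort)
        table = train_sequence_embeddings(corpus, dimension=8, epochs=2, seed=0)
        deltas = similarity_change(
            table, "deceased", small_cohort.chunks[0], small_cohort.chunks[-1]
        )
        assert all(-2 <= d.delta <= 2 for d in deltas)


class TestChapterAggregation:
    def _delta(self, tok, d):
        return SimilarityDelta(tok, 0.0, d, d, "more similar" if d >= 0 else "less similar")

    def test_mean_of_members(self):
        deltas = [self._delta("a", 0.2), self._delta("b", 0.4)]
        agg = aggregate_by_chapter(deltas, {"a": "ch1", "b": "ch1"})
        assert agg.loc[0, "delta"] == pytest.approx(0.3)
        assert agg.loc[0, "direction"] == "more similar"

    def test_single_member_identity(self):
        agg = aggregate_by_chapter([self._delta("a", -0.7)], {"a": "ch1"})
        assert agg.loc[0, "delta"] == pytest.approx(-0.7)
        assert agg.loc[0, "direction"] == "less similar"

    def test_matches_loop_oracle_and_permutation_invariance(self):
        rng = np.random.default_rng(2)
        toks = [f"t{i}" for i in range(12)]
        cmap = {t: f"ch{i % 3}" for i, t in enumerate(toks)}
        vals = rng.normal(size=12)
        deltas = [self._delta(t, v) for t, v in zip(toks, vals)]
        agg1 = aggregate_by_chapter(deltas, cmap)
        perm = rng.permutation(12)
        agg2 = aggregate_by_chapter([deltas[i] for i in perm], cmap)
        assert agg1.equals(agg2)
        for ch in ("ch0", "ch1", "ch2"):
            members = [vals[i] for i, t in enumerate(toks) if cmap[t] == ch]
            expected = sum(members) / len(members)
            assert agg1.set_index("chapter").loc[ch, "delta"] == pytest.approx(expected)

    def test_unmapped_token_listed(self):
        with pytest.raises(ValueError, match="t_missing"):
            aggregate_by_chapter([self._delta("t_missing", 0.1)], {})


class TestTfidfBaseline:
    def _separable_dataset(self):
        rng = np.random.default_rng(4)
        recs = []
        for i in range(30):
            evs = tuple(rng.choice([f"g1_{j}" for j in range(8)], size=6))
            recs.append(PatientRecord(f"a{i}", "A", events=evs, outcome="not_deceased"))
        for i in range(30):
            evs = tuple(rng.choice([f"g2_{j}" for j in range(8)], size=6))
            recs.append(PatientRecord(f"b{i}", "B", events=evs, outcome="not_deceased"))
        return ChunkedDataset(mode=Mode.HIGH, chunks=("A", "B"), records=tuple(recs))

    def test_disjoint_groups_select_k2_with_perfect_ari(self):
        ds = self._separable_dataset()
        result = tfidf_cluster_baseline(ds, k_range=(2, 5), seed=0)
        assert result.k == 2
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, result.assignments) == 1.0

    def test_cluster_frequencies_sum_to_one(self):
        result = tfidf_cluster_baseline(self._separable_dataset(), k_range=(2, 4), seed=0)
        sums = result.chunk_cluster_frequency.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)

    def test_bad_k_range_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            tfidf_cluster_baseline(small_cohort, k_range=(1, 3))

    def test_top_features_come_from_cluster_vocab(self):
        result = tfidf_cluster_baseline(self._separable_dataset(), k_range=(2, 3), seed=0)
        prefixes = {c: {f.split("_")[0] for f in feats} for c, feats in result.top_features.items()}
        assert all(len(p) == 1 for p in prefixes.values())


class TestEmbeddingTableIO:
    def test_word2vec_roundtrip(self, tmp_path):
        vecs = {
            "a": np.array([0.5, -1.25], dtype=np.float32),
            "b@C1": np.array([1.0, 2.0], dtype=np.float32),
        }
        table = EmbeddingTable(2, vecs)
        path = tmp_path / "emb.txt"
        table.save_word2vec(path)
        back = EmbeddingTable.load_word2vec(path)
        assert back.dimension == 2
        np.testing.assert_allclose(back.vectors["a"], vecs["a"], atol=1e-6)

    def test_wrong_dimension_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingTable(3, {"a": np.zeros(2, dtype=np.float32)})
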