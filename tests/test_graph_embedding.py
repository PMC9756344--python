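"""WL tokenization and graph2vec training.

The brute-force oracle enumerates canonical rooted subtrees: the depth-d
descriptor of a node is built recursively from its own depth-(d-1)
descriptor and the sorted descriptors of its neighbours.  Two (node,
depth) pairs — in the same or different graphs — must receive equal WL
tokens exactly when their descriptors are equal.
"""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from redoxscreen import graph_embedding as ge
from redoxscreen import qm_features as qf

from conftest import (
    assert_tokens_match_oracle,
    random_attributed_graph,
)


class TestBuildGraph:
    def test_identical_molecules_give_identical_labeled_graphs(self, backend):
        graphs = []
        for k in range(2):
            mol = Chem.MolFromSmiles("CCO")
            feats = qf.compute_atom_features(mol, backend, f"m{k}")
            graphs.append(ge.build_attributed_graph(mol, feats, 3, f"m{k}"))
        assert graphs[0].labels == graphs[1].labels
        assert graphs[0].edges == graphs[1].edges

    def test_subrounding_perturbation_keeps_labels(self, backend):
        mol = Chem.MolFromSmiles("CCO")
        feats = qf.compute_atom_features(mol, backend, "m")
        base = ge.build_attributed_graph(mol, feats, 2, "m")
        feats[1].values[3] += 1e-4  # below half the 10^-2 rounding step
        bumped = ge.build_attributed_graph(mol, feats, 2, "m")
        assert base.labels == bumped.labels

    def test_suprarounding_perturbation_changes_only_that_node(self, backend):
        mol = Chem.MolFromSmiles("CCO")
        feats = qf.compute_atom_features(mol, backend, "m")
        base = ge.build_attributed_graph(mol, feats, 2, "m")
        feats[1].values[3] += 0.05  # beyond the 10^-2 rounding step
        bumped = ge.build_attributed_graph(mol, feats, 2, "m")
        assert base.labels[1] != bumped.labels[1]
        assert base.labels[0] == bumped.labels[0]
        assert base.labels[2] == bumped.labels[2]

    def test_feature_length_mismatch_raises(self, backend):
        mol = Chem.MolFromSmiles("CCO")
        feats = qf.compute_atom_features(mol, backend, "m")[:-1]
        with pytest.raises(ValueError, match="m"):
            ge.build_attributed_graph(mol, feats, 3, "m")


class TestWLTokenize:
    def test_depth_zero_equals_node_label_multiset(self):
        g = ge.AttributedMolGraph("g", ["C"] * 3, [10, 20, 10],
                                  [(0, 1, 1.0), (1, 2, 1.0)])
        toks = ge.wl_tokenize(g, 0)
        assert Counter(t.token for t in toks) == Counter([10, 20, 10])

    def test_three_node_path_depth_one(self):
        """Path A-B-A: the end tokens agree, the centre differs."""
        g = ge.AttributedMolGraph("g", ["C"] * 3, [1, 2, 1],
                                  [(0, 1, 1.0), (1, 2, 1.0)])
        depth1 = {t.root_node: t.token
                  for t in ge.wl_tokenize(g, 1) if t.depth == 1}
        assert depth1[0] == depth1[2]
        assert depth1[1] != depth1[0]
        assert_tokens_match_oracle([g], max_depth=2)

    def test_matches_bruteforce_oracle_on_random_small_graphs(self):
        rng = np.random.default_rng(99)
        graphs = [random_attributed_graph(rng) for _ in range(25)]
        assert_tokens_match_oracle(graphs, max_depth=3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), perm_seed=st.integers(0, 10_000))
    def test_token_multiset_invariant_under_permutation(self, seed, perm_seed):
        rng = np.random.default_rng(seed)
        g = random_attributed_graph(rng)
        perm = list(np.random.default_rng(perm_seed).permutation(g.n_nodes))
        h = g.permuted(perm)
        assert ge.token_multiset(g, 3) == ge.token_multiset(h, 3)

    def test_empty_graph_yields_empty_multiset(self, caplog):
        g = ge.AttributedMolGraph("empty", [], [], [])
        with caplog.at_level("WARNING"):
            assert ge.wl_tokenize(g, 3) == []
        assert "empty" in caplog.text


class TestTraining:
    def test_identical_graphs_get_identical_vectors(self, backend):
        graphs = []
        for k in range(2):
            mol = Chem.MolFromSmiles("CCN")
            feats = qf.compute_atom_features(mol, backend, f"t{k}")
            graphs.append(ge.build_attributed_graph(mol, feats, 3, f"t{k}"))
        model = ge.train_embedding(
            graphs, ge.EmbeddingConfig(dimension=16, epochs=30, seed=3))
        np.testing.assert_allclose(model.vector("t0"), model.vector("t1"))

    def test_vectors_have_configured_dimension(self, trained_small_model):
        for vec in trained_small_model.graph_vectors.values():
            assert vec.shape == (32,)

    def test_seed_determinism_bit_identical(self, ten_graph_corpus):
        cfg = ge.EmbeddingConfig(dimension=16, epochs=20, seed=11)
        m1 = ge.train_embedding(ten_graph_corpus, cfg)
        m2 = ge.train_embedding(ten_graph_corpus, cfg)
        for mid in m1.graph_vectors:
            assert (m1.graph_vectors[mid].tobytes()
                    == m2.graph_vectors[mid].tobytes())
        assert m1.token_vectors.tobytes() == m2.token_vectors.tobytes()

    def test_duplicate_more_similar_than_near_duplicate(
            self, trained_small_model):
        """g0 and g1 are copies; g2 differs by one substituent."""
        m = trained_small_model

        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        dup = cos(m.vector("g0"), m.vector("g1"))
        near = cos(m.vector("g0"), m.vector("g2"))
        assert dup > near

    def test_vocabulary_counts_all_distinct_tokens(self, ten_graph_corpus):
        cfg = ge.EmbeddingConfig(dimension=8, epochs=1, seed=0)
        model = ge.train_embedding(ten_graph_corpus, cfg)
        distinct = set()
        for g in ten_graph_corpus:
            distinct |= {t.token for t in ge.wl_tokenize(g, cfg.depth)}
        assert len(model.token_vocabulary) == len(distinct)

    def test_corpus_permutation_of_nodes_keeps_embedding(self, backend):
        """Node re-indexing of a corpus member leaves its vector unchanged."""
        mol = Chem.MolFromSmiles("NCC(O)CS")
        feats = qf.compute_atom_features(mol, backend, "a")
        g = ge.build_attributed_graph(mol, feats, 3, "a")
        rng = np.random.default_rng(4)
        perm = list(rng.permutation(g.n_nodes))
        h = g.permuted(perm)
        h.molecule_id = "a"
        cfg = ge.EmbeddingConfig(dimension=16, epochs=20, seed=2)
        m1 = ge.train_embedding([g], cfg)
        m2 = ge.train_embedding([h], cfg)
        np.testing.assert_array_equal(m1.vector("a"), m2.vector("a"))

    def test_empty_vocabulary_raises(self):
        g = ge.AttributedMolGraph("empty", [], [], [])
        with pytest.raises(ge.TrainingError):
            ge.train_embedding([g], ge.EmbeddingConfig(dimension=4, epochs=1))

    def test_dimension_below_two_raises(self, ten_graph_corpus):
        with pytest.raises(ge.TrainingError):
            ge.train_embedding(ten_graph_corpus,
                               ge.EmbeddingConfig(dimension=1))


class TestInference:
    def test_corpus_molecule_infers_close_to_stored_vector(
            self, ten_graph_corpus, trained_small_model):
        m = trained_small_model
        g = ten_graph_corpus[3]
        res = ge.infer_vector(m, g, steps=60, seed=5)
        stored = m.vector(g.molecule_id)
        cos = (res.vector @ stored
               / np.linalg.norm(res.vector) / np.linalg.norm(stored))
        assert cos >= 0.9
        assert not res.oov_flag

    def test_empty_graph_gives_zero_vector_with_flag(self,
                                                     trained_small_model):
        g = ge.AttributedMolGraph("none", [], [], [])
        res = ge.infer_vector(trained_small_model, g, steps=5, seed=0)
        assert res.oov_flag
        np.testing.assert_array_equal(res.vector, np.zeros(32))

    def test_inference_is_deterministic(self, ten_graph_corpus,
                                        trained_small_model):
        g = ten_graph_corpus[0]
        a = ge.infer_vector(trained_small_model, g, steps=20, seed=9)
        b = ge.infer_vector(trained_small_model, g, steps=20, seed=9)
        assert a.vector.tobytes() == b.vector.tobytes()


def test_model_save_load_round_trip(tmp_path, trained_small_model):
    prefix = str(tmp_path / "emb")
    trained_small_model.save(prefix)
    loaded = ge.EmbeddingModel.load(prefix)
    assert loaded.dimension == trained_small_model.dimension
    for mid, vec in trained_small_model.graph_vectors.items():
        np.testing.assert_array_equal(loaded.graph_vectors[mid], vec)
    assert loaded.token_vocabulary == trained_small_model.token_vocabulary
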