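import numpy as np
import pytest
from rdkit import Chem

from redoxscreen import graph_embedding as ge
from redoxscreen import qm_features as qf
from redoxscreen import synthetic as syn


@pytest.fixture(scope="session")
def backend():
    return qf.MockQMBackend()


@pytest.fixture(scope="session")
def small_molecules():
    smiles = {
        "methane": "C",
        "ethane": "CC",
        "propane": "CCC",
        "ether": "COC",
        "benzene": "c1ccccc1",
        "ethanolamine": "NCCO",
        "thioether": "CSC",
    }
    return {name: Chem.MolFromSmiles(s) for name, s in smiles.items()}


@pytest.fixture(scope="session")
def ten_graph_corpus(backend):
    """Small fixed corpus of attributed graphs, incl. a duplicate pair."""
    smiles = ["CCO", "CCO", "CCN", "CCC", "CC(C)O", "COC", "CCS",
              "NCCO", "OCCO", "CC(N)C"]
    graphs = []
    for k, s in enumerate(smiles):
        mol = Chem.MolFromSmiles(s)
        feats = qf.compute_atom_features(mol, backend, f"g{k}")
        graphs.append(ge.build_attributed_graph(mol, feats, 3, f"g{k}"))
    return graphs


@pytest.fixture(scope="session")
def trained_small_model(ten_graph_corpus):
    config = ge.EmbeddingConfig(dimension=32, epochs=40, seed=7)
    return ge.train_embedding(ten_graph_corpus, config)


def rooted_subtree_descriptor(graph: ge.AttributedMolGraph, node: int,
                              depth: int) -> tuple:
    """Independent canonical form of the depth-d rooted subtree at a node.

    Built recursively from the node's own depth-(d-1) descriptor and the
    sorted multiset of its neighbours' depth-(d-1) descriptors — the
    brute-force enumeration the WL token hashing must agree with.
    """
    if depth == 0:
        return (graph.labels[node],)
    adj = graph.neighbors()
    own = rooted_subtree_descriptor(graph, node, depth - 1)
    branches = tuple(sorted(
        rooted_subtree_descriptor(graph, nbr, depth - 1)
        for nbr in adj[node]))
    return (own, branches)


def assert_tokens_match_oracle(graphs, max_depth=3):
    """WL tokens and brute-force descriptors must induce the same
    equivalence classes over (graph, node, depth) — across graphs."""
    token_to_desc: dict = {}
    desc_to_token: dict = {}
    for gi, graph in enumerate(graphs):
        for tok in ge.wl_tokenize(graph, max_depth):
            desc = (tok.depth,
                    rooted_subtree_descriptor(graph, tok.root_node,
                                              tok.depth))
            key = (tok.depth, tok.token)
            assert token_to_desc.setdefault(key, desc) == desc, \
                f"token collision at graph {gi}"
            assert desc_to_token.setdefault(desc, key) == key, \
                f"equivalent subtrees got different tokens at graph {gi}"


def random_attributed_graph(rng: np.random.Generator, max_nodes: int = 6,
                            n_labels: int = 4) -> ge.AttributedMolGraph:
    """Random small attributed graph with arbitrary integer node labels."""
    n = int(rng.integers(1, max_nodes + 1))
    labels = [int(rng.integers(n_labels)) for _ in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                edges.append((i, j, 1.0))
    return ge.AttributedMolGraph(
        molecule_id=f"rand-{rng.integers(1 << 30)}",
        elements=["C"] * n, labels=labels, edges=edges)


@pytest.fixture(scope="session")
def competency_pipeline(backend):
    """Small end-to-end fixture: synthetic competency data + embeddings."""
    spec = syn.SyntheticSpec(n_molecules=80, positive_fraction=0.5,
                             noise_scale=0.1, seed=23)
    dataset = syn.generate_competency_dataset(spec)
    graphs = ge.graphs_from_molecules(dataset.molecules, backend)
    model = ge.train_embedding(
        graphs, ge.EmbeddingConfig(dimension=32, epochs=30, seed=5))
    records = dataset.to_records(model.graph_vectors)
    return dataset, graphs, model, records
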