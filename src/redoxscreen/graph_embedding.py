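"""Whole-molecule embeddings from QM-attributed graphs.

A molecule becomes an attributed graph whose nodes carry a discretized
label derived from the 34-entry atom descriptor.  Iterative
Weisfeiler-Lehman (WL) relabelling turns each graph into a multiset of
rooted-subgraph tokens, and a skip-gram model with negative sampling
(PV-DBOW: the graph vector predicts its own tokens) learns a fixed-length
vector per molecule — the "DFT-embedded fingerprint".

Training is single-threaded and fully seeded, so two runs with the same
corpus, configuration and seed produce bit-identical vector tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .qm_features import AtomFeatureVector, heavy_atoms

logger = logging.getLogger(__name__)


def stable_hash64(payload: str) -> int:
    """Platform-independent 64-bit hash (truncated SHA-256), non-salted."""
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big")


@dataclass
class AttributedMolGraph:
    """Molecular graph with discretized per-node attribute labels.

    ``labels[i]`` is a pure function of ``(elements[i], features[i])``
    rounded to the construction precision; ``edges`` are unordered heavy-atom
    bond pairs with a bond-order tag.
    """

    molecule_id: str
    elements: list[str]
    labels: list[int]
    edges: list[tuple[int, int, float]]
    features: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j, _order in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def permuted(self, perm: Sequence[int]) -> "AttributedMolGraph":
        """Re-index nodes: new node ``perm[i]`` is old node ``i``."""
        n = self.n_nodes
        inv = [0] * n
        for old, new in enumerate(perm):
            inv[new] = old
        return AttributedMolGraph(
            molecule_id=self.molecule_id,
            elements=[self.elements[inv[k]] for k in range(n)],
            labels=[self.labels[inv[k]] for k in range(n)],
            edges=[(perm[i], perm[j], o) for i, j, o in self.edges],
            features=None if self.features is None
            else self.features[inv, :],
        )


@dataclass(frozen=True)
class WLToken:
    token: int
    depth: int
    root_node: int


def node_attribute_label(element: str, features: np.ndarray, precision: int) -> int:
    rounded = tuple(round(float(x), precision) for x in features)
    # normalize -0.0 so that equal-after-rounding vectors hash equally
    rounded = tuple(0.0 if x == 0 else x for x in rounded)
    return stable_hash64(f"{element}|{rounded}")


def build_attributed_graph(
    mol: Chem.Mol,
    features: Sequence[AtomFeatureVector],
    precision: int = 3,
    molecule_id: str = "",
) -> AttributedMolGraph:
    """Attach discretized feature labels to the heavy-atom graph of ``mol``."""
    atoms = heavy_atoms(mol)
    if len(features) != len(atoms):
        raise ValueError(
            f"molecule {molecule_id!r}: {len(features)} feature vectors for "
            f"{len(atoms)} heavy atoms")
    heavy_index = {a.GetIdx(): i for i, a in enumerate(atoms)}
    elements = [a.GetSymbol() for a in atoms]
    labels = [
        node_attribute_label(el, fv.values, precision)
        for el, fv in zip(elements, features)
    ]
    edges = []
    for bond in mol.GetBonds():
        b, e = bond.GetBeginAtom(), bond.GetEndAtom()
        if b.GetAtomicNum() > 1 and e.GetAtomicNum() > 1:
            i, j = heavy_index[b.GetIdx()], heavy_index[e.GetIdx()]
            edges.append((min(i, j), max(i, j), bond.GetBondTypeAsDouble()))
    feat = np.vstack([fv.values for fv in features]) if features else None
    return AttributedMolGraph(molecule_id, elements, labels, sorted(edges), feat)


def wl_tokenize(
    graph: AttributedMolGraph,
    max_depth: int = 3,
    use_bond_orders: bool = False,
) -> list[WLToken]:
    """Weisfeiler-Lehman rooted-subgraph tokens for depths 0..max_depth.

    Depth-0 tokens are the node attribute labels; the depth-d token of a
    node hashes its depth-(d-1) token together with the sorted multiset of
    its neighbours' depth-(d-1) tokens (optionally tagged by bond order).
    The token multiset is invariant under node re-indexing.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    if graph.n_nodes == 0:
        logger.warning("empty graph %r: no WL tokens", graph.molecule_id)
        return []
    adj: list[list[tuple[int, float]]] = [[] for _ in range(graph.n_nodes)]
    for i, j, order in graph.edges:
        tag = order if use_bond_orders else 1.0
        adj[i].append((j, tag))
        adj[j].append((i, tag))

    tokens = [WLToken(lab, 0, i) for i, lab in enumerate(graph.labels)]
    current = list(graph.labels)
    for depth in range(1, max_depth + 1):
        nxt = []
        for i in range(graph.n_nodes):
            neigh = sorted((current[j], tag) for j, tag in adj[i])
            nxt.append(stable_hash64(f"{current[i]}|{neigh}"))
        for i, tok in enumerate(nxt):
            tokens.append(WLToken(tok, depth, i))
        current = nxt
    return tokens


def token_multiset(graph: AttributedMolGraph, max_depth: int = 3,
                   use_bond_orders: bool = False) -> Counter:
    return Counter(t.token for t in wl_tokenize(graph, max_depth, use_bond_orders))


@dataclass
class EmbeddingConfig:
    """graph2vec training configuration.

    Defaults: WL depth 3, 128-dimensional vectors, 50 epochs of skip-gram
    with 5 negative samples, initial learning rate 0.025 decayed linearly,
    seed 17, single worker.
    """

    depth: int = 3
    dimension: int = 128
    epochs: int = 50
    negative: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    seed: int = 17
    use_bond_orders: bool = False
    precision: int = 3


class TrainingError(RuntimeError):
    pass


@dataclass
class EmbeddingModel:
    """Trained token/graph vector store."""

    dimension: int
    token_vocabulary: dict[int, int]          # token -> row in token_vectors
    token_vectors: np.ndarray                 # (vocab, dimension)
    graph_vectors: dict[str, np.ndarray]      # molecule_id -> vector
    token_counts: np.ndarray                  # corpus frequency per vocab row
    config: EmbeddingConfig

    def vector(self, molecule_id: str) -> np.ndarray:
        return self.graph_vectors[molecule_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"molecule_id": mid, **{f"e{i}": x for i, x in enumerate(vec)}}
            for mid, vec in self.graph_vectors.items()
        ]
        return pd.DataFrame(rows)

    def save(self, prefix: str) -> tuple[str, str]:
        """Persist as a JSON metadata file plus an NPZ vector file."""
        meta_path, vec_path = f"{prefix}.json", f"{prefix}.npz"
        ids = list(self.graph_vectors)
        with open(meta_path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "dimension": self.dimension,
                    "config": asdict(self.config),
                    "tokens": [str(t) for t in self.token_vocabulary],
                    "molecule_ids": ids,
                    "vectors_file": vec_path,
                },
                fh, indent=1)
        np.savez(
            vec_path,
            token_vectors=self.token_vectors,
            graph_vectors=np.vstack([self.graph_vectors[i] for i in ids])
            if ids else np.zeros((0, self.dimension)),
            token_counts=self.token_counts,
        )
        return meta_path, vec_path

    @classmethod
    def load(cls, prefix: str) -> "EmbeddingModel":
        with open(f"{prefix}.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        arrays = np.load(meta["vectors_file"])
        ids = meta["molecule_ids"]
        gv = arrays["graph_vectors"]
        return cls(
            dimension=meta["dimension"],
            token_vocabulary={int(t): i for i, t in enumerate(meta["tokens"])},
            token_vectors=arrays["token_vectors"],
            graph_vectors={mid: gv[i] for i, mid in enumerate(ids)},
            token_counts=arrays["token_counts"],
            config=EmbeddingConfig(**meta["config"]),
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _negative_table(counts: np.ndarray) -> np.ndarray:
    """Cumulative unigram^0.75 distribution for negative sampling."""
    weights = counts.astype(float) ** 0.75
    cum = np.cumsum(weights)
    return cum / cum[-1]


def _train_doc_vectors(
    docs: list[list[int]],
    doc_vectors: np.ndarray,
    token_vectors: np.ndarray,
    neg_table: np.ndarray,
    config: EmbeddingConfig,
    rng: np.random.Generator,
    epochs: int,
    train_tokens: bool,
) -> None:
    """In-place PV-DBOW SGD over (doc, token) pairs with negative sampling."""
    pairs = np.array(
        [(d, t) for d, doc in enumerate(docs) for t in doc], dtype=np.int64)
    if pairs.size == 0:
        return
    n_pairs = len(pairs)
    total = epochs * n_pairs
    lr0, lr_min = config.learning_rate, config.min_learning_rate
    done = 0
    for _epoch in range(epochs):
        order = rng.permutation(n_pairs)
        negs = np.searchsorted(
            neg_table, rng.random((n_pairs, config.negative)))
        for row, (d, t) in enumerate(pairs[order]):
            lr = max(lr_min, lr0 * (1.0 - done / total))
            targets = np.concatenate(([t], negs[row]))
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            dvec = doc_vectors[d]
            w = token_vectors[targets]
            g = (labels - _sigmoid(w @ dvec)) * lr
            d_grad = g @ w
            if train_tokens:
                token_vectors[targets] += np.outer(g, dvec)
            dvec += d_grad
            done += 1


def train_embedding(
    corpus: Sequence[AttributedMolGraph],
    config: EmbeddingConfig | None = None,
) -> EmbeddingModel:
    """Learn a fixed-length vector per corpus graph (graph2vec, PV-DBOW).

    Deterministic for a fixed corpus, configuration and seed.
    """
    config = config or EmbeddingConfig()
    if not corpus:
        raise TrainingError("empty corpus")
    if config.dimension < 2:
        raise TrainingError("embedding dimension must be >= 2")
    ids = [g.molecule_id for g in corpus]
    if len(set(ids)) != len(ids):
        raise TrainingError("corpus molecule_ids must be unique")

    # canonical document = sorted token multiset; graphs with identical
    # token multisets (duplicates, node permutations of isomorphic graphs)
    # share one training document, so their vectors are exactly equal
    doc_tokens = [
        tuple(sorted(
            t.token for t in
            wl_tokenize(g, config.depth, config.use_bond_orders)))
        for g in corpus
    ]
    counts = Counter(t for doc in doc_tokens for t in doc)
    if not counts:
        raise TrainingError("corpus produced an empty token vocabulary")
    vocab = {tok: i for i, tok in enumerate(sorted(counts))}
    unique_docs: list[tuple[int, ...]] = []
    class_index: dict[tuple[int, ...], int] = {}
    class_of: list[int] = []
    for doc in doc_tokens:
        key = tuple(vocab[t] for t in doc)
        if key not in class_index:
            class_index[key] = len(unique_docs)
            unique_docs.append(key)
        class_of.append(class_index[key])
    flat = np.array([t for doc in unique_docs for t in doc], dtype=np.int64)
    count_arr = np.maximum(
        np.bincount(flat, minlength=len(vocab)).astype(np.int64), 1)

    rng = np.random.default_rng(config.seed)
    dim = config.dimension
    doc_vectors = (rng.random((len(unique_docs), dim)) - 0.5) / dim
    token_vectors = np.zeros((len(vocab), dim))
    neg_table = _negative_table(count_arr)
    _train_doc_vectors([list(d) for d in unique_docs], doc_vectors,
                       token_vectors, neg_table, config, rng,
                       config.epochs, train_tokens=True)
    return EmbeddingModel(
        dimension=dim,
        token_vocabulary=vocab,
        token_vectors=token_vectors,
        graph_vectors={mid: doc_vectors[class_of[i]]
                       for i, mid in enumerate(ids)},
        token_counts=count_arr,
        config=config,
    )


@dataclass
class InferenceResult:
    vector: np.ndarray
    n_tokens: int
    n_oov: int
    oov_flag: bool


def infer_vector(
    model: EmbeddingModel,
    graph: AttributedMolGraph,
    steps: int = 50,
    seed: int = 0,
) -> InferenceResult:
    """Embed an out-of-corpus graph against the frozen token vectors.

    Tokens absent from the vocabulary are skipped and counted; if every
    token is out-of-vocabulary the zero vector is returned with the OOV
    flag set.
    """
    config = model.config
    tokens = [t.token for t in
              wl_tokenize(graph, config.depth, config.use_bond_orders)]
    known = sorted(model.token_vocabulary[t] for t in tokens
                   if t in model.token_vocabulary)
    n_oov = len(tokens) - len(known)
    if not known:
        logger.warning("graph %r: all %d tokens out of vocabulary",
                       graph.molecule_id, len(tokens))
        return InferenceResult(np.zeros(model.dimension), len(tokens),
                               n_oov, True)
    rng = np.random.default_rng(seed)
    dvec = (rng.random((1, model.dimension)) - 0.5) / model.dimension
    neg_table = _negative_table(model.token_counts)
    frozen = model.token_vectors.copy()
    _train_doc_vectors([known], dvec, frozen, neg_table, config, rng,
                       epochs=steps, train_tokens=False)
    return InferenceResult(dvec[0], len(tokens), n_oov, False)


def graphs_from_molecules(
    molecules: Iterable[tuple[str, Chem.Mol]],
    backend,
    precision: int = 3,
) -> list[AttributedMolGraph]:
    """Featurize and attribute a batch of (molecule_id, mol) pairs."""
    from .qm_features import compute_atom_features

    out = []
    for mol_id, mol in molecules:
        feats = compute_atom_features(mol, backend, mol_id)
        out.append(build_attributed_graph(mol, feats, precision, mol_id))
    return out
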