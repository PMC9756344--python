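"""End-to-end orchestration: simulate -> featurize -> embed -> train -> screen.

Library-level composition of the pipeline stages with all randomness
derived from one master seed.  The embedding is trained transductively
over the union of training and screening molecules (unsupervised, so no
label leakage); the competency ensemble then sees only the training
records.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig, derive_seed
from .graph_embedding import (
    AttributedMolGraph,
    EmbeddingConfig,
    EmbeddingModel,
    graphs_from_molecules,
    train_embedding,
)
from .modeling import EnsembleConfig, EnsembleModel, train_reactivity_ensemble
from .qm_features import MockQMBackend
from .screening import ScreeningConfig, ScreeningResult, screen_library
from .synthetic import (
    CompetencyDataset,
    ScreenLibrary,
    SyntheticSpec,
    generate_competency_dataset,
    generate_screen_library,
)


@dataclass
class DiscoveryRun:
    dataset: CompetencyDataset
    library: ScreenLibrary | None
    embedding: EmbeddingModel
    ensemble: EnsembleModel
    results: list[ScreeningResult] | None
    train_graphs: list[AttributedMolGraph]
    library_graphs: list[AttributedMolGraph]


def embedding_config_from(config: RunConfig) -> EmbeddingConfig:
    return EmbeddingConfig(
        depth=config.wl_depth,
        dimension=config.embedding_dimension,
        epochs=config.embedding_epochs,
        negative=config.negative_samples,
        learning_rate=config.embedding_learning_rate,
        seed=derive_seed(config.master_seed, "embedding"),
        use_bond_orders=config.use_bond_orders,
        precision=config.label_precision,
    )


def ensemble_config_from(config: RunConfig) -> EnsembleConfig:
    return EnsembleConfig(
        n_members=config.ensemble_members,
        train_fraction=config.ensemble_train_fraction,
        alpha=config.ridge_alpha,
        alpha_grid=config.ridge_alpha_grid,
        seed=derive_seed(config.master_seed, "ensemble"),
    )


def run_discovery(
    config: RunConfig,
    n_train: int | None = None,
    n_library: int | None = None,
) -> DiscoveryRun:
    """Run the full competency-screening pipeline on synthetic data.

    ``n_train`` molecules of labelled competency data are generated and
    ``n_library`` unlabelled candidates are screened (skip screening when
    ``n_library`` is None or 0).
    """
    backend = MockQMBackend()
    train_spec = SyntheticSpec(
        n_molecules=n_train or config.n_molecules,
        atom_range=config.atom_range,
        positive_fraction=config.positive_fraction,
        n_template_groups=config.n_template_groups,
        noise_scale=config.noise_scale,
        seed=derive_seed(config.master_seed, "competency-data"),
    )
    dataset = generate_competency_dataset(train_spec)
    train_graphs = graphs_from_molecules(dataset.molecules, backend,
                                         config.label_precision)

    library = None
    library_graphs: list[AttributedMolGraph] = []
    if n_library:
        lib_spec = SyntheticSpec(
            n_molecules=n_library,
            atom_range=config.atom_range,
            positive_fraction=0.10,
            noise_scale=config.noise_scale,
            seed=derive_seed(config.master_seed, "screen-library"),
            id_prefix="lib",
        )
        library = generate_screen_library(lib_spec)
        library_graphs = graphs_from_molecules(library.molecules, backend,
                                               config.label_precision)

    embedding = train_embedding(train_graphs + library_graphs,
                                embedding_config_from(config))
    records = dataset.to_records(embedding.graph_vectors)
    ensemble = train_reactivity_ensemble(records, ensemble_config_from(config))

    results = None
    if library is not None:
        triples = [(mid, mol, g) for (mid, mol), g
                   in zip(library.molecules, library_graphs)]
        results = screen_library(
            triples, ensemble, embedding,
            ScreeningConfig(infer_steps=config.infer_steps,
                            infer_seed=derive_seed(config.master_seed,
                                                   "inference")))
    return DiscoveryRun(dataset, library, embedding, ensemble, results,
                        train_graphs, library_graphs)


def screening_recall(run: DiscoveryRun) -> float:
    """Fraction of planted-positive library molecules flagged reactive."""
    if run.library is None or run.results is None:
        raise ValueError("run has no screening stage")
    truth = dict(zip(run.library.truth.molecule_id,
                     run.library.truth.true_label))
    positives = {m for m, lab in truth.items() if lab == 1}
    flagged = {r.molecule_id for r in run.results if r.mean_vote > 0}
    return len(flagged & positives) / len(positives)
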