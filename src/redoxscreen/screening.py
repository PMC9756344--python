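"""Library screening: embed, score, rank, shortlist.

The discovery workflow embeds every parseable candidate molecule, scores
it with the competency ensemble, sorts by prediction probability (ties
broken by molecule id), and emits a ranked report from which a shortlist
of top candidates — optionally restricted by a SMARTS substructure
filter — can be drawn for manual review.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .graph_embedding import (
    AttributedMolGraph,
    EmbeddingModel,
    infer_vector,
)
from .modeling import EnsembleModel, ensemble_predict

logger = logging.getLogger(__name__)


class ScreeningError(RuntimeError):
    pass


@dataclass
class ScreeningResult:
    molecule_id: str
    smiles: str
    predicted_label: int
    probability: float
    mean_vote: float
    rank: int
    oov_flag: bool


@dataclass
class ScreeningConfig:
    infer_steps: int = 50
    infer_seed: int = 0


def screen_library(
    library: Sequence[tuple[str, Chem.Mol, AttributedMolGraph]],
    ensemble: EnsembleModel,
    embedding: EmbeddingModel,
    config: ScreeningConfig | None = None,
) -> list[ScreeningResult]:
    """Score and rank a candidate library.

    ``library`` holds ``(molecule_id, mol, attributed_graph)`` triples.
    Molecules present in the embedding model's vector table (the
    transductive default: the embedding is refit on training + screening
    molecules, which leaks no labels since it is unsupervised) use their
    stored vectors; others are embedded by inference against the frozen
    token vocabulary.  Results are sorted by probability descending, then
    molecule_id ascending, and ranked 1..n.
    """
    config = config or ScreeningConfig()
    if not library:
        raise ScreeningError("empty screening library")
    rows = []
    for mol_id, mol, graph in library:
        oov = False
        if mol_id in embedding.graph_vectors:
            vec = embedding.graph_vectors[mol_id]
        else:
            res = infer_vector(embedding, graph, config.infer_steps,
                               config.infer_seed)
            vec, oov = res.vector, res.oov_flag
        label, prob, mean_vote = ensemble_predict(ensemble, vec)
        rows.append(ScreeningResult(
            molecule_id=mol_id,
            smiles=Chem.MolToSmiles(mol),
            predicted_label=label,
            probability=prob,
            mean_vote=mean_vote,
            rank=0,
            oov_flag=oov,
        ))
    rows.sort(key=lambda r: (-r.probability, r.molecule_id))
    for i, row in enumerate(rows, start=1):
        row.rank = i
    n_reactive = sum(1 for r in rows if r.mean_vote > 0)
    logger.info("screened %d molecules, %d predicted reactive",
                len(rows), n_reactive)
    return rows


def predicted_reactive(results: Sequence[ScreeningResult]) -> list[ScreeningResult]:
    """The likely-reactive subset: strictly positive mean vote."""
    return [r for r in results if r.mean_vote > 0]


def select_candidates(
    results: Sequence[ScreeningResult],
    k: int,
    smarts_filter: str | None = None,
) -> list[ScreeningResult]:
    """Top-``k`` results by rank, after an optional substructure filter."""
    if k > len(results):
        raise ScreeningError(
            f"k={k} exceeds number of results ({len(results)})")
    pool = sorted(results, key=lambda r: r.rank)
    if smarts_filter is not None:
        query = Chem.MolFromSmarts(smarts_filter)
        if query is None:
            raise ScreeningError(f"invalid SMARTS filter {smarts_filter!r}")
        pool = [r for r in pool
                if Chem.MolFromSmiles(r.smiles).HasSubstructMatch(query)]
        if not pool:
            logger.warning("substructure filter %r matched no molecules",
                           smarts_filter)
            return []
    return pool[:k]


def results_to_frame(results: Sequence[ScreeningResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def write_results(results: Sequence[ScreeningResult], path: str) -> None:
    results_to_frame(results).to_csv(path, index=False,
                                     float_format="%.10g", lineterminator="\n")


def screening_summary(results: Sequence[ScreeningResult]) -> dict:
    probs = np.array([r.probability for r in results])
    return {
        "n_screened": len(results),
        "n_predicted_reactive": len(predicted_reactive(results)),
        "n_oov": sum(1 for r in results if r.oov_flag),
        "max_probability": float(probs.max()) if len(probs) else 0.0,
    }
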