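"""Synthetic datasets emulating the statistical shape of the study data.

No public dataset accompanies the experimental campaign, so the test
suite and demos run on generated stand-ins: random chemically valid
molecules over {C, N, O, S} (valence-checked, rendered to SMILES),
featurized through the deterministic mock QM backend, with labels planted
by a linear rule on the atom descriptors plus Gaussian noise.

Four corpora are emulated:

* an atom-level oxidation-site corpus with a minority positive class
  (8% oxidized atoms by default) grouped into five reaction templates;
* a 141-record reaction-competency corpus with ~43% productive labels
  (60/141), categories tagged known/AR/BN/CH/Misc;
* electronic-property regression benchmarks whose node attributes carry
  a latent per-molecule state beyond the 2D graph;
* unlabeled screening libraries whose hidden truth labels are written to
  a separate file that the screening pipeline never reads.

Everything is a pure function of the spec, including its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import RWMol

from .modeling import CompetencyRecord, SiteLabeledAtom
from .qm_features import (
    FeatureLayout,
    MockQMBackend,
    VECTOR_LENGTH,
    compute_atom_features,
)

_ELEMENTS = ("C", "N", "O", "S")
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
_ELEMENT_WEIGHTS = (0.70, 0.12, 0.12, 0.06)


def default_planted_coefficients() -> np.ndarray:
    """The planted linear rule over the 34-entry atom descriptor.

    Weight sits on the electronically meaningful entries of the mock
    features: frontier-orbital energies of the neutral and cation species,
    the cation frontier occupancy (how much density the atom loses on
    oxidation), the neutral natural charge, and electronegativity.
    Electron-rich, easily oxidized centres score high.
    """
    w = np.zeros(VECTOR_LENGTH)
    w[FeatureLayout.energy_index("neutral", 0)] = 1.0
    w[FeatureLayout.energy_index("oxidized", 0)] = 0.5
    w[FeatureLayout.occupancy_index("oxidized", 0)] = -1.0
    w[FeatureLayout.charge_index("neutral")] = 1.5
    w[FeatureLayout.electronegativity_index()] = -0.3
    return w


@dataclass
class SyntheticSpec:
    """Generation parameters; the seed fully determines the output."""

    n_molecules: int = 141
    atom_range: tuple[int, int] = (4, 12)
    positive_fraction: float = 60 / 141
    site_positive_fraction: float = 0.08
    n_template_groups: int = 5
    coefficients: np.ndarray | None = None
    noise_scale: float = 0.1
    ring_probability: float = 0.35
    seed: int = 0
    id_prefix: str = "mol"

    def __post_init__(self) -> None:
        for name in ("positive_fraction", "site_positive_fraction"):
            frac = getattr(self, name)
            if not 0.0 < frac < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {frac}")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be positive")
        lo, hi = self.atom_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid atom_range {self.atom_range}")
        if self.n_template_groups < 1:
            raise ValueError("n_template_groups must be positive")

    @property
    def rule(self) -> np.ndarray:
        if self.coefficients is not None:
            return np.asarray(self.coefficients, dtype=float)
        return default_planted_coefficients()

    def to_json(self) -> str:
        d = asdict(self)
        d["coefficients"] = (None if self.coefficients is None
                             else list(map(float, self.coefficients)))
        d["atom_range"] = list(self.atom_range)
        return json.dumps(d, indent=1)


def _random_molecule(rng: np.random.Generator, n_atoms: int,
                     ring_probability: float) -> Chem.Mol:
    """Random valence-respecting connected molecule, single bonds only."""
    mol = RWMol()
    symbols: list[str] = []

    def pick_element() -> str:
        return str(rng.choice(_ELEMENTS, p=_ELEMENT_WEIGHTS))

    sym = pick_element()
    mol.AddAtom(Chem.Atom(sym))
    symbols.append(sym)
    degree = [0]
    for _ in range(n_atoms - 1):
        open_sites = [i for i, s in enumerate(symbols)
                      if degree[i] < _VALENCE[s]]
        if not open_sites:
            break
        parent = int(rng.choice(np.array(open_sites)))
        sym = pick_element()
        idx = mol.AddAtom(Chem.Atom(sym))
        symbols.append(sym)
        degree.append(0)
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        degree[parent] += 1
        degree[idx] += 1
    if rng.random() < ring_probability and len(symbols) >= 3:
        # close one ring between distant atoms that both have free valence
        dist = Chem.GetDistanceMatrix(mol.GetMol())
        pairs = [(i, j) for i in range(len(symbols))
                 for j in range(i + 1, len(symbols))
                 if dist[i, j] >= 2
                 and degree[i] < _VALENCE[symbols[i]]
                 and degree[j] < _VALENCE[symbols[j]]]
        if pairs:
            i, j = pairs[int(rng.integers(len(pairs)))]
            mol.AddBond(i, j, Chem.BondType.SINGLE)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def generate_molecules(spec: SyntheticSpec) -> list[tuple[str, Chem.Mol]]:
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.atom_range
    out = []
    width = max(4, len(str(spec.n_molecules)))
    for k in range(spec.n_molecules):
        n_atoms = int(rng.integers(lo, hi + 1))
        mol = _random_molecule(rng, n_atoms, spec.ring_probability)
        out.append((f"{spec.id_prefix}-{k:0{width}d}", mol))
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("planted scores are constant; spec is infeasible")
    return (x - x.mean()) / sd


@dataclass
class SiteDataset:
    atoms: list[SiteLabeledAtom]
    molecules: list[tuple[str, Chem.Mol]]
    truth: pd.DataFrame  # per-molecule planted top-scoring atom
    spec: SyntheticSpec

    @property
    def positive_fraction(self) -> float:
        return float(np.mean([a.oxidized for a in self.atoms]))


def generate_site_dataset(spec: SyntheticSpec) -> SiteDataset:
    """Atom-level oxidation-site corpus with planted threshold labels.

    Every atom scores ``w . features``; scores are standardized, Gaussian
    noise of ``noise_scale`` standard deviations is added, and the top
    ``site_positive_fraction`` of atoms are labelled oxidized.  Each
    molecule carries one of ``n_template_groups`` reaction-template tags
    (all non-empty), and the per-molecule noiseless argmax atom is
    recorded as truth for rank-order evaluation.
    """
    molecules = generate_molecules(spec)
    backend = MockQMBackend()
    rng = np.random.default_rng(spec.seed + 1)
    w = spec.rule

    all_feats, owners = [], []
    for mol_id, mol in molecules:
        feats = compute_atom_features(mol, backend, mol_id)
        all_feats.extend(feats)
        owners.extend([mol_id] * len(feats))
    F = np.vstack([f.values for f in all_feats])
    scores = _zscore(F @ w)
    noisy = scores + rng.normal(0.0, spec.noise_scale, size=len(scores))
    threshold = np.quantile(noisy, 1.0 - spec.site_positive_fraction)
    oxidized = noisy > threshold
    if not oxidized.any() or oxidized.all():
        raise ValueError("site spec infeasible: degenerate label split")

    # round-robin template assignment over a shuffled molecule order keeps
    # every template non-empty
    order = rng.permutation(len(molecules))
    group_of = {
        molecules[idx][0]: f"T{order_pos % spec.n_template_groups + 1}"
        for order_pos, idx in enumerate(order)
    }
    atoms = [
        SiteLabeledAtom(fv.molecule_id, fv.atom_index, fv,
                        bool(oxidized[i]), group_of[fv.molecule_id])
        for i, fv in enumerate(all_feats)
    ]
    truth_rows = []
    for mol_id, _mol in molecules:
        idxs = [i for i, owner in enumerate(owners) if owner == mol_id]
        best = max(idxs, key=lambda i: scores[i])
        truth_rows.append({"molecule_id": mol_id,
                           "planted_top_atom": all_feats[best].atom_index})
    return SiteDataset(atoms, molecules, pd.DataFrame(truth_rows), spec)


@dataclass
class CompetencyDataset:
    molecules: list[tuple[str, Chem.Mol]]
    labels: pd.DataFrame  # molecule_id, label, category
    spec: SyntheticSpec

    def to_records(self, vectors: dict[str, np.ndarray]) -> list[CompetencyRecord]:
        return [
            CompetencyRecord(row.molecule_id, vectors[row.molecule_id],
                             int(row.label), row.category)
            for row in self.labels.itertuples()
        ]


_POSITIVE_CATEGORIES = ("AR", "BN", "CH", "Misc")


@dataclass
class LatentStateBackend:
    """Mock backend with a latent per-molecule electronic state.

    Real quantum-chemical attributes carry information the 2D molecular
    graph does not determine (conformation, conjugation, solvation shifts
    of absolute orbital energies).  This wrapper emulates that: every
    molecule is assigned one of ``n_states`` latent electronic classes —
    deterministically from its id — whose energy shift is applied to all
    of its orbital energies.  Topology-only representations cannot see
    the shift; attribute-aware ones can.
    """

    base: "MockQMBackend"
    n_states: int = 5
    step: float = 0.02
    seed: int = 0

    def shift_for(self, molecule_id: str) -> float:
        import zlib

        c = zlib.crc32(f"{self.seed}:{molecule_id}".encode()) % self.n_states
        return (c - (self.n_states - 1) / 2) * self.step

    def compute_for(self, mol, molecule_id: str):
        from .qm_features import SpeciesOrbitalData

        out = self.base.compute(mol)
        delta = self.shift_for(molecule_id)
        for state, data in out.items():
            shifted = [[(s, occ, round(en + delta, 4))
                        for s, occ, en in orbs]
                       for orbs in data.per_atom_orbitals]
            out[state] = SpeciesOrbitalData(state, shifted,
                                            data.per_atom_charges)
        return out


def ionization_target_coefficients() -> np.ndarray:
    """Ionization-potential-like target: frontier energies + cation charge."""
    w = np.zeros(VECTOR_LENGTH)
    w[FeatureLayout.energy_index("neutral", 0)] = 1.0
    w[FeatureLayout.energy_index("oxidized", 0)] = 1.0
    w[FeatureLayout.charge_index("oxidized")] = 0.5
    return w


@dataclass
class PropertyBenchmark:
    molecules: list[tuple[str, Chem.Mol]]
    features: list[list]          # AtomFeatureVectors per molecule
    y: np.ndarray
    spec: SyntheticSpec


def generate_property_benchmark(
    spec: SyntheticSpec,
    target_coefficients: np.ndarray | None = None,
    n_latent_states: int = 5,
    latent_step: float = 0.02,
) -> PropertyBenchmark:
    """Electronic-property regression benchmark data.

    Targets are the molecule mean of a linear functional of the node
    attributes (default: the ionization-potential-like functional), where
    the attributes include a latent per-molecule electronic state beyond
    the 2D graph, plus Gaussian noise of ``noise_scale`` standard
    deviations after standardization.
    """
    molecules = generate_molecules(spec)
    backend = LatentStateBackend(MockQMBackend(), n_latent_states,
                                 latent_step, seed=spec.seed)
    w = (ionization_target_coefficients() if target_coefficients is None
         else np.asarray(target_coefficients, dtype=float))

    class _Bound:
        def __init__(self, parent, mol_id):
            self.parent, self.mol_id = parent, mol_id

        def compute(self, mol):
            return self.parent.compute_for(mol, self.mol_id)

    features, means = [], []
    for mol_id, mol in molecules:
        feats = compute_atom_features(mol, _Bound(backend, mol_id), mol_id)
        features.append(feats)
        means.append(np.vstack([f.values for f in feats]).mean(axis=0))
    y = _zscore(np.vstack(means) @ w)
    rng = np.random.default_rng(spec.seed + 4)
    y = y + rng.normal(0.0, spec.noise_scale, size=len(y))
    return PropertyBenchmark(molecules, features, y, spec)


def competency_scores(molecules: Sequence[tuple[str, Chem.Mol]],
                      w: np.ndarray) -> np.ndarray:
    """Noiseless per-molecule rule scores: w . (mean heavy-atom features)."""
    backend = MockQMBackend()
    means = []
    for mol_id, mol in molecules:
        feats = compute_atom_features(mol, backend, mol_id)
        means.append(np.vstack([f.values for f in feats]).mean(axis=0))
    return _zscore(np.vstack(means) @ w)


def generate_competency_dataset(spec: SyntheticSpec) -> CompetencyDataset:
    """Molecule-level competency labels: sign of the planted rule + noise.

    Defaults mirror the canonical corpus: 141 molecules, ~43% productive.
    Roughly half the positives are tagged ``known`` (functionality already
    established as reactive), the rest cycle through AR/BN/CH/Misc;
    negatives are ``unknown``.
    """
    molecules = generate_molecules(spec)
    rng = np.random.default_rng(spec.seed + 2)
    scores = competency_scores(molecules, spec.rule)
    noisy = scores + rng.normal(0.0, spec.noise_scale, size=len(scores))
    threshold = np.quantile(noisy, 1.0 - spec.positive_fraction)
    labels = np.where(noisy > threshold, 1, -1)
    if len(np.unique(labels)) < 2:
        raise ValueError("competency spec infeasible: single-class labels")

    rows, pos_seen = [], 0
    for (mol_id, _mol), label in zip(molecules, labels):
        if label == 1:
            if pos_seen % 2 == 0:
                cat = "known"
            else:
                cat = _POSITIVE_CATEGORIES[(pos_seen // 2)
                                           % len(_POSITIVE_CATEGORIES)]
            pos_seen += 1
        else:
            cat = "unknown"
        rows.append({"molecule_id": mol_id, "label": int(label),
                     "category": cat})
    return CompetencyDataset(molecules, pd.DataFrame(rows), spec)


@dataclass
class ScreenLibrary:
    molecules: list[tuple[str, Chem.Mol]]
    truth: pd.DataFrame  # molecule_id, true_label — for evaluation only
    spec: SyntheticSpec


def generate_screen_library(spec: SyntheticSpec) -> ScreenLibrary:
    """Unlabeled screening library plus a separate hidden-truth table.

    The truth table exists only so that planted-positive recovery can be
    evaluated; the screening pipeline itself never takes it as an input.
    """
    molecules = generate_molecules(spec)
    rng = np.random.default_rng(spec.seed + 3)
    scores = competency_scores(molecules, spec.rule)
    noisy = scores + rng.normal(0.0, spec.noise_scale, size=len(scores))
    threshold = np.quantile(noisy, 1.0 - spec.positive_fraction)
    labels = np.where(noisy > threshold, 1, -1)
    truth = pd.DataFrame({"molecule_id": [m for m, _ in molecules],
                          "true_label": labels})
    return ScreenLibrary(molecules, truth, spec)


def asdict_spec(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["atom_range"] = tuple(d["atom_range"])
    return d


# --------------------------- file emission ---------------------------------

def write_smi(molecules: Sequence[tuple[str, Chem.Mol]], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mol_id, mol in molecules:
            fh.write(f"{Chem.MolToSmiles(mol)}\t{mol_id}\n")


def write_site_dataset(dataset: SiteDataset, prefix: str) -> dict[str, str]:
    paths = {
        "molecules": f"{prefix}_molecules.smi",
        "atom_labels": f"{prefix}_atom_labels.csv",
        "truth": f"{prefix}_truth.csv",
        "spec": f"{prefix}_spec.json",
    }
    write_smi(dataset.molecules, paths["molecules"])
    pd.DataFrame([
        {"molecule_id": a.molecule_id, "atom_index": a.atom_index,
         "oxidized": int(a.oxidized), "template_group": a.template_group}
        for a in dataset.atoms
    ]).to_csv(paths["atom_labels"], index=False, lineterminator="\n")
    dataset.truth.to_csv(paths["truth"], index=False, lineterminator="\n")
    with open(paths["spec"], "w", encoding="utf-8") as fh:
        fh.write(dataset.spec.to_json())
    return paths


def write_competency_dataset(dataset: CompetencyDataset,
                             prefix: str) -> dict[str, str]:
    paths = {
        "molecules": f"{prefix}_molecules.smi",
        "labels": f"{prefix}_labels.csv",
        "spec": f"{prefix}_spec.json",
    }
    write_smi(dataset.molecules, paths["molecules"])
    dataset.labels.to_csv(paths["labels"], index=False, lineterminator="\n")
    with open(paths["spec"], "w", encoding="utf-8") as fh:
        fh.write(dataset.spec.to_json())
    return paths


def write_screen_library(library: ScreenLibrary, prefix: str) -> dict[str, str]:
    paths = {
        "molecules": f"{prefix}_library.smi",
        "truth": f"{prefix}_truth.csv",
        "spec": f"{prefix}_spec.json",
    }
    write_smi(library.molecules, paths["molecules"])
    library.truth.to_csv(paths["truth"], index=False, lineterminator="\n")
    with open(paths["spec"], "w", encoding="utf-8") as fh:
        fh.write(library.spec.to_json())
    return paths
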