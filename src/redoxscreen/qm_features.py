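"""Per-atom quantum-chemical descriptors.

Each heavy atom of a molecule is described by a 34-dimensional feature
vector assembled from orbital occupancies and energies of three charge
states of the parent molecule — the neutral species, the radical cation
("oxidized") and the radical anion ("reduced") — plus a small set of
whole-atom quantities.  The fixed layout is::

    for state in (neutral, oxidized, reduced):
        occupancy[slot 0..4]     # electrons, [0, 2]
        energy[slot 0..4]        # hartree, slots ranked by energy
    natural_charge[neutral], natural_charge[oxidized],
    natural_charge[reduced], electronegativity

i.e. 3 x (5 + 5) + 4 = 34 entries.  Orbital slots an atom does not
populate (e.g. no lone pairs) are imputed with a sentinel (default 0.0,
the physical occupancy of an empty orbital).

Backends supplying the raw orbital data are pluggable.  ``MockQMBackend``
derives deterministic pseudo-properties from molecular topology alone and
supports the full pipeline without any quantum-chemistry software;
``TableBackend`` imports real per-atom tables (e.g. exported from an NBO
population analysis) from CSV/JSON.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

logger = logging.getLogger(__name__)

CHARGE_STATES = ("neutral", "oxidized", "reduced")
N_ORBITAL_SLOTS = 5
VECTOR_LENGTH = 3 * 2 * N_ORBITAL_SLOTS + 4  # = 34

#: Pauling electronegativities for the elements the pipeline handles.
ELECTRONEGATIVITY = {
    "H": 2.20, "B": 2.04, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98,
    "Si": 1.90, "P": 2.19, "S": 2.58, "Cl": 3.16, "Br": 2.96, "I": 2.66,
}
_DEFAULT_EN = 2.20

#: Typical lone-pair counts used by the mock backend.
_LONE_PAIRS = {"C": 0, "N": 1, "O": 2, "S": 2, "P": 1, "F": 3, "Cl": 3,
               "Br": 3, "I": 3, "B": 0, "Si": 0, "H": 0}


class FeatureLayout:
    """Index bookkeeping for the 34-entry vector."""

    n_slots = N_ORBITAL_SLOTS
    length = VECTOR_LENGTH

    @staticmethod
    def state_offset(state: str) -> int:
        return CHARGE_STATES.index(state) * 2 * N_ORBITAL_SLOTS

    @classmethod
    def occupancy_index(cls, state: str, slot: int) -> int:
        return cls.state_offset(state) + slot

    @classmethod
    def energy_index(cls, state: str, slot: int) -> int:
        return cls.state_offset(state) + N_ORBITAL_SLOTS + slot

    @classmethod
    def charge_index(cls, state: str) -> int:
        return 3 * 2 * N_ORBITAL_SLOTS + CHARGE_STATES.index(state)

    @classmethod
    def electronegativity_index(cls) -> int:
        return cls.length - 1

    @classmethod
    def column_names(cls) -> list[str]:
        names: list[str] = []
        for state in CHARGE_STATES:
            names += [f"{state}_occ{s}" for s in range(cls.n_slots)]
            names += [f"{state}_en{s}" for s in range(cls.n_slots)]
        names += [f"{state}_charge" for state in CHARGE_STATES]
        names.append("electronegativity")
        return names


class DescriptorError(RuntimeError):
    """Raised when a backend fails or returns inconsistent data."""


@dataclass
class SpeciesOrbitalData:
    """Orbital data for one charge state of a molecule.

    ``per_atom_orbitals[i]`` is a sequence of ``(slot, occupancy, energy)``
    triples for heavy atom ``i``; ``per_atom_charges[i]`` is that atom's
    natural charge in this state.  Atom ordering must agree across the
    three charge states of a molecule.
    """

    charge_state: str
    per_atom_orbitals: Sequence[Sequence[tuple[int, float, float]]]
    per_atom_charges: Sequence[float]

    def __post_init__(self) -> None:
        if self.charge_state not in CHARGE_STATES:
            raise ValueError(f"unknown charge state {self.charge_state!r}")
        if len(self.per_atom_orbitals) != len(self.per_atom_charges):
            raise ValueError("orbital and charge tables differ in length")
        for orbs in self.per_atom_orbitals:
            for _slot, occ, _en in orbs:
                if not 0.0 <= occ <= 2.0:
                    raise ValueError(f"occupancy {occ} outside [0, 2]")

    @property
    def n_atoms(self) -> int:
        return len(self.per_atom_orbitals)


@dataclass
class AtomFeatureVector:
    """The 34-entry descriptor of one heavy atom."""

    values: np.ndarray
    atom_index: int
    molecule_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (VECTOR_LENGTH,):
            raise ValueError(
                f"feature vector must have length {VECTOR_LENGTH}, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")


class QMBackend(Protocol):
    """Contract for orbital-data providers.

    ``compute`` must be deterministic for a fixed molecule and backend
    configuration, and must return data for all three charge states with
    identical heavy-atom ordering.
    """

    def compute(self, mol: Chem.Mol) -> Mapping[str, SpeciesOrbitalData]:
        ...


def heavy_atoms(mol: Chem.Mol) -> list[Chem.Atom]:
    return [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]


def _en(symbol: str) -> float:
    return ELECTRONEGATIVITY.get(symbol, _DEFAULT_EN)


def _topological_charges(mol: Chem.Mol) -> np.ndarray:
    """Closed-form electronegativity-equalization partial charges.

    Each atom receives charge proportional to the summed electronegativity
    differences to its bonded neighbours (implicit hydrogens included).
    A pure function of the local graph, hence exactly invariant under
    graph automorphisms — and coarse-grained enough that atoms in similar
    environments of *different* molecules share values.
    """
    atoms = heavy_atoms(mol)
    q = np.zeros(len(atoms))
    for i, atom in enumerate(atoms):
        en_i = _en(atom.GetSymbol())
        delta = 0.0
        for nbr in atom.GetNeighbors():
            if nbr.GetAtomicNum() > 1:
                delta += _en(nbr.GetSymbol()) - en_i
        delta += atom.GetTotalNumHs() * (_en("H") - en_i)
        q[i] = round(0.16 * delta, 4)
    return q


@dataclass
class MockQMBackend:
    """Deterministic topology-derived pseudo-orbital data.

    Occupancies and energies are closed-form functions of the element,
    heavy-atom degree, ring membership and the equalization charge of each
    atom.  The numbers are not quantum-chemically accurate; they reproduce
    the *structure* of an orbital population analysis (bounded occupancies,
    energy-ranked slots, systematic shifts between the neutral, cation and
    anion species) so the rest of the pipeline can be exercised and tested
    without electronic-structure software.
    """

    energy_scale: float = 0.35
    charge_coupling: float = 0.25

    def compute(self, mol: Chem.Mol) -> dict[str, SpeciesOrbitalData]:
        atoms = heavy_atoms(mol)
        if not atoms:
            raise DescriptorError("molecule has no heavy atoms")
        charges = _topological_charges(mol)
        # local susceptibility of each atom to electron removal/addition:
        # removal favours electropositive centres, addition electronegative.
        # Purely element-local so that atoms in comparable environments of
        # different molecules receive identical values.
        en = np.array([_en(a.GetSymbol()) for a in atoms])
        w_ox = np.round(0.4 * _en("C") / en, 4)
        w_red = np.round(0.4 * en / _en("C"), 4)

        out: dict[str, SpeciesOrbitalData] = {}
        for state in CHARGE_STATES:
            per_atom: list[list[tuple[int, float, float]]] = []
            per_charge: list[float] = []
            for i, atom in enumerate(atoms):
                sym = atom.GetSymbol()
                degree = sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1)
                n_h = atom.GetTotalNumHs()
                ring = 1.0 if atom.IsInRing() else 0.0
                n_orb = min(N_ORBITAL_SLOTS,
                            degree + n_h + _LONE_PAIRS.get(sym, 0))
                base_e = -self.energy_scale * _en(sym) / _en("C")
                triples: list[tuple[int, float, float]] = []
                for slot in range(n_orb):
                    occ = 2.0
                    energy = (base_e - 0.05 * slot + 0.02 * degree
                              - 0.03 * ring + self.charge_coupling * charges[i])
                    if state == "oxidized":
                        if slot == 0:  # highest-energy slot loses density
                            occ = max(0.0, 2.0 - w_ox[i])
                        energy -= 0.15 * w_ox[i] + 0.05
                    elif state == "reduced":
                        energy += 0.15 * w_red[i] + 0.05
                    triples.append((slot, round(occ, 4), round(energy, 4)))
                if state == "reduced" and n_orb < N_ORBITAL_SLOTS:
                    # the extra electron enters the first vacant slot
                    triples.append((n_orb, round(float(w_red[i]), 4),
                                    round(base_e + 0.3, 4)))
                q = charges[i]
                if state == "oxidized":
                    q = q + w_ox[i]
                elif state == "reduced":
                    q = q - w_red[i]
                per_atom.append(triples)
                per_charge.append(round(float(q), 4))
            out[state] = SpeciesOrbitalData(state, per_atom, per_charge)
        return out


@dataclass
class TableBackend:
    """Read-only import of per-atom orbital tables (e.g. NBO exports).

    Expects a table with columns ``molecule_id, atom_index, charge_state,
    orbital_slot, occupancy, energy`` and optionally ``natural_charge``.
    """

    table: pd.DataFrame
    molecule_ids: Mapping[int, str] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path) -> "TableBackend":
        return cls(pd.read_csv(path))

    def compute_by_id(self, molecule_id: str, n_atoms: int) -> dict[str, SpeciesOrbitalData]:
        sub = self.table[self.table["molecule_id"] == molecule_id]
        if sub.empty:
            raise DescriptorError(f"no orbital data for molecule {molecule_id!r}")
        out: dict[str, SpeciesOrbitalData] = {}
        for state in CHARGE_STATES:
            s = sub[sub["charge_state"] == state]
            if s.empty:
                raise DescriptorError(
                    f"molecule {molecule_id!r}: missing charge state {state!r}")
            per_atom: list[list[tuple[int, float, float]]] = [[] for _ in range(n_atoms)]
            per_charge = [0.0] * n_atoms
            for row in s.itertuples():
                idx = int(row.atom_index)
                if idx >= n_atoms:
                    raise DescriptorError(
                        f"molecule {molecule_id!r}: atom index {idx} out of range")
                per_atom[idx].append(
                    (int(row.orbital_slot), float(row.occupancy), float(row.energy)))
                if hasattr(row, "natural_charge") and not pd.isna(row.natural_charge):
                    per_charge[idx] = float(row.natural_charge)
            out[state] = SpeciesOrbitalData(state, per_atom, per_charge)
        return out

    def compute(self, mol: Chem.Mol) -> dict[str, SpeciesOrbitalData]:
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        return self.compute_by_id(mol_id, len(heavy_atoms(mol)))


def impute_missing_slots(
    raw: Mapping[str, Sequence[tuple[int, float, float]]],
    *,
    charges: Mapping[str, float] | None = None,
    electronegativity: float = 0.0,
    sentinel: float = 0.0,
    atom_index: int = 0,
    molecule_id: str = "",
) -> AtomFeatureVector:
    """Assemble one atom's 34-entry vector, filling unpopulated slots.

    ``raw`` maps charge state to that atom's (slot, occupancy, energy)
    triples.  Slots beyond the layout are truncated with a warning; absent
    states or slots are imputed with ``sentinel``.
    """
    values = np.full(VECTOR_LENGTH, sentinel, dtype=float)
    for state in CHARGE_STATES:
        for slot, occ, energy in raw.get(state, ()):  # type: ignore[arg-type]
            if slot >= N_ORBITAL_SLOTS:
                logger.warning(
                    "molecule %s atom %d (%s): orbital slot %d exceeds layout "
                    "(%d slots); truncated", molecule_id, atom_index, state,
                    slot, N_ORBITAL_SLOTS)
                continue
            values[FeatureLayout.occupancy_index(state, slot)] = occ
            values[FeatureLayout.energy_index(state, slot)] = energy
        if charges is not None and state in charges:
            values[FeatureLayout.charge_index(state)] = charges[state]
    values[FeatureLayout.electronegativity_index()] = electronegativity
    return AtomFeatureVector(values, atom_index, molecule_id)


def compute_atom_features(
    mol: Chem.Mol,
    backend: QMBackend,
    molecule_id: str = "",
) -> list[AtomFeatureVector]:
    """Featurize every heavy atom of ``mol`` through ``backend``.

    Returns one :class:`AtomFeatureVector` per heavy atom, in the parser's
    canonical atom order (hydrogens are excluded from featurization).
    """
    atoms = heavy_atoms(mol)
    if not atoms:
        raise DescriptorError(f"molecule {molecule_id!r} has no heavy atoms")
    try:
        species = backend.compute(mol)
    except DescriptorError:
        raise
    except Exception as exc:  # noqa: BLE001 — backend contract boundary
        raise DescriptorError(
            f"backend failed for molecule {molecule_id!r}: {exc}") from exc
    for state in CHARGE_STATES:
        if state not in species:
            raise DescriptorError(
                f"molecule {molecule_id!r}: backend returned no data "
                f"for state {state!r}")
        if species[state].n_atoms != len(atoms):
            raise DescriptorError(
                f"molecule {molecule_id!r}: state {state!r} has "
                f"{species[state].n_atoms} atoms, expected {len(atoms)}")
    vectors = []
    for i, atom in enumerate(atoms):
        raw = {state: species[state].per_atom_orbitals[i] for state in CHARGE_STATES}
        charges = {state: species[state].per_atom_charges[i] for state in CHARGE_STATES}
        vectors.append(
            impute_missing_slots(
                raw,
                charges=charges,
                electronegativity=_en(atom.GetSymbol()),
                atom_index=i,
                molecule_id=molecule_id,
            )
        )
    return vectors


def feature_matrix(vectors: Iterable[AtomFeatureVector]) -> np.ndarray:
    return np.vstack([v.values for v in vectors])


def features_to_frame(vectors: Iterable[AtomFeatureVector]) -> pd.DataFrame:
    """Long-form feature table: molecule_id, atom_index, f0..f33."""
    rows = [
        {"molecule_id": v.molecule_id, "atom_index": v.atom_index,
         **{f"f{i}": x for i, x in enumerate(v.values)}}
        for v in vectors
    ]
    return pd.DataFrame(rows)


def frame_to_features(frame: pd.DataFrame) -> list[AtomFeatureVector]:
    cols = [f"f{i}" for i in range(VECTOR_LENGTH)]
    return [
        AtomFeatureVector(row[cols].to_numpy(dtype=float),
                          int(row["atom_index"]), str(row["molecule_id"]))
        for _, row in frame.iterrows()
    ]
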