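"""Morgan circular-fingerprint baselines and feature concatenation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

VALID_LENGTHS = (512, 1024, 2048, 4096)


@dataclass
class BitFingerprint:
    bits: np.ndarray
    radius: int
    length: int

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (self.length,):
            raise ValueError("bit array length disagrees with declared length")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def morgan_fingerprint(mol: Chem.Mol, radius: int = 2,
                       length: int = 1024) -> BitFingerprint:
    """Circular (ECFP-like) bit fingerprint of ``mol``.

    Deterministic per molecule: two SMILES spellings of the same structure
    yield identical fingerprints.
    """
    if mol is None:
        raise ValueError("molecule failed to parse")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if length not in VALID_LENGTHS:
        raise ValueError(f"length must be one of {VALID_LENGTHS}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=length)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(length, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return BitFingerprint(arr, radius, length)


def concat_features(fp: BitFingerprint, dft: np.ndarray) -> np.ndarray:
    """Concatenate fingerprint bits with a dense vector, fp block first."""
    dft = np.asarray(dft, dtype=float)
    if fp.length == 0 or dft.size == 0:
        raise ValueError("both feature blocks must be non-empty")
    return np.concatenate([fp.bits.astype(float), dft])


def split_concat(vec: np.ndarray, fp_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`concat_features` given the fingerprint length."""
    return vec[:fp_length], vec[fp_length:]


def fingerprint_matrix(molecules: Iterable[tuple[str, Chem.Mol]],
                       radius: int = 2, length: int = 1024) -> pd.DataFrame:
    rows = []
    for mol_id, mol in molecules:
        fp = morgan_fingerprint(mol, radius, length)
        rows.append({"molecule_id": mol_id,
                     **{f"b{i}": int(b) for i, b in enumerate(fp.bits)}})
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    radius: int
    length: int
    score: float


def sweep_morgan_grid(
    molecules: Sequence[tuple[str, Chem.Mol]],
    labels: np.ndarray,
    scorer,
    radii: Sequence[int] = (1, 2, 3),
    lengths: Sequence[int] = (512, 1024, 2048),
) -> tuple[SweepResult, list[SweepResult]]:
    """Grid-evaluate fingerprint hyperparameters.

    ``scorer(X, y) -> float`` supplies the cross-validated figure of merit
    (higher is better); the best cell and the full grid are returned.
    Ties break toward smaller radius then smaller length.
    """
    results = []
    for radius in radii:
        for length in lengths:
            X = np.vstack([
                morgan_fingerprint(mol, radius, length).bits.astype(float)
                for _id, mol in molecules
            ])
            results.append(SweepResult(radius, length, float(scorer(X, labels))))
    best = max(results, key=lambda r: (r.score, -r.radius, -r.length))
    return best, results
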