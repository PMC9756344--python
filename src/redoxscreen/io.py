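"""Molecule parsing, manifests, and format round-tripping.

Supported inputs: SMILES lists (``.smi``, one ``SMILES<TAB>id`` record per
line) and SDF v2000.  Per-record parse failures are collected into a skip
report rather than aborting the run.  Every CLI run writes a JSON
manifest recording the configuration, derived seeds, and SHA-256 digests
of inputs and outputs, so identical manifests imply identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from rdkit import Chem

logger = logging.getLogger(__name__)


class ParseError(RuntimeError):
    pass


@dataclass
class SkippedRecord:
    line_number: int
    content: str
    reason: str


@dataclass
class SkipReport:
    skipped: list[SkippedRecord]

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def _parse_smi(path: Path) -> tuple[list[tuple[str, Chem.Mol]], SkipReport]:
    molecules, skipped = [], []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"line{lineno}"
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            skipped.append(SkippedRecord(lineno, line, "unparseable SMILES"))
            continue
        mol.SetProp("_Name", mol_id)
        molecules.append((mol_id, mol))
    return molecules, SkipReport(skipped)


def _parse_sdf(path: Path) -> tuple[list[tuple[str, Chem.Mol]], SkipReport]:
    molecules, skipped = [], []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for record_no, mol in enumerate(supplier, start=1):
        if mol is None:
            skipped.append(SkippedRecord(record_no, f"record {record_no}",
                                         "unparseable SDF record"))
            continue
        mol_id = (mol.GetProp("_Name")
                  if mol.HasProp("_Name") and mol.GetProp("_Name")
                  else f"record{record_no}")
        molecules.append((mol_id, mol))
    return molecules, SkipReport(skipped)


def parse_molecules(path, fmt: str | None = None
                    ) -> tuple[list[tuple[str, Chem.Mol]], SkipReport]:
    """Parse a molecule file into canonical RDKit molecules.

    ``fmt`` is ``"smi"`` or ``"sdf"``; inferred from the suffix when
    omitted.  Returns the parsed ``(molecule_id, mol)`` list and a report
    of skipped records.  An unreadable or empty file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise ParseError(f"empty molecule file: {path}")
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "smi":
        molecules, report = _parse_smi(path)
    elif fmt == "sdf":
        molecules, report = _parse_sdf(path)
    else:
        raise ParseError(f"unsupported molecule format {fmt!r}")
    if report.n_skipped:
        logger.warning("%s: skipped %d unparseable record(s)",
                       path, report.n_skipped)
    if not molecules:
        raise ParseError(f"{path}: no parseable molecules")
    return molecules, report


def write_smiles(molecules: Sequence[tuple[str, Chem.Mol]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mol_id, mol in molecules:
            fh.write(f"{Chem.MolToSmiles(mol)}\t{mol_id}\n")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, command: str, config: dict, seeds: dict,
                   inputs: Sequence[str] = (), outputs: Sequence[str] = (),
                   extra: dict | None = None) -> dict:
    """Record a run's provenance: config, seeds, input/output digests."""
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    if extra:
        manifest["extra"] = extra
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
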