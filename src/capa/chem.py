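"""Structure parsing, canonical identity and stereoisomer-aware deduplication.

Molecular identity throughout the package is the canonical SMILES of the
structure *after* all stereochemistry (tetrahedral and double-bond) has been
removed.  Two records that differ only as stereoisomers therefore share one
``canonical_key`` and collapse to a single library entry.  Tautomers, salts
and protonation states are deliberately *not* merged: the screening libraries
this package targets contain neutral, desalted compounds, and the redundancy
that has to be removed before pattern screening is stereo redundancy only.

Aromaticity is perceived once, at parse time, with RDKit's default
sanitization model; every downstream substructure match sees the same
perception.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty on stderr about kekulization etc.; errors are raised as
# ParseError with the offending record id instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


class ParseError(ValueError):
    """A record could not be parsed into a valid structure."""

    def __init__(self, record_id: str, reason: str):
        self.record_id = record_id
        self.reason = reason
        super().__init__(f"record {record_id!r}: {reason}")


@dataclass(frozen=True)
class Molecule:
    """A parsed structure with a stereo-agnostic canonical identity key.

    Attributes
    ----------
    id : str
        Record identifier as given in the input.
    smiles_input : str
        The SMILES exactly as provided.
    canonical_key : str
        Canonical SMILES after removal of all stereo descriptors; invariant
        under atom renumbering of the input.
    heavy_atom_count : int
        Number of non-hydrogen atoms (>= 1 for any parsed record).
    """

    id: str
    smiles_input: str
    canonical_key: str
    heavy_atom_count: int
    rdmol: Chem.Mol = field(repr=False, compare=False, hash=False)


def _stereo_free_canonical_smiles(mol: Chem.Mol) -> str:
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    return Chem.MolToSmiles(flat)


def parse_structure(smiles: str, id: str) -> Molecule:
    """Parse a SMILES record into a :class:`Molecule`.

    Invalid input is rejected with :class:`ParseError` naming the record;
    nothing is silently coerced.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError(id, "empty SMILES input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(id, f"unparsable SMILES {smiles!r}")
    if mol.GetNumHeavyAtoms() < 1:
        raise ParseError(id, "structure contains no heavy atoms")
    return Molecule(
        id=str(id),
        smiles_input=smiles,
        canonical_key=_stereo_free_canonical_smiles(mol),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        rdmol=mol,
    )


def strip_stereochemistry(mol: Molecule) -> Molecule:
    """Return the stereo-free counterpart of ``mol``.

    All tetrahedral and double-bond stereo descriptors are removed; the
    constitution (heavy-atom and bond multisets) is unchanged.  Idempotent.
    """
    flat = Chem.Mol(mol.rdmol)
    Chem.RemoveStereochemistry(flat)
    return Molecule(
        id=mol.id,
        smiles_input=Chem.MolToSmiles(flat),
        canonical_key=mol.canonical_key,
        heavy_atom_count=mol.heavy_atom_count,
        rdmol=flat,
    )


def deduplicate_stereoisomers(
    mols: Sequence[Molecule],
) -> tuple[list[Molecule], int]:
    """Collapse stereoisomer-redundant records to first-seen representatives.

    Both tetrahedral and geometric (E/Z) redundancy collapse, because the
    identity key is fully stereo-agnostic.  Input order is preserved, and
    ``len(unique) + removed == len(mols)``.
    """
    unique, removed = deduplicate_with_provenance(mols)
    return unique, len(removed)


def deduplicate_with_provenance(
    mols: Sequence[Molecule],
) -> tuple[list[Molecule], dict[str, str]]:
    """As :func:`deduplicate_stereoisomers`, also mapping removed id -> kept id."""
    seen: dict[str, str] = {}
    unique: list[Molecule] = []
    removed: dict[str, str] = {}
    for mol in mols:
        kept = seen.get(mol.canonical_key)
        if kept is None:
            seen[mol.canonical_key] = mol.id
            unique.append(mol)
        else:
            removed[mol.id] = kept
            logger.info("record %s removed as stereoisomer of %s", mol.id, kept)
    return unique, removed


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------


def read_smiles_file(path: str | Path) -> tuple[list[Molecule], list[ParseError]]:
    """Read a ``SMILES[whitespace]ID`` file, one record per line.

    Lines starting with ``#`` and blank lines are ignored.  Records lacking an
    explicit id are numbered by line.  Parse failures are collected, not
    raised.
    """
    mols: list[Molecule] = []
    errors: list[ParseError] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            rec_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            try:
                mols.append(parse_structure(smiles, rec_id))
            except ParseError as exc:
                errors.append(exc)
    return mols, errors


def read_csv_library(path: str | Path) -> tuple[list[dict], list[ParseError]]:
    """Read a CSV compound table with at least ``id`` and ``smiles`` columns.

    Returns row dicts augmented with a parsed ``molecule`` entry; other
    columns (e.g. per-target IC50 columns) pass through untouched for the
    classification layer.
    """
    rows: list[dict] = []
    errors: list[ParseError] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: CSV must have 'id' and 'smiles' columns")
        for row in reader:
            try:
                row = dict(row)
                row["molecule"] = parse_structure(row["smiles"], row["id"])
                rows.append(row)
            except ParseError as exc:
                errors.append(exc)
    return rows, errors


def read_sdf(path: str | Path) -> tuple[list[Molecule], list[ParseError]]:
    """Read a V2000 SDF; the molecule title field is used as record id."""
    mols: list[Molecule] = []
    errors: list[ParseError] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, rdmol in enumerate(supplier):
        rec_id = f"sdf{i + 1}"
        if rdmol is None:
            errors.append(ParseError(rec_id, "unparsable SDF record"))
            continue
        if rdmol.HasProp("_Name") and rdmol.GetProp("_Name").strip():
            rec_id = rdmol.GetProp("_Name").strip()
        try:
            mols.append(parse_structure(Chem.MolToSmiles(rdmol), rec_id))
        except ParseError as exc:
            errors.append(exc)
    return mols, errors


def write_smiles_file(mols: Iterable[Molecule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for mol in mols:
            fh.write(f"{mol.smiles_input}\t{mol.id}\n")
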