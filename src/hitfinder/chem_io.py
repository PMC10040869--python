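"""Molecule parsing, standardization and compound-table I/O.

Every structure entering the pipeline passes through :func:`standardize_molecule`,
which canonicalizes the SMILES, strips salts/counter-ions by keeping the largest
covalently bonded fragment, and derives the InChI key used as the compound
identity everywhere downstream (two records with equal InChI keys are the same
compound).

Policy notes
------------
* Salt stripping keeps the fragment with the most heavy atoms; ties are broken
  by molecular weight.  No charge neutralization or tautomer canonicalization
  is attempted — the identity key is the full (stereo-sensitive) InChI key.
* Invalid records encountered while reading a library are skipped with a
  warning and counted; an input yielding zero valid molecules is fatal.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

logger = logging.getLogger(__name__)

# RDKit is chatty about every bad SMILES; we report skips ourselves.
RDLogger.DisableLog("rdApp.error")


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecular graph."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        self.reason = reason
        super().__init__(f"{reason}: {smiles!r}")


class InputError(ValueError):
    """Fatal input problem (missing file, empty library, zero valid records)."""


@dataclass(frozen=True)
class Molecule:
    """A standardized compound: canonical SMILES + InChI key identity."""

    smiles: str
    inchikey: str
    source_id: str = ""

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - guarded by construction
            raise MoleculeParseError(self.smiles)
        return mol


@dataclass
class CompoundLibrary:
    """An ordered, identity-deduplicated collection of molecules."""

    molecules: list[Molecule] = field(default_factory=list)
    name: str = "library"

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self) -> Iterator[Molecule]:
        return iter(self.molecules)

    @property
    def inchikeys(self) -> list[str]:
        return [m.inchikey for m in self.molecules]

    @property
    def smiles(self) -> list[str]:
        return [m.smiles for m in self.molecules]


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]
    # Most heavy atoms wins; molecular weight breaks ties.
    return max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)))


def standardize_molecule(raw_smiles: str, source_id: str = "") -> Molecule:
    """Parse ``raw_smiles``, keep the largest fragment, canonicalize.

    Returns a :class:`Molecule` whose ``smiles`` is the RDKit canonical form of
    the largest covalently bonded fragment of the input and whose ``inchikey``
    is computed from that fragment.

    Raises
    ------
    MoleculeParseError
        If the SMILES cannot be parsed (callers typically log and skip).
    """
    if not isinstance(raw_smiles, str) or not raw_smiles.strip():
        raise MoleculeParseError(str(raw_smiles), "empty SMILES")
    mol = Chem.MolFromSmiles(raw_smiles.strip())
    if mol is None:
        raise MoleculeParseError(raw_smiles)
    mol = _largest_fragment(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # noqa: BLE001 - any sanitization failure is a parse error
        raise MoleculeParseError(raw_smiles, f"sanitization failed ({exc})") from exc
    smiles = Chem.MolToSmiles(mol)
    inchikey = Chem.MolToInchiKey(mol)
    if not inchikey:
        raise MoleculeParseError(raw_smiles, "InChI key generation failed")
    return Molecule(smiles=smiles, inchikey=inchikey, source_id=source_id)


def _iter_smi(path: Path) -> Iterator[tuple[str, str]]:
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"line{i + 1}"
            yield smiles, mol_id


def _iter_csv(path: Path) -> Iterator[tuple[str, str]]:
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols:
        raise InputError(f"{path}: CSV library needs a 'smiles' column")
    id_col = cols.get("id")
    for i, row in df.iterrows():
        smiles = row[cols["smiles"]]
        mol_id = str(row[id_col]) if id_col else f"row{i + 1}"
        yield ("" if pd.isna(smiles) else str(smiles)), mol_id


def _iter_sdf(path: Path) -> Iterator[tuple[str, str]]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            yield "", f"sdf_record{i + 1}"
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf_record{i + 1}"
        yield Chem.MolToSmiles(mol), mol_id


_READERS = {"smi": _iter_smi, "csv": _iter_csv, "sdf": _iter_sdf}


def read_library(path: str | Path, fmt: str | None = None, name: str | None = None) -> CompoundLibrary:
    """Read a screening library from ``.smi``, ``.csv`` or ``.sdf``.

    Every record is standardized; unparseable records are skipped with a
    warning; duplicates by InChI key are dropped keeping the first occurrence.
    Record order follows the file, so the result is reproducible from the same
    bytes.

    Raises
    ------
    InputError
        If the file is missing, the format is unknown, or no valid molecule
        survives parsing.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"library file not found: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _READERS:
        raise InputError(f"unsupported library format {fmt!r} (expected smi/csv/sdf)")
    molecules: list[Molecule] = []
    seen: set[str] = set()
    n_skipped = n_dup = 0
    for smiles, mol_id in _READERS[fmt](path):
        try:
            mol = standardize_molecule(smiles, source_id=mol_id)
        except MoleculeParseError:
            n_skipped += 1
            logger.warning("skipping unparseable record %s (%r)", mol_id, smiles)
            continue
        if mol.inchikey in seen:
            n_dup += 1
            continue
        seen.add(mol.inchikey)
        molecules.append(mol)
    if not molecules:
        raise InputError(f"{path}: no valid molecules (skipped {n_skipped})")
    logger.info(
        "read %d molecules from %s (%d unparseable skipped, %d duplicates dropped)",
        len(molecules), path, n_skipped, n_dup,
    )
    return CompoundLibrary(molecules=molecules, name=name or path.stem)


def library_to_frame(library: CompoundLibrary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "inchikey": [m.inchikey for m in library],
            "smiles": [m.smiles for m in library],
            "source_id": [m.source_id for m in library],
        }
    )


def write_table(rows: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write a table as UTF-8 CSV with header and deterministic column order."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if df.empty:
        raise InputError(f"refusing to write empty table to {path}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        df.to_csv(path, index=False, encoding="utf-8", quoting=csv.QUOTE_MINIMAL, float_format="%.12g")
    except OSError as exc:
        raise InputError(f"cannot write table to {path}: {exc}") from exc


def write_library_smi(library: CompoundLibrary, path: str | Path) -> None:
    """Write a library as a two-column ``.smi`` file (SMILES, id)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for mol in library:
            fh.write(f"{mol.smiles}\t{mol.source_id or mol.inchikey}\n")
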