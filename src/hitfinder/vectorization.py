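"""Molecular fingerprints: fixed-length bit-vectors for compound sets.

Four standard fingerprint families are supported, all delegated to RDKit's
reference implementations:

* ``morgan`` — circular environments up to a radius (default 2), hashed to
  ``n_bits`` (default 1024);
* ``atompair`` — typed atom pairs with topological distances, hashed;
* ``torsion`` — topological torsions (paths of four heavy atoms), hashed;
* ``maccs`` — the 166 MDL substructure keys.  RDKit returns a 167-long vector
  whose bit 0 is unused padding, so key *i* lives at index *i*; the matrix
  keeps the native 167 length.

Chirality is not hashed (toolkit default).  Vectors are binary (presence,
not counts) and deterministic: any SMILES notation of the same molecule
yields an identical vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .chem_io import CompoundLibrary, InputError, Molecule

logger = logging.getLogger(__name__)

FingerprintKind = Literal["morgan", "atompair", "torsion", "maccs"]

MACCS_VECTOR_LENGTH = 167  # 166 keys + unused bit 0


class ConfigError(ValueError):
    """Invalid fingerprint/model configuration."""


@dataclass(frozen=True)
class FingerprintSpec:
    kind: FingerprintKind = "morgan"
    radius: int = 2
    n_bits: int = 1024

    def __post_init__(self) -> None:
        if self.kind not in ("morgan", "atompair", "torsion", "maccs"):
            raise ConfigError(f"unsupported fingerprint kind {self.kind!r}")
        if self.n_bits <= 0 or self.radius < 0:
            raise ConfigError("n_bits must be > 0 and radius >= 0")

    @property
    def length(self) -> int:
        return MACCS_VECTOR_LENGTH if self.kind == "maccs" else self.n_bits

    def to_dict(self) -> dict:
        return {"kind": self.kind, "radius": self.radius, "n_bits": self.n_bits}

    @classmethod
    def from_dict(cls, d: dict) -> "FingerprintSpec":
        return cls(kind=d["kind"], radius=int(d["radius"]), n_bits=int(d["n_bits"]))


def _generator(spec: FingerprintSpec):
    if spec.kind == "morgan":
        return rdFingerprintGenerator.GetMorganGenerator(radius=spec.radius, fpSize=spec.n_bits)
    if spec.kind == "atompair":
        return rdFingerprintGenerator.GetAtomPairGenerator(fpSize=spec.n_bits)
    if spec.kind == "torsion":
        return rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=spec.n_bits)
    raise ConfigError(f"no hashed generator for {spec.kind!r}")


def compute_fingerprint(molecule: Molecule | Chem.Mol, spec: FingerprintSpec) -> np.ndarray:
    """Binary fingerprint vector (dtype uint8) for one molecule."""
    mol = molecule.to_rdkit() if isinstance(molecule, Molecule) else molecule
    if spec.kind == "maccs":
        bv = MACCSkeys.GenMACCSKeys(mol)
        arr = np.zeros(MACCS_VECTOR_LENGTH, dtype=np.uint8)
        arr[list(bv.GetOnBits())] = 1
        return arr
    return _generator(spec).GetFingerprintAsNumPy(mol).astype(np.uint8)


@dataclass
class FingerprintMatrix:
    """Row-aligned fingerprints for an ordered compound set."""

    keys: list[str]
    bits: np.ndarray
    spec: FingerprintSpec = field(default_factory=FingerprintSpec)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.keys):
            raise ValueError("bits must be 2-D with one row per key")
        if self.bits.shape[1] != self.spec.length:
            raise ValueError(
                f"row length {self.bits.shape[1]} != spec length {self.spec.length}"
            )

    def __len__(self) -> int:
        return len(self.keys)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(self.bits, columns=[f"bit_{i}" for i in range(self.bits.shape[1])])
        df.insert(0, "inchikey", self.keys)
        header = f"# fingerprint={self.spec.kind} radius={self.spec.radius} n_bits={self.spec.n_bits}\n"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FingerprintMatrix":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("# fingerprint="):
                raise InputError(f"{path}: missing fingerprint spec header")
            fields = dict(part.split("=") for part in header[2:].split())
            spec = FingerprintSpec(
                kind=fields["fingerprint"], radius=int(fields["radius"]), n_bits=int(fields["n_bits"])
            )
            df = pd.read_csv(fh)
        keys = df["inchikey"].astype(str).tolist()
        bits = df.drop(columns=["inchikey"]).to_numpy(dtype=np.uint8)
        return cls(keys=keys, bits=bits, spec=spec)


def vectorize_set(
    compounds: CompoundLibrary | Sequence[Molecule] | Iterable[Molecule],
    spec: FingerprintSpec = FingerprintSpec(),
) -> FingerprintMatrix:
    """One fingerprint row per compound, order-preserving.

    Compounds whose fingerprint computation fails are skipped with a warning
    and excluded from the keys; if every compound fails, that is fatal.
    """
    molecules = list(compounds.molecules if isinstance(compounds, CompoundLibrary) else compounds)
    if not molecules:
        raise InputError("cannot vectorize an empty compound set")
    keys: list[str] = []
    rows: list[np.ndarray] = []
    n_failed = 0
    for mol in molecules:
        try:
            rows.append(compute_fingerprint(mol, spec))
            keys.append(mol.inchikey)
        except Exception:  # noqa: BLE001 - any toolkit failure is a per-row skip
            n_failed += 1
            logger.warning("fingerprint failed for %s; row skipped", mol.inchikey)
    if not rows:
        raise InputError(f"all {n_failed} compounds failed fingerprinting")
    if n_failed:
        logger.warning("%d of %d compounds failed fingerprinting", n_failed, len(molecules))
    return FingerprintMatrix(keys=keys, bits=np.vstack(rows), spec=spec)
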