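"""Offline synthetic fixtures with a planted structure-activity relationship.

The generator emulates, at desk scale, the situation the pipeline is built
for: a family of homologous pseudo-targets whose active ligands share a
recognizable chemical motif (default: a benzenesulfonamide group) with potent
activity values, while inactives and most screening-library decoys lack it.
It emits exactly the offline inputs the pipeline consumes:

* a homology table (query + homologs with percent identities),
* a ChEMBL-schema bioactivity CSV (one IC50 record per compound-target pair;
  potencies drawn from lognormals whose medians straddle the 1000 nM labeling
  cutoff by more than an order of magnitude on each side, so labeling is
  nearly — but not exactly — deterministic),
* a ``.smi`` screening library in which a small fraction of compounds carry
  the planted motif.

Compounds are assembled combinatorially from scaffold templates and fragment
lists (never random strings), so every structure is chemically valid and the
motif is planted or excluded by construction.  Generation is fully seeded:
the same spec yields byte-identical files.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import (
    CompoundLibrary,
    InputError,
    Molecule,
    MoleculeParseError,
    standardize_molecule,
    write_library_smi,
)

logger = logging.getLogger(__name__)

DEFAULT_PLANTED_SMARTS = "NS(=O)(=O)c1ccccc1"  # benzenesulfonamide motif

# Scaffold templates carrying the planted benzenesulfonamide motif.
_ACTIVE_TEMPLATES = (
    "O=S(=O)(N{a})c1ccc({b})cc1",
    "O=S(=O)(N{a})c1cccc({b})c1",
    "O=S(=O)(N{a})c1ccc({b})c(C)c1",
    "O=S(=O)(N{a})c1ccc({b})c(F)c1",
    "O=S(=O)(N{a})c1ccc({b})c(Cl)c1",
    "O=S(=O)(N{a})c1ccc({b})c(OC)c1",
)

# Decoy scaffolds: amides, esters, anilines and a pyridine-sulfonamide
# near-miss; none can contain an N-S(=O)(=O)-benzene motif.
_DECOY_TEMPLATES = (
    "O=C(N{a})c1ccc({b})c({c})c1",
    "O=C(N{a})c1cc({c})cc({b})c1",
    "{a}Nc1ccc({b})c({c})c1",
    "O=C(O{a})c1ccc({b})c({c})c1",
    "O=C(N{a})c1cc({c})nc({b})c1",
    "{a}N(C)C(=O)c1ccc({b})c({c})c1",
    "O=S(=O)(N{a})c1cc({c})nc({b})c1",
    "{a}NC(=O)C({c}){b}",
    "O=C(N{a})Nc1ccc({b})c({c})c1",
    "{a}Oc1ccc({b})c({c})c1",
    "O=S(=O)(C{a})c1ccc({b})c({c})c1",
)

_FRAG_A = (
    "C", "CC", "CCC", "C(C)C", "CC(C)C", "CCO", "CCOC",
    "CCN(C)C", "C2CCCC2", "C2CCCCC2", "Cc2ccccc2", "CCc2ccccc2",
)
_FRAG_B = (
    "C", "CC", "OC", "F", "Cl", "Br", "O", "N(C)C",
    "C(F)(F)F", "CCO", "OCC", "C#N",
)
_FRAG_C = ("C", "CC", "OC", "F", "Cl", "O", "N", "CCO")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic structure-activity world."""

    n_targets: int = 5
    identities: tuple[float, ...] = (100.0, 85.0, 70.0, 55.0, 45.0)
    n_actives_per_target: int = 40
    n_inactives_per_target: int = 160
    planted_smarts: str = DEFAULT_PLANTED_SMARTS
    active_potency_median_nm: float = 100.0
    active_potency_sigma: float = 1.0
    inactive_potency_median_nm: float = 30000.0
    inactive_potency_sigma: float = 1.0
    library_size: int = 5000
    library_planted_fraction: float = 0.05
    micromolar_fraction: float = 0.2  # records expressed in uM instead of nM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or len(self.identities) != self.n_targets:
            raise ValueError("identities must list one percent identity per target")
        if min(self.n_actives_per_target, self.n_inactives_per_target, self.library_size) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.library_planted_fraction <= 1.0:
            raise ValueError("library_planted_fraction must be in [0, 1]")
        if not self.active_potency_median_nm < 1000.0 < self.inactive_potency_median_nm:
            raise ValueError("potency medians must straddle the 1000 nM labeling cutoff")
        if Chem.MolFromSmarts(self.planted_smarts) is None:
            raise ValueError(f"invalid planted SMARTS: {self.planted_smarts!r}")

    @property
    def query_uniprot(self) -> str:
        return "P10001"

    def target_uniprots(self) -> list[str]:
        return [f"P{10001 + i:05d}" for i in range(self.n_targets)]


@dataclass(frozen=True)
class FixturePaths:
    homology: Path
    bioactivity: Path
    library: Path


def plant_check(molecule: Molecule | Chem.Mol | str, smarts: str = DEFAULT_PLANTED_SMARTS) -> bool:
    """True when the molecule contains the planted substructure."""
    pattern = Chem.MolFromSmarts(smarts)
    if pattern is None:
        raise ValueError(f"invalid SMARTS pattern: {smarts!r}")
    if isinstance(molecule, Molecule):
        mol = molecule.to_rdkit()
    elif isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise MoleculeParseError(molecule)
    else:
        mol = molecule
    return mol.HasSubstructMatch(pattern)


def _assemble(
    templates: Sequence[str],
    rng: np.random.Generator,
    n_needed: int,
    require_motif: bool | None,
    smarts: str,
    exclude: set[str],
    id_prefix: str,
) -> list[Molecule]:
    """Draw unique valid molecules from the template x fragment space.

    ``require_motif`` True keeps only motif matches, False only non-matches.
    Uniqueness is by InChI key against ``exclude`` (updated in place).
    """
    combos = [
        (t, a, b, c)
        for t in templates
        for a in _FRAG_A
        for b in _FRAG_B
        for c in _FRAG_C
    ]
    order = rng.permutation(len(combos))
    out: list[Molecule] = []
    for idx in order:
        if len(out) >= n_needed:
            break
        template, a, b, c = combos[idx]
        smiles = template.format(a=a, b=b, c=c)
        try:
            mol = standardize_molecule(smiles, source_id=f"{id_prefix}{len(out) + 1:06d}")
        except MoleculeParseError:
            continue
        if mol.inchikey in exclude:
            continue
        if require_motif is not None and plant_check(mol, smarts) != require_motif:
            continue
        exclude.add(mol.inchikey)
        out.append(mol)
    if len(out) < n_needed:
        raise InputError(
            f"fragment space exhausted: needed {n_needed} unique molecules, built {len(out)}"
        )
    return out


def _potency_rows(
    rng: np.random.Generator,
    molecules: Sequence[Molecule],
    target: str,
    median_nm: float,
    sigma: float,
    micromolar_fraction: float,
) -> Iterator[dict]:
    values = rng.lognormal(mean=np.log(median_nm), sigma=sigma, size=len(molecules))
    in_um = rng.random(len(molecules)) < micromolar_fraction
    for mol, value_nm, um in zip(molecules, values, in_um):
        if um:
            value, units = value_nm / 1000.0, "uM"
        else:
            value, units = value_nm, "nM"
        yield {
            "smiles": mol.smiles,
            "inchikey": mol.inchikey,
            "target_uniprot": target,
            "value_type": "IC50",
            "standard_value": f"{value:.6g}",
            "standard_units": units,
        }


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixturePaths:
    """Write the homology table, bioactivity corpus and screening library.

    Every target gets a disjoint set of planted actives and motif-free
    inactives; the library mixes planted decoys (``library_planted_fraction``)
    into a motif-free background.  Deterministic per seed: same spec, same
    bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    targets = spec.target_uniprots()

    n_planted_lib = round(spec.library_size * spec.library_planted_fraction)
    n_active_total = spec.n_actives_per_target * spec.n_targets + n_planted_lib
    n_decoy_total = (
        spec.n_inactives_per_target * spec.n_targets + spec.library_size - n_planted_lib
    )
    seen: set[str] = set()
    planted = _assemble(
        _ACTIVE_TEMPLATES, rng, n_active_total, True, spec.planted_smarts, seen, "ACT"
    )
    decoys = _assemble(
        _DECOY_TEMPLATES, rng, n_decoy_total, False, spec.planted_smarts, seen, "DEC"
    )

    # Homology table: query self-hit plus homologs at the stated identities.
    homology = pd.DataFrame(
        {
            "query_uniprot": spec.query_uniprot,
            "gene_name": [("QRY1" if i == 0 else f"HOM{i}") for i in range(spec.n_targets)],
            "subject_uniprot": targets,
            "percent_identity": list(spec.identities),
        }
    )
    homology_path = out_dir / "homology.csv"
    homology.to_csv(homology_path, index=False)

    # Bioactivity corpus: one IC50 record per compound-target pair.
    rows: list[dict] = []
    a_off = i_off = 0
    for target in targets:
        target_actives = planted[a_off : a_off + spec.n_actives_per_target]
        a_off += spec.n_actives_per_target
        target_inactives = decoys[i_off : i_off + spec.n_inactives_per_target]
        i_off += spec.n_inactives_per_target
        rows.extend(
            _potency_rows(
                rng, target_actives, target,
                spec.active_potency_median_nm, spec.active_potency_sigma,
                spec.micromolar_fraction,
            )
        )
        rows.extend(
            _potency_rows(
                rng, target_inactives, target,
                spec.inactive_potency_median_nm, spec.inactive_potency_sigma,
                spec.micromolar_fraction,
            )
        )
    bioactivity_path = out_dir / "bioactivity.csv"
    pd.DataFrame(rows).to_csv(bioactivity_path, index=False)

    # Screening library: planted decoys shuffled into the motif-free background.
    lib_molecules = list(planted[a_off:]) + list(decoys[i_off:])
    lib_order = rng.permutation(len(lib_molecules))
    library = CompoundLibrary(
        molecules=[
            Molecule(
                smiles=lib_molecules[i].smiles,
                inchikey=lib_molecules[i].inchikey,
                source_id=f"LIB{pos + 1:06d}",
            )
            for pos, i in enumerate(lib_order)
        ],
        name="synthetic_library",
    )
    library_path = out_dir / "library.smi"
    write_library_smi(library, library_path)

    logger.info(
        "fixture written to %s: %d targets, %d bioactivity records, library of %d "
        "(%d planted)",
        out_dir, spec.n_targets, len(rows), len(library), n_planted_lib,
    )
    return FixturePaths(homology=homology_path, bioactivity=bioactivity_path, library=library_path)


def expected_active_recovery(spec: FixtureSpec, potency_cutoff_nm: float = 1000.0) -> float:
    """Closed-form probability that a planted active labels as active.

    A single lognormal potency draw passes the cutoff when
    ``ln(X) <= ln(cutoff)``, i.e. with probability
    ``Phi((ln cutoff - ln median) / sigma)``.
    """
    from scipy.stats import norm

    z = (np.log(potency_cutoff_nm) - np.log(spec.active_potency_median_nm)) / spec.active_potency_sigma
    return float(norm.cdf(z))


def planted_bit_dataset(
    n_per_class: int = 100,
    n_bits: int = 1024,
    n_planted: int = 8,
    background_density: float = 0.05,
    planted_on_rate: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic fingerprint matrix with a planted, nearly separable signal.

    Actives carry ``n_planted`` dedicated bits set with high probability;
    inactives set them at the background density.  Returns (X, y) with y=1
    for actives.  Used for classifier sanity checks independent of chemistry.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = (rng.random((n, n_bits)) < background_density).astype(np.uint8)
    y = np.array([1] * n_per_class + [0] * n_per_class, dtype=int)
    planted_cols = rng.choice(n_bits, size=n_planted, replace=False)
    X[: n_per_class, planted_cols] = (
        rng.random((n_per_class, n_planted)) < planted_on_rate
    ).astype(np.uint8)
    X[n_per_class:, planted_cols] = (
        rng.random((n_per_class, n_planted)) < background_density
    ).astype(np.uint8)
    perm = rng.permutation(n)
    return X[perm], y[perm]
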