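"""Bioactivity retrieval, unit normalization and active/inactive labeling.

Records are fetched for the expanded target list from a bioactivity source
(offline CSV fixture with a ChEMBL-like schema, or the live ChEMBL service
when the optional web client is installed).  The dominant assay value type
across the corpus is selected, concentrations are normalized to nM, replicate
measurements per compound are aggregated by median, and compounds are labeled:

* ``Ki``/``IC50``/``EC50``: active when the median potency <= 1000 nM (default);
* ``INH`` (percent inhibition): active when the median >= 50% (default).

Both cutoff comparisons are inclusive.  Measurements are pooled across all
expanded targets before taking the median ("pooled-median" policy); an
alternative "any-active" policy labels a compound active when its per-target
median passes the cutoff on at least one target.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Protocol

import pandas as pd

from .chem_io import InputError, Molecule, MoleculeParseError, standardize_molecule
from .target_expansion import HomologHit

logger = logging.getLogger(__name__)

ValueType = Literal["Ki", "IC50", "EC50", "INH", "other"]

#: Controlled vocabulary and the fixed tie-break priority (binding-first).
VALUE_TYPE_PRIORITY: tuple[str, ...] = ("Ki", "IC50", "EC50", "INH")

_VALUE_TYPE_ALIASES = {
    "ki": "Ki",
    "ic50": "IC50",
    "ec50": "EC50",
    "inh": "INH",
    "%inh": "INH",
    "inhibition": "INH",
    "percent inhibition": "INH",
}

_UNIT_TO_NM = {
    "pm": 1e-3,
    "nm": 1.0,
    "um": 1e3,
    "µm": 1e3,
    "μm": 1e3,
    "mm": 1e6,
    "m": 1e9,
}

CONCENTRATION_TYPES = frozenset({"Ki", "IC50", "EC50"})

FIXTURE_COLUMNS = ["smiles", "target_uniprot", "value_type", "standard_value", "standard_units"]


def normalize_value_type(raw: str) -> str:
    return _VALUE_TYPE_ALIASES.get(str(raw).strip().lower(), "other")


def normalize_to_nm(value: float, units: str) -> float | None:
    """Scale a concentration to nM; ``None`` when the unit is unknown."""
    factor = _UNIT_TO_NM.get(str(units).strip().lower())
    if factor is None or value is None or not math.isfinite(value):
        return None
    return float(value) * factor


@dataclass(frozen=True)
class ActivityRecord:
    """One experimental measurement tying a compound to a target."""

    molecule: Molecule
    target_uniprot: str
    value_type: str
    standard_value: float
    standard_units: str

    @property
    def value_nm(self) -> float | None:
        """Concentration in nM for Ki/IC50/EC50; raw percentage for INH."""
        if self.value_type == "INH":
            if str(self.standard_units).strip().lower() in {"%", "percent", "pct", ""}:
                return float(self.standard_value)
            return None
        return normalize_to_nm(self.standard_value, self.standard_units)


@dataclass(frozen=True)
class LabelingConfig:
    potency_cutoff_nm: float = 1000.0
    inhibition_cutoff_pct: float = 50.0
    conflict_policy: Literal["pooled-median", "any-active"] = "pooled-median"

    def __post_init__(self) -> None:
        if self.potency_cutoff_nm <= 0 or self.inhibition_cutoff_pct <= 0:
            raise ValueError("labeling cutoffs must be strictly positive")


@dataclass(frozen=True)
class LabeledCompound:
    molecule: Molecule
    label: Literal["active", "inactive"]
    evidence_count: int = 1


class BioactivitySource(Protocol):
    def records_for(self, target_uniprot: str) -> pd.DataFrame:
        """Rows with the fixture schema for one target (possibly empty)."""


class CsvBioactivitySource:
    """Offline bioactivity corpus with the ChEMBL-like fixture schema.

    Columns: ``smiles, target_uniprot, value_type, standard_value,
    standard_units`` (an ``inchikey`` column, when present, is ignored and
    recomputed from the structure).
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if not self.path.is_file():
            raise InputError(f"bioactivity fixture not found: {self.path}")
        self._table = pd.read_csv(self.path)
        missing = set(FIXTURE_COLUMNS) - set(self._table.columns)
        if missing:
            raise InputError(f"{self.path}: missing bioactivity columns {sorted(missing)}")

    def records_for(self, target_uniprot: str) -> pd.DataFrame:
        return self._table[self._table["target_uniprot"] == target_uniprot]


class ChemblWebSource:  # pragma: no cover - requires the optional web client
    """Live ChEMBL bioactivity source (network + optional client required)."""

    def records_for(self, target_uniprot: str) -> pd.DataFrame:
        try:
            from chembl_webresource_client.new_client import new_client
        except ImportError as exc:
            raise InputError(
                "live ChEMBL retrieval needs the 'chembl_webresource_client' package; "
                "use the CSV fixture source offline"
            ) from exc
        targets = new_client.target.filter(
            target_components__accession=target_uniprot
        ).only(["target_chembl_id"])
        rows = []
        for tgt in targets:
            acts = new_client.activity.filter(
                target_chembl_id=tgt["target_chembl_id"]
            ).only(["canonical_smiles", "standard_type", "standard_value", "standard_units"])
            for act in acts:
                rows.append(
                    {
                        "smiles": act.get("canonical_smiles"),
                        "target_uniprot": target_uniprot,
                        "value_type": act.get("standard_type"),
                        "standard_value": act.get("standard_value"),
                        "standard_units": act.get("standard_units"),
                    }
                )
        return pd.DataFrame(rows, columns=FIXTURE_COLUMNS)


def fetch_records(
    targets: Iterable[HomologHit | str],
    source: BioactivitySource,
) -> list[ActivityRecord]:
    """Fetch and standardize one :class:`ActivityRecord` per measurement.

    Structures are standardized through ``chem_io``; unparseable SMILES are
    skipped and counted.  Records with non-normalizable units are retained
    here (flagged via ``value_nm is None``) and excluded at labeling time.
    """
    records: list[ActivityRecord] = []
    n_skipped = 0
    for target in targets:
        uniprot = target.uniprot_id if isinstance(target, HomologHit) else str(target)
        rows = source.records_for(uniprot)
        if rows.empty:
            logger.warning("no bioactivity records for target %s", uniprot)
            continue
        for row in rows.itertuples(index=False):
            try:
                mol = standardize_molecule(str(row.smiles))
            except MoleculeParseError:
                n_skipped += 1
                logger.warning("skipping record with unparseable SMILES %r", row.smiles)
                continue
            try:
                value = float(row.standard_value)
            except (TypeError, ValueError):
                n_skipped += 1
                continue
            records.append(
                ActivityRecord(
                    molecule=mol,
                    target_uniprot=uniprot,
                    value_type=normalize_value_type(row.value_type),
                    standard_value=value,
                    standard_units=str(row.standard_units),
                )
            )
    logger.info("fetched %d activity records (%d skipped)", len(records), n_skipped)
    return records


def datatype_distribution(records: list[ActivityRecord]) -> pd.DataFrame:
    counts = Counter(r.value_type for r in records)
    order = list(VALUE_TYPE_PRIORITY) + ["other"]
    rows = [{"value_type": t, "n_records": counts[t]} for t in order if counts[t]]
    return pd.DataFrame(rows)


def select_primary_value_type(records: list[ActivityRecord]) -> str:
    """Pick the assay value type with the most records over the whole corpus.

    Ties are broken by the fixed priority Ki > IC50 > EC50 > INH > other.
    """
    if not records:
        raise InputError("cannot select a value type from zero records")
    counts = Counter(r.value_type for r in records)
    order = {t: i for i, t in enumerate((*VALUE_TYPE_PRIORITY, "other"))}
    chosen = min(counts, key=lambda t: (-counts[t], order.get(t, len(order))))
    logger.info("primary value type: %s (%d of %d records)", chosen, counts[chosen], len(records))
    return chosen


def _passes(median: float, value_type: str, config: LabelingConfig) -> bool:
    if value_type == "INH":
        return median >= config.inhibition_cutoff_pct
    return median <= config.potency_cutoff_nm


def label_compounds(
    records: list[ActivityRecord],
    chosen_type: str,
    config: LabelingConfig = LabelingConfig(),
) -> list[LabeledCompound]:
    """Aggregate measurements per compound and assign active/inactive labels.

    Only records of ``chosen_type`` with normalizable values participate.
    Under the default pooled-median policy the median is taken over all
    measurements of a compound across the expanded targets; under
    "any-active" the compound is active when any single target's median
    passes the cutoff.  Every labelable compound receives exactly one label.
    """
    if chosen_type == "other":
        raise InputError("cannot label on the 'other' value type")
    per_compound: dict[str, list[ActivityRecord]] = defaultdict(list)
    n_non_normalizable = 0
    for rec in records:
        if rec.value_type != chosen_type:
            continue
        if rec.value_nm is None:
            n_non_normalizable += 1
            continue
        per_compound[rec.molecule.inchikey].append(rec)
    if not per_compound:
        raise InputError(
            f"zero labelable records for value type {chosen_type} "
            f"({n_non_normalizable} non-normalizable)"
        )
    if n_non_normalizable:
        logger.warning("%d records with non-normalizable units excluded", n_non_normalizable)

    labeled: list[LabeledCompound] = []
    n_conflicts = 0
    for key in sorted(per_compound):
        recs = per_compound[key]
        values = [r.value_nm for r in recs]
        if config.conflict_policy == "any-active":
            by_target: dict[str, list[float]] = defaultdict(list)
            for r in recs:
                by_target[r.target_uniprot].append(r.value_nm)
            per_target_pass = [
                _passes(_median(vals), chosen_type, config) for vals in by_target.values()
            ]
            active = any(per_target_pass)
            if any(per_target_pass) and not all(per_target_pass):
                n_conflicts += 1
        else:
            active = _passes(_median(values), chosen_type, config)
        labeled.append(
            LabeledCompound(
                molecule=recs[0].molecule,
                label="active" if active else "inactive",
                evidence_count=len(recs),
            )
        )
    n_active = sum(1 for c in labeled if c.label == "active")
    logger.info(
        "labeled %d compounds: %d active / %d inactive (%d cross-target conflicts)",
        len(labeled), n_active, len(labeled) - n_active, n_conflicts,
    )
    return labeled


def _median(values: list[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


def labeled_to_frames(labeled: list[LabeledCompound]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a labeled set into (active, inactive) tables."""

    def _frame(items: list[LabeledCompound]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "inchikey": [c.molecule.inchikey for c in items],
                "smiles": [c.molecule.smiles for c in items],
                "evidence_count": [c.evidence_count for c in items],
            }
        )

    actives = [c for c in labeled if c.label == "active"]
    inactives = [c for c in labeled if c.label == "inactive"]
    return _frame(actives), _frame(inactives)
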