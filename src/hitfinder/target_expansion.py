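"""Homology-based target expansion.

A single query protein rarely has enough annotated chemistry to train a
classifier, so the query is expanded to sequence-similar proteins (default:
human) whose ligands are pooled as surrogate training data.  Hits at or above
the identity cutoff (default 40%) are retained.

Two interchangeable backends implement the search:

* :class:`CsvHomologyBackend` — an offline table of precomputed hits; the
  default and the only backend exercised by the test suite.
* :class:`NcbiBlastBackend` — live BLASTp over NCBI via Biopython; requires
  network access and is provided for completeness.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import pandas as pd

from .chem_io import InputError, write_table

logger = logging.getLogger(__name__)

# UniProt accession syntax (release 2023 rules, both 6- and 10-char forms).
_UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)

FIXTURE_COLUMNS = ["query_uniprot", "gene_name", "subject_uniprot", "percent_identity"]


@dataclass(frozen=True)
class TargetQuery:
    uniprot_id: str
    organism_filter: str = "human"

    def __post_init__(self) -> None:
        if not _UNIPROT_RE.match(self.uniprot_id):
            raise ValueError(f"not a UniProt accession: {self.uniprot_id!r}")


@dataclass(frozen=True)
class HomologHit:
    gene_name: str
    uniprot_id: str
    percent_identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity out of [0, 100]: {self.percent_identity}")


@dataclass(frozen=True)
class ExpansionConfig:
    identity_cutoff: float = 40.0
    include_query: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_cutoff <= 100.0:
            raise ValueError(f"identity cutoff out of (0, 100]: {self.identity_cutoff}")


class HomologyBackend(Protocol):
    def search(self, query: TargetQuery) -> list[HomologHit]:
        """Return all reported hits for the query (unfiltered by identity)."""


class CsvHomologyBackend:
    """Offline backend reading a precomputed homology table.

    Expected columns: ``query_uniprot, gene_name, subject_uniprot,
    percent_identity``.  Organism filtering is assumed to have happened when
    the table was built.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if not self.path.is_file():
            raise InputError(f"homology fixture not found: {self.path}")
        self._table = pd.read_csv(self.path)
        missing = set(FIXTURE_COLUMNS) - set(self._table.columns)
        if missing:
            raise InputError(f"{self.path}: missing homology columns {sorted(missing)}")

    def search(self, query: TargetQuery) -> list[HomologHit]:
        rows = self._table[self._table["query_uniprot"] == query.uniprot_id]
        if rows.empty:
            logger.warning("no homology rows for query %s", query.uniprot_id)
            return []
        return [
            HomologHit(str(r.gene_name), str(r.subject_uniprot), float(r.percent_identity))
            for r in rows.itertuples()
        ]


class NcbiBlastBackend:
    """Live BLASTp search against NCBI (network required, untested offline).

    Restricts hits to the query's organism via an entrez query and reports the
    best (maximum) percent identity per subject, as returned by the service.
    """

    def __init__(self, hitlist_size: int = 50):
        self.hitlist_size = hitlist_size

    def search(self, query: TargetQuery) -> list[HomologHit]:  # pragma: no cover - network
        from Bio.Blast import NCBIWWW, NCBIXML  # lazy: only needed online

        taxon = "txid9606[ORGN]" if query.organism_filter == "human" else query.organism_filter
        handle = NCBIWWW.qblast(
            "blastp", "swissprot", query.uniprot_id,
            entrez_query=taxon, hitlist_size=self.hitlist_size,
        )
        record = NCBIXML.read(handle)
        hits: list[HomologHit] = []
        for alignment in record.alignments:
            best = max(
                100.0 * hsp.identities / hsp.align_length for hsp in alignment.hsps
            )
            accession = alignment.accession.split(".")[0]
            hits.append(HomologHit(alignment.hit_def.split("|")[-1], accession, best))
        return hits


def search_homologs(query: TargetQuery, backend: HomologyBackend) -> list[HomologHit]:
    """Run the homology search and collapse to one hit per subject accession.

    When the backend reports several alignments for the same subject, the
    maximum percent identity is kept.  The result is unfiltered by identity.
    """
    raw = backend.search(query)
    best: dict[str, HomologHit] = {}
    for hit in raw:
        prev = best.get(hit.uniprot_id)
        if prev is None or hit.percent_identity > prev.percent_identity:
            best[hit.uniprot_id] = hit
    hits = sorted(best.values(), key=lambda h: (-h.percent_identity, h.uniprot_id))
    logger.info("homology search for %s: %d subjects", query.uniprot_id, len(hits))
    return hits


def filter_homologs(
    hits: list[HomologHit],
    config: ExpansionConfig,
    query: TargetQuery | None = None,
) -> list[HomologHit]:
    """Retain hits with identity >= cutoff, sorted by descending identity.

    The cutoff is inclusive.  When ``config.include_query`` is set and a query
    is given, the query itself is always present in the output (as a 100%
    self-hit) even if the backend returned nothing for it — its own ligands
    are the most relevant chemistry whenever they exist.
    """
    kept = [h for h in hits if h.percent_identity >= config.identity_cutoff]
    if config.include_query and query is not None:
        if all(h.uniprot_id != query.uniprot_id for h in kept):
            self_hit = next(
                (h for h in hits if h.uniprot_id == query.uniprot_id),
                HomologHit(query.uniprot_id, query.uniprot_id, 100.0),
            )
            kept.append(self_hit)
    kept.sort(key=lambda h: (-h.percent_identity, h.uniprot_id))
    if not kept:
        logger.warning("expansion empty at cutoff %.1f%%", config.identity_cutoff)
    elif len(kept) == 1 and query is not None and kept[0].uniprot_id == query.uniprot_id:
        logger.warning("no homolog passed the cutoff; screening will rely on query-only chemistry")
    return kept


def expansion_table(hits: list[HomologHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_name": [h.gene_name for h in hits],
            "uniprot_id": [h.uniprot_id for h in hits],
            "percent_identity": [h.percent_identity for h in hits],
        }
    )


def expand_target(
    query: TargetQuery,
    backend: HomologyBackend,
    config: ExpansionConfig = ExpansionConfig(),
    out_path: str | Path | None = None,
) -> list[HomologHit]:
    """Search + filter + (optionally) write the expansion table."""
    hits = filter_homologs(search_homologs(query, backend), config, query=query)
    if out_path is not None and hits:
        write_table(expansion_table(hits), out_path)
    return hits
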