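"""Core domain types shared across the pipeline.

A protein-protein interaction (PPI) is an unordered pair of protein
accessions reported to interact within a single species.  Database releases
are reduced to :class:`SnapshotSet` objects keyed by ``(canonical pair,
taxid)`` so that the same accession pair observed in two species counts as
two distinct PPIs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "canonical_pair",
    "ProteinRef",
    "InteractionRecord",
    "SnapshotSet",
    "MappingTable",
    "PairKey",
]

#: comparison key for one PPI: (canonical accession pair, taxid)
PairKey = tuple[tuple[str, str], int]

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered-pair identity of two accessions.

    The canonical form is ``(min(a, b), max(a, b))`` lexicographically, so
    ``canonical_pair(a, b) == canonical_pair(b, a)`` and self-pairs
    (homo-oligomers) are preserved as ``(a, a)``.
    """
    if not a or not b:
        raise ValueError("accessions must be non-empty strings")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ProteinRef:
    """A protein accession with optional species and sequence annotation."""

    accession: str
    taxid: Optional[int] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if self.taxid is not None and self.taxid <= 0:
            raise ValueError(f"taxid must be positive, got {self.taxid}")
        if self.sequence is not None and not _AA_RE.match(self.sequence):
            raise ValueError(
                "sequence must use the 20 standard residues plus X"
            )


@dataclass(frozen=True)
class InteractionRecord:
    """One canonical PPI with provenance.

    ``pair`` is stored in canonical (lexicographic) order; both partners
    share ``taxid`` — cross-species records are rejected by the readers.
    """

    pair: tuple[str, str]
    taxid: int
    source_db: str
    interaction_type: Optional[str] = None
    pmid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pair[0] > self.pair[1]:
            raise ValueError(f"pair {self.pair} is not in canonical order")
        if self.taxid <= 0:
            raise ValueError(f"taxid must be positive, got {self.taxid}")

    @property
    def key(self) -> PairKey:
        return (self.pair, self.taxid)


class SnapshotSet:
    """A named PPI database release reduced to a set of canonical pairs.

    Records are keyed by ``(pair, taxid)``; inserting a duplicate key keeps
    the first record.  ``stats`` carries per-stage reader counts (lines
    read, malformed, filtered, cross-species, deduplicated) when the
    snapshot came from a file.
    """

    def __init__(
        self,
        name: str,
        records: Iterable[InteractionRecord] = (),
        stats: Optional[dict[str, int]] = None,
    ) -> None:
        self.name = name
        self._records: dict[PairKey, InteractionRecord] = {}
        self.stats: dict[str, int] = dict(stats or {})
        for rec in records:
            self.add(rec)

    def add(self, rec: InteractionRecord) -> bool:
        """Insert a record; return False if its key was already present."""
        if rec.key in self._records:
            return False
        self._records[rec.key] = rec
        return True

    def keys(self) -> set[PairKey]:
        return set(self._records)

    @property
    def records(self) -> list[InteractionRecord]:
        return list(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self._records.values())

    def __contains__(self, key: PairKey) -> bool:
        return key in self._records

    def __repr__(self) -> str:
        return f"SnapshotSet({self.name!r}, n={len(self)})"


@dataclass
class MappingTable:
    """A key→value accession mapping of a declared kind.

    Kinds: ``secondary_to_primary`` (UniProt secondary → primary IDs;
    idempotent after one application), ``accession_to_group`` (protein →
    ortholog-group ID, one group per protein), ``accession_to_taxid``.
    ``n_rejected`` counts rows dropped on read (e.g. an accession listed
    with multiple ortholog groups).
    """

    kind: str
    entries: dict[str, str] = field(default_factory=dict)
    n_rejected: int = 0

    KINDS = ("secondary_to_primary", "accession_to_group", "accession_to_taxid")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown mapping kind {self.kind!r}")

    def get(self, key: str, default: Optional[str] = None) -> Optional[str]:
        return self.entries.get(key, default)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries
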