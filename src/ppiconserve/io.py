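"""Readers and writers for PPI snapshots, mapping tables, FASTA and PDB.

Supported inputs: PSI-MITAB 2.5/2.7 tab-separated interaction files,
2–3 column edge lists, two-column mapping tables, FASTA sequence files and
(multi-model) PDB coordinate files.  All text readers transparently accept
gzip-compressed paths (``.gz`` suffix).

Accessions are normalized to primary IDs via :func:`normalize_accessions`
before any cross-database comparison; inconsistent isoform suffixes and
secondary accessions are the dominant ID artifacts between releases.
"""

from __future__ import annotations

import gzip
import logging
import re
import warnings
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

from .core import InteractionRecord, MappingTable, SnapshotSet, canonical_pair
from .ensembles import Ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PHYSICAL_TYPES",
    "read_mitab",
    "read_edgelist",
    "write_edgelist",
    "write_mitab",
    "read_mapping_table",
    "normalize_accessions",
    "read_fasta",
    "read_pdb_ensemble",
]

#: default physical-interaction allow-list (PSI-MI controlled vocabulary):
#: MI:0915 physical association, MI:0407 direct interaction.
DEFAULT_PHYSICAL_TYPES = frozenset({"MI:0915", "MI:0407"})

_TAXID_RE = re.compile(r"taxid:(-?\d+)")
_MI_RE = re.compile(r"MI:\d{4}")
# UniProt accession shape (6- or 10-character), used to scope isoform stripping
_UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})"
)
_ISOFORM_RE = re.compile(r"-\d+$")


def _open_text(path: Union[str, Path], mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _first_accession(field: str) -> Optional[str]:
    """Extract the accession from a MITAB identifier field.

    Takes the first ``db:acc`` token (fields may be pipe-separated
    alternatives) and keeps the part after the first colon.
    """
    token = field.split("|")[0].strip()
    if not token or token == "-":
        return None
    if ":" in token:
        token = token.split(":", 1)[1]
    token = token.strip().strip('"')
    return token or None


def _parse_taxid(field: str) -> Optional[int]:
    m = _TAXID_RE.search(field)
    if not m:
        return None
    taxid = int(m.group(1))
    return taxid if taxid > 0 else None


def read_mitab(
    path: Union[str, Path],
    allowed_interaction_types: Iterable[str] = DEFAULT_PHYSICAL_TYPES,
    name: Optional[str] = None,
    default_taxid: Optional[int] = None,
) -> SnapshotSet:
    """Read a PSI-MITAB 2.5/2.7 file into a :class:`SnapshotSet`.

    Parameters
    ----------
    path
        Tab-separated MITAB file (≥15 columns per non-comment line).
    allowed_interaction_types
        PSI-MI identifiers (e.g. ``"MI:0915"``) to keep.  An empty iterable
        disables the filter.  The default mirrors physical-only releases.
    name
        Snapshot name; defaults to the file stem.
    default_taxid
        Taxid assigned to records lacking one; records without a taxid are
        otherwise dropped (and counted in ``stats["dropped_no_taxid"]``).

    Notes
    -----
    Lines whose two interactor taxids differ (cross-species records) are
    dropped and counted: the species grouping downstream requires a single
    species per PPI.  Malformed lines (fewer than 15 columns) are counted
    in ``stats["malformed"]``.  A file with zero surviving records yields
    an empty snapshot with a warning, not a failure.
    """
    allowed = frozenset(allowed_interaction_types)
    name = name or Path(path).stem
    snap = SnapshotSet(name)
    stats = {
        "lines": 0,
        "malformed": 0,
        "filtered_type": 0,
        "cross_species": 0,
        "dropped_no_taxid": 0,
        "duplicates": 0,
    }
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            stats["lines"] += 1
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                stats["malformed"] += 1
                continue
            acc_a = _first_accession(cols[0])
            acc_b = _first_accession(cols[1])
            if acc_a is None or acc_b is None:
                stats["malformed"] += 1
                continue
            itype_match = _MI_RE.search(cols[11])
            itype = itype_match.group(0) if itype_match else None
            if allowed and (itype is None or itype not in allowed):
                stats["filtered_type"] += 1
                continue
            tax_a = _parse_taxid(cols[9])
            tax_b = _parse_taxid(cols[10])
            if tax_a is not None and tax_b is not None and tax_a != tax_b:
                stats["cross_species"] += 1
                continue
            taxid = tax_a if tax_a is not None else tax_b
            if taxid is None:
                taxid = default_taxid
            if taxid is None:
                stats["dropped_no_taxid"] += 1
                continue
            pmid = None
            if len(cols) > 8 and cols[8] not in ("-", ""):
                pmid = cols[8].split("|")[0]
            rec = InteractionRecord(
                pair=canonical_pair(acc_a, acc_b),
                taxid=taxid,
                source_db=name,
                interaction_type=itype,
                pmid=pmid,
            )
            if not snap.add(rec):
                stats["duplicates"] += 1
    snap.stats = stats
    if stats["malformed"]:
        logger.warning("%s: %d malformed line(s)", path, stats["malformed"])
    if len(snap) == 0:
        warnings.warn(f"snapshot {name!r} from {path} has zero records")
    return snap


def read_edgelist(
    path: Union[str, Path],
    name: Optional[str] = None,
    taxid: Optional[int] = None,
) -> SnapshotSet:
    """Read a 2- or 3-column edge list (accA, accB[, taxid]) as a snapshot.

    A default ``taxid`` must be supplied when the third column is absent.
    Pairs are canonicalized and deduplicated; self-pairs are kept.
    """
    name = name or Path(path).stem
    snap = SnapshotSet(name)
    stats = {"lines": 0, "malformed": 0, "duplicates": 0}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            stats["lines"] += 1
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2 or not cols[0] or not cols[1]:
                stats["malformed"] += 1
                continue
            if len(cols) >= 3 and cols[2].strip():
                tax = int(cols[2])
            elif taxid is not None:
                tax = taxid
            else:
                raise ValueError(
                    f"{path}: no taxid column and no default taxid given"
                )
            rec = InteractionRecord(
                pair=canonical_pair(cols[0].strip(), cols[1].strip()),
                taxid=tax,
                source_db=name,
            )
            if not snap.add(rec):
                stats["duplicates"] += 1
    snap.stats = stats
    return snap


def write_edgelist(snapshot: SnapshotSet, path: Union[str, Path]) -> None:
    """Write a snapshot as a 3-column TSV (accA, accB, taxid), sorted."""
    with _open_text(path, "wt") as fh:
        for (pair, taxid) in sorted(snapshot.keys()):
            fh.write(f"{pair[0]}\t{pair[1]}\t{taxid}\n")


def write_mitab(snapshot: SnapshotSet, path: Union[str, Path]) -> None:
    """Write a minimal 15-column MITAB 2.5 file (reader round-trip support)."""
    with _open_text(path, "wt") as fh:
        for rec in sorted(snapshot, key=lambda r: r.key):
            itype = rec.interaction_type or "MI:0915"
            cols = ["-"] * 15
            cols[0] = f"uniprotkb:{rec.pair[0]}"
            cols[1] = f"uniprotkb:{rec.pair[1]}"
            cols[8] = f"pubmed:{rec.pmid}" if rec.pmid else "-"
            cols[9] = f"taxid:{rec.taxid}"
            cols[10] = f"taxid:{rec.taxid}"
            cols[11] = f'psi-mi:"{itype}"(association)'
            cols[12] = f"psi-mi:{rec.source_db}"
            fh.write("\t".join(cols) + "\n")


def read_mapping_table(path: Union[str, Path], kind: str) -> MappingTable:
    """Read a 2-column TSV mapping table of the given kind.

    For ``accession_to_group`` an accession listed with more than one
    distinct group is rejected entirely (counted in ``n_rejected``): the
    ortholog mapping must carry one group per protein at the chosen
    taxonomic level.  For other kinds, duplicate keys keep the first value.
    """
    entries: dict[str, str] = {}
    ambiguous: set[str] = set()
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                continue
            key, value = cols[0].strip(), cols[1].strip()
            if not key or not value:
                continue
            if key in entries and entries[key] != value:
                if kind == "accession_to_group":
                    ambiguous.add(key)
                continue
            entries[key] = value
    for key in ambiguous:
        del entries[key]
    if ambiguous:
        logger.warning(
            "%s: %d accession(s) mapped to multiple groups; rejected",
            path,
            len(ambiguous),
        )
    return MappingTable(kind=kind, entries=entries, n_rejected=len(ambiguous))


def strip_isoform(accession: str) -> str:
    """Remove a trailing isoform suffix (``-N``) from UniProt-shaped IDs only."""
    if _ISOFORM_RE.search(accession) and _UNIPROT_RE.match(accession):
        return _ISOFORM_RE.sub("", accession)
    return accession


def normalize_accessions(
    snapshot: SnapshotSet,
    secondary_to_primary: Optional[MappingTable] = None,
    strip_isoforms: bool = True,
) -> SnapshotSet:
    """Map accessions to primary IDs; re-canonicalize and deduplicate.

    Each accession is first stripped of an isoform suffix (when
    ``strip_isoforms``), then replaced by its primary ID when present in
    the mapping; unmapped accessions pass through unchanged.  Idempotent;
    the returned snapshot is never larger than the input.
    """
    if secondary_to_primary is not None:
        if secondary_to_primary.kind != "secondary_to_primary":
            raise ValueError(
                "normalize_accessions needs a secondary_to_primary table"
            )
        mapping = secondary_to_primary.entries
    else:
        mapping = {}

    def norm(acc: str) -> str:
        if strip_isoforms:
            acc = strip_isoform(acc)
        return mapping.get(acc, acc)

    out = SnapshotSet(snapshot.name, stats=snapshot.stats)
    merged = 0
    for rec in snapshot:
        a, b = norm(rec.pair[0]), norm(rec.pair[1])
        new = InteractionRecord(
            pair=canonical_pair(a, b),
            taxid=rec.taxid,
            source_db=rec.source_db,
            interaction_type=rec.interaction_type,
            pmid=rec.pmid,
        )
        if not out.add(new):
            merged += 1
    out.stats = dict(out.stats, merged_on_normalize=merged)
    return out


def read_fasta(
    path: Union[str, Path], split_pipes: bool = True
) -> dict[str, str]:
    """Read a FASTA file into an accession → uppercase-sequence map.

    With ``split_pipes`` (default), headers of the UniProt form
    ``sp|ACC|NAME`` yield the second pipe field as the accession; plain
    headers use the first whitespace token.  Duplicate accessions: last
    record wins, with a warning.
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            acc = record.id
            if split_pipes and "|" in acc:
                parts = acc.split("|")
                if len(parts) >= 2 and parts[1]:
                    acc = parts[1]
            if acc in sequences:
                warnings.warn(f"duplicate FASTA accession {acc!r}: last wins")
            sequences[acc] = str(record.seq).upper()
    return sequences


def read_pdb_ensemble(path: Union[str, Path]) -> Ensemble:
    """Read Cα coordinates from a (multi-model) PDB file as an ensemble.

    Every MODEL block must contain the identical (chain, residue-number)
    sequence; a file without MODEL records is a one-model ensemble.
    """
    parser = PDBParser(QUIET=True)
    with _open_text(path) as fh:
        structure = parser.get_structure(Path(path).stem, fh)
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")

    def ca_trace(model):
        labels, coords = [], []
        for chain in model:
            for residue in chain:
                if "CA" in residue:
                    labels.append((chain.id, residue.id[1]))
                    coords.append(residue["CA"].coord)
        return labels, np.asarray(coords, dtype=float)

    ref_labels, ref_coords = ca_trace(models[0])
    if not ref_labels:
        raise ValueError(f"{path}: no CA atoms found")
    stack = [ref_coords]
    for model in models[1:]:
        labels, coords = ca_trace(model)
        if labels != ref_labels:
            mismatch = next(
                (a for a, b in zip(ref_labels, labels) if a != b),
                ref_labels[min(len(labels), len(ref_labels) - 1)]
                if len(labels) != len(ref_labels)
                else None,
            )
            raise ValueError(
                f"{path}: model {model.id + 1} residue set differs from model 1 "
                f"(first mismatch near chain {mismatch[0]} residue {mismatch[1]})"
            )
        stack.append(coords)
    chains = tuple(dict.fromkeys(c for c, _ in ref_labels))
    return Ensemble(
        chains=chains,
        residues=tuple(ref_labels),
        coords=np.stack(stack),
    )
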