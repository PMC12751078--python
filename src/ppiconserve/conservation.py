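"""Cross-species conservation of interactions via ortholog-group pairs.

Interactions from different species are comparable once each protein is
replaced by its ortholog-group ID (OrthoDB-style): a PPI observed as the
same unordered group pair in several species is evolutionarily conserved.
The *conservation span* of a group pair is the number of distinct taxids
in which it was observed; span ≥ 2 defines a conserved PPI.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .core import InteractionRecord, MappingTable, SnapshotSet, canonical_pair

__all__ = [
    "GroupPairSpan",
    "to_group_pair",
    "build_spans",
    "species_pair_sharing",
    "conserved_counts_by_database",
    "span_histogram",
    "write_spans_tsv",
    "read_spans_tsv",
]

GroupPair = tuple[str, str]


@dataclass(frozen=True)
class GroupPairSpan:
    """An ortholog-group pair with the species and databases observing it."""

    group_pair: GroupPair
    taxa: frozenset[int]
    sources: frozenset[str]

    def __post_init__(self) -> None:
        if self.group_pair[0] > self.group_pair[1]:
            raise ValueError(f"group pair {self.group_pair} not canonical")
        if not self.taxa:
            raise ValueError("span requires at least one taxon")

    @property
    def span(self) -> int:
        return len(self.taxa)


def to_group_pair(
    record: InteractionRecord, accession_to_group: MappingTable
) -> Optional[GroupPair]:
    """Map an interaction to its canonical ortholog-group pair.

    Returns None when either accession has no group annotation (the caller
    counts these).  A homodimer whose partners share one group yields the
    self group-pair (g, g).
    """
    if accession_to_group.kind != "accession_to_group":
        raise ValueError("to_group_pair needs an accession_to_group table")
    ga = accession_to_group.get(record.pair[0])
    gb = accession_to_group.get(record.pair[1])
    if ga is None or gb is None:
        return None
    return canonical_pair(ga, gb)


def build_spans(
    snapshots: Iterable[SnapshotSet],
    accession_to_group: MappingTable,
) -> list[GroupPairSpan]:
    """Aggregate all snapshots into one span per distinct group pair.

    Taxa and source databases accumulate over every record that maps; span
    counts distinct taxids, so within-species paralog pairs mapping to the
    same group pair do not inflate it.  Records with unmapped accessions
    are skipped.  Output is sorted by group pair for determinism.
    """
    taxa: dict[GroupPair, set[int]] = {}
    sources: dict[GroupPair, set[str]] = {}
    for snap in snapshots:
        for rec in snap:
            gp = to_group_pair(rec, accession_to_group)
            if gp is None:
                continue
            taxa.setdefault(gp, set()).add(rec.taxid)
            sources.setdefault(gp, set()).add(rec.source_db)
    return [
        GroupPairSpan(gp, frozenset(taxa[gp]), frozenset(sources[gp]))
        for gp in sorted(taxa)
    ]


def species_pair_sharing(
    spans: Sequence[GroupPairSpan],
) -> dict[tuple[int, int], int]:
    """Shared-PPI counts per unordered species pair.

    For each unordered taxid pair, counts group pairs whose taxa include
    both (e.g. human and mouse sharing thousands of conserved PPIs).
    """
    counts: Counter[tuple[int, int]] = Counter()
    for sp in spans:
        taxa = sorted(sp.taxa)
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                counts[(taxa[i], taxa[j])] += 1
    return dict(counts)


def conserved_counts_by_database(
    spans: Sequence[GroupPairSpan], min_span: int = 2
) -> dict[str, int]:
    """Per-database counts of conserved group pairs (span ≥ min_span)."""
    if min_span < 2:
        raise ValueError("conservation requires min_span >= 2")
    counts: Counter[str] = Counter()
    for sp in spans:
        if sp.span >= min_span:
            counts.update(sp.sources)
    return dict(counts)


def span_histogram(
    spans: Sequence[GroupPairSpan], cap: int = 6
) -> dict[Union[int, str], int]:
    """Group-pair counts per span level, with an open top bin ``">=cap"``."""
    if cap < 2:
        raise ValueError("cap must be at least 2")
    hist: dict[Union[int, str], int] = {}
    top = f">={cap}"
    for sp in spans:
        level: Union[int, str] = sp.span if sp.span < cap else top
        hist[level] = hist.get(level, 0) + 1
    return hist


def write_spans_tsv(
    spans: Sequence[GroupPairSpan], path: Union[str, Path]
) -> None:
    """Write spans as TSV: group_a, group_b, span, taxa, sources
    (semicolon-joined, sorted)."""
    with open(path, "wt") as fh:
        fh.write("group_a\tgroup_b\tspan\ttaxa\tsources\n")
        for sp in sorted(spans, key=lambda s: s.group_pair):
            taxa = ";".join(str(t) for t in sorted(sp.taxa))
            sources = ";".join(sorted(sp.sources))
            fh.write(
                f"{sp.group_pair[0]}\t{sp.group_pair[1]}\t{sp.span}\t"
                f"{taxa}\t{sources}\n"
            )


def read_spans_tsv(path: Union[str, Path]) -> list[GroupPairSpan]:
    spans = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("group_a"):
            raise ValueError(f"{path}: missing spans header")
        for line in fh:
            if not line.strip():
                continue
            ga, gb, _span, taxa, sources = line.rstrip("\n").split("\t")
            spans.append(
                GroupPairSpan(
                    canonical_pair(ga, gb),
                    frozenset(int(t) for t in taxa.split(";") if t),
                    frozenset(s for s in sources.split(";") if s),
                )
            )
    return spans
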