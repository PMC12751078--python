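"""Greedy identity-threshold clustering of protein sequences.

Tests whether cross-database disagreement is an ID artifact: snapshots are
remapped onto cluster representatives (so isoforms / near-identical entries
collapse) and the overlap-coefficient matrix is recomputed.  A small shift
(a few percentage points at most) indicates genuine content disagreement
rather than identifier mis-assignment.

Identity is computed from a Needleman–Wunsch global alignment (match +1,
mismatch 0, linear gap −1) as matched positions divided by the shorter
sequence length — the CD-HIT denominator convention, robust to fragment
entries.  Clustering is the standard longest-first greedy centroid scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .core import InteractionRecord, SnapshotSet, canonical_pair
from .set_analysis import OverlapMatrix

__all__ = [
    "ClusterAssignment",
    "pairwise_identity",
    "greedy_cluster",
    "remap_snapshot",
    "overlap_delta",
    "write_cluster_tsv",
    "read_cluster_tsv",
]


@dataclass
class ClusterAssignment:
    """Member → representative map at a given identity threshold.

    Every representative maps to itself; every member has identity ≥
    threshold to its representative.
    """

    threshold: float
    rep_of: dict[str, str]

    def representative(self, accession: str) -> str:
        """Representative of an accession (uncovered accessions map to
        themselves)."""
        return self.rep_of.get(accession, accession)

    @property
    def n_clusters(self) -> int:
        return len(set(self.rep_of.values()))


def _nw_align_matches(seq_a: str, seq_b: str) -> int:
    """Matched-position count of the optimal global alignment.

    Scoring: match +1, mismatch 0, linear gap −1.  The left-gap recurrence
    is vectorized per row via a prefix-max identity (H[i,j]+j is the
    running max of candidate[k]+k for k ≤ j, exact for a linear gap).
    Traceback prefers diagonal > up > left, making the match count
    deterministic among co-optimal alignments.
    """
    a = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    n, m = a.size, b.size
    h = np.empty((n + 1, m + 1), dtype=np.int64)
    col_idx = np.arange(m + 1, dtype=np.int64)
    h[0] = -col_idx
    for i in range(1, n + 1):
        sub = (a[i - 1] == b).astype(np.int64)
        cand = np.maximum(h[i - 1, :-1] + sub, h[i - 1, 1:] - 1)
        vals = np.empty(m + 1, dtype=np.int64)
        vals[0] = -i
        vals[1:] = cand
        h[i] = np.maximum.accumulate(vals + col_idx) - col_idx
    # traceback
    i, j, matches = n, m, 0
    while i > 0 and j > 0:
        sub = 1 if a[i - 1] == b[j - 1] else 0
        if h[i, j] == h[i - 1, j - 1] + sub:
            matches += sub
            i -= 1
            j -= 1
        elif h[i, j] == h[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
    return matches


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Identity = matched positions of the optimal Needleman–Wunsch alignment
    (match +1, mismatch 0, linear gap −1) divided by the shorter sequence
    length, so an exact fragment of a longer sequence scores 1.0.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    matches = _nw_align_matches(seq_a.upper(), seq_b.upper())
    return matches / min(len(seq_a), len(seq_b))


def greedy_cluster(
    sequences: dict[str, str], threshold: float
) -> ClusterAssignment:
    """Greedy centroid clustering at an identity threshold.

    Sequences are scanned in order of decreasing length (ties broken by
    accession); each is assigned to the first existing representative with
    identity ≥ threshold, otherwise it founds a new cluster.  By
    construction representatives are mutually below threshold in scan
    order, and the result is deterministic.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(sequences, key=lambda acc: (-len(sequences[acc]), acc))
    reps: list[str] = []
    rep_of: dict[str, str] = {}
    eps = 1e-12
    for acc in order:
        seq = sequences[acc]
        for rep in reps:
            if pairwise_identity(seq, sequences[rep]) >= threshold - eps:
                rep_of[acc] = rep
                break
        else:
            reps.append(acc)
            rep_of[acc] = acc
    return ClusterAssignment(threshold=threshold, rep_of=rep_of)


def remap_snapshot(
    snapshot: SnapshotSet, assignment: ClusterAssignment
) -> SnapshotSet:
    """Replace each pair by its representative pair; dedupe.

    Accessions without a cluster map to themselves.  A pair whose members
    share a cluster collapses to a self-pair and is retained.  The result
    never exceeds the input size.
    """
    out = SnapshotSet(snapshot.name, stats=snapshot.stats)
    for rec in snapshot:
        a = assignment.representative(rec.pair[0])
        b = assignment.representative(rec.pair[1])
        out.add(
            InteractionRecord(
                pair=canonical_pair(a, b),
                taxid=rec.taxid,
                source_db=rec.source_db,
                interaction_type=rec.interaction_type,
                pmid=rec.pmid,
            )
        )
    return out


def overlap_delta(
    matrix_before: OverlapMatrix, matrix_after: OverlapMatrix
) -> float:
    """Maximum absolute off-diagonal coefficient shift, in percent.

    Entries where either matrix is NaN (empty-set sentinel) are skipped.
    """
    if matrix_before.names != matrix_after.names:
        raise ValueError(
            "matrices cover different snapshot names: "
            f"{matrix_before.names} vs {matrix_after.names}"
        )
    n = len(matrix_before.names)
    diff = np.abs(matrix_after.values - matrix_before.values)
    mask = ~np.eye(n, dtype=bool) & np.isfinite(diff)
    if not mask.any():
        return 0.0
    return float(diff[mask].max() * 100.0)


def write_cluster_tsv(
    assignment: ClusterAssignment, path: Union[str, Path]
) -> None:
    """Write (member, representative) rows, sorted by member."""
    with open(path, "wt") as fh:
        for member in sorted(assignment.rep_of):
            fh.write(f"{member}\t{assignment.rep_of[member]}\n")


def read_cluster_tsv(
    path: Union[str, Path], threshold: float = float("nan")
) -> ClusterAssignment:
    """Read an external (member, representative) TSV, e.g. MMseqs2 output."""
    rep_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                continue
            rep_of[cols[0].strip()] = cols[1].strip()
    for rep in set(rep_of.values()):
        rep_of.setdefault(rep, rep)
    return ClusterAssignment(threshold=threshold, rep_of=rep_of)
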