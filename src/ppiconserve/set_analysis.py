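"""Set algebra over PPI snapshots.

Quantifies cross-database concordance: exclusive (UpSet-style) membership
signatures, at-least-k sharing, the Szymkiewicz–Simpson overlap-coefficient
matrix, per-species protein counts of shared PPIs, and the nC2 pair
combinatorics that bound the possible interaction space.

All operations compare snapshots on ``(canonical pair, taxid)`` keys: the
same accession pair observed in two species counts as two PPIs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import PairKey, SnapshotSet, canonical_pair  # noqa: F401  (canonical_pair re-exported)

__all__ = [
    "canonical_pair",
    "n_possible_pairs",
    "MembershipSignature",
    "OverlapMatrix",
    "display_order",
    "exclusive_intersections",
    "shared_by_at_least",
    "overlap_coefficient",
    "overlap_matrix",
    "species_protein_counts",
]


def n_possible_pairs(n_proteins: int) -> int:
    """Number of unique unordered protein pairs, nC2 = n·(n−1)/2.

    The potential one-to-one interaction space grows quadratically with
    proteome size (≈8M pairs for a 4K-protein bacterium, ≈200M for the
    20K-protein human proteome).
    """
    if n_proteins < 0:
        raise ValueError("n_proteins must be non-negative")
    return math.comb(n_proteins, 2)


@dataclass(frozen=True)
class MembershipSignature:
    """One exclusive-intersection bar: the exact set of databases sharing
    a group of PPIs, with its size."""

    present_in: tuple[str, ...]
    count: int


@dataclass
class OverlapMatrix:
    """Symmetric Szymkiewicz–Simpson coefficient matrix between snapshots.

    Entries are |A∩B| / min(|A|, |B|) ∈ [0, 1]; the diagonal is 1 for
    non-empty sets.  Coefficients involving an empty set are NaN
    (reported as missing, never 0).  ``median_offdiag`` is the median of
    the strict upper triangle, NaN entries excluded.
    """

    names: tuple[str, ...]
    values: np.ndarray
    median_offdiag: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.names.index(pair[0])
        j = self.names.index(pair[1])
        return float(self.values[i, j])


def display_order(snapshots: Sequence[SnapshotSet]) -> list[str]:
    """Fixed database order: descending size, name as tie-break."""
    return [s.name for s in sorted(snapshots, key=lambda s: (-len(s), s.name))]


def _check_names(snapshots: Sequence[SnapshotSet]) -> None:
    names = [s.name for s in snapshots]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate snapshot names: {sorted(names)}")


def exclusive_intersections(
    snapshots: Sequence[SnapshotSet],
) -> list[MembershipSignature]:
    """Partition the union of all snapshots by exact membership signature.

    Every key of the union belongs to exactly one signature — the full set
    of snapshots containing it — so signature counts sum to the union
    size.  This is the quantity plotted as UpSet bars.  Signatures are
    returned sorted by count descending, then signature.
    """
    if not snapshots:
        raise ValueError("at least one snapshot required")
    _check_names(snapshots)
    order = display_order(snapshots)
    rank = {name: i for i, name in enumerate(order)}
    keysets = {s.name: s.keys() for s in snapshots}
    signature_counts: Counter[tuple[str, ...]] = Counter()
    union: set[PairKey] = set().union(*keysets.values())
    for key in union:
        sig = tuple(
            sorted(
                (n for n, ks in keysets.items() if key in ks),
                key=rank.__getitem__,
            )
        )
        signature_counts[sig] += 1
    return sorted(
        (MembershipSignature(sig, c) for sig, c in signature_counts.items()),
        key=lambda s: (-s.count, s.present_in),
    )


def shared_by_at_least(
    snapshots: Sequence[SnapshotSet], k: int
) -> set[PairKey]:
    """Keys present in at least ``k`` snapshots (k=1: union; k=n: intersection)."""
    if not 1 <= k <= len(snapshots):
        raise ValueError(f"k={k} out of range 1..{len(snapshots)}")
    _check_names(snapshots)
    counts: Counter[PairKey] = Counter()
    for snap in snapshots:
        counts.update(snap.keys())
    return {key for key, c in counts.items() if c >= k}


def shared_by_exactly(
    snapshots: Sequence[SnapshotSet], k: int
) -> set[PairKey]:
    """Keys present in exactly ``k`` snapshots."""
    if not 1 <= k <= len(snapshots):
        raise ValueError(f"k={k} out of range 1..{len(snapshots)}")
    _check_names(snapshots)
    counts: Counter[PairKey] = Counter()
    for snap in snapshots:
        counts.update(snap.keys())
    return {key for key, c in counts.items() if c == k}


def overlap_coefficient(a: set, b: set) -> float:
    """Szymkiewicz–Simpson coefficient |A∩B| / min(|A|, |B|).

    Symmetric; equals 1 whenever one set contains the other.  NaN when
    either set is empty (an empty release carries no overlap evidence).
    """
    if not a or not b:
        return float("nan")
    return len(a & b) / min(len(a), len(b))


def overlap_matrix(snapshots: Sequence[SnapshotSet]) -> OverlapMatrix:
    """All-pairs overlap-coefficient matrix in display order.

    The reported median is over the strict upper triangle (each unordered
    database pair once), excluding NaN sentinels.
    """
    if len(snapshots) < 2:
        raise ValueError("overlap matrix needs at least 2 snapshots")
    _check_names(snapshots)
    order = display_order(snapshots)
    by_name = {s.name: s.keys() for s in snapshots}
    n = len(order)
    values = np.ones((n, n))
    for i in range(n):
        if not by_name[order[i]]:
            values[i, i] = float("nan")
        for j in range(i + 1, n):
            c = overlap_coefficient(by_name[order[i]], by_name[order[j]])
            values[i, j] = values[j, i] = c
    upper = values[np.triu_indices(n, k=1)]
    finite = upper[np.isfinite(upper)]
    median = float(np.median(finite)) if finite.size else float("nan")
    return OverlapMatrix(tuple(order), values, median)


def species_protein_counts(
    shared_keys: Iterable[PairKey], top_k: Optional[int] = 10
) -> tuple[dict[int, int], list[tuple[int, int]]]:
    """Unique-protein counts per species among a set of shared PPIs.

    For each taxid, counts the distinct accessions appearing in any shared
    pair (a self-pair contributes its protein once).  Returns the full
    map plus a (taxid, count) report sorted by count descending (taxid
    ascending on ties), truncated to ``top_k`` when given.
    """
    proteins: dict[int, set[str]] = {}
    for (pair, taxid) in shared_keys:
        proteins.setdefault(taxid, set()).update(pair)
    counts = {taxid: len(accs) for taxid, accs in proteins.items()}
    report = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        report = report[:top_k]
    return counts, report
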