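"""PDB structure-coverage enrichment as a function of conservation span.

For each conservation-span level, the fraction of ortholog-group pairs
with at least one deposited complex structure is compared against the
non-conserved baseline (span 1) via a 2×2 odds ratio:

    OR = (solved_s / unsolved_s) / (solved_1 / unsolved_1)

with the Haldane–Anscombe 0.5 correction on zero cells (top span levels
leave near-empty unsolved cells) and a normal-approximation 95% CI on the
log odds ratio.  A Fisher exact p-value is reported alongside.  The
unsolved-pair listing ranks conserved group pairs still lacking any
structure — the candidates a structural program would prioritize.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from scipy import stats

from .conservation import GroupPair, GroupPairSpan
from .core import canonical_pair

__all__ = [
    "StructureIndex",
    "EnrichmentRow",
    "coverage_by_span",
    "odds_ratio_vs_baseline",
    "enrichment_table",
    "unsolved_pairs",
    "read_structure_index",
    "write_structure_index",
    "write_enrichment_tsv",
    "write_unsolved_csv",
]

_PDB_ID_RE = re.compile(r"^[0-9A-Za-z]{4}$")


@dataclass
class StructureIndex:
    """Group pairs with deposited complex structures (PDB evidence).

    A group pair is "solved" if any member pair has any PDB complex ID in
    the index; structure contents are not validated here.
    """

    evidence: dict[GroupPair, set[str]]

    def __post_init__(self) -> None:
        for gp, ids in self.evidence.items():
            if gp[0] > gp[1]:
                raise ValueError(f"group pair {gp} not canonical")
            for pdb_id in ids:
                if not _PDB_ID_RE.match(pdb_id):
                    raise ValueError(f"malformed PDB ID {pdb_id!r} for {gp}")

    @property
    def solved(self) -> set[GroupPair]:
        return set(self.evidence)

    def pdb_ids(self, gp: GroupPair) -> list[str]:
        return sorted(self.evidence.get(gp, ()))

    def is_solved(self, gp: GroupPair) -> bool:
        return gp in self.evidence


@dataclass
class EnrichmentRow:
    """Solved/unsolved counts at one span level, with enrichment stats."""

    span_level: Union[int, str]
    n_solved: int
    n_unsolved: int
    odds_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    fisher_p: Optional[float] = None

    @property
    def n_total(self) -> int:
        return self.n_solved + self.n_unsolved

    @property
    def proportion_solved(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return self.n_solved / self.n_total


def coverage_by_span(
    spans: Sequence[GroupPairSpan],
    index: StructureIndex,
    cap: int = 6,
) -> list[EnrichmentRow]:
    """Solved/unsolved counts per span level 1..cap−1 plus ``">=cap"``."""
    levels: list[Union[int, str]] = list(range(1, cap)) + [f">={cap}"]
    rows = {lvl: [0, 0] for lvl in levels}
    for sp in spans:
        lvl: Union[int, str] = sp.span if sp.span < cap else f">={cap}"
        rows[lvl][0 if index.is_solved(sp.group_pair) else 1] += 1
    return [
        EnrichmentRow(lvl, rows[lvl][0], rows[lvl][1]) for lvl in levels
    ]


def odds_ratio_vs_baseline(
    row_s: EnrichmentRow,
    row_baseline: EnrichmentRow,
    zero_cell_correction: bool = True,
) -> EnrichmentRow:
    """Fill in OR, 95% CI and Fisher p of a level against the baseline.

    OR = (a/b)/(c/d) with a, b the solved/unsolved counts at the level and
    c, d at the baseline (span 1).  When any cell is 0 and correction is
    enabled, 0.5 is added to all four cells (Haldane–Anscombe).  The CI is
    exp(ln OR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d)) on the corrected cells.
    The Fisher exact p-value uses the uncorrected table.
    """
    a, b = row_s.n_solved, row_s.n_unsolved
    c, d = row_baseline.n_solved, row_baseline.n_unsolved
    out = EnrichmentRow(row_s.span_level, a, b)
    if row_baseline.n_total == 0:
        return out
    out.fisher_p = float(
        stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    )
    cells = [float(a), float(b), float(c), float(d)]
    if 0 in (a, b, c, d):
        if not zero_cell_correction:
            if b == 0 or c == 0:
                out.odds_ratio = float("inf") if (a > 0 and d > 0) else None
            else:
                out.odds_ratio = 0.0 if (a == 0 or d == 0) else None
            return out
        cells = [x + 0.5 for x in cells]
    fa, fb, fc, fd = cells
    or_ = (fa / fb) / (fc / fd)
    se = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    out.odds_ratio = or_
    out.ci_low = math.exp(math.log(or_) - 1.96 * se)
    out.ci_high = math.exp(math.log(or_) + 1.96 * se)
    return out


def enrichment_table(
    spans: Sequence[GroupPairSpan],
    index: StructureIndex,
    cap: int = 6,
    zero_cell_correction: bool = True,
) -> list[EnrichmentRow]:
    """Coverage rows per level with ORs against the span-1 baseline.

    The baseline row (span 1, "non-conserved") carries OR = 1 by
    definition when non-empty.
    """
    rows = coverage_by_span(spans, index, cap)
    baseline = rows[0]
    out = []
    for row in rows:
        filled = odds_ratio_vs_baseline(row, baseline, zero_cell_correction)
        out.append(filled)
    return out


def unsolved_pairs(
    spans: Sequence[GroupPairSpan],
    index: StructureIndex,
    min_span: int = 2,
) -> list[tuple[GroupPair, int, frozenset[int]]]:
    """Conserved group pairs with no PDB evidence.

    Sorted by span descending, then lexicographically by group pair — the
    priority list of structures remaining to be solved.
    """
    if min_span < 2:
        raise ValueError("conservation requires min_span >= 2")
    out = [
        (sp.group_pair, sp.span, sp.taxa)
        for sp in spans
        if sp.span >= min_span and not index.is_solved(sp.group_pair)
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def read_structure_index(path: Union[str, Path]) -> StructureIndex:
    """Read a (group_a, group_b, pdb_id) TSV into a StructureIndex."""
    evidence: dict[GroupPair, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[0] == "group_a":
                continue
            if len(cols) < 3:
                continue
            gp = canonical_pair(cols[0].strip(), cols[1].strip())
            evidence.setdefault(gp, set()).add(cols[2].strip())
    return StructureIndex(evidence)


def write_structure_index(
    index: StructureIndex, path: Union[str, Path]
) -> None:
    with open(path, "wt") as fh:
        fh.write("group_a\tgroup_b\tpdb_id\n")
        for gp in sorted(index.evidence):
            for pdb_id in sorted(index.evidence[gp]):
                fh.write(f"{gp[0]}\t{gp[1]}\t{pdb_id}\n")


def write_enrichment_tsv(
    rows: Sequence[EnrichmentRow], path: Union[str, Path]
) -> None:
    def fmt(x: Optional[float]) -> str:
        return "NA" if x is None else f"{x:.6g}"

    with open(path, "wt") as fh:
        fh.write(
            "level\tn_solved\tn_unsolved\tproportion\t"
            "odds_ratio\tci_low\tci_high\tfisher_p\n"
        )
        for row in rows:
            prop = (
                "NA"
                if row.n_total == 0
                else f"{row.proportion_solved:.6g}"
            )
            fh.write(
                f"{row.span_level}\t{row.n_solved}\t{row.n_unsolved}\t{prop}\t"
                f"{fmt(row.odds_ratio)}\t{fmt(row.ci_low)}\t"
                f"{fmt(row.ci_high)}\t{fmt(row.fisher_p)}\n"
            )


def write_unsolved_csv(
    pairs: Sequence[tuple[GroupPair, int, frozenset[int]]],
    path: Union[str, Path],
) -> None:
    """Unsolved-pair listing: group_a, group_b, span, taxa."""
    with open(path, "wt") as fh:
        fh.write("group_a,group_b,span,taxa\n")
        for gp, span, taxa in pairs:
            taxa_s = ";".join(str(t) for t in sorted(taxa))
            fh.write(f"{gp[0]},{gp[1]},{span},{taxa_s}\n")
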