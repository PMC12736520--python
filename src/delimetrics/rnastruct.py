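"""ITS secondary-structure comparison and compensatory base changes.

A secondary structure is a sequence plus a dot-bracket string (no
pseudoknots).  Helices are maximal runs of stacked pairs, numbered 5'->3'
by the position of their outermost (basal) pair; pair positions within a
helix are counted from the base.

Comparing two structures through a pairwise sequence alignment, each
base pair is classified:

* **CBC** — both nucleotides of the pair differ between the structures
  while both pairs remain canonical (Watson-Crick or G.U wobble);
* **hemi-CBC** — exactly one nucleotide differs with canonical pairing
  retained on both sides;
* **identical / mismatch / pair_lost / pair_gained** otherwise.

A single CBC inside the conserved spans of the spacer helices
(conventionally the basal 5 bp of helix I, 10 bp of helix II and all of
helix III for ITS2) is treated as a species-boundary signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core_io import Alignment

logger = logging.getLogger("delimetrics")

CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

#: Default conserved spans: helix number -> basal pair count (None = whole helix)
DEFAULT_CONSERVED_REGIONS: dict[int, int | None] = {1: 5, 2: 10, 3: None}


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class SecondaryStructure:
    sequence: str  # RNA, uppercase, T normalised to U
    dotbracket: str
    pairs: tuple[tuple[int, int], ...]  # 1-based, i < j
    helices: tuple[tuple[tuple[int, int], ...], ...]  # numbered 5'->3'

    def helix_of_pair(self, pair: tuple[int, int]) -> tuple[int, int] | None:
        """(helix number 1-based, position from base 1-based) or None."""
        for h, helix in enumerate(self.helices, start=1):
            if pair in helix:
                return h, helix.index(pair) + 1
        return None


@dataclass(frozen=True)
class PairComparison:
    pair1: tuple[int, int] | None  # positions in structure 1, 1-based
    pair2: tuple[int, int] | None
    bases1: str | None  # e.g. "GC"
    bases2: str | None
    category: str  # identical|CBC|hemi-CBC|mismatch|pair_lost|pair_gained


@dataclass(frozen=True)
class CBCReport:
    comparisons: tuple[PairComparison, ...]
    totals: dict[str, int] = field(default_factory=dict)

    def count(self, category: str) -> int:
        return self.totals.get(category, 0)


def parse_dotbracket(sequence: str, dotbracket: str) -> SecondaryStructure:
    """Parse a dot-bracket string into pairs and helices.

    Helices are maximal stacked runs (i,j), (i+1,j-1), ...; unbalanced
    brackets raise with the offending position (1-based).
    """
    seq = sequence.upper().replace("T", "U")
    if len(seq) != len(dotbracket):
        raise StructureError("sequence and dot-bracket lengths differ")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    pairs.sort()
    helices: list[list[tuple[int, int]]] = []
    pair_set = set(pairs)
    seen: set[tuple[int, int]] = set()
    for p in pairs:
        if p in seen:
            continue
        run = [p]
        i, j = p
        while (i + 1, j - 1) in pair_set:
            i, j = i + 1, j - 1
            run.append((i, j))
        seen.update(run)
        helices.append(run)
    helices.sort(key=lambda h: h[0][0])
    return SecondaryStructure(seq, dotbracket, tuple(pairs),
                              tuple(tuple(h) for h in helices))


def read_structure_file(path) -> SecondaryStructure:
    """Read a two-line structure file: sequence, then dot-bracket."""
    lines = [ln.strip() for ln in open(path, encoding="utf-8") if ln.strip()]
    lines = [ln for ln in lines if not ln.startswith(("#", ">"))]
    if len(lines) != 2:
        raise StructureError(f"{path}: expected 2 non-comment lines, got {len(lines)}")
    return parse_dotbracket(lines[0], lines[1])


def _alignment_maps(aln: Alignment) -> tuple[dict[int, int], dict[int, int]]:
    """Per-column maps: seq1 position -> seq2 position (1-based), and reverse."""
    if aln.n_sequences != 2:
        raise StructureError("pairwise alignment must contain exactly 2 sequences")
    fwd: dict[int, int] = {}
    rev: dict[int, int] = {}
    p1 = p2 = 0
    for c1, c2 in zip(aln.rows[0], aln.rows[1]):
        if c1 != "-":
            p1 += 1
        if c2 != "-":
            p2 += 1
        if c1 != "-" and c2 != "-":
            fwd[p1] = p2
            rev[p2] = p1
    return fwd, rev


def compare_structures(
    ss1: SecondaryStructure, ss2: SecondaryStructure, aln: Alignment
) -> CBCReport:
    """Classify every base pair of either structure through the alignment."""
    fwd, _ = _alignment_maps(aln)
    n1 = len(aln.rows[0]) - aln.rows[0].count("-")
    n2 = len(aln.rows[1]) - aln.rows[1].count("-")
    if n1 != len(ss1.sequence) or n2 != len(ss2.sequence):
        raise StructureError(
            "alignment inconsistent with structure sequence lengths "
            f"({n1} vs {len(ss1.sequence)}, {n2} vs {len(ss2.sequence)})"
        )
    pairs2 = set(ss2.pairs)
    matched2: set[tuple[int, int]] = set()
    comparisons: list[PairComparison] = []
    for (i, j) in ss1.pairs:
        b1 = ss1.sequence[i - 1] + ss1.sequence[j - 1]
        ip, jp = fwd.get(i), fwd.get(j)
        if ip is None or jp is None or (ip, jp) not in pairs2:
            comparisons.append(PairComparison((i, j), None, b1, None, "pair_lost"))
            continue
        matched2.add((ip, jp))
        b2 = ss2.sequence[ip - 1] + ss2.sequence[jp - 1]
        n_diff = (b1[0] != b2[0]) + (b1[1] != b2[1])
        canonical = b1 in CANONICAL_PAIRS and b2 in CANONICAL_PAIRS
        if n_diff == 0:
            cat = "identical"
        elif not canonical:
            cat = "mismatch"
        elif n_diff == 2:
            cat = "CBC"
        else:
            cat = "hemi-CBC"
        comparisons.append(PairComparison((i, j), (ip, jp), b1, b2, cat))
    for (ip, jp) in ss2.pairs:
        if (ip, jp) not in matched2:
            b2 = ss2.sequence[ip - 1] + ss2.sequence[jp - 1]
            comparisons.append(PairComparison(None, (ip, jp), None, b2, "pair_gained"))
    totals: dict[str, int] = {}
    for c in comparisons:
        totals[c.category] = totals.get(c.category, 0) + 1
    return CBCReport(tuple(comparisons), totals)


def cbc_in_conserved_regions(
    report: CBCReport,
    ss1: SecondaryStructure,
    regions: dict[int, int | None] | None = None,
) -> tuple[int, str]:
    """Count CBCs whose structure-1 pair lies in the conserved spans.

    ``regions`` maps helix number (1-based, 5'->3') to the number of
    basal pairs that are conserved (None for the whole helix).  Returns
    (count, verdict); the verdict is "distinct" iff count >= 1.
    """
    n_helices = len(ss1.helices)
    if regions is None:
        # default spans apply to whichever of helices I-III exist
        regions = {h: s for h, s in DEFAULT_CONSERVED_REGIONS.items() if h <= n_helices}
    for h in regions:
        if not 1 <= h <= n_helices:
            raise StructureError(f"region references helix {h}, structure has {n_helices}")
    count = 0
    for comp in report.comparisons:
        if comp.category != "CBC" or comp.pair1 is None:
            continue
        loc = ss1.helix_of_pair(comp.pair1)
        if loc is None:
            continue
        helix, pos = loc
        if helix in regions:
            span = regions[helix]
            if span is None or pos <= span:
                count += 1
    return count, ("distinct" if count >= 1 else "not_distinct")
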