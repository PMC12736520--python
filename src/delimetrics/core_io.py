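"""Shared domain types and readers/writers for the formats the pipeline touches.

The pipeline operates on five kinds of objects: aligned DNA barcode
sequences (:class:`Alignment`), reference species assignments
(:class:`Taxonomy`), candidate molecular OTU assignments
(:class:`Partition`), pairwise distance matrices with support for
undefined entries (:class:`DistanceMatrix`), and ultrametric dendrograms
(:class:`Dendrogram`).  Everything is plain text on disk: FASTA for
alignments, TSV for tables, newick for trees.

Distances are stored as proportions (0-1) internally; user-facing reports
multiply by 100, following the percent convention of barcode-gap tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("delimetrics")

IUPAC_DNA = frozenset("ACGTURYSWKMBDHVN-")
MISSING_TOKEN = "?"


class InputError(ValueError):
    """Raised when an input file violates a format contract."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment of named DNA barcode sequences.

    Rows are uppercase IUPAC DNA with ``-`` gaps, all of equal length.
    ``U`` is normalised to ``T`` on construction.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise InputError("alignment is empty")
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dupes}")
        norm = tuple(r.upper().replace("U", "T") for r in self.rows)
        object.__setattr__(self, "rows", norm)
        lengths = {len(r) for r in norm}
        if len(lengths) != 1:
            raise InputError(f"unaligned input: row lengths {sorted(lengths)}")
        for sid, row in zip(self.ids, norm):
            bad = set(row) - IUPAC_DNA
            if bad:
                raise InputError(f"record {sid!r}: non-IUPAC symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def row(self, strain_id: str) -> str:
        return self.rows[self.ids.index(strain_id)]

    def ungapped_lengths(self) -> dict[str, int]:
        """Per-sequence length after removing gap characters."""
        return {i: len(r) - r.count("-") for i, r in zip(self.ids, self.rows)}


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Order is preserved; sequences are case-folded to upper and ``U``
    becomes ``T``.  Unequal row lengths, duplicate ids and empty files are
    rejected with a diagnostic.
    """
    ids: list[str] = []
    seqs: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                ids.append(line[1:].split()[0])
                seqs.append([])
            else:
                if not ids:
                    raise InputError(f"{path}: sequence data before first header")
                seqs[-1].append(line)
    if not ids:
        raise InputError(f"{path}: empty FASTA file")
    return Alignment(tuple(ids), tuple("".join(s) for s in seqs))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


# ---------------------------------------------------------------------------
# Taxonomy / Partition
# ---------------------------------------------------------------------------


class _StrainMap:
    """A total mapping strain-id -> group label."""

    def __init__(self, mapping: Mapping[str, str]):
        if not mapping:
            raise InputError("empty strain map")
        for strain, label in mapping.items():
            if not str(label).strip():
                raise InputError(f"strain {strain!r} has empty group label")
        self._map = {str(k): str(v) for k, v in mapping.items()}

    def __getitem__(self, strain: str) -> str:
        return self._map[strain]

    def __contains__(self, strain: str) -> bool:
        return strain in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _StrainMap) and self._map == other._map

    @property
    def strains(self) -> frozenset[str]:
        return frozenset(self._map)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self._map.values()))

    def groups(self) -> dict[str, frozenset[str]]:
        """Label -> set of member strains."""
        out: dict[str, set[str]] = {}
        for strain, label in self._map.items():
            out.setdefault(label, set()).add(strain)
        return {k: frozenset(v) for k, v in out.items()}

    def items(self):
        return self._map.items()


class Taxonomy(_StrainMap):
    """Reference strain -> species assignment."""


class Partition(_StrainMap):
    """Candidate strain -> MOTU assignment produced by a delimitation method."""


def read_table(path: str | Path, required_columns: Sequence[str]) -> pd.DataFrame:
    """Read a TSV table with a header row, checking required columns.

    Cells equal to the literal ``?`` are mapped to the missing marker
    (NaN); this is the fixed convention for unknown morphological states.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    return df.mask(df == MISSING_TOKEN)


def read_taxonomy(path: str | Path) -> Taxonomy:
    df = read_table(path, ["strain", "species"])
    _check_nonempty_cells(df, path)
    return Taxonomy(dict(zip(df["strain"], df["species"])))


def read_partition(path: str | Path) -> Partition:
    df = read_table(path, ["strain", "motu"])
    _check_nonempty_cells(df, path)
    return Partition(dict(zip(df["strain"], df["motu"])))


def _check_nonempty_cells(df: pd.DataFrame, path) -> None:
    if df.isna().any().any() or (df == "").any().any():
        raise InputError(f"{path}: empty or missing cell in strain table")


def write_taxonomy(tax: Taxonomy, path: str | Path) -> None:
    pd.DataFrame(sorted(tax.items()), columns=["strain", "species"]).to_csv(
        path, sep="\t", index=False
    )


def write_partition(part: Partition, path: str | Path) -> None:
    pd.DataFrame(sorted(part.items()), columns=["strain", "motu"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over strain ids.

    Values are proportions.  ``mask[i, j]`` is True where the distance is
    undefined (e.g. K2P saturation or no comparable sites); masked entries
    hold NaN and are excluded from summaries.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match ids")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.array_equal(self.mask, self.mask.T):
            raise InputError("mask must be symmetric")
        vals = np.where(self.mask, 0.0, self.values)
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise InputError("distance matrix must be symmetric")
        if np.any(np.diagonal(self.values) != 0):
            raise InputError("diagonal must be zero")
        if np.any(vals < 0):
            raise InputError("distances must be non-negative")
        self.values = np.where(self.mask, np.nan, self.values)
        np.fill_diagonal(self.values, 0.0)
        np.fill_diagonal(self.mask, False)

    @property
    def n(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        """Distance between two strains; NaN when masked."""
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def is_complete(self) -> bool:
        return not self.mask.any()

    def submatrix(self, keep: Iterable[str]) -> "DistanceMatrix":
        keep = [i for i in self.ids if i in set(keep)]
        idx = [self.ids.index(i) for i in keep]
        return DistanceMatrix(
            tuple(keep), self.values[np.ix_(idx, idx)], self.mask[np.ix_(idx, idx)]
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order (NaN for masked)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self, percent: bool = False, decimals: int = 4) -> pd.DataFrame:
        vals = self.values * 100 if percent else self.values
        return pd.DataFrame(np.round(vals, decimals), index=self.ids, columns=self.ids)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a square TSV matrix in percent units, 4 decimals."""
    dm.to_dataframe(percent=True).to_csv(path, sep="\t", index_label="strain")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square TSV matrix written by :func:`write_distance_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise InputError(f"{path}: row and column labels differ")
    return DistanceMatrix(tuple(str(i) for i in df.index), df.to_numpy() / 100.0)


# ---------------------------------------------------------------------------
# Dendrogram + newick
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dendrogram:
    """A rooted ultrametric tree node.

    Leaves carry a ``name`` and height 0; internal nodes carry the height
    (distance from any descendant leaf) at which their children merged.
    """

    height: float
    name: str | None = None
    children: tuple["Dendrogram", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out

    def cophenetic(self) -> dict[frozenset, float]:
        """Pairwise leaf distances implied by the tree (2x merge height)."""
        out: dict[frozenset, float] = {}

        def walk(node: Dendrogram) -> list[str]:
            if node.is_leaf:
                return [node.name]  # type: ignore[list-item]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            out[frozenset((a, b))] = 2.0 * node.height
            return [x for g in groups for x in g]

        walk(self)
        return out


def _newick_str(node: Dendrogram, parent_height: float) -> str:
    blen = parent_height - node.height
    if node.is_leaf:
        label = node.name.replace(" ", "_")  # type: ignore[union-attr]
        return f"{label}:{blen:.10g}"
    inner = ",".join(_newick_str(c, node.height) for c in node.children)
    return f"({inner}):{blen:.10g}"


def write_newick(tree: Dendrogram, path: str | Path) -> None:
    """Write a rooted tree with branch lengths; round-trips through readers."""
    inner = ",".join(_newick_str(c, tree.height) for c in tree.children)
    text = f"({inner});\n" if tree.children else f"{tree.name};\n"
    Path(path).write_text(text, encoding="utf-8")


def read_newick(path: str | Path) -> "dendropy.Tree":  # noqa: F821
    import dendropy

    return dendropy.Tree.get(
        path=str(path), schema="newick", rooting="force-rooted"
    )
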