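"""Kimura 2-parameter distances and alignment site statistics.

The K2P model separates transitions (A<->G, C<->T) from transversions and
corrects the observed proportions P (transitions) and Q (transversions)
for multiple hits:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Sites where either sequence carries a gap or an ambiguity code are
excluded pair by pair (pairwise deletion), so each pair uses the maximal
set of comparable sites.  When a log argument is non-positive the
distance is saturated: it is reported as undefined (NaN) and masked, not
clamped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core_io import Alignment, DistanceMatrix

logger = logging.getLogger("delimetrics")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_UNAMBIGUOUS = frozenset("ACGT")


class DistanceError(ValueError):
    """Raised when a pairwise distance cannot be computed at all."""


@dataclass(frozen=True)
class K2PResult:
    """K2P distance with its ingredients.

    d is NaN when the correction saturates (log argument <= 0); n_sites
    counts positions compared after pairwise deletion.
    """

    d: float
    P: float
    Q: float
    n_sites: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.d)


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def k2p_distance(seq1: str, seq2: str) -> K2PResult:
    """K2P distance between two aligned sequences (pairwise deletion).

    Raises :class:`DistanceError` when no comparable site remains.
    """
    if len(seq1) != len(seq2):
        raise DistanceError("sequences differ in aligned length")
    seq1 = seq1.upper().replace("U", "T")
    seq2 = seq2.upper().replace("U", "T")
    n = ts = tv = 0
    for a, b in zip(seq1, seq2):
        if a not in _UNAMBIGUOUS or b not in _UNAMBIGUOUS:
            continue
        n += 1
        if a != b:
            if _is_transition(a, b):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise DistanceError("no comparable sites")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        logger.warning("K2P saturation (P=%.4f, Q=%.4f); distance undefined", P, Q)
        return K2PResult(math.nan, P, Q, n)
    return K2PResult(-0.5 * math.log(w1) - 0.25 * math.log(w2), P, Q, n)


def distance_matrix(aln: Alignment) -> DistanceMatrix:
    """All-pairs K2P distances; undefined pairs are masked, not fatal."""
    if aln.n_sequences < 2:
        raise DistanceError("need at least 2 sequences")
    n = aln.n_sequences
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        try:
            res = k2p_distance(aln.rows[i], aln.rows[j])
            D[i, j] = D[j, i] = res.d
        except DistanceError:
            logger.warning(
                "no comparable sites between %s and %s; masking", aln.ids[i], aln.ids[j]
            )
            D[i, j] = D[j, i] = math.nan
    return DistanceMatrix(aln.ids, D)


def variable_site_proportion(aln: Alignment) -> float:
    """Percent of alignment columns with >= 2 distinct unambiguous bases.

    Gaps and ambiguity codes do not count as states; all columns,
    including all-gap ones, enter the denominator.
    """
    if aln.n_sequences < 2:
        raise DistanceError("need at least 2 sequences")
    variable = 0
    for col in range(aln.length):
        states = {r[col] for r in aln.rows} & _UNAMBIGUOUS
        if len(states) >= 2:
            variable += 1
    return variable / aln.length * 100.0
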