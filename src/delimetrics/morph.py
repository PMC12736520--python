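"""Morphological trait analysis and morphology-phylogeny congruence.

Multi-state trait tables (cells may carry several states, e.g.
"ellipsoidal, ovoid", or be unknown, "?") are expanded into binary
indicator vectors: one column per possible state of each trait, 1 where
the strain exhibits that state.  Strains with fewer than 80% of traits
determined are excluded before analysis.  Pairwise dissimilarity is the
Jaccard distance over set bits, computed per pair on the traits
determined in both strains.

Built on these distances the module offers per-trait Mantel permutation
tests (which traits drive the overall structure), UPGMA dendrograms,
principal coordinates analysis, and two global congruence tests between
a morphological and a phylogenetic distance matrix: CADM (Kendall's W
over the two rank-transformed distance vectors) and Procrustes/protest
on their ordinations, with Holm family-wise correction of the two
p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial import procrustes as _scipy_procrustes
from statsmodels.stats.multitest import multipletests

from .core_io import Dendrogram, DistanceMatrix

logger = logging.getLogger("delimetrics")

STATE_SEPARATOR = ","


class MorphError(ValueError):
    pass


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int


@dataclass(frozen=True)
class CongruenceResult:
    W: float
    p_cadm: float
    t0: float
    p_protest: float
    p_cadm_adj: float
    p_protest_adj: float


@dataclass(frozen=True)
class Ordination:
    ids: tuple[str, ...]
    coordinates: np.ndarray  # strains x k
    eigenvalues: np.ndarray


class BinaryMatrix:
    """Indicator expansion of a multi-state trait table.

    ``data`` is strains x indicator columns with values 0/1/NaN; a
    strain's indicators for a trait are either all determined or all
    NaN.  ``column_trait`` maps each indicator column to its trait.
    """

    def __init__(self, data: pd.DataFrame, column_trait: dict[str, str]):
        self.data = data
        self.column_trait = column_trait

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.column_trait.values()))

    def trait_columns(self, trait: str) -> list[str]:
        return [c for c, t in self.column_trait.items() if t == trait]

    def restrict(self, traits: list[str]) -> "BinaryMatrix":
        cols = [c for c in self.data.columns if self.column_trait[c] in set(traits)]
        return BinaryMatrix(self.data[cols], {c: self.column_trait[c] for c in cols})


def encode_traits(
    traits: pd.DataFrame,
    min_completeness: float = 0.8,
    vocabulary: dict[str, list[str]] | None = None,
) -> BinaryMatrix:
    """Expand a strains x traits table into binary indicators.

    Cells are comma-separated state tokens; NaN marks unknown states.
    Multi-valued cells set several indicators to 1.  Strains with fewer
    than ``min_completeness`` of traits determined are dropped (logged).
    State vocabularies default to the states observed per trait; a
    user-declared vocabulary may extend them.
    """
    determined = traits.notna()
    frac = determined.mean(axis=1)
    dropped = list(traits.index[frac < min_completeness])
    if dropped:
        logger.info(
            "excluding %d strain(s) below %.0f%% trait completeness: %s",
            len(dropped), min_completeness * 100, dropped,
        )
    kept = traits.loc[frac >= min_completeness]
    if kept.empty:
        raise MorphError("no strains pass the completeness filter")

    def cell_states(cell) -> set[str]:
        return {tok.strip() for tok in str(cell).split(STATE_SEPARATOR) if tok.strip()}

    columns: dict[str, list[float]] = {}
    column_trait: dict[str, str] = {}
    for trait in kept.columns:
        observed: set[str] = set()
        for cell in kept[trait].dropna():
            observed |= cell_states(cell)
        states = sorted(observed)
        if vocabulary and trait in vocabulary:
            extra = [s for s in vocabulary[trait] if s not in observed]
            unknown = observed - set(vocabulary[trait])
            if unknown:
                raise MorphError(
                    f"trait {trait!r}: states {sorted(unknown)} not in declared vocabulary"
                )
            states = list(vocabulary[trait])
            del extra
        for state in states:
            col = f"{trait}={state}"
            vals: list[float] = []
            for cell in kept[trait]:
                if pd.isna(cell):
                    vals.append(math.nan)
                else:
                    vals.append(1.0 if state in cell_states(cell) else 0.0)
            columns[col] = vals
            column_trait[col] = trait
    data = pd.DataFrame(columns, index=kept.index)
    return BinaryMatrix(data, column_trait)


def jaccard_matrix(bm: BinaryMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distances over set bits.

    For each pair only traits determined in both strains enter; a pair
    sharing no determined trait is masked.  If both strains have an
    empty bit union (possible only with degenerate vocabularies) the
    distance is 0 by convention.
    """
    ids = bm.strains
    n = len(ids)
    if n < 2:
        raise MorphError("need at least 2 strains")
    X = bm.data.to_numpy(dtype=float)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(X[i]) & ~np.isnan(X[j])
            if not ok.any():
                D[i, j] = D[j, i] = math.nan
                continue
            a, b = X[i, ok] > 0, X[j, ok] > 0
            union = (a | b).sum()
            if union == 0:
                logger.debug("pair (%s, %s): empty bit union; distance 0", ids[i], ids[j])
                d = 0.0
            else:
                d = 1.0 - (a & b).sum() / union
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids, D)


def _condensed(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test: Pearson r between two distance matrices.

    One-tailed upper permutation p-value with +1 correction, permuting
    the strain labels (rows and columns jointly) of the second matrix.
    """
    if dm1.ids != dm2.ids:
        raise MorphError("matrices must share the same ordered strain set")
    if dm1.mask.any() or dm2.mask.any():
        raise MorphError("Mantel test requires complete matrices")
    x = _condensed(dm1.values)
    y = _condensed(dm2.values)
    if np.std(x) == 0 or np.std(y) == 0:
        raise MorphError("degenerate trait: zero-variance distance vector")
    r_obs = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    logger.debug("mantel: %d permutations, seed=%s", n_perm, seed)
    n = dm1.n
    count = 0
    xc = x - x.mean()
    xnorm = math.sqrt((xc**2).sum())
    for _ in range(n_perm):
        p = rng.permutation(n)
        yp = _condensed(dm2.values[np.ix_(p, p)])
        yc = yp - yp.mean()
        r_perm = float((xc * yc).sum() / (xnorm * math.sqrt((yc**2).sum())))
        if r_perm >= r_obs:
            count += 1
    return MantelResult(r_obs, (count + 1) / (n_perm + 1), n_perm)


def mantel_per_trait(
    bm: BinaryMatrix, trait: str, n_perm: int = 10000, seed: int | None = None
) -> MantelResult:
    """Mantel test of one trait's Jaccard matrix against the overall one.

    Strains with the trait undetermined are excluded from both matrices
    for this comparison.
    """
    if trait not in bm.traits:
        raise MorphError(f"unknown trait {trait!r}")
    cols = bm.trait_columns(trait)
    keep = list(bm.data.index[bm.data[cols].notna().all(axis=1)])
    if len(keep) < 3:
        raise MorphError(f"trait {trait!r}: too few strains with determined state")
    sub = BinaryMatrix(bm.data.loc[keep], bm.column_trait)
    overall = jaccard_matrix(sub)
    single = jaccard_matrix(sub.restrict([trait]))
    return mantel(overall, single, n_perm=n_perm, seed=seed)


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration; returns an ultrametric dendrogram."""
    if dm.mask.any():
        raise MorphError("UPGMA requires a complete matrix; impute or drop strains")
    Z = linkage(_condensed(dm.values), method="average")
    nodes: list[Dendrogram] = [Dendrogram(0.0, name=i) for i in dm.ids]
    for h_row in Z:
        a, b, dist = int(h_row[0]), int(h_row[1]), float(h_row[2])
        nodes.append(Dendrogram(dist / 2.0, children=(nodes[a], nodes[b])))
    return nodes[-1]


def pcoa(dm: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers -D^2/2 and eigendecomposes; axes with non-positive
    eigenvalues are dropped, truncating k with a warning if needed.
    """
    if k < 1:
        raise MorphError("k must be >= 1")
    if dm.mask.any():
        raise MorphError("PCoA requires a complete matrix")
    D2 = dm.values**2
    n = dm.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > 1e-10
    if k > pos.sum():
        logger.warning("requested %d axes but only %d positive eigenvalues", k, pos.sum())
        k = int(pos.sum())
    coords = v[:, :k] * np.sqrt(w[:k])
    return Ordination(dm.ids, coords, w[pos])


def _kendall_w(x: np.ndarray, y: np.ndarray) -> float:
    # Kendall's coefficient of concordance for m=2 rankings, tie-corrected
    r1, r2 = stats.rankdata(x), stats.rankdata(y)
    n = x.size
    R = r1 + r2
    S = float(((R - R.mean()) ** 2).sum())

    def tie_term(r: np.ndarray) -> float:
        _, counts = np.unique(r, return_counts=True)
        return float(((counts**3 - counts)).sum()) / 12.0

    denom = 4 * (n**3 - n) / 12.0 - 2 * (tie_term(r1) + tie_term(r2))
    if denom <= 0:
        raise MorphError("degenerate rankings in CADM")
    return S / denom


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down family-wise adjustment (monotone, capped at 1)."""
    return list(multipletests(p_values, method="holm")[1])


def congruence_tests(
    dm_morph: DistanceMatrix,
    dm_phylo: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
) -> CongruenceResult:
    """Global morphology-phylogeny congruence: CADM and protest.

    CADM: Kendall's W over the two rank-transformed off-diagonal
    vectors, permutation p (labels of the second matrix permuted).
    Protest: both matrices are ordinated by PCoA, centred and scaled to
    unit sum of squares, optimally rotated; t0 = sqrt(1 - m2) with a
    row-permutation p-value.  The two raw p-values are Holm-adjusted.
    """
    if dm_morph.ids != dm_phylo.ids:
        raise MorphError("matrices must share the same ordered strain set")
    if dm_morph.mask.any() or dm_phylo.mask.any():
        raise MorphError("congruence tests require complete matrices")
    rng = np.random.default_rng(seed)
    n = dm_morph.n
    x = _condensed(dm_morph.values)

    w_obs = _kendall_w(x, _condensed(dm_phylo.values))
    count_w = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if _kendall_w(x, _condensed(dm_phylo.values[np.ix_(p, p)])) >= w_obs:
            count_w += 1
    p_cadm = (count_w + 1) / (n_perm + 1)

    k = min(n - 1, 3)
    ord1 = pcoa(dm_morph, k=k)
    ord2 = pcoa(dm_phylo, k=k)
    kk = max(ord1.coordinates.shape[1], ord2.coordinates.shape[1])

    def pad(c: np.ndarray) -> np.ndarray:
        if c.shape[1] < kk:
            c = np.hstack([c, np.zeros((c.shape[0], kk - c.shape[1]))])
        return c

    c1, c2 = pad(ord1.coordinates), pad(ord2.coordinates)
    _, _, m2_obs = _scipy_procrustes(c1, c2)
    t0 = math.sqrt(max(0.0, 1.0 - m2_obs))
    count_t = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        _, _, m2p = _scipy_procrustes(c1, c2[p])
        if m2p <= m2_obs:
            count_t += 1
    p_protest = (count_t + 1) / (n_perm + 1)

    adj = holm_adjust([p_cadm, p_protest])
    return CongruenceResult(w_obs, p_cadm, t0, p_protest, adj[0], adj[1])
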