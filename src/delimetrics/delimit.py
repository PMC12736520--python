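"""Distance-threshold species delimitation and partition scoring.

Two delimitation primitives are provided:

* **Threshold clustering** — MOTUs are the connected components of the
  graph whose edges join strains at distance <= t (single linkage).  A
  complete-linkage variant is available for comparison.
* **K/theta test** — Birky's population-genetic rule: two putative
  clades are distinct species when the mean between-clade distance K is
  at least 4x the within-clade diversity theta.

Any candidate partition — produced here or imported from external tools
(ASAP, GMYC, PTP variants) — is scored against a reference taxonomy
species by species as a match, split, merge, or mixture.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core_io import DistanceMatrix, Partition, Taxonomy

logger = logging.getLogger("delimetrics")

KOT_CUTOFF = 4.0  # Birky's K/theta rule of thumb


class DelimitationError(ValueError):
    pass


@dataclass(frozen=True)
class KotResult:
    K: float
    theta: float
    ratio: float
    verdict: str  # "distinct" | "not_distinct" | "indeterminate"


@dataclass(frozen=True)
class ScoreReport:
    """Per-species concordance of a candidate partition with taxonomy."""

    verdicts: dict[str, str]  # species -> match|split|merge|mixture
    n_match: int
    n_split: int
    n_merge: int
    n_mixture: int
    match_pct: float
    split_pct: float
    merge_pct: float
    mixture_pct: float

    @property
    def n_species(self) -> int:
        return len(self.verdicts)


def threshold_cluster(
    dm: DistanceMatrix, t: float, linkage: str = "single"
) -> Partition:
    """Cluster strains at distance threshold t.

    Single linkage (default) takes connected components of the <=t graph;
    complete linkage requires *all* within-MOTU pairs <= t (greedy
    agglomeration in order of increasing distance).  Masked distances are
    treated as exceeding any threshold.
    """
    if t < 0:
        raise DelimitationError("threshold must be non-negative")
    if dm.mask.any():
        logger.warning("masked distances treated as > threshold")
    n = dm.n
    if linkage == "single":
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in combinations(range(n), 2):
            d = dm.values[i, j]
            if not math.isnan(d) and d <= t:
                parent[find(i)] = find(j)
        roots = [find(i) for i in range(n)]
    elif linkage == "complete":
        clusters: list[set[int]] = [{i} for i in range(n)]
        edges = sorted(
            (dm.values[i, j], i, j)
            for i, j in combinations(range(n), 2)
            if not math.isnan(dm.values[i, j]) and dm.values[i, j] <= t
        )
        for _, i, j in edges:
            ci = next(c for c in clusters if i in c)
            cj = next(c for c in clusters if j in c)
            if ci is cj:
                continue
            ok = all(
                not math.isnan(dm.values[a, b]) and dm.values[a, b] <= t
                for a in ci
                for b in cj
            )
            if ok:
                clusters.remove(ci)
                clusters.remove(cj)
                clusters.append(ci | cj)
        roots = [0] * n
        for k, c in enumerate(clusters):
            for i in c:
                roots[i] = k
    else:
        raise DelimitationError(f"unknown linkage {linkage!r}")

    relabel: dict[int, str] = {}
    mapping: dict[str, str] = {}
    for i, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = f"MOTU{len(relabel) + 1:03d}"
        mapping[dm.ids[i]] = relabel[r]
    return Partition(mapping)


def _mean_within(dm: DistanceMatrix, members: list[int]) -> float:
    if len(members) < 2:
        return math.nan
    sub = dm.values[np.ix_(members, members)]
    return float(np.nanmean(sub[np.triu_indices(len(members), k=1)]))


def kot_test(
    dm: DistanceMatrix, clade_a: set[str], clade_b: set[str], cutoff: float = KOT_CUTOFF
) -> KotResult:
    """K/theta test for two putative clades.

    K is the mean distance over all cross-clade pairs; theta is the
    larger of the two within-clade mean pairwise distances (conservative
    toward lumping).  If both clades are singletons theta is undefined
    and the verdict is indeterminate; with one singleton, the other
    clade's diversity is used.
    """
    clade_a, clade_b = set(clade_a), set(clade_b)
    if not clade_a or not clade_b:
        raise DelimitationError("clades must be non-empty")
    if clade_a & clade_b:
        raise DelimitationError(f"clades overlap: {sorted(clade_a & clade_b)}")
    missing = (clade_a | clade_b) - set(dm.ids)
    if missing:
        raise DelimitationError(f"strains absent from matrix: {sorted(missing)}")
    idx = {s: k for k, s in enumerate(dm.ids)}
    ia = [idx[s] for s in sorted(clade_a)]
    ib = [idx[s] for s in sorted(clade_b)]
    K = float(np.nanmean(dm.values[np.ix_(ia, ib)]))
    wa, wb = _mean_within(dm, ia), _mean_within(dm, ib)
    thetas = [w for w in (wa, wb) if not math.isnan(w)]
    if not thetas:
        return KotResult(K, math.nan, math.nan, "indeterminate")
    theta = max(thetas)
    if theta == 0.0:
        ratio = math.inf if K > 0 else math.nan
    else:
        ratio = K / theta
    if math.isnan(ratio):
        verdict = "indeterminate"
    else:
        verdict = "distinct" if ratio >= cutoff else "not_distinct"
    return KotResult(K, theta, ratio, verdict)


def score_partition(candidate: Partition, reference: Taxonomy) -> ScoreReport:
    """Classify each reference species against the candidate MOTUs.

    match   — one MOTU contains exactly the species' strains;
    split   — the species spans >=2 MOTUs, each wholly inside it;
    merge   — the species sits inside a single larger MOTU;
    mixture — any other split/merge combination.
    """
    if candidate.strains != reference.strains:
        diff = sorted(candidate.strains ^ reference.strains)
        raise DelimitationError(f"strain universes differ: {diff}")
    motus = candidate.groups()
    verdicts: dict[str, str] = {}
    for species, R in reference.groups().items():
        touching = [m for m in motus.values() if m & R]
        if len(touching) == 1:
            M = touching[0]
            verdicts[species] = "match" if M == R else "merge"
        else:
            if all(m <= R for m in touching):
                verdicts[species] = "split"
            else:
                verdicts[species] = "mixture"
    counts = {v: sum(1 for x in verdicts.values() if x == v)
              for v in ("match", "split", "merge", "mixture")}
    k = len(verdicts)
    pct = {v: round(c / k * 100, 1) for v, c in counts.items()}
    return ScoreReport(
        verdicts=verdicts,
        n_match=counts["match"],
        n_split=counts["split"],
        n_merge=counts["merge"],
        n_mixture=counts["mixture"],
        match_pct=pct["match"],
        split_pct=pct["split"],
        merge_pct=pct["merge"],
        mixture_pct=pct["mixture"],
    )
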