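"""Synthetic data generators for every pipeline stage.

Real barcode datasets for coccoid green algae show a two-level
divergence structure: near-zero K2P distances within species and much
larger distances between them.  The generators here reproduce exactly
the statistical features the downstream analyses consume, nothing more:

* :func:`simulate_sequences` — a star phylogeny of species ancestors
  around a root, with strains radiating from each ancestor.  Branches
  apply a per-site two-class substitution draw (transition with
  probability kappa/(kappa+2), else one of the two transversions) with
  expected distance equal to the branch length, which is the process the
  K2P estimator inverts exactly.
* :func:`simulate_trait_matrix` — multi-state morphological traits with
  cluster-specific modal states, noise, and unknown cells.
* :func:`perturb_partition` — MOTU partitions derived from a reference
  taxonomy by a controlled number of splits and merges, for scoring
  tests with known ground truth.
* :func:`simulate_fa_replicates` — replicate fatty-acid tables drawn
  from stated means/SDs (normal, truncated at 0), n = 3 by default.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Alignment, Partition, Taxonomy

logger = logging.getLogger("delimetrics")

_BASES = np.array(list("ACGT"))
_TRANSITION = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T (indices into ACGT)
_TRANSVERSIONS = {0: (1, 3), 1: (0, 2), 2: (1, 3), 3: (0, 2)}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-level sequence divergence generator.

    d_within and d_between are expected K2P distances (proportions)
    between conspecific strains and between species ancestors; kappa is
    the transition/transversion rate ratio.
    """

    n_species: int = 4
    strains_per_species: int = 3
    seq_length: int = 1000
    d_within: float = 0.01
    d_between: float = 0.10
    ts_tv_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.d_within < self.d_between:
            raise SimulationError("require 0 <= d_within < d_between")
        if self.n_species < 1 or self.strains_per_species < 1:
            raise SimulationError("counts must be positive")
        if self.ts_tv_ratio < 0:
            raise SimulationError("kappa must be >= 0")
        if self.seq_length < 100:
            logger.warning("seq_length < 100: distance estimates will be noisy")


def _evolve(seq: np.ndarray, branch: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Apply one substitution draw per site with hit probability = branch."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < branch)
    p_ts = kappa / (kappa + 2.0) if kappa + 2.0 > 0 else 0.0
    for site in hits:
        base = out[site]
        if rng.random() < p_ts:
            out[site] = _TRANSITION[base]
        else:
            out[site] = _TRANSVERSIONS[base][rng.integers(2)]
    return out


def simulate_sequences(config: SimulationConfig) -> tuple[Alignment, Taxonomy]:
    """Generate a gapless alignment with two-level divergence structure.

    Each species ancestor sits d_between/2 from a common root; each
    strain sits d_within/2 from its ancestor.  Conspecific strains are
    therefore d_within apart in expectation, heterospecific strains
    d_between + d_within.
    """
    rng = np.random.default_rng(config.seed)
    logger.info("simulate_sequences seed=%d", config.seed)
    root = rng.integers(4, size=config.seq_length)
    ids: list[str] = []
    rows: list[str] = []
    mapping: dict[str, str] = {}
    for s in range(config.n_species):
        species = f"sp{s + 1:02d}"
        ancestor = _evolve(root, config.d_between / 2, config.ts_tv_ratio, rng)
        for k in range(config.strains_per_species):
            strain = f"{species}_st{k + 1:02d}"
            seq = _evolve(ancestor, config.d_within / 2, config.ts_tv_ratio, rng)
            ids.append(strain)
            rows.append("".join(_BASES[seq]))
            mapping[strain] = species
    return Alignment(tuple(ids), tuple(rows)), Taxonomy(mapping)


def simulate_trait_matrix(
    n_strains: int,
    n_traits: int,
    n_clusters: int,
    missing_frac: float = 0.1,
    noise: float = 0.1,
    n_states: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Multi-state trait table with cluster signal and unknown cells.

    Each cluster has a modal state per trait; a strain deviates to a
    random state with probability ``noise`` and its cell becomes
    unknown (NaN) with probability ``missing_frac``.  Returns the table
    and the true strain -> cluster map.
    """
    if not 0 <= missing_frac < 0.5:
        raise SimulationError("missing_frac must be in [0, 0.5)")
    if n_clusters > n_strains:
        raise SimulationError("more clusters than strains")
    rng = np.random.default_rng(seed)
    logger.info("simulate_trait_matrix seed=%d", seed)
    states = [f"state{s + 1}" for s in range(n_states)]
    modal = rng.integers(n_states, size=(n_clusters, n_traits))
    assignment = np.sort(rng.integers(n_clusters, size=n_strains - n_clusters))
    assignment = np.concatenate([np.arange(n_clusters), assignment])  # every cluster inhabited
    strains = [f"strain{i + 1:03d}" for i in range(n_strains)]
    data = {}
    for t in range(n_traits):
        col = []
        for i in range(n_strains):
            if rng.random() < missing_frac:
                col.append(np.nan)
                continue
            if rng.random() < noise:
                col.append(states[rng.integers(n_states)])
            else:
                col.append(states[modal[assignment[i], t]])
        data[f"trait{t + 1:02d}"] = col
    df = pd.DataFrame(data, index=strains)
    truth = {s: f"cluster{assignment[i] + 1}" for i, s in enumerate(strains)}
    return df, truth


def perturb_partition(
    reference: Taxonomy, n_splits: int = 0, n_merges: int = 0, seed: int = 0
) -> Partition:
    """Derive a MOTU partition from a taxonomy by controlled edits.

    Exactly ``n_splits`` species (chosen among those with >= 2 strains)
    are divided into two MOTUs, and ``n_merges`` disjoint species pairs
    (none of them split) are fused; everything else maps 1:1.
    """
    rng = np.random.default_rng(seed)
    groups = reference.groups()
    species = sorted(groups)
    splittable = [s for s in species if len(groups[s]) >= 2]
    if n_splits > len(splittable):
        raise SimulationError(
            f"requested {n_splits} splits but only {len(splittable)} species have >=2 strains"
        )
    split_targets = list(rng.choice(splittable, size=n_splits, replace=False)) if n_splits else []
    remaining = [s for s in species if s not in split_targets]
    if 2 * n_merges > len(remaining):
        raise SimulationError("not enough unsplit species to form merge pairs")
    merge_pool = list(rng.permutation(remaining))[: 2 * n_merges]
    merge_pairs = [(merge_pool[2 * i], merge_pool[2 * i + 1]) for i in range(n_merges)]

    mapping: dict[str, str] = {}
    for s in species:
        for strain in groups[s]:
            mapping[strain] = f"motu_{s}"
    for s in split_targets:
        members = sorted(groups[s])
        cut = rng.integers(1, len(members))
        for strain in members[:cut]:
            mapping[strain] = f"motu_{s}_a"
        for strain in members[cut:]:
            mapping[strain] = f"motu_{s}_b"
    for a, b in merge_pairs:
        fused = f"motu_{a}+{b}"
        for strain in groups[a] | groups[b]:
            mapping[strain] = fused
    return Partition(mapping)


def simulate_fa_replicates(
    means: dict[str, float],
    sds: dict[str, float],
    n: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw replicate FA mass percentages from stated means and SDs.

    Normal draws per fatty acid, truncated at 0 (clipped values are
    logged); returns a table of n replicate columns indexed by FA name.
    """
    if n < 2:
        raise SimulationError("need n >= 2 replicates")
    if set(means) != set(sds):
        raise SimulationError("means and sds must list the same fatty acids")
    rng = np.random.default_rng(seed)
    logger.info("simulate_fa_replicates seed=%d n=%d", seed, n)
    rows = {}
    for fa in means:
        if sds[fa] < 0:
            raise SimulationError(f"{fa}: negative SD")
        draws = rng.normal(means[fa], sds[fa], size=n)
        clipped = draws < 0
        if clipped.any():
            logger.info("%s: %d negative draw(s) clipped to 0", fa, int(clipped.sum()))
            draws = np.clip(draws, 0.0, None)
        rows[fa] = draws
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"rep{i + 1}" for i in range(n)]
    )
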