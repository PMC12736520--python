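"""Fatty-acid profile statistics.

Works from the summary form in which FA composition tables are printed:
per fatty acid, mean mass% +/- SD over n replicates per growth
condition.  Provides

* the unsaturation index UI = sum(mass%_i x double_bonds_i) / 100, a
  membrane-fluidity proxy;
* one-way ANOVA from summary statistics (or raw replicates) with the
  eta-squared effect size, eta2 = SSB / (SSB + SSW);
* t-distribution confidence intervals mean +/- t_{1-a/2, n-1} * sd/sqrt(n)
  (negative lower bounds are reported as-is).

FA names follow lipid shorthand "C:D" with optional double-bond
positions, e.g. "18:3 D9,12,15" (Greek delta or 'D').
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

_FA_NAME = re.compile(
    r"^\s*(\d+)\s*:\s*(\d+)\s*(?:[ΔD]\s*([\d]+(?:\s*,\s*\d+)*))?\s*$"
)


class FAError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    eta_sq: float
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    group_ns: tuple[int, ...]


def parse_fa_name(name: str) -> tuple[int, int]:
    """Parse "carbons:double_bonds [Δpositions]" shorthand.

    The position list, when present, must have exactly double_bonds
    entries.
    """
    m = _FA_NAME.match(name)
    if not m:
        raise FAError(f"cannot parse fatty-acid name {name!r}")
    carbons, n_db = int(m.group(1)), int(m.group(2))
    if m.group(3) is not None:
        positions = [int(x) for x in m.group(3).split(",")]
        if len(positions) != n_db:
            raise FAError(
                f"{name!r}: {len(positions)} double-bond positions listed "
                f"but {n_db} double bonds declared"
            )
    return carbons, n_db


def unsaturation_index(profile: dict[str, float]) -> float:
    """UI from a mapping FA name -> mass% of total fatty acids."""
    total = 0.0
    for name, pct in profile.items():
        if pct < 0:
            raise FAError(f"{name!r}: negative mass percentage")
        _, n_db = parse_fa_name(name)
        total += pct * n_db
    return total / 100.0


def one_way_anova(
    groups: list[tuple[float, float, int]] | list[np.ndarray],
) -> AnovaResult:
    """One-way fixed-effects ANOVA with eta-squared.

    ``groups`` is either summary statistics [(mean, sd, n), ...] or raw
    replicate arrays.  The two forms give identical results because SSB
    and SSW depend on the data only through the summaries.
    """
    if len(groups) < 2:
        raise FAError("need at least 2 groups")
    if isinstance(groups[0], tuple):
        summaries = [(float(m), float(s), int(n)) for m, s, n in groups]  # type: ignore[misc]
    else:
        summaries = []
        for g in groups:
            arr = np.asarray(g, dtype=float)
            if arr.size < 2:
                raise FAError("each group needs n >= 2 replicates")
            summaries.append((float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)))
    for m, s, n in summaries:
        if n < 2:
            raise FAError("each group needs n >= 2")
        if s < 0:
            raise FAError("negative SD")
    means = np.array([m for m, _, _ in summaries])
    sds = np.array([s for _, s, _ in summaries])
    ns = np.array([n for _, _, n in summaries])
    N, k = int(ns.sum()), len(summaries)
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    if ssw == 0.0:
        F = math.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        F = (ssb / (k - 1)) / (ssw / (N - k))
        p = float(stats.f.sf(F, k - 1, N - k))
    eta_sq = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
    return AnovaResult(F, p, eta_sq,
                       tuple(means.tolist()), tuple(sds.tolist()), tuple(ns.tolist()))


def t_ci(mean: float, sd: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided t confidence interval for a mean from (mean, sd, n)."""
    if n < 2:
        raise FAError("need n >= 2")
    if sd < 0:
        raise FAError("negative SD")
    half = stats.t.ppf(0.5 + level / 2, df=n - 1) * sd / math.sqrt(n)
    return (mean - half, mean + half)


def welch_pairwise(groups: list[tuple[float, float, int]]) -> list[tuple[int, int, float]]:
    """Pairwise Welch t-test p-values between summary groups.

    Offered as a simple post hoc alternative; not a Tukey HSD.
    """
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            m1, s1, n1 = groups[i]
            m2, s2, n2 = groups[j]
            se2 = s1**2 / n1 + s2**2 / n2
            if se2 == 0:
                p = 1.0 if m1 == m2 else 0.0
            else:
                t = (m1 - m2) / math.sqrt(se2)
                df = se2**2 / (
                    (s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1)
                )
                p = float(2 * stats.t.sf(abs(t), df))
            out.append((i, j, p))
    return out
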