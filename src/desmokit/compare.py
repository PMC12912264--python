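"""Set-level and abundance-level comparison of interactomes.

An interactome is a named gene set with optional per-gene log2 abundances.
This module provides:

* :func:`overlap` — exact two- or three-way Venn region counts and
  membership lists (the regions partition the union).
* :func:`abundance_regression` — ordinary least squares of one
  interactome's abundances on another's over their shared genes, with a
  normal-theory 95% CI on the slope and a two-sided p for slope != 0.
* :func:`ora_enrichment` — one-sided hypergeometric over-representation
  analysis of a hit list against named gene-set collections, with BH
  q-values and fold enrichment; generic plumbing standing in for
  proprietary pathway software.

Cross-study symbol matching is the caller's concern; :func:`apply_aliases`
harmonizes symbols through an explicit alias map (case-insensitive lookup)
and reports unmatched aliases rather than dropping anything silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

__all__ = ["Interactome", "VennRegions", "RegressionResult", "overlap",
           "abundance_regression", "ora_enrichment", "apply_aliases"]


@dataclass
class Interactome:
    """A named gene set with optional per-gene log2 abundance."""

    name: str
    genes: set[str]
    abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        extra = set(self.abundance) - self.genes
        if extra:
            raise ValueError(f"abundance keys outside gene set: {sorted(extra)}")


@dataclass
class VennRegions:
    """Disjoint Venn regions keyed by the sorted tuple of member names."""

    regions: dict[tuple[str, ...], set[str]]

    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    r_squared: float
    p_slope: float
    n: int


def overlap(a: Interactome, b: Interactome,
            c: Interactome | None = None) -> VennRegions:
    """Disjoint Venn region membership for two or three interactomes."""
    sets = [a, b] + ([c] if c is not None else [])
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate interactome names: {names}")
    if any(not s.genes for s in sets):
        raise ValueError("all interactomes must be non-empty")
    regions: dict[tuple[str, ...], set[str]] = {}
    n = len(sets)
    for pattern in range(1, 2 ** n):
        members = tuple(names[i] for i in range(n) if pattern >> i & 1)
        inside = [sets[i].genes for i in range(n) if pattern >> i & 1]
        outside = [sets[i].genes for i in range(n) if not pattern >> i & 1]
        region = set.intersection(*inside)
        for out in outside:
            region -= out
        regions[tuple(sorted(members))] = region
    return VennRegions(regions)


def abundance_regression(shared_genes: Iterable[str],
                         abund_a: Mapping[str, float],
                         abund_b: Mapping[str, float],
                         ci_level: float = 0.95) -> RegressionResult:
    """OLS of interactome-b abundance on interactome-a over shared genes.

    Interactome a is the predictor (x axis).  Genes missing an abundance in
    either map are dropped; at least three complete points are required.
    """
    genes = [g for g in shared_genes if g in abund_a and g in abund_b]
    if len(genes) < 3:
        raise ValueError("need >= 3 shared genes with abundance in both")
    x = np.array([abund_a[g] for g in genes], dtype=float)
    y = np.array([abund_b[g] for g in genes], dtype=float)
    res = stats.linregress(x, y)
    df = len(genes) - 2
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            slope_ci95=(float(ci[0]), float(ci[1])),
                            r_squared=float(res.rvalue ** 2),
                            p_slope=float(res.pvalue),
                            n=len(genes))


def ora_enrichment(hits: Iterable[str], gene_sets: Mapping[str, Iterable[str]],
                   universe: Iterable[str]):
    """One-sided hypergeometric over-representation of hits in gene sets.

    For each set, with N = |universe|, K = |set ∩ universe|, n = |hits| and
    k = |hits ∩ set|, the p-value is P(X >= k) for X ~ Hypergeom(N, K, n),
    fold enrichment is (k/n)/(K/N), and q is the BH-adjusted p across sets.
    Hits must be a subset of the universe.
    """
    import pandas as pd

    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    hits = set(hits)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    N, n = len(universe), len(hits)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        K = len(members)
        k = len(hits & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        expected = K * n / N
        fold = (k / expected) if expected > 0 else np.nan
        rows.append((name, N, K, n, k, fold, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set", "N", "K", "n", "k",
                                     "fold_enrichment", "p_value"])
    if len(df):
        df["q_value"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df.sort_values("p_value").reset_index(drop=True)


def apply_aliases(genes: Iterable[str], alias_map: Mapping[str, str]
                  ) -> tuple[set[str], set[str]]:
    """Harmonize symbols through an alias map (case-insensitive lookup).

    Returns the harmonized set and the subset of alias-map keys that
    matched nothing (reported, never silently dropped).
    """
    lower_map = {k.lower(): v for k, v in alias_map.items()}
    out = set()
    used = set()
    for g in genes:
        target = lower_map.get(g.lower())
        if target is not None:
            out.add(target)
            used.add(g.lower())
        else:
            out.add(g)
    unmatched = {k for k in alias_map if k.lower() not in used}
    return out, unmatched
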