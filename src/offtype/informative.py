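"""Differentiating-locus identification between pooled cultivars.

A locus differentiates a pair of cultivars when their collapsed genotype
classes differ — homozygous-reference, heterozygous or homozygous-alternate.
Two heterozygotes of different allele dosage (0/0/1 versus 0/1/1 in a
triploid) are NOT differentiating: without phased subgenome assignment a
dosage difference within the heterozygote class is not reliable evidence of
cultivar divergence in GBS data.

Counts are optionally restricted to loci inside a read-depth window per
cultivar (default [40, 100)): the lower bound guards against heterozygotes
missed at low coverage, the upper bound against collapsed repetitive loci.
Both the exclusive-high and inclusive-high readings of the upper bound are
supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenotypeCall, GenotypeClass, genotype_class
from .pooling import PooledCultivar


@dataclass(frozen=True)
class DepthWindow:
    """Per-cultivar read-depth acceptance window.

    ``low`` is always inclusive; ``high`` is exclusive unless
    ``high_inclusive`` is set.
    """

    low: int = 40
    high: int = 100
    high_inclusive: bool = False

    def __post_init__(self) -> None:
        if self.low < 0:
            raise ValueError("low must be >= 0")
        if self.high < self.low:
            raise ValueError("high must be >= low")

    def contains(self, depth: int) -> bool:
        if depth < self.low:
            return False
        return depth <= self.high if self.high_inclusive else depth < self.high

    def mask(self, depths: np.ndarray) -> np.ndarray:
        upper = depths <= self.high if self.high_inclusive else depths < self.high
        return (depths >= self.low) & upper


def passes_window(call: GenotypeCall, window: DepthWindow) -> bool:
    if call.missing:
        raise ValueError("passes_window is undefined for a missing call")
    return window.contains(call.depth_total)


def pair_flag(call_a: GenotypeCall, call_b: GenotypeCall) -> bool:
    """True iff the two calls' genotype classes differ.

    Hom-ref vs hom-alt and hom vs het are flagged; het vs het is never
    flagged regardless of dosage.
    """
    if call_a.missing or call_b.missing:
        raise ValueError("pair_flag requires two non-missing calls")
    if call_a.ploidy != call_b.ploidy:
        raise ValueError(f"ploidy mismatch: {call_a.ploidy} vs {call_b.ploidy}")
    ca, cb = genotype_class(call_a), genotype_class(call_b)
    assert GenotypeClass.MISSING not in (ca, cb)
    return ca != cb


@dataclass
class PairwiseDiffMatrix:
    """Symmetric counts of differentiating loci between cultivar pairs."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError("counts grid must be square on the labels")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def value(self, a: str, b: str) -> int:
        return int(self.counts[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def _check_pools(pools: list[PooledCultivar]) -> None:
    if len(pools) < 2:
        raise ValueError("need at least two pooled cultivars")
    sites = pools[0].sites
    ploidy = pools[0].ploidy
    for p in pools[1:]:
        if p.sites != sites:
            raise ValueError("pools do not share a site list")
        if p.ploidy != ploidy:
            raise ValueError("pools must share one ploidy for class comparison")


def _flag_grid(pools: list[PooledCultivar], window: DepthWindow | None) -> np.ndarray:
    """(n_pairs_upper_triangle stacked) boolean flags; returns a
    (n_pools, n_pools, n_sites) array where [i, j, s] is True when site s
    differentiates pools i and j under the window."""
    n = len(pools)
    codes = np.stack([p.class_codes() for p in pools])  # (n, S)
    ok = codes >= 0
    if window is not None:
        ok &= np.stack([window.mask(p.depth_total) for p in pools])
    flags = np.zeros((n, n, codes.shape[1]), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            f = ok[i] & ok[j] & (codes[i] != codes[j])
            flags[i, j] = f
            flags[j, i] = f
    return flags


def pairwise_matrix(
    pools: list[PooledCultivar], window: DepthWindow | None = DepthWindow()
) -> PairwiseDiffMatrix:
    """Count differentiating loci for every cultivar pair.

    A site counts for pair (i, j) when both pools are non-missing there,
    both pass the depth window (if one is given), and their genotype classes
    differ.  Sites missing or out-of-window in one pool are skipped for that
    pair only.
    """
    _check_pools(pools)
    flags = _flag_grid(pools, window)
    return PairwiseDiffMatrix([p.label for p in pools], flags.sum(axis=2))


def differing_loci(
    pools: list[PooledCultivar], window: DepthWindow | None = DepthWindow()
) -> set[str]:
    """Site ids differentiating at least one cultivar pair."""
    _check_pools(pools)
    flags = _flag_grid(pools, window)
    any_pair = flags.any(axis=(0, 1))
    site_ids = [s.site_id for s in pools[0].sites]
    return {site_ids[k] for k in np.flatnonzero(any_pair)}


def flagged_site_table(
    pools: list[PooledCultivar], window: DepthWindow | None = DepthWindow()
) -> pd.DataFrame:
    """Two-column table: flagged site id and the number of flagging pairs."""
    _check_pools(pools)
    flags = _flag_grid(pools, window)
    n_pairs = np.triu(np.ones((len(pools), len(pools)), dtype=bool), 1)
    per_site = flags[n_pairs].sum(axis=0)
    site_ids = [s.site_id for s in pools[0].sites]
    keep = per_site > 0
    return pd.DataFrame(
        {
            "site_id": [site_ids[k] for k in np.flatnonzero(keep)],
            "n_flagging_pairs": per_site[keep].astype(int),
        }
    )
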