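"""Low-yield sample exclusion and per-cultivar replicate pooling.

Clonal replicates of one cultivar are pooled by summing their per-site
allele depths, and the pooled genotype is re-called from the pooled depths
by deterministic dosage rounding.  The re-caller is a deliberate, documented
replacement for a probabilistic caller: the downstream differentiating-locus
logic consumes only genotype classes and depths, and a deterministic rule
makes the oracle tests exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenotypeCall, GenotypeTable, SampleMeta, VariantSite, call_from_dosage

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 1_000_000


def exclude_low_read_samples(table: GenotypeTable, min_reads: int = DEFAULT_MIN_READS) -> GenotypeTable:
    """Drop samples with fewer than ``min_reads`` raw reads (strictly less).

    A sample with exactly ``min_reads`` raw reads is retained.
    """
    keep = [s.sample_id for s in table.samples if s.raw_read_count >= min_reads]
    dropped = [s.sample_id for s in table.samples if s.raw_read_count < min_reads]
    if dropped:
        logger.info(
            "excluded %d sample(s) with < %d raw reads: %s",
            len(dropped), min_reads, ", ".join(dropped),
        )
    return table.subset_samples(keep)


def recall_genotype(allele_depths: tuple[int, int], ploidy: int) -> GenotypeCall:
    """Re-call a genotype from pooled (ref, alt) read depths.

    The alternate dosage is ``round(ploidy * alt / total)`` with exact-half
    fractions rounded away from zero; zero total depth yields a missing call.
    """
    if ploidy not in (2, 3, 4):
        raise ValueError(f"ploidy must be 2, 3 or 4, got {ploidy}")
    ref, alt = int(allele_depths[0]), int(allele_depths[1])
    if ref < 0 or alt < 0:
        raise ValueError("allele depths must be non-negative")
    total = ref + alt
    if total == 0:
        return GenotypeCall((), 0, (0, 0), missing=True)
    # round half away from zero == round half up for non-negative fractions;
    # integer arithmetic keeps the tie-break exact
    dosage = (2 * ploidy * alt + total) // (2 * total)
    return call_from_dosage(dosage, ploidy, total, (ref, alt))


@dataclass
class PooledCultivar:
    """Summed allele depths and re-called genotypes for one cultivar."""

    label: str
    ploidy: int
    sites: list[VariantSite]
    allele_depths: np.ndarray  # (n_sites, 2)
    member_ids: list[str]

    def __post_init__(self) -> None:
        self.allele_depths = np.asarray(self.allele_depths, dtype=np.int64)
        if self.allele_depths.shape != (len(self.sites), 2):
            raise ValueError("allele_depths must be (n_sites, 2)")
        # re-call once; -1 marks missing (zero pooled depth)
        total = self.allele_depths.sum(axis=1)
        alt = self.allele_depths[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            dosage = np.where(
                total > 0, (2 * self.ploidy * alt + total) // np.maximum(2 * total, 1), -1
            ).astype(np.int16)
        self.dosage = dosage
        self.depth_total = total

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def call(self, site_index: int) -> GenotypeCall:
        return recall_genotype(
            tuple(int(x) for x in self.allele_depths[site_index]), self.ploidy
        )

    def class_codes(self) -> np.ndarray:
        """Int codes: -1 missing, 0 HOM_REF, 1 HET, 2 HOM_ALT."""
        codes = np.ones(self.n_sites, dtype=np.int8)
        codes[self.dosage == 0] = 0
        codes[self.dosage == self.ploidy] = 2
        codes[self.dosage < 0] = -1
        return codes

    def mean_depth(self) -> float:
        covered = self.depth_total[self.depth_total > 0]
        return float(covered.mean()) if covered.size else 0.0


def pool_cultivar(table: GenotypeTable, label: str) -> PooledCultivar:
    """Sum member allele depths per site and re-call the pooled genotype."""
    idx = [j for j, s in enumerate(table.samples) if s.group_label == label]
    if not idx:
        raise ValueError(f"no samples with cultivar label {label!r}")
    ploidies = {table.samples[j].ploidy for j in idx}
    if len(ploidies) > 1:
        raise ValueError(f"samples under label {label!r} have mixed ploidies {sorted(ploidies)}")
    pooled_ad = table.allele_depths[:, idx, :].sum(axis=1)
    return PooledCultivar(
        label=label,
        ploidy=ploidies.pop(),
        sites=list(table.sites),
        allele_depths=pooled_ad,
        member_ids=[table.samples[j].sample_id for j in idx],
    )


def pool_cultivars(table: GenotypeTable, labels: list[str]) -> list[PooledCultivar]:
    return [pool_cultivar(table, label) for label in labels]


def pooled_table(pools: list[PooledCultivar]) -> GenotypeTable:
    """Pack pooled cultivars as a one-sample-per-cultivar genotype table
    (e.g. for VCF export)."""
    if not pools:
        raise ValueError("no pools given")
    sites = pools[0].sites
    for p in pools[1:]:
        if p.sites != sites:
            raise ValueError("pools do not share a site list")
    samples = [
        SampleMeta(p.label, p.label, p.ploidy, int(p.depth_total.sum()), "standard")
        for p in pools
    ]
    dosage = np.stack([p.dosage for p in pools], axis=1)
    ad = np.stack([p.allele_depths for p in pools], axis=1)
    depth = ad.sum(axis=2)
    return GenotypeTable(sites=sites, samples=samples, dosage=dosage, depth=depth, allele_depths=ad)


def depth_summary(pools: list[PooledCultivar]) -> pd.DataFrame:
    """Per-cultivar mean covered depth and number of covered sites."""
    return pd.DataFrame(
        [
            {
                "cultivar": p.label,
                "mean_depth": p.mean_depth(),
                "n_sites_covered": int((p.depth_total > 0).sum()),
            }
            for p in pools
        ]
    )
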