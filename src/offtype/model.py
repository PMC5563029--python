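"""Ploidy-aware genotype domain model.

The central container is :class:`GenotypeTable`, a rectangular sites x samples
grid of biallelic genotype calls.  Genotypes are unphased allele-dosage calls:
a triploid heterozygote carrying one alternate allele is ``(0, 0, 1)`` and is
identical to any permutation of it.  Internally the table stores the alternate
allele dosage per cell (``-1`` for missing) together with total and per-allele
read depths, which keeps whole-table operations vectorizable while
:meth:`GenotypeTable.call` materializes a :class:`GenotypeCall` on demand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ROLES = frozenset({"standard", "desirable", "off_type", "progenitor"})
VALID_PLOIDIES = frozenset({2, 3, 4})

METADATA_COLUMNS = ["sample_id", "group_label", "ploidy", "raw_read_count", "role"]


class GenotypeClass(enum.Enum):
    """Collapsed biallelic genotype class (dosage within heterozygotes ignored)."""

    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's unphased call at one biallelic locus.

    ``alleles`` is a sorted tuple of allele indices (0 = reference,
    1 = alternate) whose length equals the sample's ploidy; it is empty for a
    missing call.  ``allele_depths`` is ``(ref_depth, alt_depth)`` and must sum
    to ``depth_total``.
    """

    alleles: tuple[int, ...]
    depth_total: int = 0
    allele_depths: tuple[int, int] = (0, 0)
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing:
            if self.alleles != ():
                raise ValueError("missing call must carry an empty allele tuple")
        else:
            if not self.alleles:
                raise ValueError("non-missing call needs at least one allele")
            if any(a not in (0, 1) for a in self.alleles):
                raise ValueError(f"allele indices must be 0/1, got {self.alleles}")
            if tuple(sorted(self.alleles)) != self.alleles:
                raise ValueError(f"alleles must be sorted non-decreasing: {self.alleles}")
        if self.depth_total < 0 or any(d < 0 for d in self.allele_depths):
            raise ValueError("read depths must be non-negative")
        if sum(self.allele_depths) != self.depth_total:
            raise ValueError(
                f"allele_depths {self.allele_depths} do not sum to depth_total {self.depth_total}"
            )

    @property
    def ploidy(self) -> int:
        if self.missing:
            raise ValueError("missing call has no ploidy")
        return len(self.alleles)

    @property
    def alt_dosage(self) -> int:
        if self.missing:
            raise ValueError("missing call has no dosage")
        return sum(self.alleles)


def call_from_dosage(
    dosage: int, ploidy: int, depth_total: int = 0, allele_depths: tuple[int, int] = (0, 0)
) -> GenotypeCall:
    """Build the canonical (sorted) call carrying ``dosage`` alternate alleles."""
    if dosage < 0:
        return GenotypeCall((), depth_total, allele_depths, missing=True)
    if dosage > ploidy:
        raise ValueError(f"dosage {dosage} exceeds ploidy {ploidy}")
    return GenotypeCall((0,) * (ploidy - dosage) + (1,) * dosage, depth_total, allele_depths)


def genotype_class(call: GenotypeCall) -> GenotypeClass:
    """Collapse a call to HOM_REF / HET / HOM_ALT / MISSING.

    Heterozygotes of differing dosage (e.g. 0/0/1 versus 0/1/1) fall into the
    same HET class; this collapse is what the differentiating-locus rule in
    :mod:`offtype.informative` compares.
    """
    if call.missing:
        return GenotypeClass.MISSING
    d = call.alt_dosage
    if d == 0:
        return GenotypeClass.HOM_REF
    if d == call.ploidy:
        return GenotypeClass.HOM_ALT
    return GenotypeClass.HET


def dosage_fraction(call: GenotypeCall) -> float:
    """Alternate-allele count divided by ploidy: a ploidy-independent genotype
    coordinate in [0, 1] used by the cross-ploidy distance."""
    if call.missing:
        raise ValueError("dosage_fraction undefined for a missing call")
    return call.alt_dosage / call.ploidy


@dataclass(frozen=True)
class VariantSite:
    """A biallelic variant: a tag identifier plus a 0-based position in the tag."""

    site_id: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical at {self.site_id}")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group_label: str
    ploidy: int
    raw_read_count: int
    role: str

    def __post_init__(self) -> None:
        if self.ploidy not in VALID_PLOIDIES:
            raise ValueError(f"ploidy must be one of {sorted(VALID_PLOIDIES)}, got {self.ploidy}")
        if self.raw_read_count < 0:
            raise ValueError("raw_read_count must be >= 0")
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {sorted(VALID_ROLES)}, got {self.role!r}")


@dataclass
class GenotypeTable:
    """Sites x samples grid of biallelic genotype calls.

    Attributes
    ----------
    sites
        Ordered variant sites (unique ``site_id``).
    samples
        Ordered sample metadata (unique ``sample_id``).
    dosage
        ``(n_sites, n_samples)`` int array of alternate-allele dosages,
        ``-1`` marking a missing call.
    depth
        ``(n_sites, n_samples)`` int array of total read depth per call.
    allele_depths
        ``(n_sites, n_samples, 2)`` int array of (ref, alt) read depths.
    """

    sites: list[VariantSite]
    samples: list[SampleMeta]
    dosage: np.ndarray
    depth: np.ndarray
    allele_depths: np.ndarray
    skipped_multiallelic: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        n_sites, n_samples = len(self.sites), len(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        self.allele_depths = np.asarray(self.allele_depths, dtype=np.int32)
        if self.dosage.shape != (n_sites, n_samples):
            raise ValueError("dosage grid is not rectangular with the declared sites/samples")
        if self.depth.shape != (n_sites, n_samples):
            raise ValueError("depth grid shape mismatch")
        if self.allele_depths.shape != (n_sites, n_samples, 2):
            raise ValueError("allele_depths grid shape mismatch")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        site_ids = [s.site_id for s in self.sites]
        if len(set(site_ids)) != len(site_ids):
            raise ValueError("site ids must be unique")
        ploidies = np.array([s.ploidy for s in self.samples], dtype=np.int16)
        if n_sites and np.any(self.dosage > ploidies[None, :]):
            raise ValueError("a dosage exceeds its sample's ploidy")
        if np.any(self.allele_depths.sum(axis=2) != self.depth):
            raise ValueError("allele depths do not sum to total depth everywhere")

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def ploidies(self) -> np.ndarray:
        return np.array([s.ploidy for s in self.samples], dtype=np.int16)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def call(self, site_index: int, sample_index: int) -> GenotypeCall:
        d = int(self.dosage[site_index, sample_index])
        ad = tuple(int(x) for x in self.allele_depths[site_index, sample_index])
        return call_from_dosage(
            d, self.samples[sample_index].ploidy, int(self.depth[site_index, sample_index]), ad
        )

    # -- derived matrices ----------------------------------------------
    def dosage_fraction_matrix(self) -> np.ndarray:
        """Float matrix of alt dosage / ploidy with NaN for missing calls."""
        frac = self.dosage.astype(float) / self.ploidies.astype(float)[None, :]
        frac[self.dosage < 0] = np.nan
        return frac

    def class_matrix(self) -> np.ndarray:
        """Int codes: -1 missing, 0 HOM_REF, 1 HET, 2 HOM_ALT."""
        p = self.ploidies[None, :]
        codes = np.ones_like(self.dosage, dtype=np.int8)
        codes[self.dosage == 0] = 0
        codes[self.dosage == p] = 2
        codes[self.dosage < 0] = -1
        return codes

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, sample_ids: list[str]) -> "GenotypeTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeTable(
            sites=list(self.sites),
            samples=[self.samples[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
            depth=self.depth[:, idx].copy(),
            allele_depths=self.allele_depths[:, idx, :].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.samples == other.samples
            and np.array_equal(self.dosage, other.dosage)
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.allele_depths, other.allele_depths)
        )


# -- sample metadata CSV -----------------------------------------------


def read_sample_metadata(path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata file {path} lacks columns: {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            group_label=str(r.group_label),
            ploidy=int(r.ploidy),
            raw_read_count=int(r.raw_read_count),
            role=str(r.role),
        )
        for r in df.itertuples()
    ]


def write_sample_metadata(samples: list[SampleMeta], path) -> None:
    pd.DataFrame([vars(s) for s in samples], columns=METADATA_COLUMNS).to_csv(path, index=False)
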