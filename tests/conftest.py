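import numpy as np
import pytest
from hypothesis import settings

from offtype.model import GenotypeTable, SampleMeta, VariantSite

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_table(
    dosage,
    ploidies,
    depth=None,
    raw_reads=None,
    roles=None,
    labels=None,
    sample_ids=None,
):
    """Build a GenotypeTable from a dosage grid (-1 = missing).

    Depth defaults to 2x ploidy per call; allele depths split the depth
    proportionally to the dosage fraction (rounded), so the table satisfies
    the model invariants without the caller spelling out every read count.
    """
    dosage = np.asarray(dosage, dtype=np.int16)
    n_sites, n_samples = dosage.shape
    ploidies = list(ploidies)
    assert len(ploidies) == n_samples
    if sample_ids is None:
        sample_ids = [f"X{j+1}" for j in range(n_samples)]
    if labels is None:
        labels = [f"cv{j+1}" for j in range(n_samples)]
    if roles is None:
        roles = ["standard"] * n_samples
    if raw_reads is None:
        raw_reads = [2_000_000] * n_samples
    samples = [
        SampleMeta(sample_ids[j], labels[j], ploidies[j], raw_reads[j], roles[j])
        for j in range(n_samples)
    ]
    sites = [VariantSite(f"TP{i+1}", 16, "A", "G") for i in range(n_sites)]
    if depth is None:
        depth = np.tile(np.array([2 * p for p in ploidies], dtype=np.int32), (n_sites, 1))
    else:
        depth = np.asarray(depth, dtype=np.int32)
    depth = depth.copy().reshape(n_sites, n_samples)
    depth[dosage < 0] = 0
    ad = np.zeros((n_sites, n_samples, 2), dtype=np.int32)
    for i in range(n_sites):
        for j in range(n_samples):
            d, dp = int(dosage[i, j]), int(depth[i, j])
            if d < 0:
                continue
            alt = round(dp * d / ploidies[j])
            ad[i, j] = (dp - alt, alt)
    return GenotypeTable(
        sites=sites, samples=samples, dosage=dosage, depth=depth, allele_depths=ad
    )


def random_table(rng, n_sites=12, n_samples=6, missing_rate=0.1):
    """Random mixed-ploidy table with some missing calls."""
    ploidies = [int(rng.choice([2, 3, 4])) for _ in range(n_samples)]
    dosage = np.zeros((n_sites, n_samples), dtype=np.int16)
    for j, p in enumerate(ploidies):
        dosage[:, j] = rng.integers(0, p + 1, size=n_sites)
    miss = rng.random((n_sites, n_samples)) < missing_rate
    dosage[miss] = -1
    depth = rng.integers(1, 120, size=(n_sites, n_samples))
    return make_table(dosage, ploidies, depth=depth)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
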