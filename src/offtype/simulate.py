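"""Seeded generator of GBS genotype tables, morphology records and
flow-cytometry readings.

The generator emulates the data structure of a clonal-cultivar fingerprinting
study on hybrid bermudagrass putting greens:

* cultivar "families" of clonally propagated samples at ploidies 2x/3x/4x,
  with low within-family divergence of founder genotypes from a shared
  per-ploidy consensus;
* rare contaminant samples that are independent, highly divergent founders
  masquerading as family members;
* overdispersed (negative-binomial) GBS read depths, with per-ploidy mean
  depths of 9.5 (2x), 4.9 (3x) and 7.4 (4x) and per-sample raw read totals
  log-uniform between 1.3 and 13.9 million;
* a three-cluster morphology structure over internode length, stolon
  diameter, leaf length and leaf width;
* flow-cytometry FL2-A readings proportional to 2C genome size relative to a
  Sorghum bicolor internal standard (1.67 pg/2C).

Everything is reproducible from ``SimConfig.seed``: the same config yields
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    GenotypeTable,
    SampleMeta,
    VariantSite,
    VALID_PLOIDIES,
    write_sample_metadata,
)
from .vcfio import write_vcf

TRAITS = ["internode_mm", "stolon_diam_mm", "leaf_len_mm", "leaf_wid_mm"]

#: Default per-cluster (mean, SD) in mm for the four measured traits.  The
#: cluster means mirror the three morphological groups the pipeline is meant
#: to resolve: one long-internode group (34.6 mm), one short-leaf group
#: (9.9 mm leaves) and one long-leaf group (29.8 mm leaves); stolon diameter
#: (0.7-0.8 mm) and leaf width (2.0-2.2 mm) barely separate the groups.
DEFAULT_MORPH_CLUSTERS: dict[int, dict[str, tuple[float, float]]] = {
    1: {
        "internode_mm": (34.6, 4.0),
        "stolon_diam_mm": (0.8, 0.08),
        "leaf_len_mm": (14.9, 2.5),
        "leaf_wid_mm": (2.2, 0.2),
    },
    2: {
        "internode_mm": (21.9, 4.0),
        "stolon_diam_mm": (0.7, 0.08),
        "leaf_len_mm": (9.9, 2.5),
        "leaf_wid_mm": (2.0, 0.2),
    },
    3: {
        "internode_mm": (24.7, 4.0),
        "stolon_diam_mm": (0.75, 0.08),
        "leaf_len_mm": (29.8, 2.5),
        "leaf_wid_mm": (2.1, 0.2),
    },
}

#: Default simulated 2C genome sizes (pg) per ploidy.  The triploid value is
#: the published 'Tifgreen' nuclear DNA content; the diploid and tetraploid
#: values are synthetic stand-ins scaled linearly with ploidy from it.
DEFAULT_GENOME_SIZES: dict[int, float] = {2: 1.07, 3: 1.61, 4: 2.15}

#: Mean GBS read depth per sample per locus, by ploidy.
DEFAULT_DEPTH_MEANS: dict[int, float] = {2: 9.5, 3: 4.9, 4: 7.4}


@dataclass(frozen=True)
class CultivarSpec:
    """One block of clonal samples sharing a founder genotype.

    Two specs with the same ``label`` (e.g. standards plus putting-green
    samples attributed to the same cultivar) share one founder.
    ``n_contaminants`` of the members are silently replaced by independent,
    highly divergent founders — the unrelated-contaminant scenario.
    """

    label: str
    ploidy: int
    n_members: int
    role: str
    n_contaminants: int = 0
    member_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_contaminants > self.n_members:
            raise ValueError("n_contaminants cannot exceed n_members")
        if self.member_ids is not None and len(self.member_ids) != self.n_members:
            raise ValueError("member_ids length must equal n_members")


@dataclass
class SimConfig:
    seed: int = 0
    n_loci: int = 2000
    cultivars: list[CultivarSpec] = field(default_factory=list)
    within_family_divergence: float = 0.02
    contaminant_divergence: float = 0.5
    somatic_mutation_rate: float = 1e-3
    depth_mean: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_DEPTH_MEANS))
    depth_dispersion: float = 2.0
    sequencing_error: float = 0.005
    raw_read_count_range: tuple[float, float] = (1.3e6, 13.9e6)
    morph_cluster_params: dict[int, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MORPH_CLUSTERS.items()}
    )
    flow_cv: float = 0.02
    genome_sizes: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_GENOME_SIZES))
    flow_standard_fl2a: float = 200000.0
    flow_standard_pg: float = 1.67

    def validate(self) -> None:
        for name in (
            "within_family_divergence",
            "contaminant_divergence",
            "somatic_mutation_rate",
            "sequencing_error",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        for p, m in self.depth_mean.items():
            if m <= 0:
                raise ValueError(f"depth_mean for ploidy {p} must be > 0, got {m}")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")
        lo, hi = self.raw_read_count_range
        if not 0 < lo <= hi:
            raise ValueError("raw_read_count_range must satisfy 0 < low <= high")
        if self.flow_cv < 0:
            raise ValueError("flow_cv must be >= 0")
        for cid, params in self.morph_cluster_params.items():
            for trait, (mean, sd) in params.items():
                if mean <= 0 or sd < 0:
                    raise ValueError(f"bad morphology params for cluster {cid}, {trait}")
        for spec in self.cultivars:
            if spec.ploidy not in VALID_PLOIDIES:
                raise ValueError(f"unsupported ploidy {spec.ploidy} for {spec.label}")
            if spec.ploidy not in self.depth_mean:
                raise ValueError(f"no depth_mean configured for ploidy {spec.ploidy}")


def default_config(seed: int = 0, n_loci: int = 2000) -> SimConfig:
    """The shipped study-shaped roster.

    36 standard samples (six triploid cultivars, six clonal replicates each),
    twelve progenitor samples (two diploid and two tetraploid accessions,
    three replicates each) and 47 putting-green samples of unknown status
    attributed to three of the cultivars, five of which are contaminants.
    """
    specs: list[CultivarSpec] = []
    prefixes = {
        "Champion": "CH",
        "MiniVerde": "MV",
        "Tifdwarf": "TD",
        "TifEagle": "TE",
        "Tifgreen": "TG",
        "Tifway": "TW",
    }
    for label, pre in prefixes.items():
        specs.append(
            CultivarSpec(
                label, 3, 6, "standard", member_ids=tuple(f"{pre}{i}" for i in range(1, 7))
            )
        )
    for label, pre, ploidy in [
        ("C_dactylon_A", "TA", 4),
        ("C_dactylon_B", "TB", 4),
        ("C_transvaalensis_A", "DA", 2),
        ("C_transvaalensis_B", "DB", 2),
    ]:
        specs.append(
            CultivarSpec(
                label, ploidy, 3, "progenitor", member_ids=tuple(f"{pre}{i}" for i in range(1, 4))
            )
        )
    # 47 unknown putting-green samples S1..S47, 5 of them contaminants.
    unknown_blocks = [
        ("Champion", "desirable", 12, 1),
        ("MiniVerde", "desirable", 5, 1),
        ("TifEagle", "desirable", 3, 0),
        ("Champion", "off_type", 17, 2),
        ("MiniVerde", "off_type", 8, 1),
        ("TifEagle", "off_type", 2, 0),
    ]
    nxt = 1
    for label, role, n, n_cont in unknown_blocks:
        ids = tuple(f"S{j}" for j in range(nxt, nxt + n))
        nxt += n
        specs.append(CultivarSpec(label, 3, n, role, n_contaminants=n_cont, member_ids=ids))
    return SimConfig(seed=seed, n_loci=n_loci, cultivars=specs)


@dataclass
class GenotypeTruth:
    """Ground truth recorded alongside a simulated genotype table."""

    founder_dosage: dict[str, list[int]]  # per family label (and per contaminant id)
    sample_founder: dict[str, str]  # sample id -> founder key
    contaminants: list[str]  # sample ids that are independent founders
    consensus_dosage: dict[int, list[int]]  # per ploidy


def _nb_depths(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    # negative binomial with mean m and variance m + m^2/k (k = dispersion)
    k = dispersion
    return rng.negative_binomial(k, k / (k + mean), size=size)


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeTable, GenotypeTruth]:
    """Draw a genotype table plus its ground truth.

    Per family and locus the founder genotype equals the per-ploidy consensus
    except at loci flagged divergent (probability
    ``within_family_divergence``), where the dosage is redrawn uniformly over
    the ploidy+1 genotypes.  Contaminant founders use
    ``contaminant_divergence`` instead.  Each member sample is its founder
    plus somatic +-1 dosage steps; read depths are negative binomial and the
    stored allele depths are binomial draws around the true dosage fraction
    perturbed by ``sequencing_error``.  A call with zero reads is missing.
    """
    config.validate()
    if not config.cultivars:
        raise ValueError("config.cultivars is empty")
    rng = np.random.default_rng(config.seed)
    L = config.n_loci

    sites = [VariantSite(f"TP{i+1}", 16, "A", "G") for i in range(L)]

    # ancestral alternate-allele frequency shared across ploidies
    freq = rng.uniform(0.05, 0.95, size=L)
    ploidies_present = sorted({spec.ploidy for spec in config.cultivars})
    consensus = {p: rng.binomial(p, freq).astype(np.int16) for p in ploidies_present}

    def draw_founder(ploidy: int, divergence: float) -> np.ndarray:
        founder = consensus[ploidy].copy()
        div_mask = rng.random(L) < divergence
        founder[div_mask] = rng.integers(0, ploidy + 1, size=int(div_mask.sum()))
        return founder

    founders: dict[str, np.ndarray] = {}
    samples: list[SampleMeta] = []
    sample_founder: dict[str, str] = {}
    contaminants: list[str] = []
    dosage_cols: list[np.ndarray] = []

    lo, hi = config.raw_read_count_range
    for spec in config.cultivars:
        key = f"{spec.label}|{spec.ploidy}"
        if key not in founders:
            founders[key] = draw_founder(spec.ploidy, config.within_family_divergence)
        # contaminants are the last n_contaminants members of the block
        for m in range(spec.n_members):
            sid = (
                spec.member_ids[m]
                if spec.member_ids is not None
                else f"{spec.label}-{spec.role}-{m+1}"
            )
            is_contaminant = m >= spec.n_members - spec.n_contaminants
            if is_contaminant:
                fkey = f"contaminant|{sid}"
                founders[fkey] = draw_founder(spec.ploidy, config.contaminant_divergence)
                contaminants.append(sid)
            else:
                fkey = key
            base = founders[fkey].copy()
            mut = rng.random(L) < config.somatic_mutation_rate
            if mut.any():
                idx = np.flatnonzero(mut)
                step = np.where(rng.random(idx.size) < 0.5, -1, 1)
                new = base[idx] + step
                # a step off the valid dosage range flips direction instead
                new = np.where(new < 0, 1, new)
                new = np.where(new > spec.ploidy, spec.ploidy - 1, new)
                base[idx] = new
            raw_reads = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            samples.append(SampleMeta(sid, spec.label, spec.ploidy, raw_reads, spec.role))
            sample_founder[sid] = fkey
            dosage_cols.append(base)

    true_dosage = np.stack(dosage_cols, axis=1)  # (L, N)
    N = true_dosage.shape[1]
    ploidy_vec = np.array([s.ploidy for s in samples], dtype=np.int16)

    depth = np.empty((L, N), dtype=np.int64)
    for j, s in enumerate(samples):
        depth[:, j] = _nb_depths(rng, config.depth_mean[s.ploidy], config.depth_dispersion, L)

    true_frac = true_dosage / ploidy_vec[None, :]
    e = config.sequencing_error
    if e == 0.0:
        # error-free reads report the true allele composition exactly:
        # deterministic proportional split instead of binomial sampling
        alt_reads = np.floor(depth * true_frac + 0.5).astype(np.int64)
    else:
        p_alt_read = true_frac * (1 - e) + (1 - true_frac) * e
        alt_reads = rng.binomial(depth, p_alt_read)
    ref_reads = depth - alt_reads
    allele_depths = np.stack([ref_reads, alt_reads], axis=2)

    dosage = true_dosage.astype(np.int16).copy()
    dosage[depth == 0] = -1

    table = GenotypeTable(
        sites=sites,
        samples=samples,
        dosage=dosage,
        depth=depth,
        allele_depths=allele_depths,
    )
    truth = GenotypeTruth(
        founder_dosage={k: v.astype(int).tolist() for k, v in founders.items()},
        sample_founder=sample_founder,
        contaminants=contaminants,
        consensus_dosage={p: c.astype(int).tolist() for p, c in consensus.items()},
    )
    return table, truth


# -- morphology ---------------------------------------------------------

DATES = ["2014-06-03", "2014-06-25"]
N_POTS = 4
N_STOLONS = 3


def default_cluster_assignment(sample_ids: list[str], seed: int) -> dict[str, int]:
    """Assign samples to the three morphology clusters in proportions 14:26:12."""
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    weights = np.array([14, 26, 12], dtype=float)
    sizes = np.floor(weights / weights.sum() * n).astype(int)
    while sizes.sum() < n:
        sizes[int(np.argmax(weights / weights.sum() * n - sizes))] += 1
    labels = np.repeat([1, 2, 3], sizes)
    rng.shuffle(labels)
    return {sid: int(c) for sid, c in zip(sample_ids, labels)}


def simulate_morphology(config: SimConfig, assignments: dict[str, int]) -> pd.DataFrame:
    """24 replicate records per sample: 4 pots x 3 stolons x 2 dates.

    Each trait is drawn from a normal truncated at zero with the cluster's
    mean and SD.
    """
    config.validate()
    unknown = {c for c in assignments.values() if c not in config.morph_cluster_params}
    if unknown:
        raise ValueError(f"unknown morphology cluster id(s): {sorted(unknown)}")
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    n_rec = len(DATES) * N_POTS * N_STOLONS
    for sid, cluster in assignments.items():
        params = config.morph_cluster_params[cluster]
        draws = {}
        for trait in TRAITS:
            mean, sd = params[trait]
            if sd == 0:
                draws[trait] = np.full(n_rec, mean)
            else:
                a = (0.0 - mean) / sd  # truncate at zero
                draws[trait] = stats.truncnorm.rvs(
                    a, np.inf, loc=mean, scale=sd, size=n_rec, random_state=rng
                )
        r = 0
        for date in DATES:
            for pot in range(1, N_POTS + 1):
                for stolon in range(1, N_STOLONS + 1):
                    rows.append(
                        {
                            "sample_id": sid,
                            "date": date,
                            "pot": pot,
                            "stolon": stolon,
                            **{t: float(draws[t][r]) for t in TRAITS},
                        }
                    )
                    r += 1
    return pd.DataFrame(rows)


# -- flow cytometry -----------------------------------------------------


def simulate_flow(config: SimConfig, samples: list[SampleMeta]) -> pd.DataFrame:
    """Mean FL2-A per sample against a fixed internal standard.

    Sample FL2-A = standard FL2-A x (2C size / standard 2C size) x a
    multiplicative normal error with CV ``flow_cv``, truncated at zero.
    """
    config.validate()
    missing = sorted({s.ploidy for s in samples} - set(config.genome_sizes))
    if missing:
        raise ValueError(f"no genome size configured for ploidy level(s): {missing}")
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    for s in samples:
        gs = config.genome_sizes[s.ploidy]
        noise = 1.0 + rng.normal(0.0, config.flow_cv) if config.flow_cv > 0 else 1.0
        fl2a = max(config.flow_standard_fl2a * (gs / config.flow_standard_pg) * noise, 0.0)
        rows.append(
            {
                "sample_id": s.sample_id,
                "fl2a_sample": fl2a,
                "fl2a_standard": config.flow_standard_fl2a,
            }
        )
    return pd.DataFrame(rows)


# -- bundled output ------------------------------------------------------


def write_simulation(config: SimConfig, outdir) -> dict[str, str]:
    """Run all three generators and write the on-disk dataset.

    Writes ``genotypes.vcf``, ``metadata.csv``, ``morphology.csv``,
    ``flow.csv`` and a ``truth.json`` sidecar (founder genotypes, true
    morphology clusters, contaminant flags) under ``outdir``; returns the
    path map.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_genotypes(config)
    unknown_ids = [s.sample_id for s in table.samples if s.role in ("desirable", "off_type")]
    # the study's morphology panel is ~52 samples; pad the unknowns with
    # standards until the panel reaches 52 (or use all samples if fewer)
    panel = list(unknown_ids)
    for s in table.samples:
        if len(panel) >= 52:
            break
        if s.sample_id not in panel and s.role == "standard":
            panel.append(s.sample_id)
    assignments = default_cluster_assignment(panel, config.seed + 3)
    morph = simulate_morphology(config, assignments)
    flow = simulate_flow(config, table.samples)

    paths = {
        "vcf": str(outdir / "genotypes.vcf"),
        "metadata": str(outdir / "metadata.csv"),
        "morphology": str(outdir / "morphology.csv"),
        "flow": str(outdir / "flow.csv"),
        "truth": str(outdir / "truth.json"),
    }
    write_vcf(table, paths["vcf"])
    write_sample_metadata(table.samples, paths["metadata"])
    morph.to_csv(paths["morphology"], index=False, float_format="%.6f")
    flow.to_csv(paths["flow"], index=False, float_format="%.6f")
    truth_doc = {
        "founder_dosage": truth.founder_dosage,
        "sample_founder": truth.sample_founder,
        "contaminants": truth.contaminants,
        "consensus_dosage": {str(k): v for k, v in truth.consensus_dosage.items()},
        "morphology_clusters": assignments,
        "config": _config_doc(config),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
    return paths


def _config_doc(config: SimConfig) -> dict:
    doc = asdict(config)
    doc["cultivars"] = [asdict(c) for c in config.cultivars]
    return doc
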