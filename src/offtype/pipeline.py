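"""End-to-end orchestration: exclusion -> pooling -> differentiating loci ->
ploidy Venn partition -> distance/MDS/divergence screen -> genome size ->
morphology clustering.

Every stage writes its tabular outputs under the run's output directory and
the run finishes with a machine-readable manifest (parameter values, seed,
input checksums) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distance import DEFAULT_Z_THRESHOLD, classical_mds, divergence_screen, ibs_distance
from .genome_size import DEFAULT_MAX_REL_DEV, PloidyReference, genome_size_table
from .informative import DepthWindow, flagged_site_table, pairwise_matrix, differing_loci
from .model import read_sample_metadata
from .morphology import aggregate_replicates, kmeans_cluster, summarize_clusters
from .pooling import (
    DEFAULT_MIN_READS,
    depth_summary,
    exclude_low_read_samples,
    pool_cultivars,
    pooled_table,
)
from .vcfio import read_vcf, write_vcf
from .venn import group_variant_set, venn

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    vcf: str = ""
    metadata: str = ""
    morphology: str = ""
    flow: str = ""
    outdir: str = "offtype_run"
    ploidy_reference: str = ""  # optional CSV label,ploidy,pg_2c
    min_reads: int = DEFAULT_MIN_READS
    min_depth: int = 40
    max_depth: int = 100
    inclusive_high: bool = False
    no_window: bool = False
    z_threshold: float = DEFAULT_Z_THRESHOLD
    max_rel_dev: float = DEFAULT_MAX_REL_DEV
    k: int = 3
    seed: int = 0
    standardize: bool = False
    restarts: int = 10
    mds_dims: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def require_inputs(self) -> None:
        for name in ("vcf", "metadata", "morphology", "flow"):
            value = getattr(self, name)
            if not value:
                raise ValueError(f"config field {name!r} is required but empty")
            if not Path(value).exists():
                raise FileNotFoundError(f"config field {name!r}: no such file {value}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts; returns the manifest."""
    config.require_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    metadata = read_sample_metadata(config.metadata)
    table = read_vcf(config.vcf, metadata)

    # stage 1: exclusion
    retained = exclude_low_read_samples(table, config.min_reads)

    # stage 2: pooling of triploid standard cultivars
    standard_labels = sorted(
        {s.group_label for s in retained.samples if s.role == "standard" and s.ploidy == 3}
    )
    results: dict = {"n_samples_input": table.n_samples, "n_samples_retained": retained.n_samples}
    pools = []
    if len(standard_labels) >= 2:
        standards = retained.subset_samples(
            [s.sample_id for s in retained.samples if s.role == "standard" and s.ploidy == 3]
        )
        pools = pool_cultivars(standards, standard_labels)
        write_vcf(pooled_table(pools), outdir / "pooled.vcf")
        depth_summary(pools).to_csv(
            outdir / "pooled_depth_summary.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
        )

        # stage 3: differentiating loci
        window = None if config.no_window else DepthWindow(
            config.min_depth, config.max_depth, config.inclusive_high
        )
        matrix = pairwise_matrix(pools, window)
        matrix.to_frame().to_csv(outdir / "pairwise_diff_matrix.tsv", sep="\t")
        flagged_site_table(pools, window).to_csv(
            outdir / "flagged_sites.tsv", sep="\t", index=False
        )
        results["n_differing_loci_windowed"] = len(differing_loci(pools, window))
        results["n_differing_loci_unwindowed"] = len(differing_loci(pools, None))
        results["pairwise_matrix"] = {
            "labels": matrix.labels,
            "counts": matrix.counts.tolist(),
        }

    # stage 4: ploidy Venn partition (presence over all retained samples)
    groups = {
        "diploid": [s.sample_id for s in retained.samples if s.ploidy == 2],
        "triploid": [s.sample_id for s in retained.samples if s.ploidy == 3],
        "tetraploid": [s.sample_id for s in retained.samples if s.ploidy == 4],
    }
    present = {g: ids for g, ids in groups.items() if ids}
    if len(present) == 3:
        sets = {g: group_variant_set(retained, ids) for g, ids in present.items()}
        part = venn(
            sets["diploid"], sets["triploid"], sets["tetraploid"],
            labels=("diploid", "triploid", "tetraploid"),
        )
        part.to_frame().to_csv(outdir / "venn_partition.tsv", sep="\t", index=False)
        (outdir / "venn_partition.json").write_text(part.to_json() + "\n")
        results["venn_totals"] = part.totals
        results["venn_shared_all"] = part.shared_all()

    # stage 5: distance, MDS, divergence screen
    dmat = ibs_distance(retained, allow_missing_pairs=False)
    dmat.to_frame().to_csv(outdir / "distances.tsv", sep="\t", float_format=FLOAT_FORMAT)
    mds = classical_mds(dmat, k=config.mds_dims)
    mds.to_frame().to_csv(
        outdir / "mds_coordinates.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    # the divergence question is posed for the putting-green samples against
    # the standard cultivars; progenitor accessions separate by ploidy by
    # construction and are left out of the screened subset
    screen_ids = [
        s.sample_id
        for s in retained.samples
        if s.role in ("standard", "desirable", "off_type")
    ]
    reference_ids = [s.sample_id for s in retained.samples if s.role == "standard"]
    if len(reference_ids) >= 3 and len(screen_ids) > len(reference_ids):
        sub = retained.subset_samples(screen_ids)
        report = divergence_screen(ibs_distance(sub), reference_ids, config.z_threshold)
        report.table.to_csv(
            outdir / "divergence_report.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
        )
        unknown_roles = {"desirable", "off_type"}
        unknown_ids = {s.sample_id for s in retained.samples if s.role in unknown_roles}
        flagged = report.flagged_ids()
        flagged_unknown = sorted(unknown_ids & set(flagged))
        results["n_divergent_flagged"] = len(flagged)
        results["divergent_ids"] = flagged
        results["n_unknown_samples"] = len(unknown_ids)
        results["n_unknown_divergent"] = len(flagged_unknown)
        results["divergent_unknown_ids"] = flagged_unknown

    # stage 6: genome size
    flow = pd.read_csv(config.flow)
    ref = (
        PloidyReference.from_csv(config.ploidy_reference)
        if config.ploidy_reference
        else PloidyReference()
    )
    gs = genome_size_table(flow, ref, max_rel_dev=config.max_rel_dev)
    gs.to_csv(outdir / "genome_sizes.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    results["mean_pg_2c"] = float(gs["pg_2c"].mean())

    # stage 7: morphology clustering
    records = pd.read_csv(config.morphology)
    agg = aggregate_replicates(records)
    cluster = kmeans_cluster(
        agg, k=config.k, seed=config.seed, standardize=config.standardize,
        restarts=config.restarts,
    )
    cluster.assignments.rename("cluster").reset_index().to_csv(
        outdir / "cluster_assignments.tsv", sep="\t", index=False
    )
    stats, flags = summarize_clusters(agg, cluster.assignments)
    stats.to_csv(outdir / "cluster_summary.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    flags.to_csv(outdir / "cluster_differences.tsv", sep="\t", index=False)
    diagnostics = {
        "r_squared": cluster.r_squared,
        "ccc": cluster.ccc,
        "ssw": cluster.ssw,
        "sst": cluster.sst,
        "ssw_per_cluster": {str(c): v for c, v in cluster.ssw_per_cluster.items()},
        "cluster_sizes": {str(k): v for k, v in cluster.cluster_sizes().items()},
        "standardized": cluster.standardized,
    }
    (outdir / "cluster_diagnostics.json").write_text(
        json.dumps(diagnostics, indent=1, sort_keys=True) + "\n"
    )
    results["cluster_r_squared"] = cluster.r_squared
    results["cluster_ccc"] = cluster.ccc
    results["cluster_sizes"] = diagnostics["cluster_sizes"]

    manifest = {
        "package": "offtype",
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "input_checksums": {
            name: _sha256(getattr(config, name))
            for name in ("vcf", "metadata", "morphology", "flow")
        },
        "results": results,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
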