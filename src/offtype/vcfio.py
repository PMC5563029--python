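"""Reading and writing genotype tables as VCF 4.2.

Only the fields the pipeline consumes are modeled: per-sample GT (with the
ploidy of the sample, e.g. ``0/0/1`` for a triploid), DP and AD.  Reading goes
through :mod:`pysam`; writing emits deterministic plain text so that repeated
writes of the same table are byte-identical.

Multi-allelic records are outside the biallelic core model and are skipped on
read; the number skipped is logged and recorded on the returned table.
Records whose DP disagrees with the AD sum are repaired to ``DP = sum(AD)``
(logged), since every downstream computation treats the allele depths as the
evidence.
"""

from __future__ import annotations

import logging

import numpy as np
import pysam

from .model import GenotypeTable, SampleMeta, VariantSite

logger = logging.getLogger(__name__)

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele Depths (ref,alt)">',
]


def read_vcf(path, metadata: list[SampleMeta]) -> GenotypeTable:
    """Read a multi-sample VCF into a :class:`GenotypeTable`.

    Parameters
    ----------
    path
        VCF 4.2 file with GT, DP and AD FORMAT fields.
    metadata
        One :class:`SampleMeta` per VCF sample.  A VCF sample without a
        metadata entry is a hard error, as is a GT whose ploidy disagrees
        with the metadata.
    """
    meta_by_id = {m.sample_id: m for m in metadata}
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    unknown = [s for s in vcf_samples if s not in meta_by_id]
    if unknown:
        raise ValueError(f"no metadata for VCF sample(s): {', '.join(unknown)}")
    samples = [meta_by_id[s] for s in vcf_samples]

    sites: list[VariantSite] = []
    dosage_rows, depth_rows, ad_rows = [], [], []
    skipped = 0
    repaired_dp = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            skipped += 1
            continue
        site = VariantSite(
            site_id=rec.chrom, position=rec.pos - 1, ref_allele=rec.ref, alt_allele=alts[0]
        )
        drow, dprow, adrow = [], [], []
        for meta, name in zip(samples, vcf_samples):
            fmt = rec.samples[name]
            gt = fmt.get("GT")
            ad = fmt.get("AD")
            if ad is None or all(a is None for a in ad):
                ad_ref, ad_alt = 0, 0
            else:
                ad_ref = int(ad[0] or 0)
                ad_alt = int(ad[1] or 0) if len(ad) > 1 else 0
            dp = ad_ref + ad_alt
            declared_dp = fmt.get("DP")
            if declared_dp is not None and int(declared_dp) != dp:
                repaired_dp += 1
            if gt is None or all(a is None for a in gt):
                drow.append(-1)
            else:
                if len(gt) != meta.ploidy:
                    raise ValueError(
                        f"GT ploidy {len(gt)} at site {site.site_id} disagrees with "
                        f"metadata ploidy {meta.ploidy} for sample {name}"
                    )
                if any(a not in (0, 1) for a in gt):
                    raise ValueError(
                        f"non-biallelic allele index in GT at {site.site_id}, sample {name}"
                    )
                drow.append(sum(gt))
            dprow.append(dp)
            adrow.append((ad_ref, ad_alt))
        sites.append(site)
        dosage_rows.append(drow)
        depth_rows.append(dprow)
        ad_rows.append(adrow)
    vf.close()

    if skipped:
        logger.info("read_vcf: skipped %d multi-allelic record(s) in %s", skipped, path)
    if repaired_dp:
        logger.info("read_vcf: reset DP to sum(AD) for %d call(s) in %s", repaired_dp, path)

    n = len(sites)
    table = GenotypeTable(
        sites=sites,
        samples=samples,
        dosage=np.array(dosage_rows, dtype=np.int16).reshape(n, len(samples)),
        depth=np.array(depth_rows, dtype=np.int32).reshape(n, len(samples)),
        allele_depths=np.array(ad_rows, dtype=np.int32).reshape(n, len(samples), 2),
        skipped_multiallelic=skipped,
    )
    return table


def write_vcf(table: GenotypeTable, path) -> None:
    """Serialize a table as VCF 4.2 (GT/DP/AD), 1-based positions.

    Missing calls are written as ``./.``-style GTs with one ``.`` per ploidy
    copy.  Output is deterministic: two writes of the same table are
    byte-identical.
    """
    lines = list(_HEADER_LINES)
    for site in table.sites:
        lines.append(f"##contig=<ID={site.site_id}>")
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    cols += table.sample_ids
    lines.append("\t".join(cols))
    ploidies = table.ploidies
    for i, site in enumerate(table.sites):
        fields = [
            site.site_id,
            str(site.position + 1),
            ".",
            site.ref_allele,
            site.alt_allele,
            ".",
            ".",
            ".",
            "GT:DP:AD",
        ]
        for j in range(table.n_samples):
            d = int(table.dosage[i, j])
            p = int(ploidies[j])
            if d < 0:
                gt = "/".join(["."] * p)
            else:
                gt = "/".join(["0"] * (p - d) + ["1"] * d)
            dp = int(table.depth[i, j])
            ad = table.allele_depths[i, j]
            fields.append(f"{gt}:{dp}:{int(ad[0])},{int(ad[1])}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
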