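"""Three-way partition of variant sets across ploidy groups.

"Variant present in a group" means at least one member sample carries at
least one alternate allele at the site with a non-missing call of sufficient
depth.  The three group sets are then split into the seven disjoint regions
of a three-set Venn diagram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .model import GenotypeTable

#: membership patterns as (in_a, in_b, in_c) bit tuples, fixed order
REGIONS = [
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, 0, 1),
    (0, 1, 1),
    (1, 1, 1),
]


def group_variant_set(
    table: GenotypeTable, group: list[str], min_depth: int = 1
) -> set[str]:
    """Sites where >= 1 group member has a non-missing, sufficiently covered
    call carrying >= 1 alternate allele."""
    if not group:
        raise ValueError("group is empty")
    idx = [table.sample_index(s) for s in group]
    d = table.dosage[:, idx]
    dp = table.depth[:, idx]
    present = ((d >= 1) & (dp >= min_depth)).any(axis=1)
    ids = table.site_ids
    return {ids[i] for i, hit in enumerate(present) if hit}


@dataclass
class VennPartition:
    """Counts for the 7 disjoint membership regions of three labelled sets."""

    labels: tuple[str, str, str]
    region_counts: dict[tuple[int, int, int], int]
    totals: dict[str, int]

    def count(self, pattern: tuple[int, int, int]) -> int:
        return self.region_counts[pattern]

    def shared_all(self) -> int:
        return self.region_counts[(1, 1, 1)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": "&".join(
                    lbl for lbl, bit in zip(self.labels, pat) if bit
                ),
                **{f"in_{lbl}": bit for lbl, bit in zip(self.labels, pat)},
                "count": self.region_counts[pat],
            }
            for pat in REGIONS
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        doc = {
            "labels": list(self.labels),
            "regions": {
                "&".join(l for l, b in zip(self.labels, pat) if b): self.region_counts[pat]
                for pat in REGIONS
            },
            "totals": self.totals,
        }
        return json.dumps(doc, indent=1, sort_keys=True)


def venn(
    set_a: set[str],
    set_b: set[str],
    set_c: set[str],
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> VennPartition:
    """Split three site-id sets into the 7 disjoint Venn regions."""
    if len(set(labels)) != 3:
        raise ValueError("labels must be three distinct names")
    counts = {
        (1, 0, 0): len(set_a - set_b - set_c),
        (0, 1, 0): len(set_b - set_a - set_c),
        (0, 0, 1): len(set_c - set_a - set_b),
        (1, 1, 0): len((set_a & set_b) - set_c),
        (1, 0, 1): len((set_a & set_c) - set_b),
        (0, 1, 1): len((set_b & set_c) - set_a),
        (1, 1, 1): len(set_a & set_b & set_c),
    }
    totals = {labels[0]: len(set_a), labels[1]: len(set_b), labels[2]: len(set_c)}
    return VennPartition(tuple(labels), counts, totals)
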