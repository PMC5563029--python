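"""Flow-cytometry genome-size estimation and nearest-reference ploidy
classification.

The 2C genome size of an unknown sample is the ratio of its mean FL2-A peak
to that of a co-chopped internal standard, scaled by the standard's known 2C
value (Sorghum bicolor cv. BTx623, 1.67 pg/2C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

SORGHUM_2C_PG = 1.67
DEFAULT_MAX_REL_DEV = 0.15


@dataclass(frozen=True)
class FlowMeasure:
    sample_id: str
    fl2a_sample: float
    fl2a_standard: float
    standard_pg: float = SORGHUM_2C_PG

    def __post_init__(self) -> None:
        if self.fl2a_sample <= 0 or self.fl2a_standard <= 0 or self.standard_pg <= 0:
            raise ValueError(
                f"flow measurements for {self.sample_id!r} must be strictly positive"
            )


@dataclass(frozen=True)
class PloidyRef:
    label: str
    ploidy: int
    pg_2c: float

    def __post_init__(self) -> None:
        if self.pg_2c <= 0:
            raise ValueError("reference pg/2C must be > 0")


@dataclass
class PloidyReference:
    """Known (cultivar, ploidy, 2C size) anchors for classification.

    The shipped default carries only the two published triploid anchors
    ('Tifway' 1.37 pg/2C and 'Tifgreen' 1.61 pg/2C); diploid and tetraploid
    anchors must be supplied by the user.
    """

    entries: list[PloidyRef] = field(
        default_factory=lambda: [
            PloidyRef("Tifway", 3, 1.37),
            PloidyRef("Tifgreen", 3, 1.61),
        ]
    )

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("reference labels must be unique")

    @classmethod
    def from_csv(cls, path) -> "PloidyReference":
        df = pd.read_csv(path)
        return cls(
            [PloidyRef(str(r.label), int(r.ploidy), float(r.pg_2c)) for r in df.itertuples()]
        )


def estimate_genome_size(m: FlowMeasure) -> float:
    """2C genome size in pg: (sample FL2-A / standard FL2-A) x standard pg."""
    return (m.fl2a_sample / m.fl2a_standard) * m.standard_pg


def classify_ploidy(
    pg: float,
    ref: PloidyReference,
    max_rel_dev: float = DEFAULT_MAX_REL_DEV,
) -> tuple[str, int] | None:
    """Nearest reference anchor by relative deviation |pg - anchor| / anchor.

    Returns ``None`` (unclassified) when the closest anchor deviates by more
    than ``max_rel_dev``.  Ties break toward the lower ploidy (logged).
    """
    if not ref.entries:
        raise ValueError("reference table is empty")
    if pg <= 0:
        raise ValueError("pg must be > 0")
    devs = [(abs(pg - e.pg_2c) / e.pg_2c, e) for e in ref.entries]
    best = min(d for d, _ in devs)
    if best > max_rel_dev:
        return None
    candidates = [e for d, e in devs if d == best]
    if len(candidates) > 1:
        candidates.sort(key=lambda e: (e.ploidy, e.label))
        logger.info(
            "classification tie at pg=%.4g broken toward lower ploidy (%s)",
            pg,
            candidates[0].label,
        )
    chosen = candidates[0]
    return chosen.label, chosen.ploidy


def genome_size_table(
    flow: pd.DataFrame,
    ref: PloidyReference | None = None,
    standard_pg: float = SORGHUM_2C_PG,
    max_rel_dev: float = DEFAULT_MAX_REL_DEV,
) -> pd.DataFrame:
    """Estimate and classify every sample in a flow table.

    ``flow`` needs columns ``sample_id, fl2a_sample, fl2a_standard``; the
    result adds ``pg_2c, label, ploidy, deviation`` (label/ploidy empty when
    unclassified).
    """
    ref = ref if ref is not None else PloidyReference()
    rows = []
    for r in flow.itertuples():
        m = FlowMeasure(str(r.sample_id), float(r.fl2a_sample), float(r.fl2a_standard), standard_pg)
        pg = estimate_genome_size(m)
        hit = classify_ploidy(pg, ref, max_rel_dev)
        if hit is None:
            label, ploidy, dev = "", pd.NA, pd.NA
        else:
            label, ploidy = hit
            anchor = next(e for e in ref.entries if e.label == label)
            dev = abs(pg - anchor.pg_2c) / anchor.pg_2c
        rows.append(
            {
                "sample_id": m.sample_id,
                "pg_2c": pg,
                "label": label,
                "ploidy": ploidy,
                "deviation": dev,
            }
        )
    return pd.DataFrame(rows)
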