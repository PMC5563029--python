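"""Dosage-fraction IBS distances, classical MDS and divergent-sample
screening.

The distance generalizes identity-by-state allele sharing to mixed ploidy:
each non-missing call maps to its alternate-allele dosage fraction in
[0, 1], and the distance between two samples is the mean absolute difference
of those fractions over co-called sites.  For diploids this reduces to the
usual 1 - IBS-share metric up to scale; across ploidies it compares the
ploidy-normalized genotype coordinate.

Classical (Torgerson) MDS double-centers the squared distance matrix and
embeds on the leading positive eigenpairs, which reproduces Euclidean
configurations exactly.  The divergence screen replaces the visual
MDS-outlier call with a reproducible robust z-score against the reference
standards' own distance baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenotypeTable

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # normal-consistency constant for the median absolute deviation
DEFAULT_Z_THRESHOLD = 3.5


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance grid must be square on the ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0) or np.any(self.values[finite] > 1):
            raise ValueError("distances must lie in [0, 1]")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("self-distances must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def ibs_distance(
    table: GenotypeTable, min_shared_sites: int = 1, allow_missing_pairs: bool = False
) -> DistanceMatrix:
    """Mean absolute dosage-fraction difference over co-called sites.

    A pair with fewer than ``min_shared_sites`` co-called sites is a hard
    error naming the pair, or a NaN entry under ``allow_missing_pairs``.
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    frac = table.dosage_fraction_matrix()  # (S, N), NaN = missing
    n = table.n_samples
    d = np.zeros((n, n))
    called = ~np.isnan(frac)
    for i in range(n):
        fi = frac[:, i]
        for j in range(i + 1, n):
            shared = called[:, i] & called[:, j]
            n_shared = int(shared.sum())
            if n_shared < min_shared_sites:
                if not allow_missing_pairs:
                    raise ValueError(
                        f"samples {table.sample_ids[i]!r} and {table.sample_ids[j]!r} share "
                        f"only {n_shared} co-called site(s) (< {min_shared_sites})"
                    )
                d[i, j] = d[j, i] = np.nan
                continue
            d[i, j] = d[j, i] = float(np.mean(np.abs(fi[shared] - frac[shared, j])))
    return DistanceMatrix(list(table.sample_ids), d)


@dataclass
class MdsResult:
    ids: list[str]
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,), non-increasing, positive

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i+1}" for i in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, columns=cols)
        df.insert(0, "sample_id", self.ids)
        return df


def classical_mds(d: DistanceMatrix, k: int = 2) -> MdsResult:
    """Torgerson MDS: embed on the top-k positive eigenpairs of the
    double-centered squared-distance matrix.

    If fewer than ``k`` eigenvalues are positive the dimensionality is
    reduced with a warning.  Per-axis sign is fixed so the largest-magnitude
    coordinate is positive, making the output deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = d.values
    if np.isnan(D).any():
        raise ValueError("distance matrix contains masked (NaN) entries")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigval[0]), 1.0)
    n_pos = int(np.sum(eigval > tol))
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); returning {n_pos}-dimensional coordinates",
            stacklevel=2,
        )
    k_eff = max(min(k, n_pos), 0)
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])[None, :]
    for axis in range(k_eff):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return MdsResult(list(d.ids), coords, eigval[:k_eff].copy())


@dataclass
class DivergenceReport:
    """Per-sample mean distance to the reference standards, robust z and flag."""

    table: pd.DataFrame  # columns sample_id, score, z, flagged
    threshold: float
    reference_ids: list[str]

    def flagged_ids(self) -> list[str]:
        return list(self.table.loc[self.table.flagged, "sample_id"])


def divergence_screen(
    d: DistanceMatrix,
    reference_ids: list[str],
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> DivergenceReport:
    """Flag samples genetically divergent from the reference standards.

    Each sample's score is its mean distance to the reference samples
    (excluding itself when it is a reference).  The baseline is the
    references' own scores; z = (score - median) / (1.4826 * MAD).  With a
    degenerate baseline (MAD = 0) any score above the median is flagged with
    a warning, and scores at or below the median get z = 0.
    """
    ref_idx = [d.ids.index(r) for r in reference_ids]
    if len(ref_idx) < 3:
        raise ValueError("need at least three reference samples")
    V = d.values
    if np.isnan(V).any():
        raise ValueError("distance matrix contains masked (NaN) entries")
    n = len(d.ids)
    ref_mask = np.zeros(n, dtype=bool)
    ref_mask[ref_idx] = True
    scores = np.empty(n)
    for i in range(n):
        others = ref_mask.copy()
        others[i] = False  # self excluded for reference samples
        scores[i] = V[i, others].mean()
    baseline = scores[ref_mask]
    med = float(np.median(baseline))
    mad = float(np.median(np.abs(baseline - med)))
    if mad == 0.0:
        z = np.where(scores > med, np.inf, 0.0)
        if np.any(scores > med):
            warnings.warn(
                "degenerate reference baseline (MAD = 0): flagging every sample "
                "above the median score",
                stacklevel=2,
            )
        flagged = scores > med
    else:
        z = (scores - med) / (MAD_SCALE * mad)
        flagged = z > threshold
    report = pd.DataFrame(
        {"sample_id": d.ids, "score": scores, "z": z, "flagged": flagged}
    )
    return DivergenceReport(report, threshold, list(reference_ids))
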