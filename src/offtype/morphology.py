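"""Morphology aggregation, K-means clustering and the cubic clustering
criterion (CCC).

Replicate measurements (four pots x three stolons x two dates per sample)
are averaged per sample before clustering; the leaf length:width ratio (LWR)
is derived from the aggregated leaf means rather than averaged per record,
which is stable under measurement noise.

K-means (k-means++ initialization, Lloyd iterations, multiple restarts) is
delegated to scikit-learn.  The clustering fit is summarized by
R^2 = 1 - SSW/SST and by the CCC, which compares the observed R^2 to its
approximate expectation under a uniform-hypercube null (Sarle's SAS
approximation): strongly negative values indicate a partition that captures
less variance than random uniform data would, large positive values support
the clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .simulate import TRAITS

logger = logging.getLogger(__name__)

CLUSTER_TRAITS = TRAITS + ["lwr"]


def aggregate_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-sample trait means over all pots, stolons and dates, plus LWR.

    ``records`` must carry ``sample_id`` and the four measured traits with
    strictly positive values.  Returns one row per sample, indexed by
    ``sample_id`` order of first appearance.
    """
    missing = {"sample_id", *TRAITS} - set(records.columns)
    if missing:
        raise ValueError(f"morphology records lack columns: {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("no morphology records")
    if (records[TRAITS] <= 0).any().any():
        raise ValueError("all trait measurements must be > 0")
    agg = (
        records.groupby("sample_id", sort=False)[TRAITS].mean().reset_index()
    )
    agg["lwr"] = agg["leaf_len_mm"] / agg["leaf_wid_mm"]
    return agg


@dataclass
class ClusterResult:
    assignments: pd.Series  # index sample_id -> cluster id (1-based)
    centers: np.ndarray  # (k, n_traits) on the clustering scale
    r_squared: float
    ccc: float
    ssw: float
    sst: float
    ssw_per_cluster: dict[int, float]
    standardized: bool
    traits: list[str]

    def cluster_sizes(self) -> dict[int, int]:
        counts = self.assignments.value_counts().sort_index()
        return {int(c): int(n) for c, n in counts.items()}


def _ssw_sst(X: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    grand = X.mean(axis=0)
    sst = float(((X - grand) ** 2).sum())
    ssw = 0.0
    for c in np.unique(labels):
        Xc = X[labels == c]
        ssw += float(((Xc - Xc.mean(axis=0)) ** 2).sum())
    return ssw, sst


def kmeans_cluster(
    samples: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    standardize: bool = False,
    restarts: int = 10,
) -> ClusterResult:
    """K-means over the five morphology traits (four measured + LWR).

    Uses k-means++ initialization with ``restarts`` independent starts and
    keeps the lowest-SSW solution.  ``standardize`` z-scores each trait
    first, removing the dominance of large-scale traits (internode length)
    over small-scale ones (leaf width).
    """
    if not 1 <= k <= len(samples):
        raise ValueError(f"k must be in [1, n_samples], got {k} for n={len(samples)}")
    X = samples[CLUSTER_TRAITS].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    labels0 = km.fit_predict(X)
    labels = labels0 + 1  # 1-based cluster ids
    ssw, sst = _ssw_sst(X, labels)
    r2 = 0.0 if sst == 0 else 1.0 - ssw / sst
    ccc = cubic_clustering_criterion(X, labels) if k >= 2 and len(samples) > k else np.nan
    ssw_per_cluster = {
        int(c): float(((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum())
        for c in np.unique(labels)
    }
    return ClusterResult(
        assignments=pd.Series(labels, index=samples["sample_id"], name="cluster"),
        centers=km.cluster_centers_,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        ccc=float(ccc),
        ssw=ssw,
        sst=sst,
        ssw_per_cluster=ssw_per_cluster,
        standardized=standardize,
        traits=list(CLUSTER_TRAITS),
    )


def cubic_clustering_criterion(X: np.ndarray, labels: np.ndarray) -> float:
    """Sarle's CCC approximation for a partition of ``X``.

    The data's covariance eigenvalues are scaled to hypercube-equivalent
    axes u_j; the effective dimensionality p* is the largest j whose scaled
    axis still exceeds the cell edge implied by the cluster count
    (determined by fixed-point iteration); the null expectation E[R^2] then
    follows from the u_j and n, and

        CCC = ln((1 - E[R^2]) / (1 - R^2)) * sqrt(n p* / 2) / (0.001 + E[R^2])^1.2

    A perfect fit (R^2 = 1) returns +inf with a warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    clusters = np.unique(labels)
    q = clusters.size
    if n <= q:
        raise ValueError(f"need more samples ({n}) than clusters ({q})")
    if q < 1:
        raise ValueError("empty partition")

    ssw, sst = _ssw_sst(X, labels)
    if sst == 0:
        raise ValueError("data has zero total variance")
    r2 = 1.0 - ssw / sst

    # eigen-axes of the total-sample covariance, dropping null directions
    cov = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = eigvals[eigvals > max(eigvals[0], 0) * 1e-12]
    s = np.sqrt(eigvals)
    p_eff = s.size
    if p_eff == 0:
        raise ValueError("data has zero total variance")

    # fixed-point determination of the effective dimensionality p*
    pstar = p_eff
    for _ in range(100):
        vstar = float(np.prod(s[:pstar]))
        c = (vstar / q) ** (1.0 / pstar)
        u = s / c
        new_pstar = int(np.sum(u >= 1.0))
        new_pstar = min(max(new_pstar, 1), p_eff)
        if new_pstar == pstar:
            break
        pstar = new_pstar
    vstar = float(np.prod(s[:pstar]))
    c = (vstar / q) ** (1.0 / pstar)
    u = s / c

    num = float(np.sum(1.0 / (n + u[:pstar])) + np.sum(u[pstar:] ** 2 / (n + u[pstar:])))
    den = float(np.sum(u**2))
    e_r2 = 1.0 - (num / den) * ((n - q) ** 2 / n) * (1.0 + 4.0 / n)
    e_r2 = float(np.clip(e_r2, 1e-12, 1.0 - 1e-12))

    if r2 >= 1.0:
        warnings.warn("R^2 = 1: CCC is +inf", stacklevel=2)
        return np.inf
    return float(
        np.log((1.0 - e_r2) / (1.0 - r2))
        * np.sqrt(n * pstar / 2.0)
        / (0.001 + e_r2) ** 1.2
    )


def expected_r_squared(X: np.ndarray, q: int) -> float:
    """E[R^2] under the uniform null for data's covariance shape and q clusters."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    cov = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = eigvals[eigvals > max(eigvals[0], 0) * 1e-12]
    s = np.sqrt(eigvals)
    pstar = s.size
    for _ in range(100):
        c = (float(np.prod(s[:pstar])) / q) ** (1.0 / pstar)
        u = s / c
        new_pstar = min(max(int(np.sum(u >= 1.0)), 1), s.size)
        if new_pstar == pstar:
            break
        pstar = new_pstar
    c = (float(np.prod(s[:pstar])) / q) ** (1.0 / pstar)
    u = s / c
    num = float(np.sum(1.0 / (n + u[:pstar])) + np.sum(u[pstar:] ** 2 / (n + u[pstar:])))
    den = float(np.sum(u**2))
    return float(1.0 - (num / den) * ((n - q) ** 2 / n) * (1.0 + 4.0 / n))


def summarize_clusters(
    samples: pd.DataFrame, assignments: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster trait means/SDs and SD-overlap difference flags.

    Two clusters are flagged "different" on a trait when their
    mean +- SD intervals do not overlap.  A singleton cluster reports SD 0
    with a warning.
    """
    df = samples.set_index("sample_id")
    clusters = sorted(assignments.unique())
    stats_rows = []
    for c in clusters:
        members = df.loc[assignments.index[assignments == c]]
        if len(members) == 1:
            warnings.warn(f"cluster {c} is a singleton; SD reported as 0", stacklevel=2)
        for trait in CLUSTER_TRAITS:
            sd = float(members[trait].std(ddof=1)) if len(members) > 1 else 0.0
            stats_rows.append(
                {
                    "cluster": c,
                    "trait": trait,
                    "n": len(members),
                    "mean": float(members[trait].mean()),
                    "sd": sd,
                }
            )
    stats = pd.DataFrame(stats_rows)
    flag_rows = []
    for trait in CLUSTER_TRAITS:
        tstats = stats[stats.trait == trait].set_index("cluster")
        for i, a in enumerate(clusters):
            for b in clusters[i + 1 :]:
                ma, sa = tstats.loc[a, "mean"], tstats.loc[a, "sd"]
                mb, sb = tstats.loc[b, "mean"], tstats.loc[b, "sd"]
                flag_rows.append(
                    {
                        "trait": trait,
                        "cluster_a": a,
                        "cluster_b": b,
                        "different": bool(abs(ma - mb) > sa + sb),
                    }
                )
    return stats, pd.DataFrame(flag_rows)
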