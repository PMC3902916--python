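"""Consensus kinetic clustering with Spearman-correlation distance.

Gene profiles are grouped by k-means under the distance 1 - Spearman rho,
repeated many times from random initializations.  Genes that land in the
same (matched) cluster in at least half of the runs form that cluster's
core; the core profile is the average profile of the core members.  The
number of clusters is chosen from the elbow of the within-cluster
point-to-centroid distance sum J over a jackknifed scan, and all genes are
finally attached to the core whose profile they correlate with best
(Pearson >= 0.8 by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConstantProfileError

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringConfig",
    "ClusterRun",
    "ClusterCore",
    "spearman_distance",
    "kmeans_spearman",
    "within_cluster_J",
    "consensus_cores",
    "consensus_cluster",
    "jackknife_scan",
    "select_n",
    "assign_to_cores",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """Settings of the consensus-clustering stage."""

    n_clusters: int = 42
    n_runs: int = 500
    core_fraction: float = 0.5
    jackknife_fraction: float = 0.015
    n_range: tuple[int, int] = (30, 70)
    assign_r_min: float = 0.8
    rng_seed: int = 0
    max_iter: int = 100

    def __post_init__(self):
        if not 0 < self.core_fraction <= 1:
            raise ValueError("core_fraction must be in (0, 1]")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not -1 < self.assign_r_min <= 1:
            raise ValueError("assign_r_min must be in (-1, 1]")


@dataclass
class ClusterRun:
    """One k-means run: per-gene labels, centroid profiles, and J."""

    run_index: int
    labels: np.ndarray
    centroids: np.ndarray
    J: float


@dataclass
class ClusterCore:
    """A consensus core cluster and, optionally, the genes attached post hoc."""

    core_id: int
    member_gene_ids: list[str]
    core_profile: np.ndarray
    assigned: dict[str, float] = field(default_factory=dict)  # gene -> correlation


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return rankdata(x, axis=1, method="average")


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm; constant rows become zero rows."""
    c = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norms > 0, c / norms, 0.0)
    return z


def spearman_distance(p: np.ndarray, q: np.ndarray) -> float:
    """1 - Spearman rho (average ranks for ties); range [0, 2]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.size < 3:
        raise ValueError("profiles must share length >= 3")
    if np.ptp(p) == 0 or np.ptp(q) == 0:
        raise ConstantProfileError("Spearman distance undefined for constant profiles")
    zp = _standardize_rows(_rank_rows(p[None, :]))[0]
    zq = _standardize_rows(_rank_rows(q[None, :]))[0]
    return float(1.0 - zp @ zq)


def _spearman_dist_matrix(z_genes: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Distances genes x centroids; centroid ranks recomputed each call.

    A degenerate (constant) centroid gets correlation 0, i.e. distance 1.
    """
    zc = _standardize_rows(_rank_rows(centroids))
    return 1.0 - z_genes @ zc.T


def _plusplus_init(
    x: np.ndarray, z: np.ndarray, n_clusters: int, rng: np.random.Generator
) -> np.ndarray:
    """Seeded k-means++ (D^2-weighted) initialization under Spearman distance.

    Uniform seeding rarely draws one seed per well-separated group, leaving
    Lloyd iterations stuck with merged groups; distance-weighted seeding
    makes each repeated run start near the real structure.
    """
    n_genes = x.shape[0]
    idx = np.empty(n_clusters, dtype=int)
    idx[0] = rng.integers(n_genes)
    d_min = _spearman_dist_matrix(z, x[idx[0]][None, :])[:, 0]
    for c in range(1, n_clusters):
        d2 = np.maximum(d_min, 0.0) ** 2
        total = d2.sum()
        if total <= 0:
            remaining = np.setdiff1d(np.arange(n_genes), idx[:c])
            idx[c] = rng.choice(remaining)
        else:
            idx[c] = rng.choice(n_genes, p=d2 / total)
        d_new = _spearman_dist_matrix(z, x[idx[c]][None, :])[:, 0]
        d_min = np.minimum(d_min, d_new)
    return idx


def kmeans_spearman(
    values: np.ndarray, n_clusters: int, seed: int, max_iter: int = 100, run_index: int = 0
) -> ClusterRun:
    """Lloyd k-means under Spearman distance; centroid = mean member profile.

    Empty clusters are re-seeded with the profile farthest from its current
    centroid.  Deterministic for a given seed.
    """
    x = np.asarray(values, dtype=float)
    n_genes = x.shape[0]
    if n_clusters > n_genes:
        raise ValueError("more clusters than profiles")
    if np.any(np.ptp(x, axis=1) == 0):
        raise ConstantProfileError("constant profiles cannot be rank-clustered")
    z = _standardize_rows(_rank_rows(x))
    rng = np.random.default_rng(seed)
    centroids = x[_plusplus_init(x, z, n_clusters, rng)].copy()
    labels = np.full(n_genes, -1)
    for _ in range(max_iter):
        d = _spearman_dist_matrix(z, centroids)
        new_labels = d.argmin(axis=1)
        # re-seed empty clusters from the worst-fitting profile
        for c in range(n_clusters):
            if not np.any(new_labels == c):
                worst = np.argmax(d[np.arange(n_genes), new_labels])
                new_labels[worst] = c
                d[worst, :] = 0.0
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(n_clusters):
            members = labels == c
            if members.any():
                centroids[c] = x[members].mean(axis=0)
    d = _spearman_dist_matrix(z, centroids)
    j = float(d[np.arange(n_genes), labels].sum())
    return ClusterRun(run_index, labels, centroids, j)


def within_cluster_J(run: ClusterRun, values: np.ndarray) -> float:
    """Sum over genes of the Spearman distance to their cluster centroid."""
    z = _standardize_rows(_rank_rows(np.asarray(values, dtype=float)))
    d = _spearman_dist_matrix(z, run.centroids)
    return float(d[np.arange(len(run.labels)), run.labels].sum())


def _match_to_reference(ref_labels: np.ndarray, labels: np.ndarray, n: int) -> np.ndarray:
    """Greedy maximal-overlap mapping run cluster -> reference cluster."""
    overlap = np.zeros((n, n), dtype=int)
    for r, l in zip(ref_labels, labels):
        overlap[r, l] += 1
    mapping = np.full(n, -1)
    used_ref = np.zeros(n, dtype=bool)
    used_run = np.zeros(n, dtype=bool)
    flat = [(-overlap[i, j], i, j) for i in range(n) for j in range(n)]
    flat.sort()
    for neg, i, j in flat:
        if not used_ref[i] and not used_run[j]:
            mapping[j] = i
            used_ref[i] = True
            used_run[j] = True
    return mapping


def consensus_cores(
    runs: list[ClusterRun],
    values: np.ndarray,
    gene_ids: list[str],
    core_fraction: float = 0.5,
) -> list[ClusterCore]:
    """Consensus cores over repeated runs.

    The run with the median J is the reference partition; every other run's
    clusters are matched to it by greedy maximal member overlap.  A gene is a
    core member of the reference cluster it co-occurs with in at least
    ``core_fraction`` of the runs.
    """
    if len(runs) < 2:
        raise ValueError("need >= 2 runs for a consensus")
    n = runs[0].centroids.shape[0]
    n_genes = len(gene_ids)
    js = np.array([r.J for r in runs])
    ref = runs[int(np.argsort(js, kind="stable")[len(runs) // 2])]
    counts = np.zeros((n_genes, n), dtype=int)
    for run in runs:
        mapping = _match_to_reference(ref.labels, run.labels, n)
        counts[np.arange(n_genes), mapping[run.labels]] += 1
    need = core_fraction * len(runs) - 1e-9
    best = counts.argmax(axis=1)
    is_core = counts[np.arange(n_genes), best] >= need
    x = np.asarray(values, dtype=float)
    cores = []
    for c in range(n):
        members = np.flatnonzero(is_core & (best == c))
        if members.size == 0:
            continue
        cores.append(
            ClusterCore(
                core_id=len(cores),
                member_gene_ids=[gene_ids[i] for i in members],
                core_profile=x[members].mean(axis=0),
            )
        )
    return cores


def consensus_cluster(
    values: pd.DataFrame, config: ClusteringConfig = ClusteringConfig()
) -> list[ClusterCore]:
    """Repeated k-means plus consensus-core extraction in one call."""
    x = values.to_numpy(dtype=float)
    seeds = np.random.SeedSequence(config.rng_seed).generate_state(config.n_runs)
    runs = [
        kmeans_spearman(x, config.n_clusters, int(s % (2**31 - 1)), config.max_iter, i)
        for i, s in enumerate(seeds)
    ]
    return consensus_cores(runs, x, list(values.index), config.core_fraction)


def jackknife_scan(
    values: pd.DataFrame,
    config: ClusteringConfig = ClusteringConfig(),
    n_values: list[int] | None = None,
    repeats: int = 20,
) -> pd.DataFrame:
    """J(n) over a range of cluster counts with jackknife resampling.

    For each candidate n, clustering is repeated ``repeats`` times, each time
    omitting ``jackknife_fraction`` of the profiles uniformly at random; the
    per-run J values are summarized as mean and sd.
    """
    if n_values is None:
        n_values = list(range(config.n_range[0], config.n_range[1] + 1))
    x = values.to_numpy(dtype=float)
    n_genes = x.shape[0]
    n_omit = int(round(config.jackknife_fraction * n_genes))
    rows = []
    for n in n_values:
        ss = np.random.SeedSequence((config.rng_seed, n))
        seeds = ss.generate_state(2 * repeats)
        js = []
        for r in range(repeats):
            rng = np.random.default_rng(seeds[2 * r])
            keep = np.ones(n_genes, dtype=bool)
            if n_omit > 0:
                keep[rng.choice(n_genes, size=n_omit, replace=False)] = False
            run = kmeans_spearman(x[keep], n, int(seeds[2 * r + 1] % (2**31 - 1)))
            js.append(run.J)
        js = np.asarray(js)
        rows.append({"n": n, "J_mean": js.mean(), "J_sd": js.std(ddof=1) if len(js) > 1 else 0.0})
    return pd.DataFrame(rows)


def select_n(
    j_curve: pd.DataFrame, default_n: int = 42, rel_floor: float = 0.05
) -> int:
    """Elbow of J(n): the n with the largest second difference of log J.

    The second difference is taken on the log scale so the elbow measures a
    local change *relative* to the level of J, not the absolute early-curve
    steepness.  If no point shows a pronounced relative change (max second
    difference below ``rel_floor``), the configured default is returned with
    a warning.
    """
    if len(j_curve) < 4:
        raise ValueError("need >= 4 points on the J curve")
    curve = j_curve.sort_values("n")
    n = curve["n"].to_numpy()
    j = np.log(np.maximum(curve["J_mean"].to_numpy(dtype=float), 1e-12))
    d2 = j[:-2] - 2 * j[1:-1] + j[2:]
    jrange = float(j.max() - j.min())
    if jrange == 0 or d2.max() < rel_floor:
        warnings.warn(
            f"no pronounced elbow in J(n); falling back to default n = {default_n}",
            stacklevel=2,
        )
        return default_n
    return int(n[1:-1][int(np.argmax(d2))])


def assign_to_cores(
    values: pd.DataFrame,
    cores: list[ClusterCore],
    assign_r_min: float = 0.8,
    min_points: int = 8,
) -> list[ClusterCore]:
    """Attach every gene to the best-correlated core if the correlation passes.

    Pearson correlation against each core profile; a gene joins the core with
    the maximal correlation iff that maximum >= ``assign_r_min`` (ties go to
    the lower core id).  The correlation is stored as membership strength.
    Profiles with missing time points are correlated over their present
    points (at least ``min_points`` of them); constant profiles stay
    unassigned.
    """
    x = values.to_numpy(dtype=float)
    gene_ids = list(values.index)
    core_mat = np.stack([c.core_profile for c in cores])
    zc = _standardize_rows(core_mat)
    zg = _standardize_rows(np.nan_to_num(x))
    corr = zg @ zc.T  # exact for complete rows; recomputed below for gappy ones
    gappy = ~np.isfinite(x).all(axis=1)
    out = [
        ClusterCore(c.core_id, list(c.member_gene_ids), c.core_profile.copy(), dict(c.assigned))
        for c in cores
    ]
    for i, gid in enumerate(gene_ids):
        row = x[i]
        if gappy[i]:
            present = np.isfinite(row)
            if present.sum() < min_points:
                logger.warning("gene %s has < %d present points; unassigned", gid, min_points)
                continue
            sub = _standardize_rows(row[present][None, :])[0]
            subc = _standardize_rows(core_mat[:, present])
            corr[i] = subc @ sub
        if np.ptp(row[np.isfinite(row)]) == 0:
            logger.warning("gene %s has a constant profile; left unassigned", gid)
            continue
        best = int(corr[i].argmax())
        r = float(corr[i, best])
        if r >= assign_r_min - 1e-12:
            out[best].assigned[gid] = r
    return out


def membership_table(cores: list[ClusterCore]) -> pd.DataFrame:
    """Long-format membership: gene, core_id, role (core|assigned), correlation."""
    rows = []
    for c in cores:
        for g in c.member_gene_ids:
            rows.append({"gene": g, "core_id": c.core_id, "role": "core", "correlation": np.nan})
        for g, r in c.assigned.items():
            rows.append({"gene": g, "core_id": c.core_id, "role": "assigned", "correlation": r})
    return pd.DataFrame(rows, columns=["gene", "core_id", "role", "correlation"])
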