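"""Synthetic germination-style data sets with known ground truth.

Emulates the statistical structure the pipeline assumes: pulse-shaped sigma
factor profiles, target genes generated from the sigmoid transcription ODE
with known parameters, decoy genes unattached to any regulator, replicated
two-channel arrays with multiplicative lognormal noise and occasional gross
outliers, and functional classes planted to be enriched within kinetic
groups.  Every stage of the pipeline has a ground-truth file to test
against, and a fixed seed reproduces the fixture byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import TimeGrid, default_grid
from .kinetics import KineticParams, simulate_target
from .preprocess import ArrayMetadata, RawExpressionTable

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticDataset",
    "make_regulator_profiles",
    "make_targets",
    "add_replicate_noise",
    "plant_annotations",
    "make_kinetic_groups",
    "make_dataset",
    "write_fixture",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and noise of a generated data set.

    Defaults emulate the germination design: 13 time points at 30-min
    spacing, 3 biological replicates, 5% multiplicative replicate noise,
    1% gross outliers at 10-fold.  Most genes on a genome-wide array do not
    belong to the studied regulons, so the default background (decoy)
    population outnumbers the regulon targets 3:1; the per-array median/MAD
    centering assumes that bulk distribution is stable over time.
    """

    n_regulators: int = 5
    targets_per_regulator: int = 40
    n_decoys: int = 600
    # smooth large-amplitude "transcriptome remodeling" genes driven by
    # unmodeled regulators; they populate the tails of each array's value
    # distribution the way a real germinating transcriptome does
    n_background: int = 200
    background_log_sd: float = 1.0
    background_ls: float = 0.7
    # probe-level background hybridization: both channels of a probe see an
    # additive floor, compressing extreme ratios as real two-channel
    # microarrays do (fraction of the gene's mean abundance)
    signal_floor: float = 0.2
    n_time_points: int = 13
    replicates_per_point: int = 3
    noise_cv: float = 0.05
    outlier_rate: float = 0.01
    outlier_fold: float = 10.0
    k1_range: tuple[float, float] = (0.5, 10.0)
    k2_range: tuple[float, float] = (2.0, 5.0)
    w_range: tuple[float, float] = (1.0, 50.0)
    b_range: tuple[float, float] = (-10.0, 10.0)
    n_classes: int = 10
    # regulons are functionally coherent: with 10 classes, factor 7 puts
    # ~70% of a regulon's members into its designated class
    planted_enrichment_factor: float = 7.0
    # share one kinetic parameter set (with +-5% jitter) within each
    # regulator's targets, so regulons are co-expressed kinetic groups
    shared_group_params: bool = True
    param_jitter: float = 0.05
    # window (fractions of the sampled span) holding the regulator pulse
    # peaks; None: derived from the dataset style -- co-expressed regulons
    # need their full response inside the window to stay distinguishable,
    # independent targets benefit from maximal peak separation
    peak_window: tuple[float, float] | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_regulators, self.targets_per_regulator, self.n_decoys, self.n_background) < 0:
            raise ValueError("counts must be >= 0")
        if self.noise_cv < 0 or not 0 <= self.outlier_rate <= 1:
            raise ValueError("invalid noise settings")


@dataclass
class GroundTruth:
    """What was planted: edges with parameters, cluster labels, enrichments."""

    edges: pd.DataFrame  # regulator, target, k1, k2, w, b
    cluster_labels: pd.Series  # gene -> planted group label
    enriched: pd.DataFrame  # cluster, class


@dataclass
class SyntheticDataset:
    """A complete in-memory fixture."""

    grid: TimeGrid
    regulator_ids: list[str]
    true_profiles: pd.DataFrame  # genes (incl. regulators) x time points
    raw: RawExpressionTable
    meta: ArrayMetadata
    annotation: pd.DataFrame  # gene, class
    priors: pd.DataFrame  # regulator, target, source, citation
    truth: GroundTruth


def _pulse(t: np.ndarray, onset: float, width: float, shape: float, amp: float, base: float) -> np.ndarray:
    """Baseline plus a gamma-shaped pulse; strictly positive."""
    s = np.maximum(t - onset, 0.0) / width
    return base + amp * s**shape * np.exp(-s)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.stats import spearmanr

    return float(spearmanr(a, b).statistic)


def make_regulator_profiles(
    spec: SyntheticSpec, grid: TimeGrid, rng: np.random.Generator
) -> pd.DataFrame:
    """Distinct pulse-shaped sigma factor profiles.

    Pulse peak times are stratified across the sampled window (evenly spaced
    base positions with random jitter), and width, steepness, amplitude and
    baseline are drawn per regulator; candidates rank-correlated >= 0.7 with
    an already accepted profile are redrawn.  Narrow pulses with distinct
    peak times are what lets the screen attribute a target to the right
    sigma factor; interior-onset pulses (never a bare decay from dormancy)
    keep the driven targets identifiable.
    """
    t = grid.hours
    span = t[-1] - t[0]
    n = spec.n_regulators
    window = spec.peak_window or ((0.08, 0.70) if spec.shared_group_params else (0.08, 0.92))
    lo, hi = t[0] + window[0] * span, t[0] + window[1] * span
    base_peaks = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
    spacing = (hi - lo) / max(n - 1, 1)
    profiles: list[np.ndarray] = []
    for i in range(n):
        for _ in range(500):
            peak = base_peaks[i] + rng.uniform(-0.15, 0.15) * spacing
            width = rng.uniform(0.25, 0.6)
            shape = rng.uniform(1.0, 2.5)
            onset = peak - width * shape  # gamma pulse peaks at onset + width*shape
            if onset < 0:
                continue
            cand = _pulse(
                t, onset, width, shape,
                amp=rng.uniform(1.0, 5.0),
                base=rng.uniform(0.2, 1.0),
            )
            if all(_spearman(cand, p) < 0.7 for p in profiles):
                profiles.append(cand)
                break
        else:
            raise RuntimeError("could not draw sufficiently distinct regulator profiles")
    ids = [f"SIG{i + 1:02d}" for i in range(n)]
    return pd.DataFrame(profiles, index=ids, columns=list(grid.labels))


def _draw_params(spec: SyntheticSpec, rng: np.random.Generator) -> KineticParams:
    return KineticParams(
        k1=rng.uniform(*spec.k1_range),
        k2=rng.uniform(*spec.k2_range),
        w=rng.uniform(*spec.w_range),
        b=rng.uniform(*spec.b_range),
    )


def _jitter(p: KineticParams, frac: float, rng: np.random.Generator) -> KineticParams:
    f = 1.0 + frac * rng.uniform(-1, 1, size=4)
    return KineticParams(p.k1 * f[0], p.k2 * f[1], p.w * f[2], p.b * f[3])


# minimum over-time CV of a planted target profile; a flatter profile would
# carry no kinetic signature of its regulator (undetectable by construction)
_MIN_PROFILE_CV = 0.35
# maximum correlation a planted target may have with the regulator-free
# relaxation family A + B exp(-k2 t); above this, the target's shape does not
# require its regulator at all (w ~ 0 fits it), so the edge is unidentifiable
_MAX_RELAXATION_C = 0.8


def _responsive(profile: np.ndarray) -> bool:
    m = profile.mean()
    return m > 0 and profile.std() / m >= _MIN_PROFILE_CV


def _identifiable(profile: np.ndarray, t: np.ndarray) -> bool:
    """True if no regulator-free exponential relaxation mimics the profile.

    The model with w = 0 reduces to y = A + B exp(-k2 t); Pearson absorbs
    the affine part, so the best such fit is max_k2 |corr(profile, e^-k2 t)|.
    """
    z = profile - profile.mean()
    nz = np.linalg.norm(z)
    if nz == 0:
        return False
    for k2 in np.linspace(0.05, 10.0, 64):
        e = np.exp(-k2 * t)
        e = e - e.mean()
        c = abs(z @ e) / (nz * np.linalg.norm(e))
        if c > _MAX_RELAXATION_C:
            return False
    return True


def make_targets(
    spec: SyntheticSpec,
    regulators: pd.DataFrame,
    grid: TimeGrid,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Noise-free target and decoy profiles plus the planted truth.

    Each target descends from one regulator through the transcription model;
    with ``shared_group_params`` all targets of a regulator share one
    parameter set up to small jitter (a co-expressed kinetic group),
    otherwise parameters are drawn independently per target.  Decoys are
    smooth positive profiles attached to no regulator.  Parameter sets whose
    simulated profile is too flat (over-time CV below 0.35) or mimicked by a
    regulator-free exponential relaxation are redrawn: such targets carry no
    identifiable kinetic signature of their regulator, so they cannot
    constitute a planted edge.
    """
    rows, edge_rows, labels = [], [], {}
    ids = []
    group_bases: list[np.ndarray] = []
    for gi, rid in enumerate(regulators.index):
        rprof = regulators.loc[rid].to_numpy(dtype=float)

        def _ok(prof: np.ndarray) -> bool:
            return _responsive(prof) and _identifiable(prof, grid.hours)

        group_params = None
        group_y0 = None
        if spec.shared_group_params:
            for _ in range(2000):
                cand = _draw_params(spec, rng)
                cand_y0 = rng.uniform(0.05, 1.0)
                base = simulate_target(cand, rprof, grid, cand_y0)
                # planted kinetic groups must be mutually distinct shapes,
                # same 0.7 rank-correlation bound as for the regulators
                if _ok(base) and all(_spearman(base, b) < 0.7 for b in group_bases):
                    group_params, group_y0 = cand, cand_y0
                    group_bases.append(base)
                    break
            else:
                raise RuntimeError("could not draw an identifiable group parameter set")
        for ti in range(spec.targets_per_regulator):
            for _ in range(2000):
                if spec.shared_group_params:
                    # co-expressed members share kinetics AND initial state
                    p = _jitter(group_params, spec.param_jitter, rng)
                    y0 = group_y0 * (1.0 + spec.param_jitter * rng.uniform(-1, 1))
                else:
                    p = _draw_params(spec, rng)
                    y0 = rng.uniform(0.05, 1.0)
                prof = simulate_target(p, rprof, grid, y0)
                if spec.shared_group_params or _ok(prof):
                    break
            else:
                raise RuntimeError("could not generate an identifiable target")
            tid = f"GENE{gi + 1:02d}_{ti + 1:03d}"
            ids.append(tid)
            rows.append(prof)
            labels[tid] = f"GROUP{gi + 1:02d}"
            edge_rows.append(
                {"regulator": rid, "target": tid, "k1": p.k1, "k2": p.k2, "w": p.w, "b": p.b}
            )
    # decoys: rough positive profiles from a stationary Gaussian process on
    # the log scale (squared-exponential kernel), so the cross-gene value
    # distribution is the same at every time point -- the stationarity the
    # array normalization assumes of the bulk of the transcriptome.  The
    # log-sd 0.4 means typical ~1.5-fold swings: unregulated genes
    # fluctuate, they do not show multi-fold excursions
    t = grid.hours

    def _gp_chol(log_sd: float, ls: float) -> np.ndarray:
        cov = log_sd**2 * np.exp(-0.5 * ((t[:, None] - t[None, :]) / ls) ** 2)
        return np.linalg.cholesky(cov + 1e-10 * np.eye(t.size))

    chol = _gp_chol(0.4, 0.45)
    for di in range(spec.n_decoys):
        z = chol @ rng.normal(size=t.size)
        prof = np.exp(z) * rng.uniform(0.3, 3.0)
        tid = f"DECOY{di + 1:03d}"
        ids.append(tid)
        rows.append(prof)
    # remodeling background: slow, large-amplitude drifts (half of them
    # rising, half falling over germination on average)
    if spec.n_background > 0:
        chol_bg = _gp_chol(spec.background_log_sd, spec.background_ls)
        for bi in range(spec.n_background):
            z = chol_bg @ rng.normal(size=t.size)
            prof = np.exp(z) * rng.uniform(0.3, 3.0)
            tid = f"BG{bi + 1:03d}"
            ids.append(tid)
            rows.append(prof)
    targets = pd.DataFrame(rows, index=ids, columns=list(grid.labels))
    truth = GroundTruth(
        edges=pd.DataFrame(edge_rows, columns=["regulator", "target", "k1", "k2", "w", "b"]),
        cluster_labels=pd.Series(labels, name="cluster", dtype=object),
        enriched=pd.DataFrame(columns=["cluster", "class"]),
    )
    return targets, truth


def add_replicate_noise(
    profiles: pd.DataFrame,
    spec: SyntheticSpec,
    grid: TimeGrid,
    rng: np.random.Generator,
) -> tuple[RawExpressionTable, ArrayMetadata]:
    """Replicated two-channel arrays from true profiles.

    Each replicate value is the true value times a mean-one lognormal factor
    with CV = ``noise_cv``; with probability ``outlier_rate`` it is further
    multiplied by ``outlier_fold``.  The pooled reference of a gene is its
    mean true value over the time course, so
    log2ratio = log2(replicate / reference) and
    sample_signal = gene intensity scale x replicate are mutually
    consistent, matching the pooled-reference two-channel design.
    """
    vals = profiles.to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError("true profiles must be strictly positive")
    # probe background: an additive floor seen by both channels compresses
    # extreme ratios, as background hybridization does on real arrays
    floor = spec.signal_floor * vals.mean(axis=1, keepdims=True)
    vals = vals + floor
    n_genes, n_t = vals.shape
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    reference = vals.mean(axis=1)
    # a gene's brightness is independent of its kinetic shape: calibrate the
    # sample channel so the median over time equals the drawn intensity
    intensity = rng.lognormal(mean=np.log(500.0), sigma=1.0, size=n_genes)
    scale = intensity / np.median(vals, axis=1)

    array_ids, meta_rows = [], []
    log2ratio, signal = {}, {}
    for j, lab in enumerate(grid.labels):
        for rep in range(1, spec.replicates_per_point + 1):
            aid = f"{lab}_r{rep}"
            array_ids.append(aid)
            meta_rows.append({"array_id": aid, "time_label": lab, "replicate": rep})
            factor = np.exp(rng.normal(0.0, sigma, size=n_genes) - sigma**2 / 2.0)
            if spec.outlier_rate > 0:
                hit = rng.random(n_genes) < spec.outlier_rate
                factor = np.where(hit, factor * spec.outlier_fold, factor)
            v = vals[:, j] * factor
            log2ratio[aid] = np.log2(v / reference)
            signal[aid] = scale * v
    table = RawExpressionTable(
        log2ratio=pd.DataFrame(log2ratio, index=profiles.index),
        sample_signal=pd.DataFrame(signal, index=profiles.index),
    )
    meta = ArrayMetadata(pd.DataFrame(meta_rows))
    return table, meta


def plant_annotations(
    cluster_labels: pd.Series,
    all_genes: list[str],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One functional class per gene, over-sampled within planted clusters.

    Background genes draw their class uniformly; genes of planted cluster g
    draw the cluster's designated class with probability raised by
    ``planted_enrichment_factor`` (remaining mass spread uniformly).  With
    factor 1 nothing is planted and no enriched pair is recorded.
    """
    classes = [f"CLASS{c + 1:02d}" for c in range(spec.n_classes)]
    base = 1.0 / spec.n_classes
    planted_rows = []
    groups = sorted(cluster_labels.unique())
    designated = {g: classes[i % spec.n_classes] for i, g in enumerate(groups)}
    rows = []
    for gene in all_genes:
        group = cluster_labels.get(gene)
        if group is not None and spec.planted_enrichment_factor > 1:
            p_hit = min(spec.planted_enrichment_factor * base, 0.95)
            probs = np.full(spec.n_classes, (1.0 - p_hit) / (spec.n_classes - 1))
            probs[classes.index(designated[group])] = p_hit
        else:
            probs = np.full(spec.n_classes, base)
        rows.append({"gene": gene, "class": classes[rng.choice(spec.n_classes, p=probs)]})
    if spec.planted_enrichment_factor > 1:
        planted_rows = [{"cluster": g, "class": designated[g]} for g in groups]
    annotation = pd.DataFrame(rows, columns=["gene", "class"])
    enriched = pd.DataFrame(planted_rows, columns=["cluster", "class"])
    return annotation, enriched


def make_kinetic_groups(
    n_groups: int = 6,
    genes_per_group: int = 60,
    grid: TimeGrid | None = None,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted kinetic shape groups for clustering tests.

    Each group has a distinct pulse-shaped base profile; members are the
    base raised to a mild random power and multiplied by small lognormal
    noise, keeping within-group rank agreement high (Spearman >= 0.95 for
    the default noise) while groups stay well separated.
    """
    grid = grid or default_grid()
    t = grid.hours
    rng = np.random.default_rng(seed)
    u = (t - t[0]) / (t[-1] - t[0])  # normalized time in [0, 1]
    # log-scale archetypes with no flat stretches (small multiplicative noise
    # cannot scramble within-group ranks) and mutually low rank correlation:
    # monotone rise/fall plus one-period sinusoids at quarter phases
    log_archetypes = [
        3.0 * u,                          # exponential rise
        -3.0 * u,                         # exponential fall
        1.5 * np.sin(2 * np.pi * u),      # up-down-up wave
        1.5 * np.cos(2 * np.pi * u),      # mid valley
        -1.5 * np.sin(2 * np.pi * u),     # down-up-down wave
        -1.5 * np.cos(2 * np.pi * u),     # mid peak
    ]
    rows, labels, ids = [], [], []
    for g in range(n_groups):
        if g < len(log_archetypes):
            base_log = log_archetypes[g]
        else:  # extra groups: sinusoids at intermediate phases
            phase = 2 * np.pi * (g - len(log_archetypes) + 0.5) / 8.0
            base_log = 1.5 * np.sin(2 * np.pi * u + phase)
        for m in range(genes_per_group):
            power = rng.uniform(0.85, 1.15)
            amp = rng.uniform(0.5, 3.0)
            prof = amp * np.exp(power * base_log + rng.normal(0.0, noise_sd, size=t.size))
            gid = f"G{g + 1:02d}_{m + 1:03d}"
            ids.append(gid)
            rows.append(prof)
            labels.append(f"GROUP{g + 1:02d}")
    values = pd.DataFrame(rows, index=ids, columns=list(grid.labels))
    return values, pd.Series(labels, index=ids, name="cluster")


def make_dataset(spec: SyntheticSpec = SyntheticSpec(), grid: TimeGrid | None = None) -> SyntheticDataset:
    """Full default fixture: regulators, targets, noisy arrays, annotation, priors."""
    grid = grid or default_grid(spec.n_time_points)
    rng = np.random.default_rng(spec.rng_seed)
    regulators = make_regulator_profiles(spec, grid, rng)
    targets, truth = make_targets(spec, regulators, grid, rng)
    true_profiles = pd.concat([regulators, targets])
    raw, meta = add_replicate_noise(true_profiles, spec, grid, rng)
    annotation, enriched = plant_annotations(
        truth.cluster_labels, list(true_profiles.index), spec, rng
    )
    truth.enriched = enriched
    # prior table: a 20% sample of the true edges, labelled as ChIP evidence
    n_priors = len(truth.edges) // 5
    if n_priors > 0:
        idx = rng.choice(len(truth.edges), size=n_priors, replace=False)
        priors = truth.edges.iloc[np.sort(idx)][["regulator", "target"]].copy()
        priors["source"] = "chip"
        priors["citation"] = "synthetic"
    else:
        priors = pd.DataFrame(columns=["regulator", "target", "source", "citation"])
    return SyntheticDataset(
        grid=grid,
        regulator_ids=list(regulators.index),
        true_profiles=true_profiles,
        raw=raw,
        meta=meta,
        annotation=annotation,
        priors=priors.reset_index(drop=True),
        truth=truth,
    )


def write_fixture(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input plus ground truth as TSV; round-trip exact.

    The file set is sufficient to run every CLI subcommand without any other
    input: expression matrices, array metadata, annotation, the sigma-factor
    list, the prior table and the truth tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name: str, df: pd.DataFrame, index: bool, index_label=None):
        p = out / name
        df.to_csv(p, sep="\t", index=index, index_label=index_label, na_rep="NA")
        paths[name] = p

    _write("log2ratio.tsv", dataset.raw.log2ratio, True, "gene")
    _write("sample_signal.tsv", dataset.raw.sample_signal, True, "gene")
    _write("arrays.tsv", dataset.meta.table, False)
    _write("annotation.tsv", dataset.annotation, False)
    _write("priors.tsv", dataset.priors, False)
    _write("true_profiles.tsv", dataset.true_profiles, True, "gene")
    _write("truth_edges.tsv", dataset.truth.edges, False)
    _write(
        "truth_clusters.tsv",
        dataset.truth.cluster_labels.rename_axis("gene").reset_index(),
        False,
    )
    _write("truth_enrichment.tsv", dataset.truth.enriched, False)
    sigma_path = out / "sigma_factors.txt"
    sigma_path.write_text("".join(f"{s}\n" for s in dataset.regulator_ids))
    paths["sigma_factors.txt"] = sigma_path
    grid_df = pd.DataFrame({"time_label": dataset.grid.labels, "hours": dataset.grid.hours})
    _write("time_grid.tsv", grid_df, False)
    return paths
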