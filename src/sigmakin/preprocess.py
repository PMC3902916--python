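"""Normalization of two-channel arrays and inference of gene expression profiles.

Each array carries Log2Ratio = log2(sample Cy3 / pooled reference Cy5) values
for every gene.  Arrays are made comparable by centering every array's
Log2Ratio distribution to median 0 and median absolute deviation 1, masking
the most extreme 2% of values at either tail, and exponentiating back to the
ratio scale ("normalized Ratio").  Per gene and time point, replicate values
are screened for gross outliers (Dixon's Q test for 3-9 replicates, Peirce's
criterion for 10 or more) and averaged; interior missing time points are
linearly interpolated in time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erfc

from .errors import DegenerateArrayError
from .grid import TimeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ArrayMetadata",
    "RawExpressionTable",
    "GeneProfile",
    "ProfileSet",
    "center_array",
    "trim_intensity_extremes",
    "to_normalized_ratio",
    "dixon_q_outliers",
    "peirce_outliers",
    "normalize_arrays",
    "average_replicates",
    "fill_internal_gaps",
    "normalize_pipeline",
]

# Dixon r10 critical values, two-sided 95% confidence (Rorabacher 1991).
DIXON_Q95 = {3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493}


@dataclass(frozen=True)
class ArrayMetadata:
    """Per-array annotation: which time point and biological replicate it is."""

    table: pd.DataFrame  # columns: array_id, time_label, replicate

    def __post_init__(self):
        required = {"array_id", "time_label", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.table["array_id"].duplicated().any():
            raise ValueError("duplicate array_id in metadata")
        pairs = self.table[["time_label", "replicate"]]
        if pairs.duplicated().any():
            raise ValueError("duplicate (time_label, replicate) pair in metadata")

    def arrays_for(self, time_label: str) -> list[str]:
        sel = self.table[self.table["time_label"] == time_label]
        return list(sel.sort_values("replicate")["array_id"])


@dataclass
class RawExpressionTable:
    """Gene x array Log2Ratio matrix plus the matching sample-channel intensities.

    Missing measurements are NaN in both matrices.
    """

    log2ratio: pd.DataFrame
    sample_signal: pd.DataFrame

    def __post_init__(self):
        if self.log2ratio.shape != self.sample_signal.shape:
            raise ValueError("log2ratio and sample_signal shapes differ")
        if not self.log2ratio.index.equals(self.sample_signal.index):
            raise ValueError("gene index mismatch between channels")
        if not self.log2ratio.columns.equals(self.sample_signal.columns):
            raise ValueError("array columns mismatch between channels")
        neg = self.sample_signal.to_numpy(dtype=float)
        if np.any(neg[np.isfinite(neg)] < 0):
            raise ValueError("sample_signal must be >= 0 where present")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.log2ratio.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.log2ratio.columns)


@dataclass
class GeneProfile:
    """One gene's expression profile on the time grid.

    values holds the per-time-point normalized Ratio (NaN where missing),
    cv the replicate coefficient of variation (NaN where fewer than two
    replicates survived), n_used the number of replicates averaged.
    """

    gene_id: str
    values: np.ndarray
    cv: np.ndarray
    n_used: np.ndarray
    complete: bool = True

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class ProfileSet:
    """All gene profiles over one grid, as gene x time-point frames."""

    grid: TimeGrid
    values: pd.DataFrame
    cv: pd.DataFrame
    n_used: pd.DataFrame
    incomplete: set[str] = field(default_factory=set)

    def __post_init__(self):
        if tuple(self.values.columns) != self.grid.labels:
            raise ValueError("values columns must equal grid labels")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def profile(self, gene_id: str) -> GeneProfile:
        return GeneProfile(
            gene_id,
            self.values.loc[gene_id].to_numpy(dtype=float),
            self.cv.loc[gene_id].to_numpy(dtype=float),
            self.n_used.loc[gene_id].to_numpy(),
            complete=gene_id not in self.incomplete,
        )

    def complete_values(self) -> pd.DataFrame:
        """Rows with no missing entries (the input the downstream stages need)."""
        keep = self.values.notna().all(axis=1)
        return self.values.loc[keep]


def center_array(log2ratios: np.ndarray) -> np.ndarray:
    """Center one array's Log2Ratios to median 0 and MAD 1.

    Subtracts the array median and divides by the (unscaled) median absolute
    deviation, so afterwards median = 0 and MAD = 1 exactly over the
    non-missing entries.  Missing entries (NaN) are preserved.
    """
    x = np.asarray(log2ratios, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise DegenerateArrayError("need >= 2 finite values to center an array")
    med = np.median(x[finite])
    mad = np.median(np.abs(x[finite] - med))
    if mad == 0:
        raise DegenerateArrayError("array MAD is zero; cannot scale")
    out = x.copy()
    out[finite] = (x[finite] - med) / mad
    return out


def trim_intensity_extremes(centered: np.ndarray, q: float = 0.02) -> np.ndarray:
    """Mask the most extreme tails of one array's centered Log2Ratios.

    Returns a boolean mask, True where the value falls strictly below the
    q-quantile or strictly above the (1-q)-quantile (linear-interpolation
    quantile convention) of the array's non-missing values.
    """
    if not (0 <= q < 0.5):
        raise ValueError("q must be in [0, 0.5)")
    x = np.asarray(centered, dtype=float)
    mask = np.zeros(x.shape, dtype=bool)
    if q == 0:
        return mask
    finite = np.isfinite(x)
    if finite.sum() == 0:
        return mask
    lo = np.quantile(x[finite], q)
    hi = np.quantile(x[finite], 1 - q)
    mask[finite] = (x[finite] < lo) | (x[finite] > hi)
    return mask


def to_normalized_ratio(centered: np.ndarray) -> np.ndarray:
    """Exponentiate centered Log2Ratios back to the (strictly positive) ratio scale."""
    return np.power(2.0, np.asarray(centered, dtype=float))


def dixon_q_outliers(replicates: np.ndarray) -> np.ndarray:
    """Dixon's Q test (r10), one pass, two-sided 95% confidence; 3-9 values.

    Q = gap/range for the most extreme value at either end; if Q exceeds the
    critical value the single most discordant value is removed.  Zero range
    leaves the sample untouched (Q undefined).
    """
    x = np.asarray(replicates, dtype=float)
    n = x.size
    if not 3 <= n <= 9:
        raise ValueError(f"Dixon's Q test requires 3-9 values, got {n}")
    s = np.sort(x)
    rng = s[-1] - s[0]
    if rng == 0:
        return x
    q_low = (s[1] - s[0]) / rng
    q_high = (s[-1] - s[-2]) / rng
    q_crit = DIXON_Q95[n]
    if max(q_low, q_high) <= q_crit:
        return x
    drop = s[0] if q_low >= q_high else s[-1]
    # remove one occurrence of the discordant value, preserving input order
    out = list(x)
    out.remove(drop)
    return np.asarray(out)


def _peirce_r2(n: int, k: int, m: int = 1) -> float:
    """Squared threshold ratio of Peirce's criterion (Gould's iteration).

    n observations, k doubtful, m unknowns estimated (1: the mean).
    Returns x^2 such that the maximum allowable |deviation| is sqrt(x^2)*s.
    """
    if n - m - k <= 0:
        return 0.0
    q = (k ** (k / n) * (n - k) ** ((n - k) / n)) / n
    r_new, r_old = 1.0, 0.0
    x2 = 0.0
    while abs(r_new - r_old) > n * 2e-16:
        lam = (q**n / r_new**k) ** (1.0 / (n - k))
        x2 = 1.0 + (n - m - k) / k * (1.0 - lam**2)
        if x2 < 0:
            return 0.0
        r_old = r_new
        r_new = np.exp((x2 - 1.0) / 2.0) * erfc(np.sqrt(x2 / 2.0))
    return x2


def peirce_outliers(replicates: np.ndarray) -> np.ndarray:
    """Peirce's criterion for rejecting doubtful observations, n >= 10.

    Iterates the assumed number of doubtful observations upward until the
    count of values exceeding the maximum allowable deviation no longer
    grows, then removes them.  Deterministic; zero variance keeps all.
    """
    x = np.asarray(replicates, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"Peirce's criterion routed only for n >= 10, got {n}")
    mean = x.mean()
    std = x.std(ddof=1)
    if std == 0:
        return x
    dev = np.abs(x - mean)
    # assume k doubtful observations; raise k while more than k values exceed
    # the maximum allowable deviation, then reject the ones that do
    k = 1
    while k < n - 1:
        r2 = _peirce_r2(n, k)
        if r2 <= 0:
            return x
        thresh = np.sqrt(r2) * std
        count = int(np.sum(dev > thresh))
        if count <= k:
            return x[dev <= thresh]
        k = count
    return x


def _filter_replicates(values: np.ndarray) -> np.ndarray:
    """Route replicate vectors to the applicable outlier test."""
    n = values.size
    if n < 3:
        return values
    if n <= 9:
        return dixon_q_outliers(values)
    return peirce_outliers(values)


def normalize_arrays(table: RawExpressionTable, trim_q: float = 0.02) -> pd.DataFrame:
    """Center, trim and exponentiate every array; returns normalized Ratios.

    Arrays whose Log2Ratio distribution is degenerate (MAD = 0) are rejected
    with an error, per the centering contract.
    """
    out = {}
    for aid in table.array_ids:
        col = table.log2ratio[aid].to_numpy(dtype=float)
        centered = center_array(col)
        mask = trim_intensity_extremes(centered, q=trim_q)
        centered[mask] = np.nan
        out[aid] = to_normalized_ratio(centered)
    return pd.DataFrame(out, index=table.log2ratio.index)


def average_replicates(
    ratios: pd.DataFrame, meta: ArrayMetadata, grid: TimeGrid
) -> ProfileSet:
    """Average normalized Ratios across biological replicates per time point.

    Replicate sets are screened first (Q test for 3-9 values, Peirce for
    >= 10, none below 3), then averaged; the replicate CV (sample sd / mean)
    and retained count are recorded per time point.  Time points left empty
    after filtering are missing.
    """
    genes = ratios.index
    arrays_by_label = {lab: meta.arrays_for(lab) for lab in grid.labels}
    for lab, arrs in arrays_by_label.items():
        missing_cols = [a for a in arrs if a not in ratios.columns]
        if missing_cols:
            raise ValueError(f"arrays {missing_cols} for {lab} absent from ratio table")

    n_genes, n_t = len(genes), len(grid)
    vals = np.full((n_genes, n_t), np.nan)
    cvs = np.full((n_genes, n_t), np.nan)
    used = np.zeros((n_genes, n_t), dtype=int)

    col_arrays = {lab: ratios[arrs].to_numpy(dtype=float) for lab, arrs in arrays_by_label.items()}
    for j, lab in enumerate(grid.labels):
        block = col_arrays[lab]
        for i in range(n_genes):
            reps = block[i]
            reps = reps[np.isfinite(reps)]
            if reps.size == 0:
                continue
            kept = _filter_replicates(reps)
            vals[i, j] = kept.mean()
            used[i, j] = kept.size
            if kept.size >= 2 and kept.mean() != 0:
                cvs[i, j] = kept.std(ddof=1) / kept.mean()

    empty = ~np.isfinite(vals).any(axis=1)
    if empty.any():
        for g in genes[empty]:
            logger.warning("gene %s absent from all arrays; profile omitted", g)
    keep = ~empty
    return ProfileSet(
        grid,
        pd.DataFrame(vals[keep], index=genes[keep], columns=list(grid.labels)),
        pd.DataFrame(cvs[keep], index=genes[keep], columns=list(grid.labels)),
        pd.DataFrame(used[keep], index=genes[keep], columns=list(grid.labels)),
    )


def fill_internal_gaps(profile: GeneProfile, grid: TimeGrid) -> GeneProfile:
    """Linearly interpolate interior missing time points of one profile.

    A missing value flanked (not necessarily adjacently) by present values on
    both sides is interpolated linearly in time; leading/trailing gaps stay
    missing and the profile is flagged incomplete.  Present values are
    untouched.
    """
    v = profile.values.copy()
    finite = np.isfinite(v)
    if finite.all():
        return GeneProfile(profile.gene_id, v, profile.cv.copy(), profile.n_used.copy(), True)
    if not finite.any():
        return GeneProfile(profile.gene_id, v, profile.cv.copy(), profile.n_used.copy(), False)
    t = grid.hours
    first, last = np.flatnonzero(finite)[[0, -1]]
    interior = ~finite & (np.arange(v.size) > first) & (np.arange(v.size) < last)
    if interior.any():
        v[interior] = np.interp(t[interior], t[finite], v[finite])
    complete = bool(np.isfinite(v).all())
    return GeneProfile(profile.gene_id, v, profile.cv.copy(), profile.n_used.copy(), complete)


def fill_gaps_in_set(profiles: ProfileSet) -> ProfileSet:
    """Apply fill_internal_gaps to every profile of a set."""
    vals = profiles.values.copy()
    incomplete: set[str] = set()
    for gid in profiles.gene_ids:
        p = fill_internal_gaps(profiles.profile(gid), profiles.grid)
        vals.loc[gid] = p.values
        if not p.complete:
            incomplete.add(gid)
    return ProfileSet(profiles.grid, vals, profiles.cv.copy(), profiles.n_used.copy(), incomplete)


def normalize_pipeline(
    table: RawExpressionTable,
    meta: ArrayMetadata,
    grid: TimeGrid,
    trim_q: float = 0.02,
) -> ProfileSet:
    """Full preprocessing: normalize arrays, average replicates, fill interior gaps."""
    ratios = normalize_arrays(table, trim_q=trim_q)
    profiles = average_replicates(ratios, meta, grid)
    return fill_gaps_in_set(profiles)
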