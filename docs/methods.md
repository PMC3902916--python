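# Methods

`sigmakin` infers which sigma factors plausibly control which genes (or
groups of genes) during a densely sampled transcriptional time course, such
as bacterial spore germination followed at 30-minute intervals.  This note
documents the models, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Expression profiles from two-channel arrays

Input is a gene × array table of Log2Ratio values (sample channel over a
pooled reference) plus the matching sample-channel intensities and array
metadata (time point, biological replicate).  Each array's Log2Ratio
distribution is centered to median 0 and median absolute deviation 1
(subtract the median, divide by the unscaled MAD), the most extreme 2% of
values at either tail are masked (linear-interpolation quantile
convention), and the centered values are exponentiated back to the ratio
scale.  This presumes the bulk distribution of ratios is stable across
arrays — the usual justification is that most of the transcriptome is not
changing in lockstep; users should check this on their own data.

Per gene and time point, replicate ratios are screened for gross outliers —
Dixon's Q test (r10 statistic, two-sided 95% critical values, one pass) for
3–9 replicates, Peirce's criterion (Gould's iteration) for 10 or more,
nothing below 3 — then averaged.  The replicate coefficient of variation
(sample sd / mean, ratio scale) and retained count are recorded.  An
interior missing time point is linearly interpolated in time; boundary gaps
remain missing and flag the profile incomplete.  Incomplete profiles are
excluded from clustering but may still be attached to cluster cores (see
below).

Two gates then select genes.  The expression gate ranks genes by the median
of their sample-channel intensities over all arrays, bins them by quartiles
(categories I–IV), and drops category I; a dropped gene is rescued when its
maximum sample-channel value reaches the global median of the overall
levels — a scale-free stand-in for "has a pronounced peak", configurable.
The variability gate keeps genes whose replicate CV is below 0.47 at eight
or more of the 13 time points; undefined CVs do not count.

## Consensus kinetic clustering

Profiles are clustered by k-means under the distance 1 − Spearman rho
(average ranks for ties).  Centroids are per-time-point means of member
profiles; an empty cluster is re-seeded with the worst-fitting profile.
Initialization is seeded k-means++ (D²-weighted): uniform seeding rarely
places one seed per well-separated group, so most runs would converge to a
merged local optimum and a consensus over runs would inherit that bias
rather than average it away.

Clustering is repeated (500 runs by default) from different seeds.  The run
with the median within-cluster distance sum J is the reference partition;
every run's clusters are matched to it by greedy maximal member overlap,
and a gene is a core member of the cluster it co-occurs with in at least
50% of runs.  The core profile is the mean profile of core members.

The number of clusters is scanned (n = 30–70 by default) with a jackknife:
at each n, clustering is repeated with 1.5% of profiles omitted at random
and the per-run J recorded (mean ± sd).  The elbow is the n with the
largest second difference of log J — the log scale measures a *relative*
local change, which keeps the steep early part of the curve from always
winning.  If no point shows a pronounced relative change (second difference
below 0.05), a configured default (42) is returned with a warning.

Finally every gated gene is attached to the core whose profile it best
matches by Pearson correlation, if that correlation is ≥ 0.8 (ties to the
lower core id; the correlation is the membership strength).  Genes with
missing boundary points are correlated over their present points (at least
8 of 13); this mirrors the tolerance of real pipelines for profiles with
trimmed extremes.

## The transcription-control model

A target transcript y_i driven by sigma factor R_j follows

    dy_i/dt = k1 / (1 + exp(−(w·R_j(t) + b))) − k2·y_i

with k1 the maximal production rate (expression units/h), k2 the
first-order degradation rate (1/h), w ≥ 0 the regulator weight and b a
reaction-delay/offset.  The sigmoid encodes promoter saturation: production
rises with regulator abundance and plateaus.  R_j(t) is the regulator's
measured profile, interpolated linearly between samples and clamped
outside.  The initial condition is the measured target value at the first
time point (the dormant state).

The equation is integrated with an embedded Dormand–Prince 5(4) pair
(adaptive step control), implemented as a compiled kernel because a fit
evaluates the model tens of thousands of times.  The reporting tolerance is
rtol 1e-8 / atol 1e-11, which keeps the absolute deviation from closed-form
solutions below 1e-6 over the full time course; the annealing search uses a
looser internal tolerance (rtol 1e-4) and the winning parameter set is
always re-simulated at the reporting tolerance.  Tests cross-check the
kernel against `scipy.integrate.solve_ivp` (RK45) and against closed forms.

## Parameter estimation

Fit quality is F = 1 − c, with c the Pearson correlation between the
measured and simulated target profile; minimizing F maximizes c.  A
constant simulated profile scores F = 2 (worst case) so annealing chains
survive degenerate proposals; a constant measured profile is an error.

F is minimized by simulated annealing: Gaussian single-parameter proposals
whose scale shrinks as sqrt(T), Metropolis acceptance, geometric cooling
(T0 = 1, α = 0.95, 200 proposals per temperature, stop at T ≤ 1e-3), and
15 independent restarts from random initial parameters (k1, k2 ∈ (0, 10],
w ∈ (0, 50], b ∈ [−10, 10]); the restart with the lowest F wins.  A chain,
and the remaining restarts, stop early once F ≤ 1e-3 (c ≥ 0.999): a
near-perfect fit cannot improve meaningfully.  Everything is deterministic
given the configuration seed.

Proposals are reflected into bounds: k2 in [0.5, 10]/h, w in [0, 50], b in
[−10, 10], and k1 at 0 only.  The k2 lower bound states that bacterial
transcripts turn over in minutes — and matters numerically: as k2 → 0 the
model degenerates into a pure integrator whose monotone ramp output
correlates above 0.8 with any rising trend regardless of the regulator,
which floods a screen with false positives.  k1 has no upper bound because
the correlation objective is scale-free; k1 only sets scale (relative to
the fixed initial condition) and legitimate fits on MAD-standardized data
can need k1 well above the initial-draw range.

For screens of thousands of candidate pairs a reduced preset
(`screening_fit_config`: 4 restarts, 60 proposals per temperature, stop at
T ≤ 2e-3) trades ~20× runtime for a small loss in fit polish; mid-sized
sigma→core screens run well at 8 restarts and 120 proposals per
temperature.

## Network construction

Every requested regulator–target pair is fitted; an edge is accepted when
c > 0.8, relaxed to c > 0.65 when prior evidence (ChIP binding or
literature) supports the pair — strict inequalities, with the ≥ 0.8 cluster
attachment gate the only non-strict threshold.  Accepted edges carry the
fitted w (drawn as arrow thickness downstream), c, and a `trivial` flag set
when the two *measured* profiles themselves correlate ≥ 0.9: such pairs
show no resolvable delay, so the direction is ambiguous without priors.
Sigma–sigma pairs accepted in both directions with trivial kinetics are
`mutual`; a prior supporting exactly one direction marks it `preferred`,
and both edges are retained.  Multiple edges into one target are
alternatives — equally plausible kinetically — and are never merged or
pruned to a best regulator.  Networks export to GEXF (or GraphML) with node
and edge attributes, loadable in Gephi unmodified.

## Functional enrichment

For each cluster and functional class, a one-sided Fisher exact test
(hypergeometric upper tail) measures over-representation.  A class is
significantly enriched when P < 0.05, the fold change (k/m)/(K/N) exceeds
2, and more than 7 class genes sit in the cluster.  No multiple-testing
correction enters the flag, matching the raw-threshold convention of this
kind of screen; a Benjamini–Hochberg column is emitted alongside for
reference.  A sigma factor is linked to a class when an accepted edge leads
to a cluster in which the class is enriched; all mediating clusters are
kept.  Unannotated universe genes form an implicit "unclassified" class;
multi-class genes are allowed as repeated annotation rows, each gene–class
pair counted once.

## The synthetic benchmark generator

The generator emulates the germination design: 13 time points at 30-min
spacing, 2–3 biological replicates (default 3), multiplicative lognormal
replicate noise (default CV 5%) with mean-one factors, and 1% gross
outliers at 10-fold.  Its populations are

- **regulators** — gamma-shaped activity pulses with stratified, jittered
  peak times, widths 0.25–0.6 h, pairwise Spearman < 0.7.  Narrow,
  temporally separated pulses are what makes a target attributable to the
  right regulator at all; pulses peak inside the sampled window because a
  regulator that merely decays from dormancy drives only relaxation-shaped,
  unattributable targets.
- **targets** — integrated from the transcription model with parameters
  drawn from k1 ∈ [0.5, 10], k2 ∈ [2, 5]/h, w ∈ [1, 50], b ∈ [−10, 10].
  A draw is rejected until its profile is *responsive* (over-time CV ≥
  0.35) and *identifiable* — not mimicked by any regulator-free relaxation
  A + B·e^(−k2 t) at correlation > 0.8 (a one-dimensional scan, since the
  Pearson objective absorbs the affine part).  A flat or relaxation-shaped
  target carries no recoverable signature of its regulator, so it cannot
  constitute planted truth.  By default all targets of a regulator share
  one parameter set and initial state up to ±5% jitter (a co-expressed
  regulon whose base profiles are mutually distinct, Spearman < 0.7);
  independent per-target draws are available for screen benchmarks.
- **decoys** — stationary Gaussian-process profiles on the log scale
  (squared-exponential kernel, sd 0.4, length scale 0.45 h): unregulated
  genes with ~1.5-fold wiggles, the screen's true negatives.
- **remodeling background** — smooth large-amplitude drifts (sd 1.0,
  length scale 0.7 h) standing in for genes driven by unmodeled
  regulators.  They give each array's value distribution realistic tails,
  so the 2% trim does not systematically amputate the planted genes'
  extremes.

Array emulation: the pooled reference of a gene is its mean true abundance
over the course; both channels see an additive probe-level floor (20% of
the gene's mean), compressing extreme ratios the way background
hybridization does; each gene's sample-channel brightness is an independent
lognormal draw (median 500) to which its median signal is calibrated —
brightness is independent of kinetic shape, which is what lets the
peak-rescue rule do its intended job for dim but pulsed genes.  Functional
classes (10 by default) are uniform in the background and over-sampled by a
factor of 7 within each regulon — regulons are strongly functionally
coherent.  A separate generator provides pure kinetic shape groups
(log-scale monotone and quarter-phase sinusoid archetypes with no flat
stretches, so small multiplicative noise cannot scramble within-group
ranks) for clustering benchmarks.

Everything is deterministic under a fixed seed, to the byte after a
write/read round trip.

**What passing benchmarks show — and what they do not.**  The planted
fixtures are *identifiable by construction*: regulators are temporally
separated, targets are shaped so that only regulator timing explains them,
and noise is well behaved.  Real expression data offers no such guarantees
— sigma factors with overlapping activity windows are genuinely
indistinguishable on kinetic grounds (the screen reports such alternatives
as equally plausible, including `trivial` same-shape pairs), and a
correlation threshold has no statistical error control.  The benchmarks
validate the machinery (normalization contracts, solver accuracy, optimizer
recovery, consensus behavior, exact Fisher tails), not the biological
error rate of any real screen.

## Problem sizes of the standard checks

The test suite and `scripts/acceptance.py` run on one CPU in minutes using:
100 closed-form parameter draws; 50 (suite) / 20 (script) regulator–target
fit recoveries at 15 restarts, noise-free and at 10% noise; a planted
screen of 5×40 targets + 100 decoys at 5% noise (suite) or 4×20 + 60
(script) with the screening preset; 6×60 planted kinetic groups with a
100-run consensus and a jackknifed n = 2–10 scan; 40 random Fisher tables
with N ≤ 200 against a brute-force tail sum; and a full pipeline run on the
default fixture (suite: 5×40 regulon targets + 600 decoys + 200 background;
script: 5×25 + 300 + 100) clustered at n = 18 (script: 14) with 100
consensus runs.

## Known limitations

- One regulator per target; no combinatorial control, no anti-sigma-factor
  layer, no protein-level latent activity.
- Pearson acceptance is scale-free: a fit can track shape at a biologically
  absurd amplitude.  The thresholds carry no significance model.
- The elbow rule needs a pronounced relative change in J(n); diffuse data
  fall back to the configured default.
- The per-array median/MAD centering assumes a time-stable bulk
  distribution; data dominated by a synchronized global trend will have
  that trend partially removed.
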