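# sigmakin

Inference of sigma-factor–controlled transcriptional networks from dense
expression time series.

In bacteria, transcription initiation is steered by sigma factors: proteins
that dock onto RNA polymerase and direct it to specific promoters.  Given a
replicated two-channel microarray time course — for example a germinating
*Streptomyces* culture sampled every 30 minutes — `sigmakin` asks which
sigma factors could plausibly drive which genes, on purely kinetic grounds,
and which functional classes of genes each sigma factor thereby controls.

The pipeline: per-array normalization (median/MAD centering, 2% tail trim,
exponentiation) and replicate averaging with outlier rejection (Dixon Q /
Peirce); expression-level and replicate-CV gene gates; consensus k-means
clustering under Spearman distance with 50% core extraction and a
jackknifed elbow for the cluster count; and a kinetic screen built on the
transcription-control model

    dy/dt = k1 / (1 + exp(−(w·R(t) + b))) − k2·y

where R(t) is the sigma factor's expression profile, w its regulatory
weight, b a reaction delay, k1 the maximal production rate and k2 the
degradation rate.  Parameters are fitted per regulator–target pair by
multi-restart simulated annealing minimizing F = 1 − c (c = Pearson
correlation of measured vs simulated target profile).  A pair is accepted
when c > 0.8, relaxed to c > 0.65 when ChIP or literature priors support
it.  Accepted edges — with weight w, trivial/mutual flags and prior
annotations — export to GEXF for Gephi, and Fisher-exact enrichment
(P < 0.05, fold change > 2, more than 7 class genes in the cluster) links
sigma factors to the functional classes of the clusters they control.

A ground-truthed synthetic data generator reproduces the statistical
structure of the study design (13 time points, 2–3 replicates,
multiplicative noise, gross outliers, co-expressed regulons, planted
functional enrichment) and backs the test suite end to end.

See `docs/methods.md` for models, defaults, and the design rationale.

## Worked example

Generate a synthetic germination data set with five sigma factors driving
25-gene regulons among 400 unregulated genes, then run the whole screen:

```python
from sigmakin import SyntheticSpec, make_dataset
from sigmakin.pipeline import PipelineConfig, run_pipeline
from sigmakin.clustering import ClusteringConfig
from sigmakin.network import ScreenConfig
from sigmakin.kinetics import FitConfig

spec = SyntheticSpec(targets_per_regulator=25, n_decoys=300, n_background=100, rng_seed=1)
ds = make_dataset(spec)
cfg = PipelineConfig(
    clustering=ClusteringConfig(n_clusters=14, n_runs=100, rng_seed=0),
    screen=ScreenConfig(fit=FitConfig(seed=0)),
)
res = run_pipeline(ds.raw, ds.meta, ds.grid, ds.regulator_ids, ds.annotation, config=cfg)
```

On this fixture the run prints (abridged):

```
profiles: 530 genes; highly expressed: 468; low-CV: 527
consensus cores: 12; genes attached at r >= 0.8: 192
edge SIG01 -> core 4: c = 0.999, w = 8.6, trivial = False
edge SIG02 -> core 6: c = 0.994, w = 2.9, trivial = False
edge SIG03 -> core 0: c = 0.997, w = 6.6, trivial = False
edge SIG04 -> core 1: c = 0.999, w = 4.2, trivial = False
edge SIG05 -> core 3: c = 0.988, w = 0.8, trivial = True
...
enriched: core 0 x CLASS03: k=14/44, fold=3.3, P=9.8e-06
enriched: core 1 x CLASS04: k=20/53, fold=2.7, P=2.6e-06
enriched: core 3 x CLASS05: k=20/51, fold=3.3, P=4.3e-08
enriched: core 4 x CLASS01: k=18/59, fold=2.6, P=2.1e-05
enriched: core 6 x CLASS02: k=18/41, fold=3.6, P=8.2e-08
```

Reading it: 530 measured genes survive normalization; the gates keep most
of them.  Consensus clustering finds 12 kinetic cores; each of the five
planted regulons ends up in its own core, and the screen connects every
sigma factor to its regulon's core with c ≈ 0.99 (additional lower-c edges
are kinetically plausible alternatives, which the method deliberately
keeps; the `trivial` flag marks a regulator–core pair whose measured
profiles are themselves nearly identical, so the direction is ambiguous).
Each regulon's core is significantly enriched for exactly the functional
class planted into it — the (sigma factor → functional class) links that
are the screen's final product.

The same flow is available from the shell:

```
sigmakin simulate --seed 1 --out-dir fx/
sigmakin normalize --expr fx/log2ratio.tsv --signal fx/sample_signal.tsv \
    --meta fx/arrays.tsv --grid fx/time_grid.tsv --out-dir profiles/
sigmakin filter --profiles profiles/ --signal fx/sample_signal.tsv --out-dir gates/
sigmakin cluster --profiles profiles/ --n 14 --runs 100 --seed 0 --out-dir clusters/
sigmakin fit --profiles profiles/ --regulators fx/sigma_factors.txt \
    --target-profiles clusters/core_profiles.tsv --priors fx/priors.tsv --out edges.tsv
sigmakin network --edges edges.tsv --gexf net.gexf
sigmakin enrich --membership clusters/membership.tsv --annot fx/annotation.tsv --out enrich.tsv
```

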