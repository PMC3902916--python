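"""One-call orchestration of the full inference pipeline.

normalize -> expression/CV gates -> consensus clustering -> core assignment
-> sigma-to-core kinetic screen -> functional enrichment.  Mirrors the CLI
subcommands for callers who start from in-memory tables (e.g. the synthetic
generator's output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .clustering import ClusteringConfig, ClusterCore, assign_to_cores, consensus_cluster
from .enrichment import EnrichmentResult, cluster_enrichments
from .filters import ExpressionSummary, select_highly_expressed, select_low_cv
from .grid import TimeGrid
from .network import RegulatoryEdge, ScreenConfig, screen_regulations
from .preprocess import ArrayMetadata, ProfileSet, RawExpressionTable, normalize_pipeline

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    trim_q: float = 0.02
    cv_max: float = 0.47
    min_cv_points: int = 8
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)


@dataclass
class PipelineResult:
    profiles: ProfileSet
    expression_summary: ExpressionSummary
    low_cv_genes: list[str]
    kept_genes: list[str]  # gated genes used for assignment/enrichment
    cores: list[ClusterCore]
    edges: list[RegulatoryEdge]  # sigma -> core
    enrichments: list[EnrichmentResult]

    def gene_cluster(self) -> dict[str, int]:
        """Gene -> core id over members and post-hoc assignments."""
        out: dict[str, int] = {}
        for c in self.cores:
            for g in c.member_gene_ids:
                out[g] = c.core_id
            for g in c.assigned:
                out.setdefault(g, c.core_id)
        return out

    def implied_gene_edges(self) -> set[tuple[str, str]]:
        """(sigma, gene) pairs implied by accepted sigma -> core edges."""
        members = {
            c.core_id: set(c.member_gene_ids) | set(c.assigned) for c in self.cores
        }
        return {
            (e.regulator_id, g) for e in self.edges for g in members[e.target_id]
        }


def run_pipeline(
    raw: RawExpressionTable,
    meta: ArrayMetadata,
    grid: TimeGrid,
    sigma_ids: list[str],
    annotation: pd.DataFrame | None = None,
    priors=None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full screen from raw arrays to sigma-linked enriched clusters.

    Clustering uses genes passing both gates with complete profiles; core
    assignment additionally admits gated genes with interior-complete
    profiles (missing boundary points are tolerated).  Sigma factors are
    measured genes: their recovered profiles drive the kinetic screen
    against the core profiles.
    """
    profiles = normalize_pipeline(raw, meta, grid, trim_q=config.trim_q)
    summary = select_highly_expressed(raw.sample_signal.loc[profiles.gene_ids])
    low_cv = select_low_cv(profiles.cv, cv_max=config.cv_max, min_points=config.min_cv_points)
    gated = set(summary.kept_genes) & set(low_cv)
    complete = set(profiles.complete_values().index)
    sigma_set = set(sigma_ids)

    cluster_genes = [
        g for g in profiles.gene_ids if g in gated and g in complete and g not in sigma_set
    ]
    cores = consensus_cluster(profiles.values.loc[cluster_genes], config.clustering)
    kept = [g for g in profiles.gene_ids if g in gated and g not in sigma_set]
    cores = assign_to_cores(
        profiles.values.loc[kept], cores, assign_r_min=config.clustering.assign_r_min
    )

    usable_sigmas = [s for s in sigma_ids if s in complete]
    for s in sigma_set - set(usable_sigmas):
        logger.warning("sigma factor %s has an incomplete profile; excluded from screen", s)
    core_profiles = pd.DataFrame(
        [c.core_profile for c in cores],
        index=[c.core_id for c in cores],
        columns=list(grid.labels),
    )
    edges = screen_regulations(
        profiles.values.loc[usable_sigmas],
        core_profiles,
        grid,
        priors=priors,
        config=config.screen,
        target_kind="cluster",
    )

    enrichments: list[EnrichmentResult] = []
    if annotation is not None:
        members = {c.core_id: sorted((set(c.member_gene_ids) | set(c.assigned)) & set(kept)) for c in cores}
        enrichments = cluster_enrichments(members, annotation, kept)

    return PipelineResult(profiles, summary, low_cv, kept, cores, edges, enrichments)
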