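"""Functional-class enrichment of kinetic clusters (one-sided Fisher test).

For each cluster and functional class the 2x2 table
[[k, m-k], [K-k, N-m-(K-k)]] is tested for over-representation (k class
genes among the m cluster genes, K class genes among the N universe genes).
A class is significantly enriched when P < 0.05, the fold change
(k/m)/(K/N) exceeds 2 and more than 7 class genes sit in the cluster.
Sigma factors are then linked to the classes enriched in the clusters they
kinetically control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "significant_classes",
    "link_sigma_functions",
    "enrichment_table",
]

UNCLASSIFIED = "unclassified"


@dataclass
class EnrichmentResult:
    """One (cluster, functional class) Fisher-test record."""

    cluster_id: object
    class_label: str
    k: int  # class genes in the cluster
    m: int  # cluster size
    K: int  # class genes in the universe
    N: int  # universe size
    p_value: float
    fold_change: float
    significant: bool = False


def _class_map(annotation: pd.DataFrame, universe: list[str]) -> dict[str, set[str]]:
    """class -> set of genes, with unannotated universe genes as 'unclassified'."""
    ann = annotation[annotation["gene"].isin(universe)]
    classes: dict[str, set[str]] = {}
    for gene, label in zip(ann["gene"], ann["class"]):
        classes.setdefault(str(label), set()).add(gene)
    annotated = set(ann["gene"])
    rest = set(universe) - annotated
    if rest:
        classes.setdefault(UNCLASSIFIED, set()).update(rest)
    return classes


def fisher_enrichment(
    cluster_members: list[str],
    annotation: pd.DataFrame,
    universe: list[str],
) -> list[EnrichmentResult]:
    """One-sided Fisher exact test per class present in the universe.

    ``annotation`` is a two-column frame (gene, class); a gene may appear in
    several classes as repeated rows, each gene-class pair counted once.
    The p-value is the hypergeometric upper tail P(X >= k).
    """
    cluster = set(cluster_members)
    if not cluster <= set(universe):
        raise ValueError("cluster members must be a subset of the universe")
    if not cluster:
        return []
    n_univ = len(universe)
    m = len(cluster)
    results = []
    for label, genes in sorted(_class_map(annotation, universe).items()):
        big_k = len(genes)
        k = len(genes & cluster)
        # upper-tail hypergeometric: P(X >= k) drawing m from N with K successes
        p = float(stats.hypergeom.sf(k - 1, n_univ, big_k, m))
        fold = (k / m) / (big_k / n_univ) if big_k > 0 else 0.0
        results.append(EnrichmentResult(None, label, k, m, big_k, n_univ, p, fold))
    return results


def significant_classes(
    results: list[EnrichmentResult],
    p_max: float = 0.05,
    fc_min: float = 2.0,
    k_min_exclusive: int = 7,
) -> list[EnrichmentResult]:
    """Apply the significance gate: P < p_max, fold change > fc_min, k > 7."""
    kept = []
    for r in results:
        r.significant = (
            r.p_value < p_max and r.fold_change > fc_min and r.k > k_min_exclusive
        )
        if r.significant:
            kept.append(r)
    return kept


def cluster_enrichments(
    clusters: dict[object, list[str]],
    annotation: pd.DataFrame,
    universe: list[str],
    p_max: float = 0.05,
    fc_min: float = 2.0,
    k_min_exclusive: int = 7,
) -> list[EnrichmentResult]:
    """Fisher enrichment of every cluster, with the significance flag set."""
    all_results: list[EnrichmentResult] = []
    for cid, members in clusters.items():
        results = fisher_enrichment(members, annotation, universe)
        for r in results:
            r.cluster_id = cid
        significant_classes(results, p_max, fc_min, k_min_exclusive)
        all_results.extend(results)
    return all_results


def link_sigma_functions(edges, enriched: list[EnrichmentResult]) -> pd.DataFrame:
    """Associate sigma factors with classes enriched in clusters they control.

    Sigma S is linked to class C through cluster L iff an accepted edge
    S -> L exists and C is significantly enriched in L.  Every mediating
    cluster is retained (alternatives, not simultaneous control).
    """
    by_cluster: dict[object, list[EnrichmentResult]] = {}
    for r in enriched:
        if r.significant:
            by_cluster.setdefault(r.cluster_id, []).append(r)
    rows = []
    for e in edges:
        for r in by_cluster.get(e.target_id, []):
            rows.append(
                {
                    "sigma": e.regulator_id,
                    "class": r.class_label,
                    "cluster_id": r.cluster_id,
                    "edge_c": e.c,
                    "p_value": r.p_value,
                    "fold_change": r.fold_change,
                }
            )
    return pd.DataFrame(rows, columns=["sigma", "class", "cluster_id", "edge_c", "p_value", "fold_change"])


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """All results as a frame, with a supplementary BH-adjusted p column."""
    df = pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "class": r.class_label,
                "k": r.k,
                "m": r.m,
                "K": r.K,
                "N": r.N,
                "p_value": r.p_value,
                "fold_change": r.fold_change,
                "significant": r.significant,
            }
            for r in results
        ]
    )
    if not df.empty:
        df["p_bh"] = stats.false_discovery_control(df["p_value"].to_numpy(), method="bh")
    return df
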