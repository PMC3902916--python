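"""Regulatory-network construction from kinetic fits.

Every requested regulator-target pair is fitted with the sigmoid ODE model;
an edge is accepted when the Pearson correlation between the measured and
modeled target profile exceeds 0.8, relaxed to 0.65 when external prior
evidence (ChIP binding or literature) supports the pair.  Edges whose two
measured profiles are themselves highly correlated are flagged trivial
(direction ambiguous); sigma-sigma pairs accepted in both directions with
trivial kinetics are flagged mutual, and a one-sided prior marks the
supported direction as preferred.  Multiple edges into one target are
alternatives, never merged.  Networks export to GEXF for Gephi, with edge
weight equal to the model's regulator weight w.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import UnresolvableIdentifiersError
from .grid import TimeGrid
from .kinetics import FitConfig, FitResult, anneal_fit, classify_trivial, spawn_fit_config

logger = logging.getLogger(__name__)

__all__ = [
    "PriorInteraction",
    "RegulatoryEdge",
    "ScreenConfig",
    "screen_regulations",
    "sigma_sigma_network",
    "export_network",
    "edges_to_dataframe",
    "select_profiles",
]


@dataclass(frozen=True)
class PriorInteraction:
    """External evidence for one regulator-target pair."""

    regulator_id: str
    target_id: str
    source: str  # "chip" | "literature"
    citation: str = ""

    def __post_init__(self):
        if self.source not in ("chip", "literature"):
            raise ValueError("prior source must be 'chip' or 'literature'")


@dataclass
class RegulatoryEdge:
    """A kinetically plausible regulator -> target relation."""

    regulator_id: str
    target_id: str
    target_kind: str  # "gene" | "cluster" | "sigma"
    w: float
    c: float
    trivial: bool
    prior_source: str = "none"
    accepted_threshold: float = 0.8
    mutual: bool = False
    preferred: bool = False


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and fit settings of the pairwise screen."""

    fit: FitConfig = field(default_factory=FitConfig)
    r_accept: float = 0.8
    r_accept_prior: float = 0.65
    r_trivial: float = 0.9


def screening_fit_config(seed: int = 0) -> FitConfig:
    """Reduced-effort annealing preset for large pairwise screens.

    Same model and acceptance rules; fewer restarts and proposals per
    temperature, sized for screens of a few thousand candidate pairs.
    """
    return FitConfig(seed=seed, n_restarts=4, n_per_temp=60, t_min=2e-3)


def select_profiles(values: pd.DataFrame, ids: list[str]) -> pd.DataFrame:
    """Rows of a profile table by id; unknown identifiers raise, listing offenders."""
    missing = [i for i in ids if i not in values.index]
    if missing:
        raise UnresolvableIdentifiersError(missing)
    return values.loc[ids]


def _prior_map(priors: list[PriorInteraction] | None) -> dict[tuple[str, str], str]:
    out: dict[tuple[str, str], str] = {}
    for p in priors or []:
        key = (p.regulator_id, p.target_id)
        # chip evidence outranks literature when both exist for a pair
        if key not in out or (p.source == "chip" and out[key] == "literature"):
            out[key] = p.source
    return out


def screen_regulations(
    regulators: pd.DataFrame,
    targets: pd.DataFrame,
    grid: TimeGrid,
    priors: list[PriorInteraction] | None = None,
    config: ScreenConfig = ScreenConfig(),
    target_kind: str = "gene",
    return_fits: bool = False,
) -> list[RegulatoryEdge] | tuple[list[RegulatoryEdge], list[FitResult]]:
    """Fit every regulator-target pair and keep the kinetically plausible edges.

    Acceptance: c > 0.8 without prior evidence, c > 0.65 with it (strict
    inequalities).  Self-pairs are skipped.  Each accepted edge carries the
    fitted regulator weight w, the correlation, a trivial flag and the prior
    source.  Deterministic given the fit config seed and input order.
    """
    pmap = _prior_map(priors)
    edges: list[RegulatoryEdge] = []
    fits: list[FitResult] = []
    reg_mat = regulators.to_numpy(dtype=float)
    tgt_mat = targets.to_numpy(dtype=float)
    for i, rid in enumerate(regulators.index):
        for j, tid in enumerate(targets.index):
            if rid == tid:
                continue
            fit = anneal_fit(
                tgt_mat[j], reg_mat[i], grid,
                spawn_fit_config(config.fit, i, j),
                regulator_id=rid, target_id=tid,
            )
            if return_fits:
                fits.append(fit)
            source = pmap.get((rid, tid), "none")
            threshold = config.r_accept_prior if source != "none" else config.r_accept
            if fit.c > threshold:
                edges.append(
                    RegulatoryEdge(
                        regulator_id=rid,
                        target_id=tid,
                        target_kind=target_kind,
                        w=fit.params.w,
                        c=fit.c,
                        trivial=classify_trivial(reg_mat[i], tgt_mat[j], config.r_trivial),
                        prior_source=source,
                        accepted_threshold=threshold,
                    )
                )
    if return_fits:
        return edges, fits
    return edges


def sigma_sigma_network(
    sigma_profiles: pd.DataFrame,
    grid: TimeGrid,
    priors: list[PriorInteraction] | None = None,
    config: ScreenConfig = ScreenConfig(),
) -> list[RegulatoryEdge]:
    """Screen all ordered sigma-sigma pairs and resolve mutual regulations.

    When both directions of a pair are accepted and both are trivial, the
    pair is mutual (two opposing arrows).  If a prior supports exactly one
    direction of a mutual pair, that direction is marked preferred; both
    edges are retained.
    """
    if len(sigma_profiles) < 2:
        raise ValueError("need >= 2 sigma profiles")
    edges = screen_regulations(
        sigma_profiles, sigma_profiles, grid, priors, config, target_kind="sigma"
    )
    by_pair = {(e.regulator_id, e.target_id): e for e in edges}
    pmap = _prior_map(priors)
    for (a, b), e in by_pair.items():
        back = by_pair.get((b, a))
        if back is not None and e.trivial and back.trivial:
            e.mutual = True
            back.mutual = True
            if ((a, b) in pmap) != ((b, a) in pmap):
                (e if (a, b) in pmap else back).preferred = True
    return edges


def edges_to_dataframe(edges: list[RegulatoryEdge]) -> pd.DataFrame:
    cols = [
        "regulator_id", "target_id", "target_kind", "w", "c",
        "trivial", "mutual", "preferred", "prior_source", "accepted_threshold",
    ]
    return pd.DataFrame([{k: getattr(e, k) for k in cols} for e in edges], columns=cols)


def export_network(
    edges: list[RegulatoryEdge],
    path: str,
    node_metadata: dict[str, dict] | None = None,
    fmt: str = "gexf",
) -> nx.DiGraph:
    """Write the network as GEXF (or GraphML) with Gephi-ready attributes.

    Edge weight is the model's regulator weight w (the paper draws arrow
    thickness proportional to it); c, trivial, mutual and prior_source ride
    along as attributes.  Node attributes come from ``node_metadata``
    (e.g. kind: sigma|cluster|gene, expression category).
    """
    g = nx.DiGraph()
    node_metadata = node_metadata or {}
    for e in edges:
        for node, default_kind in ((e.regulator_id, "sigma"), (e.target_id, e.target_kind)):
            if node not in g:
                meta = dict(node_metadata.get(node, {}))
                meta.setdefault("kind", default_kind)
                g.add_node(node, **{k: _scalarize(v) for k, v in meta.items()})
        g.add_edge(
            e.regulator_id,
            e.target_id,
            weight=float(e.w),
            c=float(e.c),
            trivial=bool(e.trivial),
            mutual=bool(e.mutual),
            preferred=bool(e.preferred),
            prior_source=e.prior_source,
        )
    for node, meta in node_metadata.items():
        if node not in g:
            g.add_node(node, **{k: _scalarize(v) for k, v in meta.items()})
    if fmt == "gexf":
        nx.write_gexf(g, path)
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError("fmt must be 'gexf' or 'graphml'")
    return g


def _scalarize(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v
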