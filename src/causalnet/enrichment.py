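"""Topology-based pathway enrichment over a protein interaction network.

A random walk with restart (RWR) from a seed protein set assigns every
network node a stationary visiting probability. Pathways are then scored by
how much their members' average (genome-mean-normalized) visiting probability
deviates from the average pathway — an XD-style score, where values above a
threshold (default 1) mark pathways topologically close to the seed set. A
one-sided exact hypergeometric overlap test with Benjamini-Hochberg
correction complements the topological score.

The walk iterates ``s <- (1 - r) W s + r e`` where ``W`` is the
column-normalized, confidence-weighted adjacency matrix, ``e`` the uniform
restart distribution over the seeds, and ``r`` the restart probability.
Columns of degree-zero nodes restart to ``e`` so the score vector stays on
the probability simplex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import Pathway
from .network_causal import ProteinNetwork

logger = logging.getLogger("causalnet")


class ConvergenceError(RuntimeError):
    """The walk did not reach the tolerance within the iteration budget."""


@dataclass(frozen=True)
class EnrichmentConfig:
    restart_prob: float = 0.5
    tol: float = 1e-10
    max_iter: int = 1000
    min_overlap: int = 1
    xd_threshold: float = 1.0

    def __post_init__(self):
        if not 0 < self.restart_prob <= 1:
            raise ValueError("restart_prob must be in (0, 1]")
        if self.tol <= 0 or self.max_iter < 1 or self.min_overlap < 0:
            raise ValueError("invalid enrichment configuration")


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    name: str
    xd_score: float
    overlap: int
    pathway_size_in_network: int
    fisher_p: float
    q_value: float
    significant_xd: bool


def rwr(
    network: ProteinNetwork,
    seeds: Iterable[str],
    config: EnrichmentConfig | None = None,
) -> dict[str, float]:
    """Stationary visiting probabilities of a restart walk from ``seeds``.

    The returned scores sum to one over the network nodes. Raises if no seed
    is a network node or if the power iteration fails to converge.
    """
    config = config or EnrichmentConfig()
    nodes = sorted(network.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    seeds_in = sorted({s for s in seeds if s in index})
    if not seeds_in:
        raise ValueError("no seed protein is present in the network")
    n = len(nodes)
    adjacency = np.zeros((n, n))
    for a, b, data in network.graph.edges(data=True):
        i, j = index[a], index[b]
        adjacency[i, j] = adjacency[j, i] = data["weight"]

    restart = np.zeros(n)
    restart[[index[s] for s in seeds_in]] = 1.0 / len(seeds_in)

    column_sums = adjacency.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        transition = np.where(column_sums > 0, adjacency / column_sums, 0.0)
    for j in np.flatnonzero(column_sums == 0):
        transition[:, j] = restart  # dangling nodes hand the walker back to the seeds

    r = config.restart_prob
    scores = restart.copy()
    for _ in range(config.max_iter):
        updated = (1.0 - r) * transition @ scores + r * restart
        residual = float(np.abs(updated - scores).sum())
        scores = updated
        if residual < config.tol:
            break
    else:
        raise ConvergenceError(
            f"random walk did not converge in {config.max_iter} iterations "
            f"(L1 residual {residual:.3e})"
        )
    return {node: float(scores[index[node]]) for node in nodes}


def rwr_linear_solve(
    network: ProteinNetwork,
    seeds: Iterable[str],
    config: EnrichmentConfig | None = None,
) -> dict[str, float]:
    """Closed-form stationary vector ``s = r (I - (1-r) W)^-1 e``.

    Dense direct solve of the same fixed point the power iteration targets;
    intended for small networks and cross-checks.
    """
    config = config or EnrichmentConfig()
    nodes = sorted(network.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    seeds_in = sorted({s for s in seeds if s in index})
    if not seeds_in:
        raise ValueError("no seed protein is present in the network")
    n = len(nodes)
    adjacency = np.zeros((n, n))
    for a, b, data in network.graph.edges(data=True):
        i, j = index[a], index[b]
        adjacency[i, j] = adjacency[j, i] = data["weight"]
    restart = np.zeros(n)
    restart[[index[s] for s in seeds_in]] = 1.0 / len(seeds_in)
    column_sums = adjacency.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        transition = np.where(column_sums > 0, adjacency / column_sums, 0.0)
    for j in np.flatnonzero(column_sums == 0):
        transition[:, j] = restart
    r = config.restart_prob
    scores = r * np.linalg.solve(np.eye(n) - (1.0 - r) * transition, restart)
    return {node: float(scores[index[node]]) for node in nodes}


def xd_scores(
    node_scores: Mapping[str, float],
    pathways: list[Pathway],
    network: ProteinNetwork,
    min_overlap: int = 1,
) -> tuple[dict[str, float], list[str]]:
    """Per-pathway deviation scores from the walk's node probabilities.

    Node scores are rescaled so their mean over all network nodes is one; a
    pathway's raw score is the mean rescaled score of its in-network members,
    and its XD score is the raw score minus the mean raw score across all
    scored pathways (so XD scores sum to zero). Pathways with fewer than
    ``min_overlap`` in-network members are skipped and reported.
    """
    nodes = network.nodes
    n = len(nodes)
    scaled = {node: node_scores[node] * n for node in nodes}
    raw: dict[str, float] = {}
    skipped: list[str] = []
    for pathway in pathways:
        members = sorted(pathway.members & nodes)
        if len(members) < max(min_overlap, 1):
            skipped.append(pathway.pathway_id)
            continue
        raw[pathway.pathway_id] = float(np.mean([scaled[m] for m in members]))
    if not raw:
        raise ValueError("no pathway has members in the network")
    grand_mean = float(np.mean(list(raw.values())))
    xd = {pid: score - grand_mean for pid, score in raw.items()}
    if skipped:
        logger.info("xd_scores: skipped %d pathways with no in-network members", len(skipped))
    return xd, skipped


def fisher_overlap(seeds: Iterable[str], pathway_members: Iterable[str], universe: Iterable[str]) -> float:
    """One-sided exact overlap p-value: P[overlap >= observed] under sampling
    without replacement from the network node universe."""
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe must be non-empty")
    seed_set = set(seeds) & universe_set
    members = set(pathway_members) & universe_set
    overlap = len(seed_set & members)
    return float(hypergeom.sf(overlap - 1, len(universe_set), len(members), len(seed_set)))


def bh_qvalues(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    ps = list(p_values)
    if not ps:
        return []
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(ps, method="fdr_bh")[1])


def enrich(
    network: ProteinNetwork,
    seeds: Iterable[str],
    pathways: list[Pathway],
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Full topological enrichment: RWR, XD scores, overlap tests, BH.

    Results are sorted by descending XD score then pathway id;
    ``significant_xd`` flags pathways above the XD threshold.
    """
    config = config or EnrichmentConfig()
    seeds = sorted(set(seeds))
    node_scores = rwr(network, seeds, config)
    xd, _ = xd_scores(node_scores, pathways, network, config.min_overlap)
    nodes = network.nodes
    seed_set = set(seeds) & nodes
    scored = [p for p in pathways if p.pathway_id in xd]
    p_values = [fisher_overlap(seed_set, p.members, nodes) for p in scored]
    q_values = bh_qvalues(p_values)
    results = [
        EnrichmentResult(
            pathway_id=p.pathway_id,
            name=p.name,
            xd_score=xd[p.pathway_id],
            overlap=len(seed_set & p.members & nodes),
            pathway_size_in_network=len(p.members & nodes),
            fisher_p=pv,
            q_value=qv,
            significant_xd=xd[p.pathway_id] > config.xd_threshold,
        )
        for p, pv, qv in zip(scored, p_values, q_values)
    ]
    results.sort(key=lambda r: (-r.xd_score, r.pathway_id))
    logger.info(
        "enrichment: %d pathways scored, %d above XD threshold",
        len(results),
        sum(r.significant_xd for r in results),
    )
    return results
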