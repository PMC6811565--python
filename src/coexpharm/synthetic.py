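"""Synthetic multi-tissue expression data, interactome and drug sets with known truth.

The generator plants the statistical structure the downstream analyses are
built to detect, so every stage has a recovery test with ground truth:

* **Expression**: each planted module m in tissue t has one latent factor
  f_{t,m} per sample (a one-factor model — the module eigengene is exactly
  the factor). Gene g in module m has loading u_g and expression
  ``x = u_g * f + sqrt(1 - u_g^2) * eps``, so the pairwise correlation of two
  member genes is u_g * u_g' and hub genes (high u_g) track the factor most
  closely. For *disease* modules the factor is shifted by ``trait_shift`` in
  class-1 samples, which makes hub genes the most trait-correlated — the
  structure the gene-significance / connectivity correlation is designed to
  pick up. Module membership is identical across tissues; the factors are
  redrawn per tissue. Background genes are pure standard-normal noise.

* **Interactome**: preferential-attachment growth (heavy-tailed degrees) with
  a connected disease neighborhood planted as a breadth-first ball around a
  high-degree node.

* **Drugs**: proximal drugs target the disease neighborhood and its direct
  neighbors; distal drugs target nodes at graph distance >= 3 from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .types import DrugRecord, ExpressionDataset, Interactome

logger = logging.getLogger(__name__)

__all__ = ["SyntheticTruth", "simulate_multitissue", "simulate_interactome", "simulate_drugs"]

#: Background (non-module) label in the planted membership.
BACKGROUND = 0


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic scenario, filled in by the generators."""

    module_membership: dict[str, int] = field(default_factory=dict)
    disease_modules: set[int] = field(default_factory=set)
    hub_strength: dict[str, float] = field(default_factory=dict)
    disease_neighborhood: set[str] = field(default_factory=set)
    drug_class: dict[str, str] = field(default_factory=dict)

    def planted_module_genes(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for g, m in self.module_membership.items():
            if m != BACKGROUND:
                out.setdefault(m, set()).add(g)
        return out


def simulate_multitissue(
    n_tissues: int,
    n_genes: int,
    n_samples_per_class: int,
    module_sizes: list[int],
    within_cor: float,
    trait_shift: float,
    seed: int,
    n_disease_modules: int = 1,
    truth: SyntheticTruth | None = None,
) -> tuple[list[ExpressionDataset], SyntheticTruth]:
    """Generate expression for several tissues sharing planted modules.

    Parameters
    ----------
    within_cor
        Target within-module pairwise correlation; loadings u_g are drawn
        uniformly in [0.8*sqrt(within_cor), min(1, 1.2*sqrt(within_cor))] so
        E[cor(g, g')] ~ within_cor for two module members.
    trait_shift
        Shift added to the latent factor of disease modules in class-1
        samples (units of the factor's standard deviation).
    n_disease_modules
        The first this-many planted modules are disease modules.
    """
    if sum(module_sizes) > n_genes:
        raise ValueError("sum(module_sizes) exceeds n_genes")
    if any(s < 3 for s in module_sizes):
        raise ValueError("module sizes below 3 are not allowed")
    if trait_shift < 0:
        raise ValueError("trait_shift must be >= 0")
    if not 0 < within_cor < 1:
        raise ValueError("within_cor must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    if truth is None:
        truth = SyntheticTruth()
    membership = np.full(n_genes, BACKGROUND, dtype=int)
    pos = 0
    for m, size in enumerate(module_sizes, start=1):
        membership[pos : pos + size] = m
        pos += size
    truth.module_membership = {g: int(m) for g, m in zip(genes, membership)}
    truth.disease_modules = set(range(1, min(n_disease_modules, len(module_sizes)) + 1))

    lo = np.sqrt(within_cor) * 0.8
    hi = min(1.0, np.sqrt(within_cor) * 1.2)
    loadings = rng.uniform(lo, hi, size=n_genes)
    loadings[membership == BACKGROUND] = 0.0
    truth.hub_strength = {g: float(u) for g, u in zip(genes, loadings)}

    m_total = 2 * n_samples_per_class
    phenotype = np.concatenate(
        [np.zeros(n_samples_per_class, int), np.ones(n_samples_per_class, int)]
    )
    datasets = []
    for t in range(n_tissues):
        tissue = f"tissue{t + 1}"
        values = rng.standard_normal((n_genes, m_total))
        for m in range(1, len(module_sizes) + 1):
            f = rng.standard_normal(m_total)
            if m in truth.disease_modules:
                f = f + trait_shift * phenotype
            rows = np.flatnonzero(membership == m)
            u = loadings[rows][:, None]
            values[rows, :] = u * f[None, :] + np.sqrt(1 - u**2) * values[rows, :]
        datasets.append(
            ExpressionDataset(
                tissue_name=tissue,
                gene_ids=genes,
                sample_ids=[f"{tissue}_s{j:03d}" for j in range(m_total)],
                values=values,
                phenotype=phenotype,
            )
        )
    return datasets, truth


def simulate_interactome(
    n_nodes: int,
    edges_per_node: int,
    neighborhood_size: int,
    seed: int,
    truth: SyntheticTruth | None = None,
) -> tuple[Interactome, SyntheticTruth]:
    """Preferential-attachment interactome with a planted connected disease neighborhood.

    The neighborhood is a breadth-first ball grown around a node sampled from
    the top decile of the degree distribution, truncated to
    ``neighborhood_size`` — connected by construction and centred in a dense
    region, mimicking the agglomerated disease modules observed on real
    interactomes.
    """
    if n_nodes < neighborhood_size * 2:
        raise ValueError("n_nodes must be at least twice neighborhood_size")
    rng = np.random.default_rng(seed)
    graph = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=int(rng.integers(2**31)))
    mapping = {i: f"P{i:05d}" for i in graph.nodes}
    graph = nx.relabel_nodes(graph, mapping)

    degrees = dict(graph.degree())
    nodes_by_degree = sorted(degrees, key=lambda v: (-degrees[v], v))
    top = nodes_by_degree[: max(1, n_nodes // 10)]
    center = top[int(rng.integers(len(top)))]

    ball: list[str] = []
    for _, v in nx.bfs_edges(graph, center):
        if not ball:
            ball.append(center)
        ball.append(v)
        if len(ball) >= neighborhood_size:
            break
    neighborhood = set(ball[:neighborhood_size]) or {center}

    if truth is None:
        truth = SyntheticTruth()
    truth.disease_neighborhood = neighborhood
    return Interactome(graph=graph, restricted_to_lcc=nx.is_connected(graph)), truth


def simulate_drugs(
    interactome: Interactome,
    truth: SyntheticTruth,
    n_proximal: int,
    n_distal: int,
    targets_per_drug: int,
    seed: int,
) -> list[DrugRecord]:
    """Drug target sets at controlled distance from the disease neighborhood.

    Proximal drugs draw targets from the neighborhood plus its direct
    neighbors; distal drugs draw from nodes at distance >= 3 (falling back to
    a uniform draw with a warning if too few such nodes exist).
    """
    if targets_per_drug == 0:
        raise ValueError("targets_per_drug must be positive")
    if interactome.n_nodes < 10 * targets_per_drug:
        raise ValueError("interactome too small for the requested target sets")
    rng = np.random.default_rng(seed)
    graph = interactome.graph
    neighborhood = truth.disease_neighborhood
    if not neighborhood:
        raise ValueError("truth has no disease neighborhood; run simulate_interactome first")

    near = set(neighborhood)
    for v in neighborhood:
        near.update(graph.neighbors(v))
    near_pool = sorted(near)

    dist = nx.multi_source_dijkstra_path_length(graph, neighborhood)
    far_pool = sorted(v for v in graph.nodes if dist.get(v, np.inf) >= 3)
    if len(far_pool) < targets_per_drug:
        logger.warning(
            "only %d node(s) at distance >= 3 from the neighborhood; "
            "distal drugs fall back to uniform sampling", len(far_pool),
        )
        far_pool = sorted(graph.nodes)

    drugs = []
    for i in range(n_proximal):
        targets = rng.choice(near_pool, size=min(targets_per_drug, len(near_pool)), replace=False)
        drug_id = f"DPROX{i:03d}"
        drugs.append(DrugRecord(drug_id, f"proximal-{i}", set(targets)))
        truth.drug_class[drug_id] = "proximal"
    for i in range(n_distal):
        targets = rng.choice(far_pool, size=targets_per_drug, replace=False)
        drug_id = f"DDIST{i:03d}"
        drugs.append(DrugRecord(drug_id, f"distal-{i}", set(targets)))
        truth.drug_class[drug_id] = "distal"
    return drugs
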