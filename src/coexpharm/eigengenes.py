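"""Module eigengenes, meta-modules, and eigengene-network preservation statistics.

A module eigengene is the first principal component of the standardized
member-gene submatrix — one sample-vector summarizing the module. Eigengenes
are re-expressed as a co-expression network (soft threshold 1), combined
across tissues with the min-consensus, and the resulting dissimilarity is
embedded by classical MDS and clustered by k-means into meta-modules.
Preservation of (meta-)module networks between tissue pairs is quantified by
the preservation network 1 - (max - min), its per-node scaled connectivity C
and its density D; D is algebraically the mean of C over nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .types import ExpressionDataset, ModulePartition, SymmetricGeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Eigengene",
    "PreservationStats",
    "module_eigengene",
    "eigengene_network",
    "consensus_dissimilarity",
    "classical_mds",
    "meta_modules",
    "preservation_network",
    "scaled_connectivity",
    "density",
    "differential_eigengene_analysis",
]


@dataclass
class Eigengene:
    """First principal component of a module's expression, as sample scores."""

    owner: str
    tissue: str
    sample_ids: list[str]
    scores: np.ndarray  # unit variance, oriented
    variance_explained: float


@dataclass
class PreservationStats:
    """Preservation of one network pair: per-node C and overall density D."""

    pair: tuple[str, str]
    node_ids: list[str]
    scaled_connectivity: np.ndarray
    density: float

    @property
    def n(self) -> int:
        return len(self.node_ids)


def module_eigengene(ds: ExpressionDataset, member_genes: list[str], owner: str = "") -> Eigengene:
    """First principal component of the standardized member-gene submatrix.

    Genes are standardized to zero mean / unit variance across samples; the
    first right singular vector gives the sample scores, rescaled to unit
    variance and oriented so the mean correlation with the member genes is
    positive (exact ties broken toward a positive first loading).
    """
    members = list(member_genes)
    if len(members) < 2:
        raise ValueError("an eigengene needs at least 2 member genes")
    idx = ds.gene_index(members)
    x = ds.values[idx, :]
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2)) if s.sum() > 0 else 0.0

    mean_cor = float(np.mean(z @ scores))  # proportional to mean correlation
    if mean_cor < 0 or (mean_cor == 0 and u[0, 0] < 0):
        scores = -scores
    sd_scores = scores.std()
    if sd_scores > 0:
        scores = (scores - scores.mean()) / sd_scores
    return Eigengene(
        owner=owner or ",".join(members[:3]),
        tissue=ds.tissue_name,
        sample_ids=list(ds.sample_ids),
        scores=scores,
        variance_explained=var_explained,
    )


def eigengene_network(eigengenes: list[Eigengene]) -> SymmetricGeneMatrix:
    """Signed eigengene co-expression network at soft threshold 1:
    A = 0.5 + 0.5 * cor(scores_i, scores_j), unit diagonal."""
    if len(eigengenes) < 1:
        raise ValueError("need at least one eigengene")
    sample_sets = {tuple(e.sample_ids) for e in eigengenes}
    if len(sample_sets) != 1:
        raise ValueError("eigengenes must share the same samples")
    scores = np.stack([e.scores for e in eigengenes])
    if len(eigengenes) == 1:
        corr = np.ones((1, 1))
    else:
        corr = np.clip(np.corrcoef(scores), -1.0, 1.0)
    adj = 0.5 + 0.5 * corr
    np.fill_diagonal(adj, 1.0)
    adj = (adj + adj.T) / 2
    return SymmetricGeneMatrix([e.owner for e in eigengenes], adj, role="eigengene_adjacency")


def consensus_dissimilarity(networks: list[SymmetricGeneMatrix]) -> SymmetricGeneMatrix:
    """1 - elementwise min over the per-tissue eigengene networks.

    A single-network input degenerates to 1 - that network.
    """
    if not networks:
        raise ValueError("need at least one network")
    ref = networks[0]
    for m in networks[1:]:
        if m.gene_ids != ref.gene_ids:
            raise ValueError("networks must share the identical module list")
    stack = np.stack([m.values for m in networks])
    out = 1.0 - stack.min(axis=0)
    np.fill_diagonal(out, 0.0)
    return SymmetricGeneMatrix(ref.gene_ids, out, role="consensus_dissimilarity")


def classical_mds(dissim: np.ndarray, n_dims: int) -> np.ndarray:
    """Classical (Torgerson) MDS: double-center -squared dissimilarities/2, top eigenpairs."""
    n = dissim.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dissim**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_dims]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    return coords


def meta_modules(
    discons: SymmetricGeneMatrix,
    k: int = 6,
    mds_dims: int = 2,
    seed: int = 0,
    n_restarts: int = 50,
) -> dict[str, int]:
    """Group module eigengenes into meta-modules: classical MDS then k-means.

    k-means runs ``n_restarts`` seeded restarts and keeps the best inertia,
    so the assignment is stable under the seed. Meta-module ids are 1..k.
    """
    n = discons.n
    if k > n:
        raise ValueError(f"k={k} exceeds the number of modules ({n})")
    coords = classical_mds(discons.values, mds_dims)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(coords)
    # deterministic renumbering: by first occurrence in module order
    remap: dict[int, int] = {}
    for l in labels:
        if l not in remap:
            remap[l] = len(remap) + 1
    return {mod: remap[l] for mod, l in zip(discons.gene_ids, labels)}


def preservation_network(adjs: list[SymmetricGeneMatrix]) -> SymmetricGeneMatrix:
    """Preserv = 1 - (elementwise max - elementwise min) across networks.

    For two networks this is 1 - |a1 - a2|; identical networks give all ones.
    """
    if len(adjs) < 2:
        raise ValueError("preservation needs at least 2 networks")
    ref = adjs[0]
    for m in adjs[1:]:
        if m.gene_ids != ref.gene_ids:
            raise ValueError("networks must share the identical node list")
    stack = np.stack([m.values for m in adjs])
    out = 1.0 - (stack.max(axis=0) - stack.min(axis=0))
    return SymmetricGeneMatrix(ref.gene_ids, out, role="preservation")


def scaled_connectivity(a1: SymmetricGeneMatrix, a2: SymmetricGeneMatrix) -> np.ndarray:
    """C_i = 1 - sum_{j != i} |a1_ij - a2_ij| / (n - 1)."""
    if a1.gene_ids != a2.gene_ids:
        raise ValueError("networks must share the identical node list")
    n = a1.n
    if n < 2:
        raise ValueError("need at least 2 nodes")
    diff = np.abs(a1.values - a2.values)
    np.fill_diagonal(diff, 0.0)
    return 1.0 - diff.sum(axis=1) / (n - 1)


def density(a1: SymmetricGeneMatrix, a2: SymmetricGeneMatrix) -> float:
    """D = 1 - sum_{i, j != i} |a1_ij - a2_ij| / (n (n - 1)); equals mean(C)."""
    if a1.gene_ids != a2.gene_ids:
        raise ValueError("networks must share the identical node list")
    n = a1.n
    diff = np.abs(a1.values - a2.values)
    np.fill_diagonal(diff, 0.0)
    return float(1.0 - diff.sum() / (n * (n - 1)))


def differential_eigengene_analysis(
    datasets: list[ExpressionDataset],
    partition: ModulePartition,
    meta_assignment: dict[str, int] | None = None,
    eigengene_of_eigengenes: bool = False,
) -> tuple[dict[tuple[str, str], PreservationStats], dict[str, SymmetricGeneMatrix]]:
    """Quantify (meta-)module preservation for every tissue pair.

    Per tissue, a (meta-)module eigengene network is built; per unordered
    tissue pair the preservation statistics C (per meta-module) and D are
    computed. Meta-module eigengenes come from the union of member genes by
    default; ``eigengene_of_eigengenes`` computes them from the member-module
    eigengene scores instead.
    """
    def _mod_id(key) -> int:
        return int(key.lstrip("M")) if isinstance(key, str) else int(key)

    groups: dict[str, list[str]]
    if meta_assignment is None:
        groups = {f"M{m}": partition.members(m) for m in partition.module_ids}
        norm_assignment = None
    else:
        norm_assignment = {_mod_id(mod): mm for mod, mm in meta_assignment.items()}
        groups = {}
        for mod, mm in sorted(norm_assignment.items()):
            groups.setdefault(f"MM{mm}", []).extend(partition.members(mod))
    names = sorted(groups)

    per_tissue: dict[str, SymmetricGeneMatrix] = {}
    for ds in datasets:
        if eigengene_of_eigengenes and norm_assignment is not None:
            module_es = {
                m: module_eigengene(ds, partition.members(m), owner=f"M{m}")
                for m in partition.module_ids
            }
            mm_of = {m: f"MM{mm}" for m, mm in norm_assignment.items()}
            egs = []
            for name in names:
                mods = sorted(m for m in module_es if mm_of.get(m) == name)
                scores = np.stack([module_es[m].scores for m in mods])
                if len(mods) == 1:
                    eg = Eigengene(name, ds.tissue_name, list(ds.sample_ids), scores[0], 1.0)
                else:
                    u, s, vt = np.linalg.svd(scores - scores.mean(axis=1, keepdims=True), full_matrices=False)
                    sc = vt[0]
                    if np.mean(scores @ sc) < 0:
                        sc = -sc
                    sc = (sc - sc.mean()) / sc.std()
                    eg = Eigengene(name, ds.tissue_name, list(ds.sample_ids), sc,
                                   float(s[0] ** 2 / np.sum(s**2)))
                egs.append(eg)
        else:
            egs = [module_eigengene(ds, groups[name], owner=name) for name in names]
        per_tissue[ds.tissue_name] = eigengene_network(egs)

    stats: dict[tuple[str, str], PreservationStats] = {}
    tissues = [ds.tissue_name for ds in datasets]
    for i, ta in enumerate(tissues):
        for tb in tissues[i + 1 :]:
            a1, a2 = per_tissue[ta], per_tissue[tb]
            stats[(ta, tb)] = PreservationStats(
                pair=(ta, tb),
                node_ids=list(a1.gene_ids),
                scaled_connectivity=scaled_connectivity(a1, a2),
                density=density(a1, a2),
            )
    return stats, per_tissue
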