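"""Disease signatures on the interactome and network-proximity drug screening.

The disease signature is the set of meta-module genes passing a joint
gene-significance / gene-connectivity quantile threshold, mapped onto the
protein–protein interactome. Its agglomeration is quantified by S (largest
connected component among signature proteins) and <d_s> (mean distance of
each signature protein to its nearest signature neighbor); a drug's proximity
<d_c> is the mean distance of its targets to the nearest signature protein.
All three are judged against degree-preserving null models: reference nodes
are replaced by random nodes drawn from degree bins, z = (X - mu) / sigma
with the population-convention sigma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .types import DrugRecord, Interactome

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "NullDistribution",
    "ProximityResult",
    "GraphIndex",
    "disease_signature",
    "lcc_size",
    "mean_shortest_distance_ds",
    "degree_preserving_sample",
    "zscore",
    "signature_agglomeration",
    "drug_disease_proximity",
    "proximity_screen",
    "rank_drugs",
    "fisher_exact_2x2",
    "min_relevant_count",
    "validate_lists",
]


@dataclass
class Signature:
    """A disease gene set and its interactome-mapped subset."""

    requested: set[str]
    mapped: set[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.mapped <= self.requested:
            raise ValueError("mapped must be a subset of requested")
        if len(self.mapped) < 2:
            raise ValueError(
                f"signature maps to only {len(self.mapped)} interactome node(s); need >= 2"
            )


@dataclass
class NullDistribution:
    """Null samples of one statistic, with population-convention moments."""

    statistic: str
    samples: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) < 2:
            raise ValueError("a null distribution needs at least 2 samples")

    @property
    def n_reps(self) -> int:
        return len(self.samples)

    @property
    def mu(self) -> float:
        return float(self.samples.mean())

    @property
    def sigma(self) -> float:
        return float(self.samples.std(ddof=0))


@dataclass
class ProximityResult:
    drug_id: str
    name: str
    d_c: float
    z: float
    empirical_p: float
    n_mapped_targets: int


class GraphIndex:
    """Sparse-matrix view of an interactome for fast unweighted distances."""

    def __init__(self, interactome: Interactome):
        self.interactome = interactome
        self.nodes: list[str] = sorted(interactome.graph.nodes)
        self.index: dict[str, int] = {v: i for i, v in enumerate(self.nodes)}
        n = len(self.nodes)
        rows, cols = [], []
        for a, b in interactome.graph.edges:
            ia, ib = self.index[a], self.index[b]
            rows += [ia, ib]
            cols += [ib, ia]
        self.adj = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        self.degrees = np.asarray(self.adj.sum(axis=1)).ravel().astype(int)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def idx(self, names) -> np.ndarray:
        missing = [v for v in names if v not in self.index]
        if missing:
            raise KeyError(f"nodes absent from interactome: {sorted(missing)[:5]}")
        return np.array(sorted(self.index[v] for v in names), dtype=int)

    def min_dist_from(self, sources: np.ndarray) -> np.ndarray:
        """Distance of every node to its nearest source (inf if unreachable)."""
        return dijkstra(self.adj, indices=sources, unweighted=True, min_only=True)

    def pairwise_from(self, sources: np.ndarray) -> np.ndarray:
        return dijkstra(self.adj, indices=sources, unweighted=True)

    def lcc_of(self, node_idx: np.ndarray) -> int:
        if len(node_idx) == 0:
            return 0
        sub = self.adj[np.ix_(node_idx, node_idx)]
        n_comp, labels = connected_components(sub, directed=False)
        return int(np.bincount(labels).max())

    def degree_bins(self, min_bin_size: int = 100) -> list[np.ndarray]:
        """Nodes binned by increasing degree, adjacent bins merged until each
        holds at least ``min_bin_size`` nodes (a short final bin is merged
        back into its predecessor)."""
        order = np.argsort(self.degrees, kind="stable")
        degs = self.degrees[order]
        bins: list[np.ndarray] = []
        start = 0
        while start < len(order):
            end = start
            while end < len(order) and (
                end - start < min_bin_size or (end > start and degs[end] == degs[end - 1])
            ):
                # extend to min size, then finish the run of equal degrees
                end += 1
            bins.append(order[start:end])
            start = end
        if len(bins) > 1 and len(bins[-1]) < min_bin_size:
            bins[-2] = np.concatenate([bins[-2], bins[-1]])
            bins.pop()
        return bins


def disease_signature(
    table: pd.DataFrame,
    meta_module: int,
    interactome: Interactome,
    quantile: float = 0.8,
    by: str = "meta_module",
) -> Signature:
    """Genes of one meta-module passing the joint GS/GC quantile threshold.

    The quantile cutoffs (linear interpolation) are computed within the
    meta-module; a gene must reach the cutoff in *both* consensus GS and
    consensus GC. The surviving genes are mapped onto the interactome.
    """
    sub = table[table[by] == meta_module]
    if len(sub) == 0:
        raise ValueError(f"meta-module {meta_module} is empty")
    gs = sub["gs_consensus"].to_numpy()
    gc = sub["gc_consensus"].to_numpy()
    q_gs = np.quantile(gs, quantile)
    q_gc = np.quantile(gc, quantile)
    chosen = set(sub.index[(gs >= q_gs) & (gc >= q_gc)])
    mapped = chosen & interactome.nodes
    return Signature(
        requested=chosen,
        mapped=mapped,
        provenance=f"meta-module {meta_module}, {quantile:.0%} GS/GC quantile",
    )


def lcc_size(g: Interactome | GraphIndex, sig: Signature) -> int:
    """S: size of the largest connected component induced by the signature."""
    gi = g if isinstance(g, GraphIndex) else GraphIndex(g)
    return gi.lcc_of(gi.idx(sig.mapped))


def _nearest_other_distances(gi: GraphIndex, node_idx: np.ndarray) -> np.ndarray:
    dmat = gi.pairwise_from(node_idx)[:, node_idx]
    np.fill_diagonal(dmat, np.inf)
    return dmat.min(axis=1)


def mean_shortest_distance_ds(g: Interactome | GraphIndex, sig: Signature) -> float:
    """<d_s>: mean over signature proteins of the distance to the nearest
    *other* signature protein; proteins with no reachable partner are
    excluded from the mean (logged)."""
    gi = g if isinstance(g, GraphIndex) else GraphIndex(g)
    nearest = _nearest_other_distances(gi, gi.idx(sig.mapped))
    finite = np.isfinite(nearest)
    if not finite.any():
        raise ValueError("no signature protein can reach another signature protein")
    if (~finite).any():
        logger.info("<d_s>: excluded %d unreachable protein(s)", int((~finite).sum()))
    return float(nearest[finite].mean())


def degree_preserving_sample(
    g: Interactome | GraphIndex,
    reference: set[str] | np.ndarray,
    seed: int | np.random.Generator,
    min_bin_size: int = 100,
    bins: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Random node set matching the reference's degree profile.

    Nodes are binned by increasing degree (adjacent bins merged until each
    holds >= ``min_bin_size`` nodes); each reference node is replaced by a
    uniform draw without replacement from its bin, widening to neighboring
    bins with a warning if a bin is exhausted. Returns distinct node indices.
    """
    gi = g if isinstance(g, GraphIndex) else GraphIndex(g)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref_idx = reference if isinstance(reference, np.ndarray) else gi.idx(reference)
    if len(ref_idx) > gi.n:
        raise ValueError("reference larger than the interactome")
    if bins is None:
        bins = gi.degree_bins(min_bin_size)
    bin_of = np.empty(gi.n, dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b

    need = np.bincount(bin_of[ref_idx], minlength=len(bins))
    chosen: list[np.ndarray] = []
    taken: set[int] = set()
    for b in np.flatnonzero(need):
        pool = [v for v in bins[b] if v not in taken]
        want = int(need[b])
        width = 1
        while len(pool) < want and (b - width >= 0 or b + width < len(bins)):
            logger.warning("degree bin %d exhausted; widening to neighbors", b)
            extra = []
            if b - width >= 0:
                extra.append(bins[b - width])
            if b + width < len(bins):
                extra.append(bins[b + width])
            pool += [v for arr in extra for v in arr if v not in taken]
            width += 1
        if len(pool) < want:
            raise ValueError("cannot satisfy degree-preserving sample: pools exhausted")
        draw = rng.choice(np.asarray(pool), size=want, replace=False)
        chosen.append(draw)
        taken.update(int(v) for v in draw)
    return np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)


def zscore(x: float, null: NullDistribution) -> tuple[float, float]:
    """z = (x - mu) / sigma against the null, plus the empirical tail p.

    The empirical p is the fraction of null samples at least as extreme as x
    in the direction of the observed deviation.
    """
    if null.sigma == 0:
        raise ValueError(f"null distribution of {null.statistic} has zero sigma")
    z = (x - null.mu) / null.sigma
    if x >= null.mu:
        p = float(np.mean(null.samples >= x))
    else:
        p = float(np.mean(null.samples <= x))
    return float(z), p


def signature_agglomeration(
    g: Interactome | GraphIndex,
    sig: Signature,
    n_reps: int = 10000,
    seed: int = 0,
    min_bin_size: int = 100,
) -> dict[str, dict[str, float]]:
    """z-scores of S and <d_s> against degree-preserving random signatures.

    An agglomerated disease signature shows z(S) > 0 (bigger connected chunk
    than degree-matched chance) and z(<d_s>) < 0 (signature proteins closer
    to each other than chance).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 for a null sigma")
    gi = g if isinstance(g, GraphIndex) else GraphIndex(g)
    rng = np.random.default_rng(seed)
    sig_idx = gi.idx(sig.mapped)
    bins = gi.degree_bins(min_bin_size)

    obs_s = gi.lcc_of(sig_idx)
    nearest = _nearest_other_distances(gi, sig_idx)
    obs_ds = float(nearest[np.isfinite(nearest)].mean())

    null_s = np.empty(n_reps)
    null_ds = np.empty(n_reps)
    for r in range(n_reps):
        rand = degree_preserving_sample(gi, sig_idx, rng, min_bin_size, bins=bins)
        null_s[r] = gi.lcc_of(rand)
        nd = _nearest_other_distances(gi, rand)
        finite = nd[np.isfinite(nd)]
        null_ds[r] = finite.mean() if len(finite) else np.nan
    null_ds = null_ds[np.isfinite(null_ds)]

    dist_s = NullDistribution("S", null_s, seed=seed)
    dist_ds = NullDistribution("<d_s>", null_ds, seed=seed)
    z_s, p_s = zscore(obs_s, dist_s)
    z_ds, p_ds = zscore(obs_ds, dist_ds)
    return {
        "S": {"observed": float(obs_s), "mu": dist_s.mu, "sigma": dist_s.sigma, "z": z_s, "p": p_s},
        "d_s": {"observed": obs_ds, "mu": dist_ds.mu, "sigma": dist_ds.sigma, "z": z_ds, "p": p_ds},
    }


def drug_disease_proximity(g: Interactome | GraphIndex, drug: DrugRecord, sig: Signature) -> float:
    """<d_c>: mean over mapped drug targets of the distance to the nearest
    signature protein (a target inside the signature contributes 0)."""
    gi = g if isinstance(g, GraphIndex) else GraphIndex(g)
    mapped = (drug.mapped_targets or drug.targets) & set(gi.nodes)
    if not mapped:
        raise ValueError(f"drug {drug.drug_id}: no targets map to the interactome")
    dist = gi.min_dist_from(gi.idx(sig.mapped))
    d = dist[gi.idx(mapped)]
    finite = np.isfinite(d)
    if not finite.any():
        raise ValueError(f"drug {drug.drug_id}: all targets unreachable from the signature")
    if (~finite).any():
        logger.warning("drug %s: %d unreachable target(s) excluded", drug.drug_id, int((~finite).sum()))
    return float(d[finite].mean())


def proximity_screen(
    g: Interactome | GraphIndex,
    drugs: list[DrugRecord],
    sig: Signature,
    n_reps: int = 1000,
    seed: int = 0,
    min_bin_size: int = 100,
) -> list[ProximityResult]:
    """Screen every drug for proximity to the disease signature.

    The null replaces *both* the drug target set and the disease signature by
    degree-preserving random sets of the same sizes. Within one repetition
    the random signature is shared across drugs (each drug still draws its
    own degree-matched random targets), so one multi-source traversal serves
    the whole catalogue; nulls are marginally correct per drug. Drugs with no
    mapped target are excluded (logged).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 for a null sigma")
    gi = g if isinstance(g, GraphIndex) else GraphIndex(g)
    rng = np.random.default_rng(seed)
    bins = gi.degree_bins(min_bin_size)
    sig_idx = gi.idx(sig.mapped)

    usable: list[tuple[DrugRecord, np.ndarray]] = []
    for drug in sorted(drugs, key=lambda d: d.drug_id):
        mapped = (drug.mapped_targets or drug.targets) & set(gi.index)
        if not mapped:
            logger.warning("drug %s: no mapped targets; excluded from screen", drug.drug_id)
            continue
        usable.append((drug, gi.idx(mapped)))

    obs_dist = gi.min_dist_from(sig_idx)
    observed = {}
    for drug, tidx in usable:
        d = obs_dist[tidx]
        d = d[np.isfinite(d)]
        if len(d) == 0:
            logger.warning("drug %s: all targets unreachable; excluded", drug.drug_id)
            continue
        observed[drug.drug_id] = float(d.mean())

    nulls = {drug.drug_id: np.empty(n_reps) for drug, _ in usable if drug.drug_id in observed}
    for r in range(n_reps):
        rand_sig = degree_preserving_sample(gi, sig_idx, rng, min_bin_size, bins=bins)
        dist = gi.min_dist_from(rand_sig)
        for drug, tidx in usable:
            if drug.drug_id not in observed:
                continue
            rand_t = degree_preserving_sample(gi, tidx, rng, min_bin_size, bins=bins)
            d = dist[rand_t]
            d = d[np.isfinite(d)]
            nulls[drug.drug_id][r] = d.mean() if len(d) else np.nan

    results = []
    for drug, tidx in usable:
        if drug.drug_id not in observed:
            continue
        samples = nulls[drug.drug_id]
        samples = samples[np.isfinite(samples)]
        null = NullDistribution("<d_c>", samples, seed=seed)
        z, p = zscore(observed[drug.drug_id], null)
        results.append(
            ProximityResult(
                drug_id=drug.drug_id,
                name=drug.name,
                d_c=observed[drug.drug_id],
                z=z,
                empirical_p=p,
                n_mapped_targets=len(tidx),
            )
        )
    return results


def rank_drugs(
    results: list[ProximityResult],
    dc_quantile: float = 0.05,
    k: int = 10,
    dc_cap: float | None = None,
) -> tuple[list[ProximityResult], list[ProximityResult]]:
    """Top-k and bottom-k drugs by proximity significance.

    Eligibility for the top list: d_c at or below the ``dc_quantile`` of all
    screened d_c values (or below ``dc_cap`` if given). Top-k = eligible
    drugs by ascending z (ties: ascending d_c, then drug_id); bottom-k =
    drugs with d_c at or above the 1 - dc_quantile threshold, ascending z.
    """
    if not results:
        raise ValueError("no screening results to rank")
    dcs = np.array([r.d_c for r in results])
    lo = float(np.quantile(dcs, dc_quantile)) if dc_cap is None else dc_cap
    hi = float(np.quantile(dcs, 1 - dc_quantile))
    keyed = sorted(results, key=lambda r: (r.z, r.d_c, r.drug_id))
    eligible = [r for r in keyed if r.d_c <= lo]
    if len(eligible) < k:
        logger.warning("only %d drug(s) eligible for the top list (k=%d)", len(eligible), k)
    top = eligible[:k]
    bottom = [r for r in keyed if r.d_c >= hi][:k]
    return top, bottom


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Exact Fisher test of a 2x2 table by enumeration over fixed margins.

    Returns (two-sided p, one-sided upper-tail p for cell (0, 0)). Two-sided
    p sums the probabilities of all tables no more probable than the observed
    one (1e-12 relative slack against rounding).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, c1, n = a + b, a + c, a + b + c + d
    if r1 == 0 or c + d == 0 or c1 == 0 or b + d == 0:
        raise ValueError("all margins must be positive")
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    p_two = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    p_greater = float(pmf[support >= a].sum())
    return min(p_two, 1.0), min(p_greater, 1.0)


def min_relevant_count(
    top_hits: int = 9, top_misses: int = 1, catalogue: int = 1833, p_floor: float = 0.01
) -> int:
    """Smallest catalogue-relevant count K for which the Fisher p of
    [[top_hits, top_misses], [K, catalogue - K]] exceeds ``p_floor``.

    Measures how enriched for relevant compounds the whole catalogue would
    have to be before the top list stops being significant.
    """
    for k in range(0, catalogue + 1):
        p_two, _ = fisher_exact_2x2([[top_hits, top_misses], [k, catalogue - k]])
        if p_two > p_floor:
            return k
    return catalogue


def validate_lists(
    g: Interactome | GraphIndex,
    drugs: list[DrugRecord],
    sig: Signature,
    hits: dict[str, bool],
    seed: int = 0,
    results: list[ProximityResult] | None = None,
    n_reps: int = 1000,
    k: int = 10,
    min_bin_size: int = 100,
    dc_quantile: float = 0.05,
) -> dict:
    """Compare the top list against bottom and random control lists.

    Builds top-k and bottom-k from the real screen, plus two random-k lists
    obtained by replacing the disease signature with a degree-preserving
    random signature and taking the k lowest d_c and the k lowest z. Reports
    hit counts (labels supplied externally) and Fisher p-values for
    top-vs-random and top-vs-whole-catalogue.
    """
    gi = g if isinstance(g, GraphIndex) else GraphIndex(g)
    if results is None:
        results = proximity_screen(gi, drugs, sig, n_reps=n_reps, seed=seed,
                                   min_bin_size=min_bin_size)
    top, bottom = rank_drugs(results, dc_quantile=dc_quantile, k=k)

    rng = np.random.default_rng(seed)
    rand_idx = degree_preserving_sample(gi, gi.idx(sig.mapped), rng, min_bin_size)
    rand_nodes = {gi.nodes[i] for i in rand_idx}
    rand_sig = Signature(requested=rand_nodes, mapped=rand_nodes, provenance="random control")
    rand_results = proximity_screen(gi, drugs, rand_sig, n_reps=n_reps,
                                    seed=int(rng.integers(2**31)), min_bin_size=min_bin_size)
    random_by_dc = sorted(rand_results, key=lambda r: (r.d_c, r.z, r.drug_id))[:k]
    random_by_z = sorted(rand_results, key=lambda r: (r.z, r.d_c, r.drug_id))[:k]

    def _hits(lst):
        return sum(bool(hits.get(r.drug_id, False)) for r in lst)

    n_top, n_bottom = _hits(top), _hits(bottom)
    n_rand_dc, n_rand_z = _hits(random_by_dc), _hits(random_by_z)
    catalogue_relevant = sum(bool(v) for v in hits.values())
    catalogue_rest = len(drugs) - catalogue_relevant

    def _fisher_vs(n_other, k_other):
        try:
            return fisher_exact_2x2(
                [[n_top, len(top) - n_top], [n_other, k_other - n_other]]
            )
        except ValueError:
            return (1.0, 1.0)

    report = {
        "top": [r.drug_id for r in top],
        "bottom": [r.drug_id for r in bottom],
        "random_by_dc": [r.drug_id for r in random_by_dc],
        "random_by_z": [r.drug_id for r in random_by_z],
        "hit_counts": {
            "top": n_top,
            "bottom": n_bottom,
            "random_by_dc": n_rand_dc,
            "random_by_z": n_rand_z,
        },
        "fisher": {
            "top_vs_random_dc": _fisher_vs(n_rand_dc, len(random_by_dc)),
            "top_vs_random_z": _fisher_vs(n_rand_z, len(random_by_z)),
            "top_vs_catalogue": fisher_exact_2x2(
                [[n_top, len(top) - n_top], [catalogue_relevant, catalogue_rest]]
            )
            if catalogue_relevant > 0 and catalogue_rest > 0
            else (1.0, 1.0),
        },
    }
    return report
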