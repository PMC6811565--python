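"""Gene significance, intramodular connectivity and their per-meta-module correlation.

Gene significance (GS) is the absolute Pearson correlation of a gene's
expression with the 0/1 disease trait (point-biserial; any affine trait
encoding gives the same |r|). Gene connectivity (GC) is the weighted degree
restricted to the gene's own module. Both are medianed across tissues into a
consensus, and within each meta-module the GS–GC Pearson correlation asks
whether the module's hub genes are the trait-correlated ones — the mark of a
disease-associated meta-module.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionDataset, ModulePartition, SymmetricGeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "gene_significance",
    "gene_connectivity",
    "build_score_table",
    "consensus_scores",
    "gs_gc_correlation",
]


def gene_significance(ds: ExpressionDataset) -> np.ndarray:
    """GS_g = |cor(x_g, trait)| with the trait encoded 0/1; constant genes get 0."""
    ds.require_both_classes()
    trait = ds.phenotype.astype(float)
    x = ds.values
    sd = x.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning(
            "%s: %d constant gene(s); GS set to 0", ds.tissue_name, int(const.sum())
        )
    xc = x - x.mean(axis=1, keepdims=True)
    tc = trait - trait.mean()
    denom = sd * trait.std()
    denom[const] = 1.0
    gs = np.abs(xc @ tc) / (ds.n_samples * denom)
    gs[const] = 0.0
    return np.clip(gs, 0.0, 1.0)


def gene_connectivity(adj: SymmetricGeneMatrix, partition: ModulePartition) -> np.ndarray:
    """Within-module weighted degree: gc_i = sum of a_ij over j in module(i), j != i.

    Unassigned genes are scored over the unassigned pool, so every gene has a
    connectivity on the same footing.
    """
    if adj.gene_ids != partition.gene_ids:
        raise ValueError("adjacency and partition must share the gene list")
    a = adj.values
    gc = np.zeros(adj.n)
    for label in np.unique(partition.labels):
        idx = np.flatnonzero(partition.labels == label)
        sub = a[np.ix_(idx, idx)]
        gc[idx] = sub.sum(axis=1) - np.diag(sub)
    return gc


def build_score_table(
    datasets: list[ExpressionDataset],
    adjacencies: dict[str, SymmetricGeneMatrix],
    partition: ModulePartition,
    meta_assignment: dict | None = None,
) -> pd.DataFrame:
    """Per-tissue GS and GC for every gene, plus module / meta-module labels."""
    genes = partition.gene_ids
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for ds in datasets:
        if ds.gene_ids != genes:
            raise ValueError("datasets and partition must share the gene list")
        out[f"gs_{ds.tissue_name}"] = gene_significance(ds)
        out[f"gc_{ds.tissue_name}"] = gene_connectivity(adjacencies[ds.tissue_name], partition)
    out["module"] = partition.labels
    if meta_assignment is not None:
        def _mod_id(key):
            return int(key.lstrip("M")) if isinstance(key, str) else int(key)
        mm = {_mod_id(k): v for k, v in meta_assignment.items()}
        out["meta_module"] = [mm.get(int(l), 0) for l in partition.labels]
    return out


def consensus_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Add gs_consensus / gc_consensus: per-gene median across tissues.

    With an even number of tissues the median is the midpoint of the two
    central values (numpy convention).
    """
    gs_cols = [c for c in table.columns if c.startswith("gs_")]
    gc_cols = [c for c in table.columns if c.startswith("gc_")]
    if not gs_cols or not gc_cols:
        raise ValueError("table has no per-tissue gs/gc columns")
    out = table.copy()
    out["gs_consensus"] = table[gs_cols].median(axis=1)
    out["gc_consensus"] = table[gc_cols].median(axis=1)
    return out


def gs_gc_correlation(table: pd.DataFrame, group: int, by: str = "meta_module") -> tuple[float, float]:
    """Pearson r (and two-sided p, t-distribution with n-2 df) between the
    consensus GS and GC inside one (meta-)module group.

    Zero variance in either score makes r undefined; it is reported as 0 with
    p = 1 and a warning.
    """
    sub = table[table[by] == group]
    if len(sub) < 3:
        raise ValueError(f"group {group} has fewer than 3 genes")
    gs = sub["gs_consensus"].to_numpy()
    gc = sub["gc_consensus"].to_numpy()
    if gs.std() == 0 or gc.std() == 0:
        logger.warning("group %s: zero variance in GS or GC; r undefined, reported 0", group)
        return 0.0, 1.0
    r, p = stats.pearsonr(gs, gc)
    return float(r), float(p)
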