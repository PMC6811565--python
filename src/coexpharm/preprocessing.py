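"""Outlier-sample removal and differential expression.

Expression matrices arrive already normalized on a log2 scale. Outliers are
flagged per phenotype class from the mean inter-sample correlation (a sample
that correlates poorly with its class peers is suspect). Differential
expression uses a per-gene Welch two-sample t-test with Benjamini–Hochberg
FDR control, and a gene counts as differentially expressed only when both the
absolute log2 fold change and the adjusted p-value pass their thresholds.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = ["DEGTable", "remove_outlier_samples", "differential_expression", "deg_overlap"]

_VAR_FLOOR = 1e-12


@dataclass
class DEGTable:
    """Per-gene differential expression results for one tissue."""

    tissue_name: str
    table: pd.DataFrame  # index: gene; columns: log2_fold_change, p_value, adj_p, is_deg
    fc_threshold: float
    alpha: float

    def deg_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_deg"]])


def remove_outlier_samples(
    ds: ExpressionDataset, z_cut: float = -2.5
) -> tuple[ExpressionDataset, list[str]]:
    """Drop samples whose mean within-class correlation is anomalously low.

    For each sample, the mean Pearson correlation to every other sample of
    the same phenotype class is computed and standardized within the class;
    samples below ``z_cut`` standard deviations are removed. One pass only —
    the criterion is not iterated to convergence, so a single gross outlier
    cannot cascade into emptying a class.
    """
    for cls in (0, 1):
        if np.sum(ds.phenotype == cls) < 4:
            raise ValueError(
                f"{ds.tissue_name}: need >= 4 samples per class for outlier detection"
            )
    keep = np.ones(ds.n_samples, dtype=bool)
    removed: list[str] = []
    for cls in (0, 1):
        cols = np.flatnonzero(ds.phenotype == cls)
        corr = np.corrcoef(ds.values[:, cols].T)
        np.fill_diagonal(corr, np.nan)
        mean_cor = np.nanmean(corr, axis=1)
        sd = mean_cor.std()
        if sd == 0:
            continue
        z = (mean_cor - mean_cor.mean()) / sd
        out = cols[z < z_cut]
        if len(cols) - len(out) < 3:
            raise ValueError(
                f"{ds.tissue_name}: outlier removal would leave class {cls} "
                f"with fewer than 3 samples"
            )
        keep[out] = False
        removed.extend(ds.sample_ids[i] for i in out)
    if removed:
        logger.info("%s: removed outlier sample(s) %s", ds.tissue_name, removed)
    return ds.subset_samples(np.flatnonzero(keep)), removed


def differential_expression(
    ds: ExpressionDataset, fc_threshold: float = 1.5, alpha: float = 0.05
) -> DEGTable:
    """Welch t-test per gene with BH adjustment; DEG = |log2FC| and adj_p both pass.

    The fold-change condition applies to the absolute log2 fold change, so
    up- and down-regulated genes are counted together. Zero within-class
    variance is floored at 1e-12 (logged); a gene with equal class means and
    no variance gets p = 1.
    """
    ds.require_both_classes()
    grp1 = ds.values[:, ds.phenotype == 1]
    grp0 = ds.values[:, ds.phenotype == 0]
    n1, n0 = grp1.shape[1], grp0.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError(f"{ds.tissue_name}: both classes need >= 2 samples")

    m1, m0 = grp1.mean(axis=1), grp0.mean(axis=1)
    v1, v0 = grp1.var(axis=1, ddof=1), grp0.var(axis=1, ddof=1)
    log2fc = m1 - m0

    degenerate = (v1 == 0) & (v0 == 0)
    if degenerate.any():
        logger.info(
            "%s: %d gene(s) with zero within-class variance; variance floored",
            ds.tissue_name, int(degenerate.sum()),
        )
    v1 = np.maximum(v1, _VAR_FLOOR)
    v0 = np.maximum(v0, _VAR_FLOOR)
    se2 = v1 / n1 + v0 / n0
    t = (m1 - m0) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
    p = 2 * stats.t.sf(np.abs(t), df)
    p[degenerate & (m1 == m0)] = 1.0

    adj_p = multipletests(p, method="fdr_bh")[1]
    is_deg = (np.abs(log2fc) >= fc_threshold) & (adj_p <= alpha)
    table = pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_value": p,
            "adj_p": adj_p,
            "is_deg": is_deg,
        },
        index=pd.Index(ds.gene_ids, name="gene"),
    )
    return DEGTable(tissue_name=ds.tissue_name, table=table, fc_threshold=fc_threshold, alpha=alpha)


def deg_overlap(tables: dict[str, DEGTable]) -> dict[frozenset[str], int]:
    """Venn-style counts: for every non-empty tissue subset, genes DEG in exactly it."""
    if len(tables) < 2:
        raise ValueError("need at least 2 tissues for a DEG overlap")
    deg_sets = {t: tab.deg_genes() for t, tab in tables.items()}
    tissues = sorted(deg_sets)
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(tissues) + 1):
        for subset in itertools.combinations(tissues, r):
            inside = set.intersection(*(deg_sets[t] for t in subset)) if subset else set()
            outside = set.union(*(deg_sets[t] for t in tissues if t not in subset), set())
            counts[frozenset(subset)] = len(inside - outside)
    return counts
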