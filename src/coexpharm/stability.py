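"""Module stability under sample perturbation.

Two perturbation schemes probe how much the consensus modules depend on the
particular samples: dropping 10% of the samples, and bootstrap resampling
with replacement. After each perturbation the whole consensus clustering is
rerun (same soft threshold and cut parameters) and the perturbed partition is
compared with the reference via a best-match overlap: each reference module
claims the perturbed module with the largest intersection, and the preserved
fraction is the claimed overlap summed over modules divided by the number of
assigned reference genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .coexpression import consensus_modules
from .types import ExpressionDataset, ModulePartition

logger = logging.getLogger(__name__)

__all__ = ["StabilityReport", "perturb_samples", "preserved_fraction", "stability_analysis"]


@dataclass
class StabilityReport:
    mode: str  # "resample" | "drop10"
    preserved_fractions: list[float]

    @property
    def n_reps(self) -> int:
        return len(self.preserved_fractions)

    @property
    def median_preserved(self) -> float:
        return float(np.median(self.preserved_fractions))


def perturb_samples(ds: ExpressionDataset, mode: str, seed: int) -> ExpressionDataset:
    """Perturb the sample set: ``drop10`` removes ceil(0.1*M) samples without
    replacement, ``resample`` draws M samples with replacement (duplicated
    sample ids are suffixed). Phenotype labels travel with their samples."""
    rng = np.random.default_rng(seed)
    m = ds.n_samples
    if mode == "drop10":
        if m < 10:
            raise ValueError("drop10 requires at least 10 samples")
        n_drop = math.ceil(0.1 * m)
        drop = rng.choice(m, size=n_drop, replace=False)
        keep = np.setdiff1d(np.arange(m), drop)
        return ds.subset_samples(keep)
    if mode == "resample":
        cols = rng.integers(0, m, size=m)
        seen: dict[str, int] = {}
        ids = []
        for c in cols:
            base = ds.sample_ids[c]
            k = seen.get(base, 0)
            seen[base] = k + 1
            ids.append(base if k == 0 else f"{base}.{k}")
        return ds.subset_samples(cols, sample_ids=ids)
    raise ValueError(f"unknown perturbation mode {mode!r}")


def preserved_fraction(reference: ModulePartition, perturbed: ModulePartition) -> float:
    """Best-match overlap of the perturbed partition with the reference.

    For each reference module M the perturbed module B maximizing |M ∩ B| is
    found (the unassigned label is ineligible); preserved =
    sum |M ∩ B(M)| / sum |M|. Invariant under relabeling of either side.
    """
    if reference.gene_ids != perturbed.gene_ids:
        raise ValueError("partitions must share the identical gene list")
    ref_modules = reference.module_ids
    if not ref_modules:
        raise ValueError("reference partition has no assigned genes")
    total = 0
    claimed = 0
    for m in ref_modules:
        mask = reference.labels == m
        total += int(mask.sum())
        pert = perturbed.labels[mask]
        pert = pert[pert != perturbed.unassigned_label]
        if len(pert):
            claimed += int(np.bincount(pert).max())
    return claimed / total


def stability_analysis(
    datasets: list[ExpressionDataset],
    beta: float,
    n_reps: int = 50,
    seed: int = 0,
    modes: tuple[str, ...] = ("drop10", "resample"),
    **cluster_kwargs,
) -> dict[str, StabilityReport]:
    """Rerun the consensus clustering on perturbed samples and report medians.

    The reference partition is computed from the unperturbed data; the soft
    threshold ``beta`` is reused for every perturbed run rather than
    rescanned (perturbing samples should not change the network regime).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    reference, _ = consensus_modules(datasets, beta=beta, **cluster_kwargs)
    no_reference = not reference.module_ids
    if no_reference:
        logger.warning("unperturbed data yields no modules; preserved fractions are NaN")
    rng = np.random.default_rng(seed)
    reports: dict[str, StabilityReport] = {}
    for mode in modes:
        fractions = []
        for _ in range(n_reps):
            perturbed = [
                perturb_samples(ds, mode, seed=int(rng.integers(2**31))) for ds in datasets
            ]
            part, _ = consensus_modules(perturbed, beta=beta, **cluster_kwargs)
            fractions.append(
                float("nan") if no_reference else preserved_fraction(reference, part)
            )
        reports[mode] = StabilityReport(mode=mode, preserved_fractions=fractions)
        logger.info("stability %s: median preserved %.3f", mode, reports[mode].median_preserved)
    return reports
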