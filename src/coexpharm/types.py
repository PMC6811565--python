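"""Shared domain types for the multi-tissue co-expression / network-pharmacology pipeline.

The pipeline moves between three worlds and these containers mark the
boundaries: per-tissue expression matrices with a binary phenotype
(:class:`ExpressionDataset`), symmetric gene–gene matrices in their various
roles along the network construction (:class:`SymmetricGeneMatrix`), and the
protein–protein interactome with node subsets on it (:class:`Interactome`,
drug target sets, disease signatures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ExpressionDataset",
    "SymmetricGeneMatrix",
    "ModulePartition",
    "Interactome",
    "DrugRecord",
    "UNASSIGNED_LABEL",
    "MATRIX_ROLES",
]

#: Reserved module label for genes not assigned to any module ("grey" in the
#: colour convention of co-expression analyses).
UNASSIGNED_LABEL = 0

MATRIX_ROLES = frozenset(
    {
        "adjacency",
        "tom",
        "dissimilarity",
        "consensus",
        "consensus_dissimilarity",
        "eigengene_adjacency",
        "preservation",
    }
)

_UNIT_DIAG_ROLES = frozenset({"adjacency", "tom", "eigengene_adjacency"})
_ZERO_DIAG_ROLES = frozenset({"dissimilarity", "consensus_dissimilarity"})


@dataclass
class ExpressionDataset:
    """One tissue's genes × samples expression matrix with a binary phenotype.

    Parameters
    ----------
    tissue_name
        Human-readable tissue label, e.g. ``"cartilage"``.
    gene_ids
        Ordered unique gene symbols, length N.
    sample_ids
        Ordered unique sample identifiers, length M.
    values
        Real N × M matrix of log-scale normalized intensities.
    phenotype
        Per-sample label: 0 = healthy, 1 = diseased.
    """

    tissue_name: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=int)
        n, m = self.values.shape
        if len(self.gene_ids) != n or len(self.sample_ids) != m:
            raise ValueError(
                f"{self.tissue_name}: matrix shape {self.values.shape} does not "
                f"match {len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if n < 2:
            raise ValueError(f"{self.tissue_name}: need at least 2 genes, got {n}")
        if m < 4:
            raise ValueError(f"{self.tissue_name}: need at least 4 samples, got {m}")
        if len(set(self.gene_ids)) != n:
            raise ValueError(f"{self.tissue_name}: gene identifiers are not unique")
        if np.isnan(self.values).any():
            gi, si = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"{self.tissue_name}: missing value for gene "
                f"{self.gene_ids[gi]!r}, sample {self.sample_ids[si]!r}"
            )
        if self.phenotype.shape != (m,):
            raise ValueError(f"{self.tissue_name}: phenotype length != sample count")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError(f"{self.tissue_name}: phenotype labels must be 0 or 1")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of `genes`, raising on any symbol absent from the dataset."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(
                f"{self.tissue_name}: genes absent from dataset: {sorted(missing)}"
            )
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_index(genes)
        return ExpressionDataset(
            tissue_name=self.tissue_name,
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
            phenotype=self.phenotype.copy(),
        )

    def subset_samples(self, cols: Sequence[int], sample_ids: Sequence[str] | None = None) -> "ExpressionDataset":
        cols = np.asarray(cols, dtype=int)
        ids = list(sample_ids) if sample_ids is not None else [self.sample_ids[c] for c in cols]
        return ExpressionDataset(
            tissue_name=self.tissue_name,
            gene_ids=list(self.gene_ids),
            sample_ids=ids,
            values=self.values[:, cols],
            phenotype=self.phenotype[cols],
        )

    def require_both_classes(self) -> None:
        if not (np.any(self.phenotype == 0) and np.any(self.phenotype == 1)):
            raise ValueError(
                f"{self.tissue_name}: both phenotype classes are required"
            )


@dataclass
class SymmetricGeneMatrix:
    """N × N symmetric matrix over an ordered gene list, tagged with its role.

    Roles track where the matrix sits in the pipeline: ``adjacency`` (powered
    signed correlations, unit diagonal, entries in [0, 1]), ``tom``
    (topological overlap), ``dissimilarity`` (1 − TOM, zero diagonal),
    ``consensus`` / ``consensus_dissimilarity`` (cross-tissue combination),
    ``eigengene_adjacency`` and ``preservation``.
    """

    gene_ids: list[str]
    values: np.ndarray
    role: str

    _SYMMETRY_TOL = 1e-12

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} genes"
            )
        if self.role not in MATRIX_ROLES:
            raise ValueError(f"unknown matrix role {self.role!r}")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > self._SYMMETRY_TOL:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:.3e})")
        if self.role in _UNIT_DIAG_ROLES | _ZERO_DIAG_ROLES:
            lo, hi = self.values.min(initial=0.0), self.values.max(initial=1.0)
            if lo < -1e-12 or hi > 1 + 1e-12:
                raise ValueError(
                    f"{self.role} entries must lie in [0,1]; found [{lo}, {hi}]"
                )
        if self.role in _UNIT_DIAG_ROLES and not np.allclose(np.diag(self.values), 1.0):
            raise ValueError(f"{self.role} matrix must have unit diagonal")
        if self.role in _ZERO_DIAG_ROLES and not np.allclose(np.diag(self.values), 0.0):
            raise ValueError(f"{self.role} matrix must have zero diagonal")

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def require_role(self, *roles: str) -> None:
        if self.role not in roles:
            raise ValueError(f"expected matrix role in {roles}, got {self.role!r}")

    def with_role(self, role: str) -> "SymmetricGeneMatrix":
        return SymmetricGeneMatrix(self.gene_ids, self.values, role)


@dataclass
class ModulePartition:
    """Assignment of every gene to exactly one module.

    Labels are positive integers; :data:`UNASSIGNED_LABEL` (0) is reserved for
    genes left outside every module (the "grey" genes).
    """

    gene_ids: list[str]
    labels: np.ndarray
    unassigned_label: int = UNASSIGNED_LABEL

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.gene_ids),):
            raise ValueError("labels length must equal gene count")
        if (self.labels < 0).any():
            raise ValueError("module labels must be non-negative")

    @property
    def module_ids(self) -> list[int]:
        """Sorted proper module ids (unassigned excluded)."""
        return sorted(int(l) for l in np.unique(self.labels) if l != self.unassigned_label)

    def members(self, module_id: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == module_id]

    def module_sizes(self) -> dict[int, int]:
        return {m: int(np.sum(self.labels == m)) for m in self.module_ids}

    def n_assigned(self) -> int:
        return int(np.sum(self.labels != self.unassigned_label))


@dataclass
class Interactome:
    """Undirected simple protein–protein interaction graph over gene symbols."""

    graph: nx.Graph
    restricted_to_lcc: bool = False

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"interactome contains {len(loops)} self-loop(s)")
        if self.restricted_to_lcc and self.graph.number_of_nodes() > 0:
            if not nx.is_connected(self.graph):
                raise ValueError("restricted_to_lcc is set but graph is disconnected")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class DrugRecord:
    """An approved drug and its protein targets.

    ``targets`` holds the raw symbols from the source table; ``mapped_targets``
    (the subset present in a given interactome) is filled in by the analysis
    that owns the interactome and is tracked separately.
    """

    drug_id: str
    name: str
    targets: set[str]
    mapped_targets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.targets = set(self.targets)
        if not self.targets:
            raise ValueError(f"drug {self.drug_id}: empty target set")

    def map_to(self, interactome: Interactome) -> "DrugRecord":
        return DrugRecord(
            drug_id=self.drug_id,
            name=self.name,
            targets=set(self.targets),
            mapped_targets=self.targets & interactome.nodes,
        )
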