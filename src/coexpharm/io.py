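"""Readers and writers for the pipeline's plain-text formats.

Formats: TSV expression matrix (genes x samples, header row of sample ids),
phenotype TSV (sample id -> 0/1), edge-list TSV for the interactome,
drug-target TSV (drug_id, name, comma-separated targets) and GMT gene-set
collections. Everything round-trips losslessly on valid input.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import DrugRecord, ExpressionDataset, Interactome

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_interactome",
    "write_interactome",
    "read_drug_targets",
    "write_drug_targets",
    "intersect_gene_sets",
    "read_gmt",
]


def read_expression(path: str | Path, phenotype_path: str | Path, tissue_name: str) -> ExpressionDataset:
    """Read a genes x samples TSV plus a phenotype TSV into an ExpressionDataset.

    Duplicate gene symbols are collapsed by keeping the row with the highest
    mean expression (logged). A blank cell raises, naming the gene and sample;
    a sample missing from the phenotype table raises.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)

    if frame.isna().any().any():
        mask = frame.isna()
        gi, si = np.argwhere(mask.to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {frame.index[gi]!r}, "
            f"sample {frame.columns[si]!r}"
        )

    if frame.index.duplicated().any():
        dups = sorted(set(frame.index[frame.index.duplicated()]))
        means = frame.mean(axis=1).to_numpy()
        keep = np.ones(len(frame), dtype=bool)
        for sym in dups:
            rows = np.flatnonzero(frame.index.to_numpy() == sym)
            best = rows[np.argmax(means[rows])]
            keep[rows] = False
            keep[best] = True
        logger.info(
            "%s: collapsed %d duplicate gene symbol(s) keeping highest-mean row: %s",
            path, len(dups), dups,
        )
        frame = frame.iloc[keep]

    pheno = pd.read_csv(phenotype_path, sep="\t", index_col=0)
    pheno.index = pheno.index.astype(str)
    missing = [s for s in frame.columns if s not in pheno.index]
    if missing:
        raise ValueError(f"{phenotype_path}: no phenotype for sample(s) {missing}")
    labels = pheno.iloc[:, 0].reindex(frame.columns).to_numpy()

    return ExpressionDataset(
        tissue_name=tissue_name,
        gene_ids=list(frame.index),
        sample_ids=list(frame.columns),
        values=frame.to_numpy(dtype=float),
        phenotype=labels,
    )


def write_expression(ds: ExpressionDataset, path: str | Path, phenotype_path: str | Path | None = None) -> None:
    frame = pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.sample_ids)
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")
    if phenotype_path is not None:
        ph = pd.DataFrame({"phenotype": ds.phenotype}, index=ds.sample_ids)
        ph.index.name = "sample"
        ph.to_csv(phenotype_path, sep="\t")


def read_interactome(path: str | Path, restrict_lcc: bool = True) -> Interactome:
    """Read a two-column edge list; drop self-loops and duplicate edges.

    Extra columns beyond the first two are ignored. With ``restrict_lcc`` only
    the largest connected component is retained, so shortest paths between any
    two retained nodes are defined.
    """
    n_self = 0
    n_dup = 0
    graph = nx.Graph()
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: edge line with fewer than 2 columns: {line!r}")
            a, b = parts[0].strip(), parts[1].strip()
            n_lines += 1
            if a == b:
                n_self += 1
                continue
            if graph.has_edge(a, b):
                n_dup += 1
                continue
            graph.add_edge(a, b)
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge list")
    if n_self or n_dup:
        logger.info(
            "%s: removed %d self-loop(s) and %d duplicate edge(s)", path, n_self, n_dup
        )
    if restrict_lcc:
        lcc = max(nx.connected_components(graph), key=len)
        dropped = graph.number_of_nodes() - len(lcc)
        if dropped:
            logger.info("%s: restricted to LCC, dropped %d node(s)", path, dropped)
        graph = graph.subgraph(lcc).copy()
    return Interactome(graph=graph, restricted_to_lcc=restrict_lcc)


def write_interactome(interactome: Interactome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in interactome.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_drug_targets(path: str | Path) -> list[DrugRecord]:
    """Read a drug-target TSV (drug_id, name, comma-separated target symbols).

    Rows with an empty target field are dropped with a warning; a duplicated
    drug_id is an error.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] < 3:
        raise ValueError(f"{path}: expected columns drug_id, name, targets")
    ids = frame.iloc[:, 0]
    if ids.duplicated().any():
        dups = sorted(set(ids[ids.duplicated()]))
        raise ValueError(f"{path}: duplicate drug id(s): {dups}")
    records = []
    for _, row in frame.iterrows():
        targets = {t.strip() for t in str(row.iloc[2]).split(",") if t.strip()}
        if not targets:
            logger.warning("%s: drug %s has no targets; dropped", path, row.iloc[0])
            continue
        records.append(DrugRecord(drug_id=row.iloc[0], name=row.iloc[1], targets=targets))
    return records


def write_drug_targets(drugs: list[DrugRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tname\ttargets\n")
        for d in drugs:
            fh.write(f"{d.drug_id}\t{d.name}\t{','.join(sorted(d.targets))}\n")


def intersect_gene_sets(datasets: list[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict all datasets to their common genes, sorted lexicographically.

    Co-expression consensus across tissues requires the identical ordered gene
    list in every tissue; sample columns are untouched.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to intersect")
    common: set[str] = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        common &= set(ds.gene_ids)
    if not common:
        raise ValueError("gene intersection across datasets is empty")
    ordered = sorted(common)
    return [ds.subset_genes(ordered) for ds in datasets]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, member genes per line.

    Empty sets are dropped with a warning; duplicate set names are an error.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed GMT line: {line!r}")
            name = parts[0]
            genes = {g.strip() for g in parts[2:] if g.strip()}
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            if not genes:
                logger.warning("%s: gene set %r is empty; dropped", path, name)
                continue
            sets[name] = genes
    return sets
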