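"""Generate the synthetic multi-tissue study with known ground truth.

Writes the bulky per-tissue expression matrices, the interactome edge list
and the drug-target catalogue under scratch/data/ (inputs for the later
stages), and a small summary table under results/.

The interactome is relabeled so that the planted disease neighborhood
carries the symbols of the planted disease module's top hub genes: the
expression-derived disease signature of stage 06 then genuinely maps onto
the network, the way a real signature maps onto a protein interactome.
"""

import argparse
import json
from pathlib import Path

import networkx as nx

from coexpharm.io import write_drug_targets, write_expression, write_interactome
from coexpharm.synthetic import simulate_drugs, simulate_interactome, simulate_multitissue
from coexpharm.types import Interactome


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.data_dir.mkdir(parents=True, exist_ok=True)
    args.out_dir.mkdir(parents=True, exist_ok=True)

    datasets, truth = simulate_multitissue(
        n_tissues=4, n_genes=1000, n_samples_per_class=20,
        module_sizes=[50, 50, 50], within_cor=0.6, trait_shift=1.2, seed=args.seed,
    )
    for ds in datasets:
        write_expression(
            ds,
            args.data_dir / f"expression_{ds.tissue_name}.tsv",
            args.data_dir / f"phenotype_{ds.tissue_name}.tsv",
        )

    inter, truth = simulate_interactome(2000, 3, 25, seed=args.seed + 1, truth=truth)

    # key the planted neighborhood to the disease module's hub genes
    disease_module = sorted(truth.disease_modules)[0]
    hubs = sorted(
        (g for g, m in truth.module_membership.items() if m == disease_module),
        key=lambda g: -truth.hub_strength[g],
    )
    mapping = dict(zip(sorted(truth.disease_neighborhood), hubs))
    graph = nx.relabel_nodes(inter.graph, mapping)
    inter = Interactome(graph=graph, restricted_to_lcc=inter.restricted_to_lcc)
    truth.disease_neighborhood = {mapping.get(v, v) for v in truth.disease_neighborhood}

    drugs = simulate_drugs(inter, truth, 20, 20, 3, seed=args.seed + 2)
    write_interactome(inter, args.data_dir / "interactome.tsv")
    write_drug_targets(drugs, args.data_dir / "drugs.tsv")

    # gene sets for the enrichment stage: planted modules plus the background
    with open(args.data_dir / "genesets.gmt", "w") as fh:
        for m, genes in sorted(truth.planted_module_genes().items()):
            fh.write(f"planted_module_{m}\tsynthetic\t" + "\t".join(sorted(genes)) + "\n")

    (args.data_dir / "truth.json").write_text(json.dumps({
        "module_membership": truth.module_membership,
        "disease_modules": sorted(truth.disease_modules),
        "hub_strength": truth.hub_strength,
        "disease_neighborhood": sorted(truth.disease_neighborhood),
        "drug_class": truth.drug_class,
    }, indent=1))

    summary = {
        "tissues": len(datasets),
        "genes": datasets[0].n_genes,
        "samples_per_tissue": datasets[0].n_samples,
        "interactome_nodes": inter.n_nodes,
        "interactome_edges": inter.n_edges,
        "neighborhood_size": len(truth.disease_neighborhood),
        "drugs": len(drugs),
        "seed": args.seed,
    }
    (args.out_dir / "01_simulation_summary.json").write_text(json.dumps(summary, indent=2))
    print("simulated study:", summary)


if __name__ == "__main__":
    main()
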