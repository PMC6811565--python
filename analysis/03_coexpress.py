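"""Consensus co-expression network construction and module detection.

Scans the soft threshold for scale-free fit, builds per-tissue TOMs, takes
the min-consensus across tissues and cuts the dendrogram into modules.
Writes the scale-free fit table and the gene -> module assignment.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from coexpharm.coexpression import consensus_modules

from _common import load_tissues


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    datasets = load_tissues(args.data_dir)
    partition, info = consensus_modules(datasets)

    fits = pd.concat(
        [f.table.assign(tissue=t) for t, f in info["fits"].items()], ignore_index=True
    )
    fits.to_csv(args.out_dir / "03_scale_free_fit.tsv", sep="\t", index=False)

    assign = pd.DataFrame({"gene": partition.gene_ids, "module": partition.labels})
    assign.to_csv(args.out_dir / "03_modules.tsv", sep="\t", index=False)

    sizes = partition.module_sizes()
    beta = info["beta"][datasets[0].tissue_name]
    (args.out_dir / "03_module_summary.json").write_text(json.dumps(
        {"beta": beta, "n_modules": len(sizes), "module_sizes": sizes,
         "unassigned": int((partition.labels == 0).sum())}, indent=2))
    print(f"shared soft threshold beta = {beta}")
    print(f"found {len(sizes)} consensus modules, sizes {sizes}; "
          f"{int((partition.labels == 0).sum())} genes unassigned")


if __name__ == "__main__":
    main()
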