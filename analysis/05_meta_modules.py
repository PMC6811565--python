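"""Eigengene networks, meta-modules and cross-tissue preservation.

Builds per-tissue module eigengene networks, clusters the consensus
eigengene dissimilarity into meta-modules (MDS + k-means) and quantifies
meta-module preservation between every tissue pair via the preservation
network's scaled connectivity C and density D.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from coexpharm.eigengenes import (
    consensus_dissimilarity,
    differential_eigengene_analysis,
    eigengene_network,
    meta_modules,
    module_eigengene,
)

from _common import load_partition, load_tissues


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=13)
    ap.add_argument("--k", type=int, default=2,
                    help="number of meta-modules (k-means clusters)")
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    datasets = load_tissues(args.data_dir)
    partition = load_partition(args.out_dir)

    nets = []
    for ds in datasets:
        egs = [
            module_eigengene(ds, partition.members(m), owner=f"M{m}")
            for m in partition.module_ids
        ]
        nets.append(eigengene_network(egs))
    discons = consensus_dissimilarity(nets)
    k = min(args.k, discons.n)
    assignment = meta_modules(discons, k=k, seed=args.seed)
    pd.DataFrame(
        {"module": list(assignment), "meta_module": list(assignment.values())}
    ).to_csv(args.out_dir / "05_meta_modules.tsv", sep="\t", index=False)

    stats, _ = differential_eigengene_analysis(datasets, partition, assignment)
    report = {
        f"{a}|{b}": {
            "density": ps.density,
            "scaled_connectivity": dict(
                zip(ps.node_ids, map(float, ps.scaled_connectivity))
            ),
        }
        for (a, b), ps in stats.items()
    }
    (args.out_dir / "05_preservation.json").write_text(json.dumps(report, indent=2))
    print(f"{len(set(assignment.values()))} meta-modules over {discons.n} modules")
    for pair, entry in report.items():
        print(f"  {pair}: density D = {entry['density']:.3f}")


if __name__ == "__main__":
    main()
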