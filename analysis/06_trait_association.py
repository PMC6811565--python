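"""Gene significance, intramodular connectivity and disease meta-module calls.

Computes per-tissue GS (|cor| with the phenotype) and GC (within-module
weighted degree), medians them into consensus scores and tests, per
meta-module, whether hub genes are the trait-correlated ones.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from coexpharm.coexpression import consensus_modules
from coexpharm.traits import build_score_table, consensus_scores, gs_gc_correlation

from _common import load_partition, load_tissues


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    datasets = load_tissues(args.data_dir)
    partition = load_partition(args.out_dir)
    meta = pd.read_csv(args.out_dir / "05_meta_modules.tsv", sep="\t")
    assignment = dict(zip(meta["module"], meta["meta_module"]))

    _, info = consensus_modules(datasets)
    table = consensus_scores(
        build_score_table(datasets, info["adjacencies"], partition, assignment)
    )
    # per-gene scores are a bulky intermediate; they live with the data
    table.to_csv(args.data_dir / "gene_scores.tsv", sep="\t")

    rows = []
    for mm in sorted(set(assignment.values())):
        r, p = gs_gc_correlation(table, mm)
        n = int((table["meta_module"] == mm).sum())
        rows.append({"meta_module": mm, "r": r, "p": p, "n_genes": n})
        print(f"meta-module {mm}: GS-GC r = {r:.3f} (p = {p:.2e}, {n} genes)")
    summary = pd.DataFrame(rows)
    summary.to_csv(args.out_dir / "06_gs_gc_correlation.tsv", sep="\t", index=False)
    disease = summary.loc[(summary["r"] > 0) & (summary["p"] < 0.05), "meta_module"]
    (args.out_dir / "06_disease_meta_modules.json").write_text(
        json.dumps({"disease_meta_modules": [int(m) for m in disease]})
    )
    print("disease-associated meta-module(s):", list(disease))


if __name__ == "__main__":
    main()
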