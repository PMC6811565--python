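"""Validation of the drug ranking against bottom and random control lists.

Uses the planted drug classes as the hit labels (proximal = hit): the top
list should be enriched for proximal drugs relative to random controls, and
the Fisher tests quantify that contrast.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from coexpharm.io import read_drug_targets, read_interactome
from coexpharm.pharmacology import GraphIndex, disease_signature, validate_lists

from _common import load_truth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=15)
    ap.add_argument("--n-reps", type=int, default=300)
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    interactome = read_interactome(args.data_dir / "interactome.tsv", restrict_lcc=True)
    drugs = [d.map_to(interactome) for d in read_drug_targets(args.data_dir / "drugs.tsv")]
    truth = load_truth(args.data_dir)
    hits = {d.drug_id: truth["drug_class"][d.drug_id] == "proximal" for d in drugs}

    table = pd.read_csv(args.data_dir / "gene_scores.tsv", sep="\t", index_col=0)
    disease_mm = json.loads(
        (args.out_dir / "06_disease_meta_modules.json").read_text()
    )["disease_meta_modules"][0]
    sig = disease_signature(table, disease_mm, interactome, quantile=0.8)

    report = validate_lists(
        GraphIndex(interactome), drugs, sig, hits,
        seed=args.seed, n_reps=args.n_reps, k=10, min_bin_size=25, dc_quantile=0.5,
    )
    (args.out_dir / "09_validation.json").write_text(json.dumps(report, indent=2))
    hc = report["hit_counts"]
    print("hit counts (proximal drugs) per list of 10:")
    print(f"  top: {hc['top']}, bottom: {hc['bottom']}, "
          f"random-by-dc: {hc['random_by_dc']}, random-by-z: {hc['random_by_z']}")
    for name, (p2, p1) in report["fisher"].items():
        print(f"  Fisher {name}: two-sided p = {p2:.3g}, one-sided p = {p1:.3g}")


if __name__ == "__main__":
    main()
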