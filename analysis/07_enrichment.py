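"""Over-representation of the disease meta-module in the planted gene sets.

Sanity check of the enrichment machinery on the synthetic study: the
disease meta-module should over-represent the planted disease module's gene
set and nothing else.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from coexpharm.enrichment import GeneSetCollection, ora
from coexpharm.io import read_gmt

from _common import load_partition


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    partition = load_partition(args.out_dir)
    table = pd.read_csv(args.data_dir / "gene_scores.tsv", sep="\t", index_col=0)
    disease = json.loads(
        (args.out_dir / "06_disease_meta_modules.json").read_text()
    )["disease_meta_modules"]

    universe = set(partition.gene_ids)
    collection = GeneSetCollection(read_gmt(args.data_dir / "genesets.gmt"))
    for mm in disease:
        query = set(table.index[table["meta_module"] == mm])
        res = ora(query, universe, collection)
        res.to_csv(args.out_dir / f"07_enrichment_mm{mm}.tsv", sep="\t", index=False)
        hits = res[res["significant"]]
        print(f"meta-module {mm}: {len(hits)} significant set(s)")
        for _, row in hits.iterrows():
            print(f"  {row['set']}: overlap {row['overlap']}/{row['set_size']}, "
                  f"adj_p = {row['adj_p']:.2e}")


if __name__ == "__main__":
    main()
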