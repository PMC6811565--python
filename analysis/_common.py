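"""Shared plumbing for the numbered analysis drivers."""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from coexpharm.io import read_expression
from coexpharm.types import ModulePartition

TISSUES = ["tissue1", "tissue2", "tissue3", "tissue4"]


def load_tissues(data_dir: Path):
    return [
        read_expression(
            data_dir / f"expression_{t}.tsv", data_dir / f"phenotype_{t}.tsv", t
        )
        for t in TISSUES
    ]


def load_truth(data_dir: Path) -> dict:
    return json.loads((data_dir / "truth.json").read_text())


def load_partition(out_dir: Path) -> ModulePartition:
    frame = pd.read_csv(out_dir / "03_modules.tsv", sep="\t")
    return ModulePartition(list(frame["gene"]), np.asarray(frame["module"]))
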