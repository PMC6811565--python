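"""Over-representation analysis of gene sets with Bonferroni control.

A query gene list (e.g. a meta-module) is tested against each set of a GMT
collection with the upper-tail hypergeometric probability P(X >= k), where
the population is the analysis universe (the intersected gene list, not the
whole genome), and Bonferroni-adjusted across the tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "ora"]


@dataclass
class GeneSetCollection:
    """Named gene sets, typically read from a GMT file via `io.read_gmt`."""

    sets: dict[str, set[str]]
    source_line_count: int = 0

    def __post_init__(self) -> None:
        empties = [name for name, s in self.sets.items() if not s]
        for name in empties:
            logger.warning("gene set %r is empty; dropped", name)
            del self.sets[name]

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={n: s & universe for n, s in self.sets.items() if s & universe},
            source_line_count=self.source_line_count,
        )


def ora(
    query: set[str],
    universe: set[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of `query` in each collection set.

    Query genes outside the universe are dropped with a warning; each set is
    intersected with the universe before testing. p = P(X >= k) with
    population |universe|, successes |set|, draws |query|;
    adj_p = min(1, p * number of tested sets); significant iff adj_p <= alpha.
    Returns a table sorted by adj_p.
    """
    outside = query - universe
    if outside:
        logger.warning("%d query gene(s) outside the universe dropped", len(outside))
    query = query & universe
    if not query:
        raise ValueError("query is empty after restricting to the universe")
    tested = collection.restricted_to(universe)
    m = len(tested.sets)
    rows = []
    for name, members in sorted(tested.sets.items()):
        k = len(query & members)
        # P(X >= k) = survival function at k-1
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        p = min(p, 1.0)
        adj = min(1.0, p * m)
        rows.append((name, len(members), k, p, adj, adj <= alpha))
    frame = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "p", "adj_p", "significant"]
    ).sort_values(["adj_p", "p", "set"], kind="stable").reset_index(drop=True)
    return frame
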