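"""Hypergeometric over-representation analysis against GMT collections.

Uses the same hypergeometric kernel as the reversal statistics; one-sided
over-representation only, BH across the sets of a collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .stats import bh_adjust, hypergeom_overlap


@dataclass
class GeneSetCollection:
    sets: dict          # name -> set of gene ids
    descriptions: dict  # name -> description string
    source: str = ""

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping emptied sets."""
        universe = set(universe)
        sets = {n: s & universe for n, s in self.sets.items()}
        sets = {n: s for n, s in sets.items() if s}
        return GeneSetCollection(
            sets=sets,
            descriptions={n: self.descriptions.get(n, "") for n in sets},
            source=self.source,
        )


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line ``name<TAB>description<TAB>member...``.

    Duplicate members within a set collapse; a line with fewer than 3
    fields raises with its line number.
    """
    sets, desc = {}, {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = set(fields[2:])
        desc[name] = fields[1]
    return GeneSetCollection(sets=sets, descriptions=desc, source=str(path))


def write_gmt(coll: GeneSetCollection, path):
    lines = [
        "\t".join([name, coll.descriptions.get(name, "")] + sorted(members))
        for name, members in coll.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def enrich(query, coll: GeneSetCollection, universe) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of ``coll``.

    ``query`` must be a subset of ``universe``; each set is intersected
    with the universe before testing. Columns: set, k (overlap), K (set
    size in universe), n (query size), N (universe size), p, padj; sorted
    by p ascending.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query contains genes outside the universe")
    rows = []
    for name, members in coll.restrict(universe).sets.items():
        k = len(query & members)
        rows.append(
            {
                "set": name,
                "k": k,
                "K": len(members),
                "n": len(query),
                "N": len(universe),
                "p": hypergeom_overlap(k, len(members), len(query), len(universe)),
            }
        )
    table = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if not table.empty:
        table["padj"] = bh_adjust(table["p"])
        table = table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return table
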