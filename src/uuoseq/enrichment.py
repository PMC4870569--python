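"""Database-free gene-set over-representation analysis.

Collections arrive as GMT files; each set is scored against a query gene
list with the hypergeometric upper tail

    p = P[X >= k],  X ~ Hypergeometric(N, K, n)

where N is the universe size, K the set size within the universe, n the
query size and k the observed overlap.  P-values are BH-adjusted across
the sets of the collection.  The universe is by convention the set of
tested genes (filter survivors), so enrichment conditions on testability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust, de_gene_set
from .model import ValidationError


class GmtParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"GMT line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class GeneSetCollection:
    sets: dict = field(default_factory=dict)        # name -> set of gene ids
    descriptions: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """GMT: one set per line, tab-separated name, description, members."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(lineno, "expected name, description and >= 1 member")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise GmtParseError(lineno, f"set {name!r} has no members")
            coll.sets[name] = set(members)  # duplicates collapse
            coll.descriptions[name] = desc
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            members = "\t".join(sorted(collection.sets[name]))
            desc = collection.descriptions.get(name, "")
            fh.write(f"{name}\t{desc}\t{members}\n")


def hypergeometric_overrep(query, collection: GeneSetCollection,
                           universe) -> pd.DataFrame:
    """Over-representation of ``query`` in each set, within ``universe``.

    Query genes outside the universe are dropped with a warning.  Returns
    a frame sorted by p with columns set, k, n, K, N, p, fdr.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
        query &= universe
    n = len(query)
    big_n = len(universe)
    rows = []
    for name, members in collection.sets.items():
        in_universe = members & universe
        big_k = len(in_universe)
        k = len(query & in_universe)
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"set": name, "k": k, "n": n, "K": big_k, "N": big_n,
                     "p": min(max(p, 1e-300), 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "set"]).reset_index(drop=True)
    return df


def enrich_de_lists(de_tables: dict[str, pd.DataFrame],
                    collection: GeneSetCollection,
                    direction: str = "up",
                    top: int | None = 10) -> dict[str, pd.DataFrame]:
    """Per-contrast over-representation of the up/down/all DE gene lists.

    The universe for each contrast is the full set of tested genes in its
    DE table.  ``top`` truncates each result to the best-ranked sets
    (None keeps everything).
    """
    out = {}
    for cid, table in de_tables.items():
        universe = set(table["gene_id"])
        query = de_gene_set(table, direction=direction)
        res = hypergeometric_overrep(query, collection, universe)
        out[cid] = res.head(top) if top else res
    return out
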