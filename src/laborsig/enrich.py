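"""Gene-set over-representation analysis (exact hypergeometric test).

Given a query gene list (typically the high-confidence labor genes) and a
measured universe, each gene set is scored by the upper-tail hypergeometric
probability of observing at least the realized overlap, followed by
Benjamini-Hochberg adjustment across the retained sets. Sets are restricted
to the universe and filtered by size (defaults 5-500) before testing.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class GMTParseError(ValueError):
    pass


class GeneSetCollection:
    """Named gene-identifier lists with optional descriptions."""

    def __init__(self, sets: dict[str, list[str]], descriptions: dict[str, str] | None = None):
        for name, members in sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {name: list(dict.fromkeys(members)) for name, members in sets.items()}
        self.descriptions = descriptions or {}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT parsing: name, description, then members (deduplicated)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = fields
            sets[name] = list(dict.fromkeys(m for m in members if m))
            descriptions[name] = desc
    collection = GeneSetCollection.__new__(GeneSetCollection)
    collection.sets = sets
    collection.descriptions = descriptions
    return collection


def ora(
    query,
    universe,
    collection: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    ``query`` must be a subset of ``universe`` (the measured genes). Returns
    a DataFrame indexed by set name with columns overlap_count,
    set_size_in_universe, p_raw, q_value, overlap_members, sorted by q then
    p. p_raw is P[X >= overlap] for X hypergeometric with population
    |universe|, |set in universe| successes, and |query| draws.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe, e.g. {extra}")
    n_universe = len(universe)
    n_query = len(query)

    records = []
    for name, members in collection:
        in_universe = set(members) & universe
        size = len(in_universe)
        if not min_size <= size <= max_size:
            continue
        overlap = query & in_universe
        k = len(overlap)
        # upper tail: P[X >= k] = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, n_universe, size, n_query))
        p = min(p, 1.0)
        records.append((name, k, size, p, ",".join(sorted(overlap))))
    table = pd.DataFrame(
        records, columns=["set", "overlap_count", "set_size_in_universe", "p_raw", "overlap_members"]
    ).set_index("set")
    if len(table):
        _, q, _, _ = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")
        table["q_value"] = q
    else:
        table["q_value"] = pd.Series(dtype=float)
    table = table[["overlap_count", "set_size_in_universe", "p_raw", "q_value", "overlap_members"]]
    return table.sort_values(["q_value", "p_raw"], kind="stable")
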