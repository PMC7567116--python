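"""Set-overlap bookkeeping and over-representation analysis.

Jaccard agreement between feature sets, Venn-region counts, and one-sided
hypergeometric over-representation (ORA) with Benjamini-Hochberg correction
across a GMT gene-set collection. The background universe is an explicit,
mandatory choice of the caller: enrichment p-values depend on it directly,
so no silent default is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def jaccard(size_a: int, size_b: int, overlap: int) -> float:
    """|A n B| / |A u B| from the three printed counts."""
    if overlap > min(size_a, size_b) or min(size_a, size_b, overlap) < 0:
        raise ValueError(f"inconsistent counts: |A|={size_a}, |B|={size_b}, overlap={overlap}")
    union = size_a + size_b - overlap
    if union <= 0:
        raise ValueError("empty union")
    return overlap / union


def union_size(size_a: int, size_b: int, overlap: int) -> int:
    """Inclusion-exclusion union size from printed counts."""
    if overlap > min(size_a, size_b) or min(size_a, size_b, overlap) < 0:
        raise ValueError("inconsistent counts")
    return size_a + size_b - overlap


def venn_counts(sets: dict[str, set]) -> dict[tuple[bool, ...], int]:
    """Element counts for every region of the Venn partition of 2-4 sets.

    Keys are membership tuples in the order of ``sets``; the all-False
    pattern is omitted. Region counts sum to the union size.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("venn_counts supports 2-4 sets")
    names = list(sets)
    counts = {
        pattern: 0
        for pattern in product([True, False], repeat=len(names))
        if any(pattern)
    }
    for element in set().union(*sets.values()):
        pattern = tuple(element in sets[n] for n in names)
        counts[pattern] += 1
    return counts


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to an explicit background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if any(not name for name in self.sets):
            raise ValueError("empty gene-set name")
        self.sets = {n: set(s) & self.universe for n, s in self.sets.items()}

    @classmethod
    def from_gmt(cls, path: str | Path, universe: set[str]) -> "GeneSetCollection":
        return cls(sets=read_gmt(path), universe=universe)


def hypergeom_ora(hits: set[str], collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided (over-representation) hypergeometric test per gene set.

    For each set of size K in a universe of size N, with n = |hits| and
    k = |hits n set|: p = P(X >= k), X ~ Hypergeom(N, K, n); BH across the
    collection; fold enrichment (k/n) / (K/N).
    """
    universe = collection.universe
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    N = len(universe)
    n = len(hits)
    rows = []
    for name, members in sorted(collection.sets.items()):
        K = len(members)
        k = len(hits & members)
        if n == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 and K > 0 else np.nan
        rows.append((name, k, K, n, N, p, fold))
    out = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "N", "p", "fold_enrichment"]
    ).set_index("set")
    if len(out):
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = q
    else:
        out["q"] = []
    return out.sort_values(["p", "set"], kind="mergesort")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")
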