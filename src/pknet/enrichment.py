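"""Over-representation analysis against a gene-set collection.

The statistic is the upper-tail hypergeometric probability: given a
universe of N identifiers of which K belong to a gene set, and a query of
n identifiers with k falling in the set, the enrichment p-value is
P(X >= k) for X ~ Hypergeometric(N, K, n). P-values are adjusted with the
Benjamini–Hochberg step-up procedure over *all* tested sets (including
zero-overlap sets, so the hypothesis count does not depend on outcomes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .interactome import ProteinSet

__all__ = [
    "GeneSetCollection",
    "hypergeometric_tail",
    "benjamini_hochberg",
    "enrich",
    "significant_overlap",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a common identifier universe.

    The universe defaults to the union of all set members; supplying a
    larger background (e.g. the interactome node set intersected with
    annotated genes) tightens the null model.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(m) for name, m in self.sets.items()}
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if not self.universe:
            self.universe = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        else:
            self.universe = frozenset(self.universe)
            for name, members in self.sets.items():
                if not members <= self.universe:
                    raise ValueError(f"gene set {name!r} has members outside the universe")

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(
        cls, source: str | TextIO, universe: Iterable[str] | None = None
    ) -> "GeneSetCollection":
        """Parse GMT (name <tab> description <tab> member...). Members
        outside a supplied universe are dropped per set."""
        close = False
        if not hasattr(source, "read"):
            source = open(source, "r", encoding="utf-8")
            close = True
        sets: dict[str, frozenset[str]] = {}
        try:
            for line in source:  # type: ignore[union-attr]
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT line: {line!r}")
                name, members = fields[0], frozenset(f for f in fields[2:] if f)
                if universe is not None:
                    members = members & frozenset(universe)
                if members:
                    sets[name] = members
        finally:
            if close:
                source.close()  # type: ignore[union-attr]
        return cls(sets=sets, universe=frozenset(universe) if universe else frozenset())

    def to_gmt(self, sink: str | TextIO, description: str = "na") -> None:
        close = False
        if not hasattr(sink, "write"):
            sink = open(sink, "w", encoding="utf-8")
            close = True
        try:
            for name in sorted(self.sets):
                members = "\t".join(sorted(self.sets[name]))
                sink.write(f"{name}\t{description}\t{members}\n")  # type: ignore[union-attr]
        finally:
            if close:
                sink.close()  # type: ignore[union-attr]


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``N``: universe size; ``K``: gene-set size; ``n``: query size;
    ``k``: observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require K, n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), in the
    input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: ProteinSet | Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in every
    collection set.

    Query members outside the universe are dropped (the count is recorded
    in ``attrs['n_unmapped']``). The BH adjustment runs over all sets in
    the collection; the returned table keeps only sets with overlap >= 1,
    sorted by p ascending with ties broken by set name.
    """
    members = query.members if isinstance(query, ProteinSet) else frozenset(query)
    mapped = frozenset(members) & collection.universe
    if not mapped:
        raise ValueError("query has no members in the collection universe")
    N, n = len(collection.universe), len(mapped)
    names = sorted(collection.sets)
    ks = [len(collection.sets[name] & mapped) for name in names]
    ps = [
        hypergeometric_tail(N, len(collection.sets[name]), n, k)
        for name, k in zip(names, ks)
    ]
    qs = benjamini_hochberg(ps)
    rows = [
        {
            "set_name": name,
            "overlap_k": k,
            "set_size_K": len(collection.sets[name]),
            "query_size_n": n,
            "universe_size_N": N,
            "p": p,
            "q": q,
        }
        for name, k, p, q in zip(names, ks, ps, qs)
        if k >= 1
    ]
    table = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap_k", "set_size_K",
            "query_size_n", "universe_size_N", "p", "q",
        ],
    )
    table = table.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    table.attrs["n_tested"] = len(names)
    table.attrs["n_unmapped"] = len(frozenset(members) - mapped)
    return table


def significant_overlap(
    tables: Mapping[str, pd.DataFrame], q_threshold: float
) -> dict[tuple[str, ...], list[str]]:
    """Venn-region decomposition of the significant sets of 2–3 enrichment
    tables.

    Returns a mapping from each non-trivial label combination (exclusive
    region, as a sorted tuple) to the sorted gene-set names falling in
    exactly that region; regions are present even when empty so counts sum
    to the union size.
    """
    if not 0 < q_threshold < 1:
        raise ValueError("q_threshold must lie in (0, 1)")
    if not 2 <= len(tables) <= 3:
        raise ValueError("significant_overlap expects 2 or 3 tables")
    sig = {
        label: set(t.loc[t["q"] < q_threshold, "set_name"])
        for label, t in tables.items()
    }
    labels = sorted(sig)
    regions: dict[tuple[str, ...], list[str]] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(sig[l] for l in combo))
            outside = set.union(set(), *(sig[l] for l in labels if l not in combo))
            regions[combo] = sorted(inside - outside)
    return regions
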