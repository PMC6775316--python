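"""Gene-set over-representation with the EASE-modified Fisher statistic.

The EASE score is the one-tailed Fisher exact (hypergeometric upper
tail) p-value computed after removing one gene from the overlap: with
overlap k, query size n, set size K and universe N,

    ease_p = P(X >= k - 1),   X ~ Hypergeom(N, K, n),

so ease_p >= fisher_p always, and k <= 1 gives p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .expression import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested on."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def restricted(self, background: set[str]) -> "GeneSetCollection":
        """Intersect every set with *background* and drop emptied sets."""
        new = {
            name: members & background
            for name, members in self.sets.items()
        }
        return GeneSetCollection(
            sets={k: v for k, v in new.items() if v}, universe=set(background)
        )


def _check_table(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) <= N and n <= N and K <= N):
        raise ValueError(f"inconsistent contingency table: k={k} n={n} K={K} N={N}")


def fisher_p(k: int, n: int, K: int, N: int) -> float:
    """One-tailed Fisher exact p-value: P(X >= k), X ~ Hypergeom(N, K, n)."""
    _check_table(k, n, K, N)
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """EASE p-value: upper hypergeometric tail at max(k - 1, 0)."""
    _check_table(k, n, K, N)
    if k <= 1:
        return 1.0
    return float(hypergeom.sf(k - 2, N, K, n))


def enrich_module(
    module_genes: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
) -> pd.DataFrame:
    """Test every gene set for over-representation in *module_genes*.

    Gene sets are restricted to the background universe first; only sets
    with overlap k >= 1 are reported.  Returns a DataFrame with columns
    term, k, n, K, N, ease_p, fisher_p, fdr sorted by ease_p (BH across
    the tested sets).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    query = set(module_genes) & background
    restricted = collection.restricted(background)
    N, n = len(background), len(query)

    rows = []
    for term, members in sorted(restricted.sets.items()):
        K = len(members)
        k = len(query & members)
        if k < 1:
            continue
        rows.append((term, k, n, K, N, ease_score(k, n, K, N), fisher_p(k, n, K, N)))
    df = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "ease_p", "fisher_p"]
    )
    if len(df):
        df["fdr"] = bh_adjust(df["ease_p"].to_numpy())
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df.sort_values("ease_p", kind="mergesort").reset_index(drop=True)


def common_enriched(
    results: Mapping[str, pd.DataFrame],
    module_genes: Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Terms enriched (ease_p <= p_cut) in every group, with common genes.

    The common genes of a term are the intersection over groups of
    (term members ∩ that group's module genes).  Returns a DataFrame with
    columns term, max_ease_p, n_common_genes, common_genes.
    """
    if len(results) < 2:
        raise ValueError("need results from at least 2 groups")
    per_group_sig = {
        g: set(df.loc[df["ease_p"] <= p_cut, "term"]) for g, df in results.items()
    }
    common_terms = set.intersection(*per_group_sig.values())

    rows = []
    for term in sorted(common_terms):
        members = collection.sets.get(term, set())
        genes = set(members)
        for g, mg in module_genes.items():
            genes &= set(mg)
        max_p = max(
            float(df.loc[df["term"] == term, "ease_p"].iloc[0])
            for df in results.values()
        )
        rows.append((term, max_p, len(genes), ",".join(sorted(genes))))
    return pd.DataFrame(
        rows, columns=["term", "max_ease_p", "n_common_genes", "common_genes"]
    )
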