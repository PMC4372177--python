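"""Gene-set over-representation of aDMC genes by Fisher's exact test.

The genes carried by clusters of one direction (positive or negative age
association) form the query; each user-supplied gene set (GMT format) is
tested for over-representation against a background universe — by default
every gene covered by at least one post-QC probe, which controls for array
coverage bias. The one-sided P value is the upper hypergeometric tail

    P(X >= k),  X ~ Hypergeom(N, K, n)

with N the background size, K the background genes in the set, n the query
size and k the query genes in the set. Benjamini-Hochberg (default) or
Bonferroni correction is applied across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "fisher_overrep",
    "enrich_genes",
    "enrich_clusters",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background gene universe."""

    sets: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self):
        clean = {}
        for name, genes in self.sets.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            inter = genes & self.background
            if len(inter) < len(genes):
                warnings.warn(
                    f"gene set {name!r}: {len(genes) - len(inter)} genes outside "
                    "the background were dropped",
                    stacklevel=2,
                )
            clean[name] = genes
        self.sets = clean
        self.background = frozenset(self.background)


def read_gmt(path, background) -> GeneSetCollection:
    """Read sets from GMT (name <tab> description <tab> gene1 <tab> ...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return GeneSetCollection(sets=sets, background=frozenset(background))


def fisher_overrep(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation P value ``P(X >= k)``.

    k: query genes in the set; K: background genes in the set; n: query size;
    N: background size.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N} "
            "(need 0 <= k <= min(K, n) <= N)"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_genes(
    query,
    collection: GeneSetCollection,
    method: str = "fdr_bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every set of the collection against a query gene list.

    Query genes outside the background are dropped (logged). Returns one row
    per set with the contingency counts, raw one-sided P and the adjusted P
    (Benjamini-Hochberg by default; ``method='bonferroni'`` for the stricter
    family-wise control).
    """
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError("method must be 'fdr_bh' or 'bonferroni'")
    query = set(query)
    outside = query - collection.background
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the background were dropped",
            stacklevel=2,
        )
    query &= collection.background
    if not query:
        warnings.warn("empty query after background intersection", stacklevel=2)
        return pd.DataFrame(
            columns=["set_name", "k", "K", "n", "N", "p", "p_adjusted", "significant"]
        )
    N = len(collection.background)
    n = len(query)
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name] & collection.background
        K = len(genes)
        k = len(genes & query)
        p = fisher_overrep(k, K, n, N) if K else 1.0
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows)
    rej, adj, _, _ = multipletests(out["p"], alpha=alpha, method=method)
    out["p_adjusted"] = adj
    out["significant"] = rej
    return out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)


def enrich_clusters(
    clusters,
    direction: str,
    collection: GeneSetCollection,
    method: str = "fdr_bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation for the genes of one cluster direction.

    ``clusters`` is a list of :class:`~kinewas.clusters.ClusterRecord`; the
    query is the union of gene symbols carried by clusters labeled with the
    requested ``direction`` ('positive' or 'negative').
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    query = sorted({g for c in clusters if c.direction == direction for g in c.genes})
    if not query:
        warnings.warn(f"no genes in {direction} clusters; empty result", stacklevel=2)
    return enrich_genes(query, collection, method=method, alpha=alpha)
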