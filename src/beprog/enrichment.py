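"""Hypergeometric gene-set enrichment and guilt-by-association ranking.

Over-representation is one-sided: for a query of n genes from a universe of
N, a set covering K universe genes and overlapping the query in k, the
p-value is P(X >= k) for X ~ Hypergeometric(N, K, n), adjusted across sets
by Benjamini-Hochberg.  Network prioritization is regularized label
propagation on a user-supplied weighted network: scores f solve
(I + lambda * L) f = y with L the symmetric-normalized graph Laplacian and
y the seed indicator — the algorithmic core of guilt-by-association tools,
kept testable offline against a dense linear solve.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import stats

from beprog.types import (
    EnrichmentResult,
    GeneSetCollection,
    ValidationError,
    WeightedNetwork,
)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be a 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def hypergeom_enrich(
    query: set, sets: GeneSetCollection, universe: set
) -> list[EnrichmentResult]:
    """One-sided over-representation of each named set in the query.

    Query genes outside the universe are dropped with a warning; each set
    is intersected with the universe before testing.  Results are sorted by
    p, ties by set name.
    """
    if not universe:
        raise ValidationError("empty universe")
    outside = set(query) - set(universe)
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=2,
        )
    q = set(query) & set(universe)
    if not q:
        raise ValidationError("query empty after restricting to the universe")
    N, n = len(universe), len(q)
    rows = []
    for name, members in sets.items():
        in_universe = set(members) & set(universe)
        K = len(in_universe)
        k = len(in_universe & q)
        # P(X >= k); k = 0 gives the certain event, p = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        rows.append((name, k, K, p))
    p_adj = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(set_name=name, k=k, K=K, n=n, N=N, p=p, p_adj=float(pa))
        for (name, k, K, p), pa in zip(rows, p_adj)
    ]
    return sorted(results, key=lambda r: (r.p, r.set_name))


def propagate_labels(
    net: WeightedNetwork, seeds: set, lam: float = 1.0
) -> pd.DataFrame:
    """Regularized label propagation from a seed gene set.

    Solves (I + lambda * L_sym) f = y with y = 1 on seeds, 0 elsewhere.
    Scores are non-negative; nodes in components without a seed score 0.
    Returns a frame (score, is_seed) sorted by descending score, ties by
    gene id.
    """
    if not lam > 0:
        raise ValidationError("lambda must be > 0")
    nodes = sorted(net.graph.nodes)
    seed_nodes = set(seeds) & set(nodes)
    if not seed_nodes:
        raise ValidationError("no seed gene is present in the network")
    L = nx.normalized_laplacian_matrix(net.graph, nodelist=nodes, weight="weight")
    A = sp.identity(len(nodes), format="csc") + lam * L.tocsc()
    y = np.array([1.0 if v in seed_nodes else 0.0 for v in nodes])
    f = spla.spsolve(A, y)
    f = np.maximum(f, 0.0)  # clip numerical negatives
    df = pd.DataFrame(
        {"score": f, "is_seed": [v in seed_nodes for v in nodes]},
        index=pd.Index(nodes, name="gene_id"),
    )
    return df.iloc[sorted(range(len(nodes)), key=lambda i: (-f[i], nodes[i]))]


def expand_neighbors(
    net: WeightedNetwork, seeds: set, k: int = 100, lam: float = 1.0
) -> set:
    """Seeds plus the top-k non-seed genes by propagation score.

    Non-seeds with zero score (unreachable from any seed) are never added;
    ties are broken by gene id.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")
    scores = propagate_labels(net, seeds, lam=lam)
    non_seed = scores[(~scores["is_seed"]) & (scores["score"] > 0)]
    return set(seeds) | set(non_seed.index[:k])
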