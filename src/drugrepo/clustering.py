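"""Agglomerative clustering of drug latent vectors and known-drug enrichment.

Drugs that share interaction profiles end up close in the PMF latent
space, so hierarchical clustering of latent rows groups pharmacologically
related drugs. The merge tree is scanned for clusters over-represented in
the query target's known-drug set (one-sided hypergeometric tail with
Benjamini-Hochberg correction across the evaluated nodes), under each of
several distance metrics; candidates recovered under every metric form
the consensus hit set.

Agglomeration is a hand-rolled Lance-Williams loop rather than a call
into scipy because downstream selection demands a fully specified tie
rule: equal minimum distances break on the lowest (node_a, node_b) id
pair, making the dendrogram a pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

METRICS = ("euclidean", "cosine", "cityblock", "mahalanobis")
LINKAGES = ("average", "complete", "single")


def pairwise_distance(
    U_rows: np.ndarray, metric: str, ids: list[str] | None = None
) -> np.ndarray:
    """Symmetric n x n distance matrix over latent rows.

    euclidean = L2, cityblock = L1, cosine = 1 - u.v/(|u||v|); mahalanobis
    (using the latent covariance) is available behind the same interface.
    A zero-norm row under the cosine metric raises, naming the drug.
    """
    U_rows = np.asarray(U_rows, dtype=float)
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "cosine":
        norms = np.linalg.norm(U_rows, axis=1)
        bad = np.nonzero(norms == 0)[0]
        if bad.size:
            name = ids[bad[0]] if ids is not None else f"row {bad[0]}"
            raise ValueError(f"cosine distance undefined for zero-norm latent vector ({name})")
    if metric == "mahalanobis":
        cov = np.cov(U_rows, rowvar=False)
        VI = np.linalg.pinv(np.atleast_2d(cov))
        D = squareform(pdist(U_rows, metric="mahalanobis", VI=VI))
    else:
        D = squareform(pdist(U_rows, metric=metric))
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy node numbering.

    Leaves are 0..n-1; merge step s creates node n+s. ``merges`` holds
    (node_a, node_b, height, new_size) with node_a < node_b.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_ids: list[str]
    metric: str = "euclidean"
    linkage: str = "average"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def node_members(self) -> dict[int, frozenset[str]]:
        """Drug-id membership of every node (leaves and internal)."""
        n = self.n_leaves
        members: dict[int, frozenset[str]] = {
            i: frozenset([d]) for i, d in enumerate(self.leaf_ids)
        }
        for s, (a, b, _, _) in enumerate(self.merges):
            members[n + s] = members[a] | members[b]
        return members

    def to_linkage_matrix(self) -> np.ndarray:
        """scipy-format (n-1) x 4 linkage matrix."""
        return np.array([[a, b, h, sz] for a, b, h, sz in self.merges], dtype=float)

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        children: dict[int, tuple[int, int]] = {}
        for s, (a, b, h, _) in enumerate(self.merges):
            heights[n + s] = h
            children[n + s] = (a, b)

        def render(node: int, parent_h: float) -> str:
            blen = parent_h - heights[node]
            if node < n:
                return f"{self.leaf_ids[node]}:{blen:g}"
            a, b = children[node]
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{blen:g}"

        root = n + len(self.merges) - 1
        a, b = children[root]
        h = heights[root]
        return f"({render(a, h)},{render(b, h)});"


def agglomerate(
    D: np.ndarray,
    linkage: str = "average",
    leaf_ids: list[str] | None = None,
    metric: str = "euclidean",
) -> Dendrogram:
    """Lance-Williams agglomeration with a deterministic tie rule.

    At each step the active pair with minimum inter-cluster distance is
    merged; ties break on the lowest (node_a, node_b) pair. Supported
    linkages (single, complete, average) all yield non-decreasing merge
    heights.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 items to agglomerate")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    if len(leaf_ids) != n:
        raise ValueError("leaf_ids length must match distance matrix")

    # dist maps active node id -> {other active node id -> distance}
    dist: dict[int, dict[int, float]] = {
        i: {j: float(D[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    size = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        best: tuple[float, int, int] | None = None
        for a in dist:
            for b, d in dist[a].items():
                if a < b and (best is None or (d, a, b) < best):
                    best = (d, a, b)
        assert best is not None
        d_ab, a, b = best
        new = n + step
        new_size = size[a] + size[b]
        merges.append((a, b, d_ab, new_size))
        dist[new] = {}
        for k in list(dist):
            if k in (a, b, new):
                continue
            dak, dbk = dist[a][k], dist[b][k]
            if linkage == "single":
                dnk = min(dak, dbk)
            elif linkage == "complete":
                dnk = max(dak, dbk)
            else:  # average (UPGMA)
                dnk = (size[a] * dak + size[b] * dbk) / new_size
            dist[new][k] = dnk
            dist[k][new] = dnk
            del dist[k][a], dist[k][b]
        del dist[a], dist[b]
        size[new] = new_size
    return Dendrogram(merges=merges, leaf_ids=list(leaf_ids), metric=metric, linkage=linkage)


def hypergeom_tail(x: int, n_c: int, K: int, N: int) -> float:
    """Upper tail P[X >= x] for X ~ Hypergeometric(N, K, n_c), in log space.

    N = universe size, K = reference ("known") drugs in the universe,
    n_c = cluster size, x = reference drugs observed in the cluster.
    """
    if not (0 <= K <= N and 0 <= n_c <= N):
        raise ValueError(f"inconsistent hypergeometric arguments K={K}, n_c={n_c}, N={N}")
    if not (0 <= x <= min(n_c, K)):
        raise ValueError(f"x={x} outside [0, min(n_c={n_c}, K={K})]")
    if x <= max(0, n_c + K - N):
        return 1.0
    ks = np.arange(x, min(n_c, K) + 1)
    return float(np.exp(logsumexp(hypergeom.logpmf(ks, N, K, n_c))))


@dataclass
class EnrichmentResult:
    """One candidate cluster with its known-drug over-representation stats."""

    node_id: int
    members: frozenset[str]
    x: int        # known drugs in cluster
    n_c: int      # cluster size
    K: int        # known drugs in universe
    N: int        # universe size
    p_value: float
    q_value: float = float("nan")


def enriched_clusters(
    dendrogram: Dendrogram,
    known_set: set[str],
    alpha: float = 0.05,
    min_size: int = 3,
    max_size: int | None = None,
) -> list[EnrichmentResult]:
    """Internal nodes significantly enriched in known drugs.

    Every internal node with cluster size in [min_size, max_size] is
    scored with the hypergeometric upper tail against the leaf universe;
    Benjamini-Hochberg correction is applied across the evaluated nodes
    and nodes with q <= alpha are kept. Nested significant nodes collapse
    to the most significant (lowest-p) ancestor-descendant representative:
    within any chain of nested significant clusters only the one with the
    strongest known-drug over-representation is reported, while disjoint
    significant clusters are all kept.
    """
    if not known_set:
        raise ValueError("known_set must be non-empty")
    leaves = set(dendrogram.leaf_ids)
    if not known_set <= leaves:
        missing = sorted(known_set - leaves)
        raise ValueError(f"known drugs absent from dendrogram leaves: {missing}")
    N = dendrogram.n_leaves
    K = len(known_set)
    if max_size is None:
        max_size = N - 1
    members = dendrogram.node_members()
    cands: list[EnrichmentResult] = []
    for node in range(N, N + len(dendrogram.merges)):
        mem = members[node]
        n_c = len(mem)
        if not (min_size <= n_c <= max_size):
            continue
        x = len(mem & known_set)
        p = hypergeom_tail(x, n_c, K, N)
        cands.append(EnrichmentResult(node, mem, x, n_c, K, N, p))
    if not cands:
        return []
    reject, q, _, _ = multipletests([c.p_value for c in cands], alpha=alpha, method="fdr_bh")
    sig = []
    for c, rej, qv in zip(cands, reject, q):
        c.q_value = float(qv)
        if rej:
            sig.append(c)
    # collapse nested significant nodes: keep the most significant representative
    sig.sort(key=lambda c: (c.p_value, c.n_c, c.node_id))
    kept: list[EnrichmentResult] = []
    for c in sig:
        if not any(k.members <= c.members or c.members <= k.members for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: (c.p_value, c.node_id))
    return kept


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node_id": r.node_id,
                "members": ";".join(sorted(r.members)),
                "x": r.x,
                "n_c": r.n_c,
                "K": r.K,
                "N": r.N,
                "p": r.p_value,
                "q": r.q_value,
            }
            for r in results
        ],
        columns=["node_id", "members", "x", "n_c", "K", "N", "p", "q"],
    )


def consensus_hits(
    per_metric_hits: dict[str, set[str]] | list[set[str]],
    candidate_universe: set[str],
) -> set[str]:
    """Drugs recovered in enriched clusters under every metric, restricted
    to the ensemble-selected candidate universe."""
    sets = list(per_metric_hits.values()) if isinstance(per_metric_hits, dict) else list(per_metric_hits)
    if not sets:
        raise ValueError("need at least one per-metric hit set")
    inter = set(sets[0])
    for s in sets[1:]:
        inter &= set(s)
    return inter & set(candidate_universe)


__all__ = [
    "METRICS",
    "LINKAGES",
    "Dendrogram",
    "EnrichmentResult",
    "pairwise_distance",
    "agglomerate",
    "hypergeom_tail",
    "enriched_clusters",
    "enrichment_table",
    "consensus_hits",
]
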