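"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is written from the definitions, without touching the
package's implementation paths, so agreement is a genuine cross-check.
"""

import itertools

import numpy as np


def pearson_abs(x, y) -> float:
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    return abs(float((x * y).sum() / denom)) if denom > 0 else 0.0


def rank_auc(pos, neg) -> float:
    """All-pairs P(pos > neg), ties counted 1/2."""
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def score_a(net_succ, gene, expr_rows, network_genes, ts_genes):
    """Brute-force Score_A for one gene.

    net_succ: gene -> list of downstream neighbours; expr_rows: gene -> tumor
    expression vector; network_genes: co-expression network membership;
    ts_genes: genes in tumor-specific modules.
    """
    out = net_succ.get(gene, [])
    if not out or gene not in expr_rows:
        return None
    c_all = len(out)
    c_in = sum(1 for g in out if g in ts_genes)
    n_all = len(network_genes)
    n_in = len(ts_genes & network_genes)
    out_set = set(out)
    neg_genes = [g for g in network_genes if g != gene and g not in out_set]
    pos = [pearson_abs(expr_rows[gene], expr_rows[g]) for g in out if g in expr_rows]
    neg = [pearson_abs(expr_rows[gene], expr_rows[g]) for g in neg_genes if g in expr_rows]
    auc = rank_auc(pos, neg) if pos and neg else 0.5
    if c_in <= 0 or n_in <= 0:
        return {"auc": auc, "score": -np.inf, "c_in": c_in, "c_all": c_all}
    score = abs(auc - 0.5) * np.log2((c_in / c_all) / (n_in / n_all))
    return {"auc": auc, "score": float(score), "c_in": c_in, "c_all": c_all}


def bh_stepup(p):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def exact_ranksum_p_separated(n: int, m: int) -> float:
    """Two-sided exact p for complete separation with no ties: 2 / C(n+m, n)."""
    from math import comb

    return 2.0 / comb(n + m, n)


def complete_linkage_partitions(mat):
    """Brute-force agglomerative complete linkage on rows of ``mat``.

    Returns the list of partitions (as frozensets of frozensets) after each
    merge, built straight from the definition.
    """
    items = list(range(mat.shape[0]))
    d = {(i, j): float(np.linalg.norm(mat[i] - mat[j]))
         for i, j in itertools.combinations(items, 2)}

    def dist(a, b):
        return max(d[tuple(sorted((i, j)))] for i in a for j in b)

    clusters = [frozenset([i]) for i in items]
    partitions = []
    while len(clusters) > 1:
        best = min(
            ((dist(a, b), ai, bi) for ai, a in enumerate(clusters)
             for bi, b in enumerate(clusters) if ai < bi),
            key=lambda t: t[0],
        )
        _, ai, bi = best
        merged = clusters[ai] | clusters[bi]
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)] + [merged]
        partitions.append((best[0], frozenset(clusters)))
    return partitions
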