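"""Network-based epi-driver gene discovery.

The stage builds a tumor co-expression network (|Pearson r| over tumor
samples on log2(CPM+1)), partitions it into modules by average-linkage
hierarchical clustering of the distance 1 - |r|, flags modules whose
member-mean z-scored expression differs between tumor and normal as
tumor-specific, derives directed gene networks from metabolic reactions
(enzyme A feeds enzyme B when a product of A is a substrate of B) or from
PPI edges (weight >= 0.4, both directions), and scores each upstream gene A
with

    Score_A = |AUC_ROC - 0.5| * log2( (C_in / C_all) / (N_in / N_all) )

where C_in/C_all count A's downstream neighbours inside tumor-specific
modules vs all of A's downstream neighbours, N_in/N_all count
tumor-specific-module genes vs all genes in the co-expression network, and
AUC_ROC is the probability that a random downstream neighbour of A is more
strongly co-expressed with A (|Pearson r| over tumor samples) than a random
non-neighbour, ties counted 1/2.  Genes in the top ``key_fraction`` of
finite scores are key genes; epi-drivers are differentially expressed key
genes (in either network) with a significant methylation association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .differential import bh_adjust, log2_cpm
from .omics_io import CountMatrix, EdgeList, ReactionTable, SampleSheet, ValidationError

PPI_WEIGHT_CUTOFF = 0.4
DEFAULT_TAU = 0.6
DEFAULT_CUT_HEIGHT = 0.3
DEFAULT_MIN_MODULE_SIZE = 10
DEFAULT_KEY_FRACTION = 0.10


@dataclass
class CoexpressionModules:
    gene_to_module: dict[str, int]  # 0 = unassigned
    modules: dict[int, set[str]]
    tumor_specific: set[int]
    tau: float
    min_module_size: int
    network_genes: set[str]  # genes with >= 1 co-expression edge at tau
    n_dropped_constant: int = 0

    @property
    def tumor_specific_genes(self) -> set[str]:
        return set().union(*(self.modules[m] for m in self.tumor_specific)) if self.tumor_specific else set()


def build_coexpression_modules(
    counts: CountMatrix,
    samples: SampleSheet,
    tau: float = DEFAULT_TAU,
    min_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> CoexpressionModules:
    """Correlation network + hierarchical modules + tumor-specific flags."""
    tumor = [s for s in samples.tumor_samples() if s in counts.sample_ids]
    normal = [s for s in samples.table.index[samples.table["condition"] == "normal"]
              if s in counts.sample_ids]
    if len(tumor) < 3 or len(normal) < 3:
        raise ValidationError("need >= 3 tumor and >= 3 normal samples")
    expr = log2_cpm(counts)
    t_expr = expr[tumor]
    sd = t_expr.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    t_arr = t_expr.loc[keep].to_numpy()
    gene_ids = list(t_expr.index[keep])
    if len(gene_ids) < 2:
        raise ValidationError("fewer than 2 non-constant genes")

    corr = np.corrcoef(t_arr)
    acorr = np.abs(corr)
    np.fill_diagonal(acorr, 1.0)
    adj = acorr >= tau
    np.fill_diagonal(adj, False)
    network_genes = {g for g, deg in zip(gene_ids, adj.sum(axis=1)) if deg > 0}

    dist = np.clip(1.0 - acorr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=cut_height, criterion="distance")

    modules: dict[int, set[str]] = {}
    next_id = 1
    for lab in sorted(set(labels)):
        members = {gene_ids[i] for i in np.flatnonzero(labels == lab)}
        if len(members) >= min_size:
            modules[next_id] = members
            next_id += 1
    gene_to_module = {g: 0 for g in counts.gene_ids}
    for mid, members in modules.items():
        for g in members:
            gene_to_module[g] = mid

    # tumor-specific call: rank-sum on the per-sample mean of z-scored
    # member expression, tumor vs normal, BH over modules
    tumor_specific: set[int] = set()
    if modules:
        all_arr = expr.loc[gene_ids, tumor + normal].to_numpy()
        mu = all_arr.mean(axis=1, keepdims=True)
        s = all_arr.std(axis=1, ddof=1, keepdims=True)
        zs = np.where(s > 0, (all_arr - mu) / s, 0.0)
        idx = {g: i for i, g in enumerate(gene_ids)}
        pvals, mids = [], []
        for mid, members in sorted(modules.items()):
            rows = [idx[g] for g in sorted(members)]
            score = zs[rows].mean(axis=0)
            t_scores, n_scores = score[: len(tumor)], score[len(tumor):]
            pvals.append(float(stats.mannwhitneyu(t_scores, n_scores,
                                                  alternative="two-sided").pvalue))
            mids.append(mid)
        qvals = bh_adjust(pvals)
        tumor_specific = {mid for mid, q in zip(mids, qvals) if q < 0.05}

    return CoexpressionModules(
        gene_to_module=gene_to_module,
        modules=modules,
        tumor_specific=tumor_specific,
        tau=tau,
        min_module_size=min_size,
        network_genes=network_genes,
        n_dropped_constant=n_dropped,
    )


def build_directed_net(source: ReactionTable | EdgeList,
                       weight_cutoff: float = PPI_WEIGHT_CUTOFF) -> nx.DiGraph:
    """Directed gene network from reactions (product feeds substrate) or PPI."""
    g = nx.DiGraph()
    if isinstance(source, ReactionTable):
        g.graph["source"] = "metabolic"
        t = source.table
        for enzyme in t["enzyme_gene"].unique():
            g.add_node(enzyme)
        producers: dict[str, set[str]] = {}
        consumers: dict[str, set[str]] = {}
        for _, row in t.iterrows():
            for m in row["products"]:
                producers.setdefault(m, set()).add(row["enzyme_gene"])
            for m in row["substrates"]:
                consumers.setdefault(m, set()).add(row["enzyme_gene"])
        for m, ups in producers.items():
            for a in ups:
                for b in consumers.get(m, ()):  # a's product is b's substrate
                    if a != b:
                        g.add_edge(a, b)
        return g
    if isinstance(source, EdgeList):
        g.graph["source"] = "ppi"
        for _, row in source.table.iterrows():
            if row["weight"] >= weight_cutoff:
                g.add_edge(row["gene_a"], row["gene_b"])
                if not source.directed:
                    g.add_edge(row["gene_b"], row["gene_a"])
        return g
    raise ValidationError(f"unsupported network source {type(source)}")


def score_a_formula(auc: float, c_in: int, c_all: int, n_in: int, n_all: int) -> float:
    """|AUC - 0.5| * log2((C_in/C_all) / (N_in/N_all)); -inf when undefined."""
    if min(c_in, n_in) <= 0 or min(c_all, n_all) <= 0:
        return -np.inf
    return float(abs(auc - 0.5) * np.log2((c_in / c_all) / (n_in / n_all)))


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) with ties at 1/2 (Mann-Whitney AUC)."""
    scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(scores)
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0)
                 / (len(pos) * len(neg)))


def score_importance(
    net: nx.DiGraph,
    modules: CoexpressionModules,
    counts: CountMatrix,
    samples: SampleSheet,
    key_fraction: float = DEFAULT_KEY_FRACTION,
) -> pd.DataFrame:
    """Score_A for every gene with downstream neighbours.

    Genes with C_in = 0 (or an empty tumor-specific gene set) receive -inf
    and can never be key genes; key genes are the top ``key_fraction`` of
    finite scores (ties broken toward the lexicographically smaller gene id).
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("directed network is empty")
    tumor = [s for s in samples.tumor_samples() if s in counts.sample_ids]
    expr = log2_cpm(counts)[tumor]
    arr = expr.to_numpy()
    gene_idx = {g: i for i, g in enumerate(expr.index)}
    ts_genes = modules.tumor_specific_genes
    n_all = len(modules.network_genes)
    n_in = len(ts_genes & modules.network_genes)

    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    unit = centered / np.where(norms > 0, norms, 1.0)[:, None]  # unit rows: dot = Pearson r

    rows = []
    skipped = 0
    network_sorted = sorted(modules.network_genes)
    for gene in sorted(net.nodes):
        out = sorted(net.successors(gene))
        if not out:
            continue
        if gene not in gene_idx:
            skipped += 1
            continue
        c_all = len(out)
        c_in = sum(1 for g in out if g in ts_genes)
        out_set = set(out)
        neg_genes = [g for g in network_sorted if g != gene and g not in out_set]
        pos_scored = [g for g in out if g in gene_idx]
        neg_scored = [g for g in neg_genes if g in gene_idx]
        if pos_scored and neg_scored:
            gvec = unit[gene_idx[gene]]
            pos_r = np.abs(unit[[gene_idx[g] for g in pos_scored]] @ gvec)
            neg_r = np.abs(unit[[gene_idx[g] for g in neg_scored]] @ gvec)
            auc = _rank_auc(pos_r, neg_r)
        else:
            auc = 0.5
        rows.append((gene, auc, c_in, c_all, n_in, n_all,
                     score_a_formula(auc, c_in, c_all, n_in, n_all)))

    out_df = pd.DataFrame(
        rows, columns=["gene", "auc", "c_in", "c_all", "n_in", "n_all", "score_a"]
    )
    out_df.attrs["skipped_no_expression"] = skipped
    finite = out_df[np.isfinite(out_df["score_a"])]
    key = set()
    if len(finite):
        k = max(1, int(np.ceil(key_fraction * len(finite))))
        ranked = finite.sort_values(["score_a", "gene"], ascending=[False, True])
        key = set(ranked["gene"].head(k))
    out_df["key_gene"] = out_df["gene"].isin(key)
    return out_df


def call_epidrivers(
    de: pd.DataFrame,
    scores_met: pd.DataFrame | None,
    scores_ppi: pd.DataFrame | None,
    assoc_flags: dict[str, bool] | pd.Series,
    combine: str = "union",
) -> pd.DataFrame:
    """Intersect DE genes, network key genes and methylation association.

    epi_driver <=> is_de AND (key in metabolic net OR key in PPI net, or AND
    of both when combine='intersection') AND has_meth_assoc.
    """
    if combine not in ("union", "intersection"):
        raise ValidationError(f"unknown combine mode {combine!r}")
    de_genes = set(de.loc[de["significant"], "gene_id"]) if len(de) else set()

    def key_set(scores):
        if scores is None or len(scores) == 0:
            return set()
        return set(scores.loc[scores["key_gene"], "gene"])

    key_met, key_ppi = key_set(scores_met), key_set(scores_ppi)
    if isinstance(assoc_flags, pd.Series):
        assoc_flags = assoc_flags.to_dict()
    assoc_genes = {g for g, flag in assoc_flags.items() if flag}

    universe = sorted(de_genes | key_met | key_ppi | assoc_genes)
    rows = []
    for gene in universe:
        is_de = gene in de_genes
        km, kp = gene in key_met, gene in key_ppi
        net_ok = (km and kp) if combine == "intersection" else (km or kp)
        has_assoc = gene in assoc_genes
        rows.append((gene, is_de, km, kp, has_assoc, is_de and net_ok and has_assoc))
    return pd.DataFrame(
        rows,
        columns=["gene", "is_de", "is_key_metabolic", "is_key_ppi", "has_meth_assoc", "epi_driver"],
    )


def overlap_significance(set_a: set, set_b: set, universe: set) -> dict:
    """One-sided (enrichment) Fisher exact test of the overlap of two sets."""
    if not universe:
        raise ValidationError("universe must be non-empty")
    if not (set(set_a) <= set(universe) and set(set_b) <= set(universe)):
        raise ValidationError("set_a and set_b must be subsets of the universe")
    a, b, u = set(set_a), set(set_b), set(universe)
    ov = len(a & b)
    table = [[ov, len(a) - ov], [len(b) - ov, len(u) - len(a) - len(b) + ov]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return {"overlap": ov, "p": float(p)}
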